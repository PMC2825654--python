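"""Dark-field extraction by varying the collimation aspect ratio.

Simulates the reference water phantom (four cubes that differ only in
their Rayleigh/Compton split) through a high-aspect (50) and a low-aspect
(10) anti-scatter grid with one matched photon stream, subtracts the two
images, and reports the mean dark-field signal over each cube's shadow.
The signal should rank with the cubes' Rayleigh fractions even though all
five materials share the same total attenuation.
"""

from darkscatter import (
    CollimatorSpec,
    DetectorBank,
    DetectorChannel,
    DetectorGrid,
    ScatterPhysics,
    SimulationConfig,
    build_table1_phantom,
    darkfield_subtract,
    region_stats,
    simulate,
)

phantom = build_table1_phantom()
physics = ScatterPhysics.calibrated(photon_energy_kev=50.0)
grid = DetectorGrid(n_u=60, n_v=60, pitch=0.2)
bank = DetectorBank(grid, [
    DetectorChannel("IH", CollimatorSpec(50.0), distance_cm=2.5),
    DetectorChannel("IL", CollimatorSpec(10.0), distance_cm=2.5),
], phantom_exit_z=phantom.z_max)

n = 4_000_000
images, tally = simulate(SimulationConfig(n_photons=n, seed=7), phantom,
                         bank, physics)
print(f"launched {tally.launched}, absorbed {tally.absorbed}, "
      f"escaped {tally.escaped}")
print(f"escaped by class: {tally.escaped_by_class}")

darkfield = darkfield_subtract(images.total("IL"), images.total("IH"))
stats = region_stats(darkfield, phantom, grid, margin_cm=1.5)
order = ["cube1", "cube2", "water", "cube3", "cube4"]
beta = {"cube1": 0.0193, "cube2": 0.0385, "water": 0.0769,
        "cube3": 0.1429, "cube4": 0.2858}
print("\nregion   beta     dark-field mean (counts/photon)")
for name in order:
    print(f"{name:<8} {beta[name]:<8} {stats.loc[name, 'mean']:.3e}")
print("-> the dark-field means track the Rayleigh fraction even though all")
print("   five materials attenuate identically.  At this quick 4e6-photon")
print("   run the closest pair (cube1 vs cube2, a ~3% contrast) can swap")
print("   within counting noise; ~5e7 photons resolve the full ranking.")
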