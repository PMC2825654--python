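"""Dark-field extraction without changing the collimator.

The same small-angle information can be read out by moving the detector:
the primary beam (parallel geometry) is distance-invariant, while the
scattered flux per pixel dilutes and blurs with distance.  Subtracting a
17.5 cm acquisition from a 2.5 cm acquisition at the same aspect ratio 10
again isolates the small-angle signal.
"""

from darkscatter import (
    CollimatorSpec,
    DetectorBank,
    DetectorChannel,
    DetectorGrid,
    ScatterPhysics,
    SimulationConfig,
    build_table1_phantom,
    distance_subtract,
    region_stats,
    simulate,
)

phantom = build_table1_phantom()
physics = ScatterPhysics.calibrated(50.0)
grid = DetectorGrid(60, 60, 0.2)
bank = DetectorBank(grid, [
    DetectorChannel("near", CollimatorSpec(10.0), distance_cm=2.5),
    DetectorChannel("far", CollimatorSpec(10.0), distance_cm=17.5),
], phantom_exit_z=phantom.z_max)

n = 8_000_000
images, _ = simulate(SimulationConfig(n_photons=n, seed=13), phantom, bank,
                     physics)
primary_near = images.class_image("near", "primary")
primary_far = images.class_image("far", "primary")
print("primary image is distance-invariant: mean near = "
      f"{primary_near.mean():.4e}, far = {primary_far.mean():.4e}")

diff = distance_subtract(images.total("near"), images.total("far"))
stats = region_stats(diff, phantom, grid, margin_cm=1.5)
print("\nnear - far region means (counts/photon):")
for name in ("cube1", "cube2", "water", "cube3", "cube4"):
    print(f"  {name:<8} {stats.loc[name, 'mean']:+.3e}")
print("-> low-Rayleigh cubes give negative signal (they scatter less than")
print("   the blurred surroundings), high-Rayleigh cubes positive — the")
print("   same ranking the aspect-ratio subtraction yields.  As there, the")
print("   closest pairs need ~5e7 photons to separate beyond noise.")
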