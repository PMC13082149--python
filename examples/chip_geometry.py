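"""Channel taper geometry and acquisition-plan accounting.

Builds the two shipped channel designs, samples their taper profiles, plans
FOV coverage of a 40-channel well, and counts the images produced by the
minimal and full acquisition plans.
"""

from wormdart.chip import (
    d1_geometry, l4_geometry, height_profile_at, fovs_required,
    minimal_plan, full_plan, plan_image_count, default_chip_map,
)

chip = default_chip_map()
print(f"chip: {chip.n_wells} wells x {chip.channels_per_well} channels "
      f"= {chip.total_channels} trapping channels")

for geo in (d1_geometry(), l4_geometry()):
    print(f"\n{geo.design_name} taper (width x height, um):")
    for s in (0.0, 1500.0, geo.channel_length):
        w, h = height_profile_at(geo, s)
        print(f"  s = {s:6.0f} um -> {w:5.1f} x {h:5.1f}")

n_fov = fovs_required(40, chip.channel_pitch, 1300.0)
print(f"\nFOV planning: {int(1300 // chip.channel_pitch)} channels fit one "
      f"1.3 mm FOV; a 40-channel well needs {n_fov} FOVs")

for name, plan in (("minimal", minimal_plan()), ("full", full_plan())):
    print(f"{name} plan: {plan_image_count(plan):,} images per chip "
          f"({plan.volumes_per_fov} volume(s) x {plan.z_slices} z-slices "
          f"x {plan.fovs_per_well} FOVs x {plan.wells} wells + fiduciaries)")

# The two totals correspond to the single-timepoint protocol and the
# timelapse protocol (1 static + 5 timelapse volumes) respectively.
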