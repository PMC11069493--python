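"""Constrained searches: hemispheric symmetry, cascade nesting, mirroring.

The cascade runs nested optimizations for decreasing channel counts, each
stage restricted to the best combination the previous stage found; the
symmetry constraint keeps equal channel counts in both hemispheres; and
mirror expansion turns an asymmetric combination into a symmetric cap.
"""

import numpy as np

from esiopt import (
    ChannelMask,
    ConstraintSpec,
    GaConfig,
    ShellModel,
    SimConfig,
    add_noise,
    build_montage,
    build_source_space,
    check_constraints,
    forward_gain,
    lambda2_for_snr,
    mirror_expand,
    run_cascade,
    simulate_epochs,
)

labels = ["F7", "F3", "Fz", "F4", "F8", "FC5", "FC1", "FC2", "FC6",
          "T7", "C3", "Cz", "C4", "T8", "CP5", "CP1", "CP2", "CP6", "P3", "P4"]
montage = build_montage("10-10").subset(labels)
src = build_source_space(5, seed=2)
lf = forward_gain(ShellModel(), montage, src)
epochs, _ = simulate_epochs(lf, np.arange(10), SimConfig(), seed=3, background=False)
epochs = add_noise(epochs, 5.0, seed=4)
cfg = GaConfig(population_size=20, n_generations=15, seed=5,
               lambda2=lambda2_for_snr(lf, 5.0))

staged = run_cascade(lf, epochs, counts=(8, 5, 3), cfg=cfg)
print("cascade search (each stage searches inside the previous best mask):")
for count, (best, _) in staged.items():
    print(f"  {count} ch: {best.mean_loc_error:5.2f} mm  "
          f"{','.join(best.mask.labels(montage))}")

best3 = staged[3][0].mask
expanded = mirror_expand(best3, montage)
print(f"mirror expansion of the 3-channel set: "
      f"{','.join(best3.labels(montage))} -> {','.join(expanded.labels(montage))}")
print(f"expanded set satisfies the symmetry constraint: "
      f"{check_constraints(expanded, ConstraintSpec(symmetric=True), montage)}")
print("Nested masks make a practical electrode cap family: unplug channels "
      "to step down from 8 to 5 to 3 without repositioning anything.")
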