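"""Register a synthetic restained section pair and measure the accuracy.

Builds a 256 x 256 pair at 4 um/px whose two images show the same
nucleus-like structures under different stain responses, deformed by a
known smooth displacement field (5 px bumps).  Runs the three-step
pipeline and prints the median landmark error after each step.
"""

import numpy as np

import histovar as hv

SPACING_UM = 4.0
EXTENT_UM = (255 * SPACING_UM, 255 * SPACING_UM)

spec = hv.SynthSpec(seed=7, pair_kind="restained")
spec.deformation = hv.smooth_deformation(
    amplitude_px=5.0, sigma_px=40.0, seed=11, extent_um=EXTENT_UM,
    spacing_um=SPACING_UM)
pair = hv.make_pair(spec)

config = hv.RegistrationConfig()
config.prealign.target_spacing_um = 32.0  # ~8x downsampled prealignment
config.deformable.grid_nodes = (17, 17)   # ~64 um node spacing

result = hv.run_pipeline(pair.reference, pair.template, config)

print("median landmark error (MTRE), micrometers:")
print(f"  before registration : "
      f"{hv.compute_tre(pair.landmarks).mtre_um:8.3f}")
for name, tf in (("after prealignment", result.rigid),
                 ("after affine      ", result.affine),
                 ("after deformable  ", result.deformable)):
    rep = hv.compute_tre(pair.landmarks, tf)
    print(f"  {name} : {rep.mtre_um:8.3f}")
print(f"fold count of final deformation: "
      f"{result.diagnostics['fold_count']}")
print()
print("Each step should cut the error: the rigid step removes the bulk "
      "misalignment, the affine step the global linear part, and the "
      "deformable step the local bumps; zero folds means the final map "
      "never inverts orientation (anatomically plausible).")
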