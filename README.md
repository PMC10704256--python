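# histovar

Variational registration of whole-slide histology images.

Serial sections of the same tissue block — either *restained* sections
(one physical section stained, scanned, bleached, restained and
rescanned) or *consecutive* sections (neighboring ~4 μm slices, each
with its own stain) — must be spatially aligned before their signals can
be combined, e.g. to relate immunohistochemical markers to H&E
morphology. The two images of such a pair look radically different in
intensity (different stains) while sharing most of their structure, and
tissue handling introduces both large rigid misplacement (sections land
on the slide in arbitrary orientation) and smooth nonlinear distortion.

`histovar` implements a three-step energy-minimizing pipeline for this
problem, for image analysts working with bright-field slide scans:

1. **Rigid prealignment.** Centers of mass (intensity-weighted) of both
   images are matched; an exhaustive search over `N_rot` equidistant
   rotation angles φ_k = 2πk/N_rot seeds local rigid optimizations, and
   the angle with the smallest image distance wins. This escapes the
   upside-down local minima that defeat purely local methods.
2. **Affine registration.** Multilevel (coarse-to-fine) Gauss–Newton
   over the 6 affine parameters.
3. **Deformable registration.** The displacement field u is discretized
   on a nodal control-point grid (bilinear interpolation between nodes,
   y(x) = x + u(x)) and optimized with multilevel L-BFGS.

All three steps minimize the **normalized gradient fields (NGF)**
distance, which scores gradient *alignment* rather than intensity
agreement and is therefore stain-insensitive:

    NGF(R, T, y) = (h²/2) Σ_i  1 − ( ⟨∇T(y(x_i)), ∇R(x_i)⟩_ε /
                                     (‖∇T(y(x_i))‖_ε ‖∇R(x_i)‖_ε) )²

with ⟨a,b⟩_ε = aᵀb + ε², ‖a‖_ε = √(aᵀa + ε²), pixel size h, and edge
parameter ε separating real edges from noise. The deformable step adds
curvature regularization,

    J(y) = NGF(R, T, y) + α · CURV(y),
    CURV(y) = (h²/2) Σ_i |Δ u₁(x_i)|² + |Δ u₂(x_i)|²,

with Δ the five-point discrete Laplacian (Neumann boundary conditions):
second-order smoothness that leaves affine motion free and suppresses
folds. Accuracy is evaluated as the **median target registration error**
MTRE = median_k ‖y(r_k) − t_k‖₂ over manually placed landmark pairs
(r_k, t_k), in micrometers.

Default parameters: ε = 0.1 (steps 1–2), ε = 1.0 (step 3), α = 0.1,
N_rot = 32, 4 prealignment levels at ~200 μm/px, 257×257 control nodes.

A seeded synthetic generator (`histovar.synthfix`) renders
nucleus-like sections under two stain responses, with optional
structural dropout (consecutive-like pairs) and known rigid / affine /
smooth ground-truth deformations with exact landmark pairs — so the
whole pipeline is testable at desk scale without slide downloads.

## Worked example

`examples/01_register_synthetic_pair.py` builds a restained-like pair
(256×256 px at 4 μm/px) deformed by a smooth field of 5 px bumps,
registers it, and prints:

```
median landmark error (MTRE), micrometers:
  before registration :    7.163
  after prealignment :    6.079
  after affine       :    3.418
  after deformable   :    0.635
fold count of final deformation: 0
```

Each step cuts the error — prealignment removes bulk misplacement, the
affine step the global linear part, the deformable step the local
distortion, ending at 0.16 px — and the zero fold count certifies that
the final deformation never inverts orientation. The other examples
sweep registration resolution (`02_resolution_sweep.py`) and show the
landmark CSV round trip and TRE arithmetic (`03_landmark_evaluation.py`).

A thin CLI wraps the same API:

```sh
histovar synth --seed 3 --kind restained --deformation smooth --out pair/
histovar register --reference pair/reference.tiff --template pair/template.tiff \
    --spacing-um 4.0 --out reg/
histovar evaluate --transform reg/transform_deformable.json \
    --landmarks-ref pair/landmarks_ref.csv \
    --landmarks-template pair/landmarks_tmpl.csv --spacing-um 4.0
```

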