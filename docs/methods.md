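# Methods

`nanovote` classifies the polarization state of single adherent
macrophages (resting M0, pro-inflammatory M1, pro-healing M2) from AFM
force-volume maps. This note records the models, the numerical choices,
and what the synthetic data generator does and does not emulate.

## Contact model and channel extraction

Each pixel of a force-volume map is one indentation event. The approach
segment is modelled as zero force up to the contact point, then the Hertz
force for a rigid sphere (radius R) on an incompressible elastic layer of
height h over a rigid support, with the finite-thickness polynomial
correction:

    F(d) = (4/3) E sqrt(R) d^(3/2) / (1 - nu^2)
           * [1 + c1 chi + c2 chi^2 + c3 chi^3 + c4 chi^4],
    chi = sqrt(R d) / h.

chi is defined with sqrt(R d) so that it is dimensionless; E is the
*effective* Young's modulus of the cell. Three coefficient sets are
shipped: `bonded` (sample firmly attached to the support), `free`
(frictionless interface), and the default `mean` set
(1.009, 1.032, 0.578, 0.0048) — adherent cells are between the two ideal
boundary conditions. The default Poisson ratio is 0.5 (incompressible
cell), configurable on `ProbeSpec`.

Four channels are extracted per pixel:

* **MechL** — E fitted on the shallow indentation window, 0–30 % of the
  maximum depth; sensitive to superficial cytoskeleton.
* **MechH** — E fitted on the deep window, 70–100 %; sensitive to deeper
  structure but convoluted with the shallow layers (on two-layer samples
  it lands between the shallow and deep moduli, as it should).
* **Adh** — magnitude of the retract-curve minimum after aligning the
  retract baseline at zero force; reported non-negative.
* **Morpho** — zero-force height: the topography recorded at maximum
  force plus the indentation length. The substrate defines height 0.

Because F is linear in E once d and h are fixed, each window fit is an
exact closed-form least-squares solution; no iteration is needed and the
estimate is reproducible to machine precision.

### Contact-point detection

The non-contact baseline is found by histogramming the approach forces
(64 bins by default): the baseline appears as a dominant, sharply defined
peak. Its mean and width are estimated with iterative 4-sigma clipping
(a plain peak-bin estimate is contaminated by early-contact samples).
The initial contact estimate is the first sample exceeding w·sigma above
the aligned baseline (w = 2 by default). A curve whose histogram has no
such peak — e.g. an all-contact curve — raises a detection error and the
pixel is flagged invalid.

A Hertz-like onset (F ~ d^(3/2)) crosses the w·sigma threshold several
samples *after* true contact, so the estimate is refined below the
threshold:

* **Map processing** (reference probe altitude known): profiled least
  squares. For each candidate contact position z0 on a 2 nm grid
  (refined to 0.25 nm around the minimum, with parabolic interpolation),
  the local height is h = A − z0, the best-fitting E is computed in
  closed form, and the candidate with the smallest residual wins.
  Baseline samples just before the crossing are included so that
  too-early candidates are penalised. The fit window starts at 5 % of
  the maximum force and is then widened towards 30 % only while the data
  remain within 5 % of the single-modulus prediction — on layered
  samples, where a stiffer deep layer bends the curve upward, the window
  stays shallow and the contact estimate stays unbiased.
* **Generic curves** (no altitude metadata): quadratic extrapolation of
  F^(2/3) versus displacement to zero force over the 10 %-of-maximum
  window.

The refined contact is continuous (sub-sample); the integer
`contact_index` is kept for bookkeeping. On noiseless single-layer
curves the whole inverse pipeline then recovers the generating modulus to
better than 0.1 %; at 0.01 nN force noise (the generator default) the
contact lands within ±2 samples of truth on >95 % of cell pixels, and at
0.05 nN the median modulus error stays under 5 %.

## Pixel table and spatial features

A per-cell mask is the largest 4-connected component of
Morpho > 200 nm (threshold configurable); pixels whose contact detection
or fits failed are excluded from the mask and from everything downstream.
The cell centre is the Morpho-weighted centroid. Two normalized spatial
features are attached to every mask pixel:

* **ND** = Euclidean distance to the centre / maximum such distance in
  the cell (the farthest pixel has ND = 1; a single-pixel cell gets 0).
* **NDR** = 1-based ascending rank of that distance / pixel count, with
  ties broken by row-major pixel order, so the NDR multiset of an
  n-pixel cell is exactly {1/n, …, 1} (a single-pixel cell gets 1).

ND and NDR vary pixel-to-pixel, so they preserve positional information
without collapsing the pixel dataset back into one row per cell the way
whole-cell descriptors (area, volume, mean modulus) would. At the cell
centre both features degenerate towards their minimum (−1 after
normalization); the pixel-vote maps inherit the resulting small central
bias, which is reproduced rather than corrected.

Splitting into train/validation/test (0.6/0.2/0.2, largest-remainder
rounding) happens at the *cell* level before pixel expansion, so no
pixel of one cell can appear in two splits. Features are min-max scaled
to [−1, 1] with statistics learned from the training split only and
applied unchanged elsewhere (values outside the training range
extrapolate past ±1 and are not clipped); a global-fit mode exists for
strict replication attempts but leaks test statistics and is off by
default.

## Classifier

A fully connected network: 6 inputs, seven ReLU hidden layers of widths
(24, 24, 24, 24, 24, 16, 46), 3-way softmax output — 3891 trainable
parameters. Training: Adam (lr 1e-3), batch 32, categorical
cross-entropy plus L2 penalty (1e-4), inverted dropout 0.2 on hidden
activations, at most 200 epochs with early stopping on validation loss
(patience 10, best weights restored). One integer seed drives
initialisation, shuffling and dropout, and the implementation is plain
numpy, so a run is bit-reproducible on a single thread. All widths and
hyper-parameters are configurable; the depth contract (exactly seven
hidden layers) can be relaxed with `strict_depth=False`.

## Voting

Each pixel votes for its argmax class with weight
W(x) = alpha (Morpho(x) − beta)^gamma + C; the defaults
alpha = 0, gamma = 0, C = 1 give unit weights (plain plurality), keeping
the cell decision free of empirical tuning. beta is the substrate height,
0 by convention. An exact tally tie sets a flag and is broken by summed
weighted softmax probability, then by lowest class index — deterministic
by construction.

The theoretical voting accuracy treats pixel predictions as independent
with probabilities (p0, p1, p2) for the correct and two wrong classes:
the probability that the correct class wins a strict plurality among m
pixels is the exact sum of multinomial probabilities over outcomes
(r, w1, w2) with r > max(w1, w2). Ties count as failures — a
conservative convention matching the tie flag. Terms are evaluated in
log space (lgamma), so the enumeration is stable at least to m = 500,
where the full multinomial sum is 1 within 1e-10. Real pixel predictions
are spatially correlated, so the independent-pixel accuracy is an
idealisation; it explains why ~75 % per-pixel accuracy already yields
>99.9 % cell accuracy at ~20 pixels. When only per-class accuracies are
known (a confusion-matrix diagonal), the `even_split` helper assigns the
error mass equally to the two wrong classes.

## Permutation feature importance

Each feature column of the (normalized) test set is shuffled across the
whole test set; the mean absolute difference between new and original
softmax probability vectors, averaged over records, classes and shuffle
rounds, measures the disturbance; normalising across features gives
importances that sum to 1. MAE is computed on probabilities rather than
hard labels so small systematic shifts register. The production default
is 20 000 rounds; a few hundred already give stable rankings at desk
scale (estimates at 50 vs 400 rounds agree within Monte-Carlo error in
the test suite). A per-cell permutation mode (shuffling within cells)
exists behind a flag.

## Synthetic force-volume generator

No public force-volume dataset of polarized macrophages exists, so every
stage is validated against a forward simulator whose defaults encode the
study conditions: 32×32 grids, ramp 8000 nm, setpoint 7 nN, 512 samples
per segment, force noise 0.01 nN, probe R = 5000 nm, k = 0.2 N/m,
adhesion drawn around 0.2–0.5 nN.

Each cell is a smooth dome h = H(1 − rho²)^1.5 over a jittered, randomly
oriented elliptical footprint on an exactly-zero substrate. Phenotype
contrasts follow the reported phenomenology; magnitudes not stated
anywhere were fixed once at values typical for live macrophages:

| profile | footprint semi-axes (px) | max height (nm) | shallow E (Pa) | periphery × |
|---------|--------------------------|-----------------|----------------|-------------|
| M0      | 9 × 8                    | 5000            | 150            | 1.3         |
| M1      | 13 × 12                  | 3500            | 600            | 1.5         |
| M2      | 11 × 4.5 (elongated)     | 4000            | 250            | 1.8         |

The deep modulus is 2× the shallow one; spatial lognormal noise
(sigma 0.25) roughens the modulus fields; the periphery multiplier
raises the rim modulus (migrating macrophages concentrate actin at the
edge). Adhesion is drawn identically for all phenotypes
(N(0.30, 0.06) nN, truncated at 0.05) — a non-functionalised probe shows
no phenotype-specific adhesion, so the feature is uninformative by
construction and should rank last in importance. A `hard` profile set
with overlapping moduli (180/260/220 Pa, noise sigma 0.45) exercises the
misclassification paths.

Curves are forward-generated from the contact model with a two-layer
modulus: shallow E up to 50 % of the final depth, blending linearly to
the deep E at full depth (blend point configurable). The maximum depth
solves F = setpoint; the layer cannot be indented past 95 % of its
height, beyond which a stiff linear wall (5 nN/nm) stands in for the
substrate — thin soft rim pixels therefore show "bottom-out" stiffening,
as real periphery pixels do. The retract mirrors the approach with a
Gaussian pull-off well of depth equal to the adhesion truth (width
150 nm) centred at the contact point. The substrate is glass-like
(2 GPa), indenting < 0.1 nm at the setpoint. A pixel whose setpoint
cannot be reached within the ramp is flagged, mimicking real acquisition
failures.

What the generator does **not** emulate: viscoelastic hysteresis and
rate dependence, thermal drift, tilted or rough substrates, touching
cells, probe contamination, and spatially correlated noise. Passing the
end-to-end tests therefore shows the *pipeline* is correct and the
method behaves as designed under its own assumptions — not that the
stated accuracies transfer to any particular real instrument or cell
line.

## Problem sizes and determinism

The test suite validates the full pipeline on 90 cells (30 per
phenotype) at 32×32 resolution with seed 0 — about 21 000 mask pixels —
chosen to mirror a realistic "10–15 maps per sample over three
conditions" campaign while remaining a desk-scale computation (the whole
run takes on the order of a minute). Every stochastic component (cell
draws, curve noise, splits, network training, permutation rounds) is
driven by explicit integer seeds; rerunning a configuration reproduces
every artifact exactly.

## Known limitations

* The independent-pixel voting theory ignores spatial correlation of
  errors; real cells need more pixels than the theoretical threshold.
* MechH is a windowed effective modulus, not a deconvolved deep-layer
  modulus.
* The adaptive contact-window extension assumes stiffness does not
  *decrease* with depth; a markedly softer deep layer would leave the
  narrow window in use (correct but noisier).
* Segmentation assumes one cell per map (largest connected component);
  touching cells are out of scope.
* At 0.05 nN noise on strongly layered soft curves, contact bias grows
  and shallow-modulus errors can exceed 10 %; the default acquisition
  noise (0.01 nN) is well inside the safe regime.
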