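# Methods

This note records the models, conventions and design choices behind
`meatspec`, in the spirit of a software methods section: what is computed,
under which assumptions, and where the genuinely open choices were decided.

## Data model

A `SpectralDataset` is a scan × channel matrix with per-scan metadata
(sample id, species ∈ {lamb, beef, chicken, pork}, form ∈ {intact, ground},
replicate 1–6). Two sensor layouts are supported: Vis-NIR rows are 1200
channels built by concatenating two 600-channel derived spectra per scan
(the acquisition geometry of handheld Vis-NIR devices with dual light
sources), NIR rows are 252 channels on 900–1700 nm. Some handheld NIR
instruments nominally report 256 variables per measurement while the
delivered data matrix carries 252 wavelength columns; the package treats the
data matrix (252) as authoritative. Wavelength grids travel with the data
and are reconstructed from CSV headers on read; mixing grids in one
operation is an error. Replicate counts below 6 are accepted (real
campaigns lose scans); all replicate aggregation uses the median, which is
defined for any count.

## Synthetic campaigns

No public spectra exist for this application, so all development and testing
runs on simulated campaigns. Each species/sensor profile is a smooth
baseline (a low-order polynomial in scaled wavelength) plus Gaussian
absorption bands:

* visible block: haem-pigment (myoglobin/haemoglobin) bands at 418, 546 and
  578 nm whose heights scale with a per-species pigment level
  (beef 1.0 > lamb 0.8 > pork 0.55 > chicken 0.30), a small 760-nm
  deoxy-myoglobin feature, and the 970-nm water band;
* NIR-emphasis block and NIR sensor: C–H bands near 930/1200 nm scaling
  with a per-species fat level (pork 0.9 > lamb 0.7 > beef 0.5 >
  chicken 0.35) and the O–H first-overtone water band at 1450 nm shared by
  all species.

Pigment contrasts are large and fat contrasts small, so Vis-NIR campaigns
are by construction easier to separate than NIR campaigns — the ranking the
two sensor types show in practice. The default effect sizes were fixed once
to give realistic-but-imperfect one-class separation (screening AUROCs
roughly 0.9–1.0 for Vis-NIR, lower for NIR) and are configuration, not
constants.

Noise model, per sample and replicate:

| parameter | default | meaning |
|---|---|---|
| `sample_latent_sd` | 0.08 | relative band-height jitter drawn once per sample (animal-to-animal variation) |
| `scatter_mult_sd` | 0.08 | per-replicate multiplicative scatter `1+N(0,·)` |
| `scatter_add_sd` | 0.02 | per-replicate additive offset |
| `noise_sd` | 0.003 | independent channel noise |
| `intact_extra_replicate_sd` | 0.05 | extra per-replicate band jitter for intact meat only |

Intensities are in arbitrary units (baseline ≈ 0.3–0.6). All randomness
flows through one `numpy.random.Generator` with the PCG64 bit generator;
equal seeds give bit-identical datasets on any platform.
`paper_shaped_datasets` produces the two reference campaign shapes:
Vis-NIR 157 samples (lamb 37, beef 40, chicken 40, pork 40) × 6 = 942 rows ×
1200 channels, and NIR 161 samples (lamb 41, beef 48, chicken 40,
pork 32) × 6 = 966 rows × 252 channels.

What the generator does **not** emulate: instrument response functions,
wavelength-dependent resolution, temperature drift, chemical interferents,
breed/cut/age composition effects, and any radiative-transfer realism.
Passing tests therefore demonstrate that the algorithms behave correctly on
data with the assumed statistical structure — not that any particular
accuracy will be reached on real meat spectra.

## Pre-processing operators

All operators act row-wise and deterministically; stateful operators
(MSC/EMSC reference, column centering statistics, OSC components) learn
their state from training rows only, so chains are leak-free by
construction. Chains serialise to canonical strings
(`snv|gapseg(gap=5,order=2,seg=5)`) used as combination ids in screening.

Conventions worth pinning:

* **SNV** standardises each row with the sample standard deviation (ddof 1);
  zero-variance rows are an error naming the row.
* **MSC** fits x = a + b·ref per row against the training-mean reference and
  returns (x−a)/b; the median-ratio mode returns x / median(x/ref); the
  weighted mode takes an explicit channel-weight vector (uniform weights
  reduce exactly to the mean-reference fit).
* **EMSC** adds polynomial terms in the channel position affinely scaled to
  [−1, 1] (equivalent to scaled wavelength on evenly spaced grids, and
  well-conditioned); degree 0 reduces exactly to MSC.
* **Savitzky–Golay** uses polynomial-fit extrapolation inside the edge
  windows; derivatives are per channel step.
* **Gap-segment derivatives** (Norris-style) use segment means s(i) over a
  window centred at i. Order 1: D(i) = [s(i+h) − s(i−h)]/(2h) with
  h = ⌈gap/2⌉ + ⌊segment/2⌋; order 2: D(i) = [s(i+g) − 2s(i) + s(i−g)]/g²
  with g = gap + segment − 1. These stencils are pinned by the property
  tests (second difference of any quadratic is constant; first difference of
  a ramp is its slope). Channels whose stencil leaves the row are trimmed
  and the validity mask is exposed.
* **OSC** components start from the first principal score of the (deflated)
  matrix, are projected onto the orthogonal complement of the class
  indicators, and re-expressed through spectral weights by least squares so
  new rows are filtered by projection alone. For spectra (channels ≫ rows)
  the re-expression is exact and scores are numerically orthogonal to every
  indicator column; for tall matrices it is a least-squares approximation.
* **DWT features** interpolate each row linearly onto 128 points and apply a
  dyadic wavelet transform with periodic extension. "Short Daubechies" is
  the 2-tap Daubechies (Haar) wavelet, "LA8" the 8-tap least-asymmetric
  symlet; both are configurable. Only detail coefficients are returned
  (levels 5–7 → 7 features for Haar, levels 3–5 → 28 for LA8): details are
  invariant to constant offsets, which is the property the screening
  exploits; approximation coefficients are deliberately excluded.
* **Quarter subsets** are floor-balanced contiguous quarters of the channel
  axis.

## Sample-set partitioning and cross-validation

Replicate scans of one sample never straddle a partition or fold; all
partitioning operates on samples and expands to rows at the end. Duplex and
Kennard–Stone work on one representative vector per sample — the
SNV-corrected mean of its replicates (SNV first, so scatter does not
dominate the distances; this standardisation is a package default and
configurable). Duplex seeds the training set with the two mutually farthest
samples, the test set with the next farthest pair, then alternates max–min
assignment; ties break to the lowest index, which makes degenerate inputs
(identical vectors) deterministic. The outer split runs within each species
stratum so every species appears on both sides. Venetian blinds assigns
sample i to fold ⌊i/thickness⌋ mod n_splits (defaults 10 splits,
thickness 1); leave-one-out, shuffled k-fold and repeated random subsets are
also available. The one-class screening protocol is 80 repeats of a random
70/30 sample-level split of the target class.

## One-class screening

Class distances (all ≥ 0, smaller = more target-like):

* SIMCA: √((Q/Q̄)(T²/T̄²)) — the geometric mean of the orthogonal residual
  and score distance, each normalised by its training mean. This combined
  variant was chosen among the several distances called "SIMCA" in the
  literature and is pinned by the self-normalisation test (training means
  exactly 1).
* PCA residual: the Q statistic alone (3 PCs default).
* kNN distance: mean Euclidean distance to the k nearest training points in
  PCA-score space (2 PCs, k = 1 default; k is configurable since only the
  PC count is conventionally reported).
* Mahalanobis: distance to the training mean in PCA-score space with the
  empirical score covariance.
* One-class SVM: RBF kernel, ν = 0.05, γ = 1/(p·var(X)); decision values f
  are reversed and shifted to max(0, m − f) with m the training maximum, so
  the "smaller = in-class" orientation is uniform across algorithms.

AUROC uses the Mann–Whitney pair-counting form with ties counted ½, hence
is invariant under strictly monotone transforms of the distances. The "all"
contrast pools every non-target row (averaging the three per-species
contrasts is an alternative and is not used). Mean over the 80 repeats is
the aggregation.

Triplet selection replaces an expert's manual choice with a deterministic
greedy rule: first the combination with the best worst-class AUROC, then
twice the combination maximising min over classes of the best AUROC among
those selected; ties break by pooled AUROC, then combination id. A manual
override accepting three explicit ids preserves expert choice.

Class limits are calibrated on the median replicate distances of the target
training samples: scenario 1 just above their maximum (100 % of target
training samples in-class — the certification-safe setting), scenario 2 at
the 95th percentile (quantile configurable; no canonical value exists).
The final flag is a 2-of-3 vote over the triplet on each sample's median
replicate distance.

A practical caveat established on simulated campaigns: subspace-residual
distances (SIMCA, PCA residual) generalise their limits to out-of-sample
target data only when enough target samples shape the subspace. With ~14
training pork samples, held-out pork medians regularly exceed the
scenario limits; at the reference campaign size (40 pork samples) the
ensemble reaches the expected behaviour (every pork sample in-class under
scenario 1; a single pork sample sacrificed under scenario 2).

## Discriminant models

PLS-DA uses the NIPALS PLS2 implementation of scikit-learn behind the
package's interface; coefficients for any smaller LV count are derived
algebraically from one maximal fit (W(PᵀW)⁻¹Qᵀ truncated), which makes the
CV error curve cheap. The LV count minimises group-aware Venetian-blinds CV
misclassification error, ties toward fewer LVs. Class assignment is argmax
of the predicted indicators (ties to the alphabetically first class);
probability-like shares (clipped, row-normalised predictions) exist only for
the leave-class-out cutoff. A SIMPLS implementation in the test suite
cross-checks predictions on two-class instances, where the two algorithms
coincide; at full rank PLS-DA must reproduce direct indicator least squares,
which is tested against `numpy.linalg.lstsq`.

VIP_j = √(p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a) with SSY_a = (tᵀt)(qᵀq);
Σ VIP² = p holds identically and is asserted. Selection uses the ">1" rule;
a hook accepts custom masks.

Outlier limits: Hotelling T² at A(n−1)/(n−A)·F₁₋α(A, n−A), Q by the
Jackson–Mudholkar approximation from the residual eigenvalues. The default
removal rule flags rows exceeding **both** limits (conservative; "either" is
available), is applied once to training data, and the model is refit.

SVM tuning grids: C ∈ {0.1, 1, 10, 100}, RBF γ ∈ 10^[−3, 1] (5 points);
quadratic/cubic polynomial kernels use γ = scale, coef0 = 1. Features are
standardised inside each CV fold. Ties prefer the simpler kernel
(quadratic < cubic < RBF), then smaller C, then smaller γ. Leave-class-out
probability shares are a softmax over the one-vs-rest aggregated SVM
decision values — a deterministic approximation chosen over Platt
calibration (whose scikit-learn entry point is deprecated and internally
randomised); spectra with no share above the 0.5 cutoff count as
unassigned. Metrics follow the confusion-matrix definitions (sensitivity,
specificity, accuracy, error = 1 − accuracy), computed per spectrum, with an
optional per-sample majority-vote aggregation.

## Statistical yardsticks in the tests

The null-condition check (identical species profiles) compares each
combination's mean screening AUROC to 0.5 within three standard errors.
Because the 80 CV repeats resample one finite dataset, repeat-to-repeat
variation understates the sampling error of the dataset-conditional mean;
the SE used is therefore the sample-level Mann–Whitney null standard error
√((n_t+n_o+1)/(12·n_t·n_o)) with n_t, n_o the numbers of target and
non-target samples. The separable-condition check runs the full ensemble on
the reference-size Vis-NIR campaign and requires >95 % correct
classification for every species under scenario-2 limits.

## Problem sizes

Test and demonstration runs use campaigns of 8–40 samples per species with
6 replicates; screening uses the protocol's 80 repeats on grids of 3–5
combinations. These sizes were chosen so the whole suite documents the
method at interactive speed while matching the reference campaign scale
(157–161 samples) wherever a claim depends on it.

## Known limitations

* Synthetic-only validation; no claim transfers to real spectra without a
  real calibration campaign.
* OSC re-expression is approximate for matrices with more rows than
  channels.
* The DWT step discards approximation coefficients; if absolute level
  matters for a future application this is the first knob to revisit.
* "Baseline filtering" is implemented as polynomial detrend only;
  asymmetric-least-squares baselines are out of scope.
* Leave-class-out shares are decision-value softmaxes, not calibrated
  probabilities; the 0.5 cutoff therefore has no frequentist guarantee.
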