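# Methods

`dreamdecode` reimplements a hierarchical visual-feature decoding analysis
of dream content as a reusable pipeline over synthetic data. This note
records the model, the choices that were genuinely open, the synthetic
generator's assumptions, and the numerical details.

## The analysis

The core idea: object categories can be read out of spontaneous sleep
activity *zero-shot* — without ever training on dream data — by going
through an intermediate feature space. Images (and the categories they
belong to) are represented as vectors of hierarchical visual-feature
values, one table per layer of a deep-network-like feature hierarchy, with
within-category invariance rising with depth. Per feature unit, a sparse
linear regressor is trained to predict that unit's value from
stimulus-evoked multivoxel patterns. The trained decoders are then applied
to activity windows preceding awakenings from sleep; decoded vectors are
scored against *category feature vectors* (per-category averages of
exemplar feature vectors; multi-label dream reports use the unweighted
mean of the reported categories' vectors), and dreamed categories are
identified by pairwise correlation matching against a large candidate
pool.

### Decoder: screening + ARD regression

For each feature unit, the `k` voxels of the ROI most correlated with the
unit's training values are pre-selected (`k` = 500 per atomic ROI, 1000
for the union ROI VC at full scale; 100/200 at desk scale). Ranking uses
|r| — an anticorrelated voxel is as informative as a correlated one for a
linear readout; a flag switches to signed ranking. Ties break by ascending
voxel index so selection is deterministic.

The regression is sparse Bayesian linear regression with an automatic
relevance determination prior, fitted by evidence maximisation with
MacKay-style fixed-point updates: given per-weight precisions `alpha_j`
and noise precision `beta`, the weight posterior is `Sigma = (beta X'X +
diag(alpha))^-1`, `mu = beta Sigma X'y`; the updates are `gamma_j = 1 -
alpha_j Sigma_jj`, `alpha_j <- gamma_j / mu_j^2`, `beta <- (n - sum
gamma) / ||y - X mu||^2`. Weights whose precision exceeds
`prune_threshold` (1e10) are removed from the active set, which performs
the voxel selection. Both predictors and targets are standardised with
training statistics (the prior is scale-sensitive) and predictions mapped
back, so each unit decoder is affine in the voxel pattern.

Numerical choices:

* `tol` = 1e-6 relative change of the weight vector; `max_iterations` =
  500; `alpha_init` = 1.
* `noise_precision_init` defaults to the OLS-residual estimate
  `(n-p)/RSS` when `n > p+1`, falling back to `1/var(y)` otherwise.
  Starting from `1/var(y)` treats all signal variance as noise, which
  over-shrinks the first posterior; on dense-truth low-noise problems the
  resulting small `mu_j` drive `alpha_j` past the prune threshold before
  `beta` can grow, permanently discarding relevant predictors. The
  OLS-based start estimates the noise floor directly and preserves the
  oracle property (noiseless, well-conditioned, `n > p`: ARD predictions
  match OLS to r >= 0.999) while leaving sparse-truth behaviour intact.
* `beta` is capped at 1e12 so noiseless problems stay finite; a failed
  Cholesky factorisation falls back to a pseudo-inverse, and a unit whose
  fit still fails is skipped, logged and excluded downstream.
* Degenerate inputs: constant targets are rejected at screening (the unit
  is skipped upstream); zero-variance voxels are excluded before ranking.

### Preprocessing

Fixed order, per run: nuisance regression -> despiking -> (sleep only)
baseline normalisation -> windowing -> optional averaging. The nuisance
design is a linear trend plus six motion-proportional series, with a
constant term for perception/imagery runs but not for sleep runs; sleep
runs are instead normalised per voxel against the mean over the 60–90 s
window before each awakening. Normalisation subtracts the baseline mean by
default; a percent-change variant (`divide`) is provided, since the choice
of divisor is not dictated by the method — subtraction is the minimal
reading. Despiking clips each voxel's series to mean ± 3 SD with
statistics computed once, before clipping: attenuation rather than removal
preserves the sample count. Dream windows are defined on the volume grid —
the sample at offset 0 is the mean of the last three whole volumes
acquired before the awakening — so windowing is deterministic for any TR.
Samples whose window leaves the run are dropped and logged, never imputed.

Block samples average 3 volumes (9-s stimulus blocks) or 5 volumes (15-s
imagery blocks) after shifting by one volume to compensate hemodynamic
delay; sleep windows are not shifted. Test-session and imagery blocks of
the same category are averaged into one sample per category, as are dream
samples sharing a reported category (ignoring co-reported categories).

### Evaluation and inference

Accuracy is the Pearson correlation per feature unit between the decoded
series and the reference (category or multi-category) feature series
across test samples — not a per-sample vector correlation, which would be
inflated by the baseline amplitude pattern across independently trained
units. Unit correlations are pooled per layer x ROI cell (concatenated
across subjects where applicable), Fisher-Z transformed (`z = atanh r`,
|r| clamped at 1 - 1e-7 so z stays finite) and tested against zero with a
one-sided one-sample t-test. Cells report the plain mean of r with a
normal-approximation 95% CI across units; a zero-variance cell is flagged
(`degenerate_variance`) and reported with p -> 0 or 1 rather than a NaN.
Pairwise identification scores a decoded vector against every false
candidate by correlation over units; the true category is excluded from
the false pool and exact ties count as incorrect (conservative and
deterministic). No multiple-testing correction is applied; the analysis
convention is uncorrected one-sided p-values.

## The synthetic generator

The generator stands in for both the feature-extraction network and the
scanner. What it emulates:

* **Layered feature tables.** Per layer, each category has an i.i.d.
  standard-normal prototype over units; exemplars are `prototype +
  sigma * noise` with `sigma = sqrt(1-rho^2)/rho` so the expected
  exemplar-prototype correlation equals the layer's invariance target
  `rho` (non-decreasing with depth; `rho = 0` degenerates to pure
  scatter, `rho >= 1` is rejected). Training, test, dream-base and
  extra-candidate categories are disjoint; test and base categories live
  inside the candidate pool so identification is genuinely zero-shot.
* **Encoding model.** Each ROI responds to an affinity-weighted sum of
  per-layer linear projections (Gaussian weights, `1/sqrt(units)`
  scaling); the affinity is a normalised Gaussian bump over layers whose
  peak rises along the ROI order, giving the low-to-high
  brain-to-hierarchy correspondence the analysis is designed to detect.
  Per-voxel signal SD is measured on the training exemplars, and session
  noise is `signal_sd / snr`.
* **Sessions.** Perception runs present 3-volume blocks back-to-back
  (training: every training exemplar once — 1200 stimuli at full scale;
  test: one fixed exemplar per test category, repeated). Imagery runs use
  5-volume blocks flanked by cue/evaluation/rest volumes that carry no
  category signal, with the *category prototype* as content (one imagines
  the category, not a particular image). Sleep runs hold one awakening
  each at a fixed volume; the content signal — the encoding response to
  the mean of the reported categories' prototype vectors — occupies only
  the final 9 s before the awakening, with a stable baseline-only
  stretch covering the 60–90 s normalisation window. Report label sets
  (1–3 categories, a free parameter of the simulator) are drawn randomly
  and topped up deterministically until every base category reaches its
  minimum report count.
* **Nuisance.** A constant BOLD offset (100), linear drift, six
  random-walk motion series coupled into the data, i.i.d. Gaussian noise,
  and occasional logged 10-SD spikes so despiking is testable against
  ground truth.

What it does **not** emulate: hemodynamic convolution (delay is a pure
1-volume shift, matching the analysis' own compensation), physiological
noise spectra, spatial voxel correlations, subject motion artefacts beyond
linear coupling, EEG sleep staging (eligibility is an input flag), or real
image content. Passing tests therefore demonstrate the *statistical
machinery* — screening, sparse regression, pooling, identification,
windowing — under the structural assumptions above, not performance on
real scanner data.

Default SNRs were fixed once at values typical for block-design fMRI:
`snr_perception = 0.5`, `snr_imagery = 0.25`, `snr_dream = 0.12`
(signal SD / noise SD per volume; single-volume contrast-to-noise below 1
is realistic, and sleep content is markedly weaker than stimulus-evoked
responses).

A consequence of faithful preprocessing worth noting: because runs are
densely occupied by stimulus blocks, the runwise constant/trend regression
absorbs part of the block signal, and because the sleep design omits the
constant regressor, projecting the BOLD baseline onto trend/motion leaves
a smooth position-dependent residual. Both effects are properties of the
method itself, not bugs; sleep runs share one fixed layout so the residual
is identical across awakenings (and thus invisible to Pearson-over-samples
evaluation), mirroring the role of the pre-awakening baseline
normalisation. Exact ground-truth closure (decoded == presented features,
r >= 0.999) therefore holds when the nuisance chain is disabled, and is
tested that way; the nuisance steps are tested separately against
analytic oracles.

## Desk scale

The standard reduced experiment (`presets.desk_config`) uses 4 ROIs x 4
layers, 100 units per layer, 300 voxels per ROI, 50 training categories x
8 exemplars (400 training samples), 25 test categories x 10 repetitions,
and a 200-category candidate pool, while keeping the sleep-study session
structure at its full size (200 awakenings, 16 base categories, >= 10
reports each) — sleep sessions are cheap to simulate, and the decoder
grid is the expensive axis. Screening caps scale to 100 (atomic) / 200
(VC). This trains in a few minutes on one CPU and reproduces the
qualitative findings: a clean diagonal ROI-to-layer correspondence in
perception and imagery, attenuated but significantly positive dream
decoding that grows with sleep SNR, above-chance zero-shot identification
of dreamed categories, and an awakening-locked accuracy peak in the final
pre-awakening window.

## Known limitations

* Evaluation against category features has an invariance-limited ceiling:
  even a perfect decoder of image features cannot reach r = 1 against
  category averages at low-invariance layers. This is inherent to the
  category-level analysis and is why low layers score modestly even
  noise-free.
* The per-unit correlation series for dream data is short (one sample per
  base category in averaged mode), so unit-level r values are noisy and
  inference leans on pooling across units.
* The MacKay fixed point has no revival step: a pruned voxel never
  returns. The sequential (Tipping-Faul) algorithm would allow it; the
  interface admits substitute fitters via `ArdSettings`.
* Subject structure is trivial (one synthetic subject); pooling across
  subjects is implemented as concatenation of unit-level correlations and
  exercised with multiple `subject_id` values in tests only.
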