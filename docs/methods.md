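# Methods

## Study design

A study has `n_animals` (default 6) rats implanted with a single-shank
16-contact array for `n_weeks` (default 8) weeks. Recordings and
behavior tests happen twice a week and are averaged to one weekly value
before analysis; behavior additionally has a presurgery baseline week
(week 0). Histology is endpoint-only: four markers (NeuN neurons, GFAP
astrocytes, CD68 microglia/macrophages, IgG blood–brain-barrier
permeability) quantified at two distance bins (0–50, 50–100 µm) from the
implant. Sixteen analysis variables result: 2 recording, 6 behavior,
8 histology; their registry order is frozen so outputs are string-stable.

The default design yields 480 channel-level recording observations
(6 × 10 kept channels × 8 weeks), 54 weekly behavior observations per
variable (6 × 9 weeks), and 6 endpoint measurements per histology
variable.

## Synthetic-study generator

Cross-modal structure is planted with a Gaussian copula: one latent
standard-normal 16-vector per animal-week with cross-variable
correlation `StudyConfig.latent_correlation` (validated symmetric PSD
with unit diagonal). An optional AR(1) knob adds week-to-week
autocorrelation within animals (default 0: nothing in the protocol pins
it down). Monotone links map latents to observables:

* **Channel activity.** P(contact records ≥ 1 unit) = 0.10 + 0.85·Φ(z).
  The number of active contacts per session tracks this probability
  directly (activity across a shank is spatially structured, not an iid
  coin flip per contact); which contacts are active is random. Active
  contacts carry 1 + Poisson(λ−1) units with λ = exp(1.05 + 0.4·z).
* **Behavior.** Weekly true scores: ladder time 6 s·exp(0.25 z) with
  lognormal trial noise (σ = 0.08, 5 crossings, fastest 3 kept); grid
  distance 2000 cm·exp(0.2 z) and maximum velocity 50 cm/s·exp(0.2 z)
  (σ = 0.05, one measurement per session); grip 900 gf + 120·z with
  Gaussian pull noise (σ = 40 gf, 3 pulls). Slips are Poisson totals
  over the 5 crossings of a session with per-crossing rate
  exp(1.1 + 0.45 z); the baseline-week rate is near zero, matching the
  presurgery observation that slips hardly occur. A per-animal lognormal
  baseline factor (σ = 0.05) makes animals individual; the percent-change
  normalization cancels it.
* **Histology.** The endpoint latent of each histology variable is the
  animal's week-mean latent rescaled to unit variance, so animal-level
  correlations with the longitudinal modalities match the planted
  entries. Intensity markers target a normalized ring-band mean
  1 + a·exp(0.35 z) (a = 0.9 for 0–50 µm, 0.35 for 50–100 µm); NeuN
  targets percent-of-background lo + (hi−lo)·σ(0.9 z) (15–85% inner bin,
  55–115% outer). Section images plant a piecewise-linear radial profile
  whose band means equal the targets (relaxing to background by 300 µm),
  with Poisson pixel noise around 500 expected counts per background
  pixel at 2 µm/pixel, and — for NeuN — point neurons thinned from a
  2000/mm² homogeneous field (≈ 10⁵ neurons/mm³ through a 20 µm
  section). Six sections per animal (2 slides × 3 sections) with 3%
  lognormal section jitter are averaged.
* **Traces.** Voltage traces are Gaussian background (10 µV) plus fixed
  biphasic templates (negative phase leading, 1.2 ms support,
  peak-to-peak 120–200 µV, i.e. SNR 6–10) at Poisson times with a 1 ms
  within-unit refractory. Default duration is 30 s per session — enough
  for the ≥ 20-spike unit filter at the planted 4–8 Hz rates — and a
  config knob; real sessions are longer.

Traces and section images are rendered lazily (deterministic given the
study seed and the trace/section key): a full default study is 768
traces at 24.414 kHz and 144 images, too large to hold eagerly. The
eager ground-truth tables (latents, channel unit counts, behavior
trials, histology targets and their analytic analysis values) are what
the metric-level pipeline and the large-replicate analyses consume;
the raw-trace and raw-image paths are exercised on full-resolution
subsets.

**What the generator does and does not emulate.** It reproduces the
design (counts, sessions, granularities), plantable cross-modal
correlation, realistic noise families (Poisson counts, binomial-like
channel activity, lognormal times, Gaussian forces, Poisson pixel
noise, small-count neuron statistics), and ground truth for every
stage. It does not model anesthesia effects, electrode drift or tissue
micromotion, spatial correlation of histology beyond the radial
profile, electrode-artifact waveforms, or nonstationary firing. Passing
tests therefore certify the pipeline's arithmetic and statistical
calibration under the stated noise families, not robustness to every
artifact of real recordings.

**Link attenuation.** Observation noise and link curvature shrink
observable Pearson correlations below the planted latent values by a
measured factor of 0.86–0.98 per variable (weakest for slip counts,
whose Poisson noise is irreducible at realistic rates, and for the
percent-active metric, which is quantized over 10 contacts). The
recovery property test therefore plants moderate correlations (0.4) and
checks agreement within 0.1 at ≈ 500–1500 observation units; at extreme
planted values (0.9) the observables still carry |cc| ≈ 0.6–0.85, which
is what the network-recovery test relies on.

## Recording metrics

Preprocessing, noise, detection and the unit filters follow the
standard extracellular chain: zero-phase 4th-order Butterworth 300–3000
Hz, common average reference (skipped with a warning for single
channels), σ_bg = MAD/0.6745 on the processed trace, detection at
downward crossings of mean − 3.5 σ_bg with a 1.6 ms window centered on
the local minimum and 1 ms refractory suppression. Candidate units are
k-means clusters of the waveform windows (k chosen by silhouette over
2–4; one cluster when the best silhouette is below 0.25) — the
clustering identity is deliberately simple because the analysis contract
is the two inclusion filters: ≥ 20 spikes and SNR strictly above 3 with
SNR = peak-to-peak(mean waveform)/(2 σ_bg). On band-limited Gaussian
noise a 3.5 σ threshold crossing fires a few times per second; those
events form low-amplitude clusters whose SNR ≈ 2.7 < 3 and are removed
by the filter, which is why event accuracy is assessed on the filtered
unit output (the quantity the metrics are built from) rather than on
raw crossings.

Weekly outcomes are computed per session and averaged: % active = 100 ×
(kept contacts with ≥ 1 unit)/n_keep; units/channel = mean unit count
over *active* contacts only (undefined and flagged when none are
active). The kept block is the 10 consecutive contacts maximizing the
summed per-contact mean unit count across the study, ties to the lowest
start. Flagged missing channel-days are excluded, never zero-filled.

## Histology quantification

Pixels are assigned to half-open 5 µm rings by the distance of their
centers to the implant center (a polygonal-boundary mode is out of
scope; the point mode matches the synthetic images). The 700–750 µm
annulus must lie fully inside the image, else an error names the
missing margin. Normalization divides by the background-annulus mean
raw intensity; AUC increments are trapezoidal integrals of the
piecewise-linear interpolant of normalized ring means over each 50 µm
band (a constant profile integrates to exactly 50 per band;
normalization is idempotent). Neuron density uses 50 µm rings to
600 µm, ring areas measured by counting in-image pixel centers so edge
clipping affects counts and areas identically; the 450–500 µm ring is
100% by construction. Inner-ring neuron counts are intrinsically small
(≈ 8 in the 0–50 µm ring of one synthetic section at 2000/mm²), so
section-level percent values carry ≈ 35% counting noise; per-animal
values average six sections.

## Behavior normalization

Session scores: fastest 3 of 5 ladder crossings (all, with a warning,
when fewer), mean of 3 grip pulls, grid metrics as recorded; the two
weekly sessions average to the weekly score, the baseline week is
aggregated identically. Percent change applies the uniform ×(−100)
convention, so positive values mean times/forces *below* baseline. Slip
counts enter analyses raw: with baselines at zero the ratio is
undefined, and the count itself is the meaningful scale.

## Correlation network

Pearson correlation is used throughout (the association model is
linear); pairs mixing weekly and endpoint variables correlate per-animal
means with the endpoint values (n = 6), weekly pairs use animal-week
rows (n = 48). The presurgery baseline week is excluded from
correlations: it is a different physiological condition whose inclusion
would inject a shared surgery-effect cluster into every behavior pair
(it exists to normalize, not to witness the implanted state).

The bootstrap prunes spurious pairs by resampling animals — the
exchangeable unit — *independently* for the two variables of a pair,
which yields the null distribution of |cc| under no cross-variable
association while preserving each variable's within-animal dependence;
a pair is retained iff its observed |cc| exceeds the (1−α) null
quantile. This construction is calibrated by design even at 6 animals
(measured null retention 3–5% at α = 5%), whereas a percentile
confidence interval from jointly resampled clusters retains ≈ 15% of
independent pairs at this cluster count; the percentile-CI variant
remains available as `method="percentile"`. At α ≥ 1 the confidence
level is zero and nothing can be demonstrated, so nothing is retained.

Graph construction: scan retained pairs by descending |cc| (ties broken
lexicographically, so the graph is deterministic); a pair that connects
two components joins the hierarchy layer (maximum spanning forest — the
same merge order a concept lattice produces as the incidence threshold
descends); remaining pairs with |cc| ≥ τ join the influence layer.
Dominance s(v) = Σ_u |cc(v,u)| over retained pairs; an edge is
bidirectional when |s(a) − s(b)| ≤ ε·max(s(a), s(b)), else directed from
the dominant variable. Defaults τ = 0.25, ε = 0.05, B = 1000, α = 0.05
are exposed configuration, chosen once: τ keeps the influence layer
above trivially weak associations, ε declares dominance only beyond a
5% mass difference. Concept lattices are enumerated by NextClosure at
every distinct retained strength ≥ τ and written as a JSON diagnostic;
enumeration is capped at 20 000 concepts per level as dense incidence
relations grow exponentially.

The exact graph-construction internals of the original nFCA software
are not public; this module is a documented reconstruction that
satisfies the stated properties of the output (strength = |cc|, sign
retention, dominance-directed arrows, bidirectional ties, hierarchy
plus influence edges).

## Regression modelling

Y1 (units/channel) is modelled at channel-week level (480 rows), Y2
(% active) at animal-week level (48 rows); the baseline behavior week is
excluded from regression rows; histology covariates broadcast as
time-constant per-animal baselines. LME families use transformed
outcomes — log(y + 0.5) for counts, and for percents a boundary-safe
squeeze logit((p(N−1) + 0.5)/N) with N the kept-channel count — with
animal random intercept or intercept + slope; GLM families (Poisson,
negative binomial, binomial) use the raw counts/proportions with
canonical links, counts rounded to integers where a count family
demands them. Covariates are standardized by default (grip force must
be: its raw scale is two orders larger than the others').

Selection is exhaustive over the ≤ 8-term pool (≤ 256 subsets) per
family × random structure, ranked by the BIC-type score
−2 logLik + log(n)(#nonzero fixed + #unique nonzero random-covariance
elements); nonzero means |b| > 1e−8 on standardized covariates; a
random intercept contributes 1 element, intercept + slope 3. The
likelihood-ratio test acts as a parsimony tie-break only: a nested
submodel that scores no worse and that the LRT cannot reject replaces
the winner — the penalized ranking itself is never overridden. AIC and
conditional R² (Nakagawa-style for LME, deviance-based pseudo-R² for
GLM) are reported for every candidate so the search path is auditable.
Wald z approximations give the coefficient p-values (the reference
degrees-of-freedom method for these designs is not pinned down).
MixedLM fits walk an optimizer ladder (lbfgs → bfgs → powell → cg)
because variance components on the boundary can break a single
optimizer.

Best-of-256 selection bias means a BIC penalty still admits an
occasional spurious term under the null (measured: the selected set is
empty or time-only in most studies, one spurious term sometimes, two
rarely); support recovery of two planted 1-SD effects at n = 480
succeeds with ≤ 1 spurious term in ≥ 90% of studies, which is the
calibration the tests pin.

## Problem sizes in the test suite

Tests run the full default study (6 animals) wherever the quantity is
design-level; calibration and recovery simulations use the sizes that
make their tolerances meaningful: ≈ 500–1500 observation units for
correlation recovery, 200 replicates × B = 1000 for bootstrap
calibration, 50 studies for network and support recovery, 10 × 30 s
traces for detection recall, 10⁶ samples for the noise-estimator check.

## Known limitations

* Waveform clustering is template-style k-means, not wavelet
  superparamagnetic clustering; overlapping spikes and drifting
  waveforms are not handled.
* The radial quantification assumes a point implant center; real
  implant sites are areas.
* With 6 animals, endpoint-histology correlations are estimated from 6
  points; a handful of chance associations will always survive a 5%
  test across ≈ 100 null pairs, as the worked example shows.
* The negative-binomial family estimates its dispersion by ML and can
  fail to converge on near-Poisson data; such candidates are recorded
  with their diagnostics and skipped in ranking.
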