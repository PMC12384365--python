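# Methods

`sleepmem` implements a lightweight hybrid sleep-staging framework for
single-channel frontopolar EEG: hand-crafted per-epoch features feed a
pair of small feedforward networks — one memoryless, one augmented with
a first-order Markov "transition vector" — whose outputs are fused by a
confidence rule with a reject option. This note describes the model,
its assumptions, the tunable parameters, and the synthetic data the
package is validated on.

## Signal path

The input is one bipolar forehead derivation, Fp1−Fp2, obtained by
subtracting two referential channels that share a linked-ear reference.
The signal is downsampled to 125 Hz by polyphase rational resampling
(e.g. 256→125 Hz uses the ratio 125/256 with the resampler's built-in
anti-alias low-pass); no other filtering is applied. The stream is cut
into contiguous, non-overlapping scoring epochs (30 s by default, 20 s
for R&K-scored data, whose N4 labels are merged into N3 at load time),
each carrying one expert label from {W, N1, N2, N3, REM}.

Subject-level quality control excludes a recording when any per-subject
feature summary (by default the mean of each of the 37 features) lies
more than 1.5 interquartile ranges from the study-wide median, or when
the hypnogram changes stage more than 40 times per hour — churn that
usually signals scoring or recording errors. The IQR rule degenerates
gracefully: a zero IQR disables that dimension, so identical subjects
are all kept. QC summaries are computed on raw (un-z-scored) activity.

## The 37 features

Per epoch, in fixed order:

| block | features |
|---|---|
| time domain (3) | skewness; kurtosis (Pearson, non-excess: Gaussian → 3, sine → 1.5); Higuchi fractal dimension |
| Hjorth (3) | activity (variance), mobility √(var Δx / var x), complexity (mobility of Δx / mobility of x) |
| band ratios (8) | δ/α, δ/β, δ/θ, θ/α, θ/β, σ/δ, δ/(α+β), (δ+θ)/(α+β) |
| spectral shape (3) | normalized spectral entropy, centroid (Hz), 95 % roll-off (Hz), all over 0.5–30 Hz |
| wavelet (20) | per detail band D1…D5 of a 5-level db4 decomposition: relative energy, coefficient entropy, Hjorth mobility and complexity of the coefficient sequence |

Bands are δ 0.5–4, θ 4–8, α 8–13, σ 11–16, β 13–30, full 0.5–30 Hz
(half-open intervals of DFT bins; σ deliberately overlaps α and β
because it targets spindle activity). Band power is the plain sum of
squared one-sided DFT magnitudes of the untapered, undetrended epoch.

Numerical choices worth stating explicitly:

* **Higuchi FD** uses the curve-length regression with `kmax = 10`
  (conventional for 3750-sample epochs; configurable). A second,
  deliberately naive transcription of the algorithm lives in the test
  suite as an oracle.
* **Spectral entropy** is normalized by log(number of in-band bins), so
  a flat in-band spectrum scores exactly 1 and a line spectrum ~0.
* **Wavelet decomposition** uses periodized boundary handling, which
  keeps the transform orthogonal and makes the filter-bank test oracle
  exact on dyadic lengths. Relative energy is normalized by the total
  detail energy D1…D5; the approximation band A5 is excluded by default
  (configurable) since the five detail bands cover the classical EEG
  rhythms at this sampling rate. Band entropy is the Shannon entropy
  (nats) of the normalized squared coefficients.
* **Zero-denominator ratios** are guarded with ε = 1e−12 and logged
  rather than dropping the epoch, keeping the pipeline total.
* **Hjorth activity** is z-scored within each subject (population SD)
  in a separate pass, because amplitude varies across subjects far more
  than across stages. This is an unsupervised per-subject transform
  applied identically to training and test subjects, so it leaks no
  labels; it is, however, acausal for true real-time use (it needs the
  subject's full night), a known trade-off. All other features are
  amplitude-invariant by construction.
* Degenerate inputs (constant epochs, zero in-band power) raise typed
  errors; zero-dispersion z-scoring returns zeros with a warning.

## Temporal structure of hypnograms

The memory feature is motivated by how long a stage "remembers" itself.
For stage s, the indicator I_t ∈ {0,1} along the hypnogram has biased
autocovariance (1/n convention, so γ(0) is the population variance)

    γ(τ) = (1/n) Σ_t (I_{t+τ} − Ī)(I_t − Ī),   ρ(τ) = γ(τ)/γ(0),

and the discrete autocorrelation time

    t_c = Δt Σ_{τ=0}^{τmax} ρ(τ),

where τmax is the last lag before ρ first becomes non-positive — only
positive autocorrelation reflects persistence, and including negative
lobes would bias t_c downward. τmax = 0 (t_c = Δt) is the memoryless
limit. Group profiles average γ across subjects lag-wise and normalize
the *mean* profile by its own zero-lag value (not the mean of
individual ρ's; the two differ and the former weights subjects by
indicator variance). For a symmetric two-state chain with
stay-probability p the theory is closed-form, ρ(τ) = (2p−1)^τ, which
the tests verify by simulation. On sticky hypnograms t_c runs to
minutes — many epochs — which is exactly the information the memoryless
model throws away.

## Transition matrix and memory feature

A first-order transition matrix T is estimated from training hypnograms
by normalized transition counts, pooled within subjects only (counting
across a concatenation would fabricate transitions at subject
boundaries). Rows for never-observed predecessor stages fall back to
uniform so T stays row-stochastic; additive smoothing is available but
defaults to 0. The memory feature of epoch t is the transition vector

    v_t = p_{t−1} · T ∈ R^5,

the previous epoch's stage distribution pushed one step through the
chain. At training time v_t is teacher-forced from the one-hot *true*
previous label; at test time it is self-fed from the model's own
previous softmax output, strictly causally, with a one-hot wake prior
for each subject's first epoch (recordings start awake). The
teacher-forced width-42 input (37 features + 5 transition-vector
entries) was chosen over additionally concatenating the raw one-hot
previous label (width 47); the transition vector already carries that
information smoothed by T.

## Classifiers and fusion

Both networks are multilayer perceptrons: input → 128 → 64 → 32 (ReLU)
→ softmax over 5 stages, trained with Adam (learning rate 0.001, batch
128, ≤ 100 epochs) on cross-entropy, with early stopping on a held-out
10 % validation split (patience 10, best weights restored). Features
are standardized by a scaler fitted on training subjects only; the
transition-vector inputs are probabilities in [0,1] and bypass the
scaler by default (configurable). No class reweighting is applied. The
networks are scikit-learn `MLPClassifier` instances configured to this
regime; its internal seeded, stratified row-wise validation split
serves as the early-stopping split. Training is deterministic under a
fixed seed.

At inference each model's confidence is its maximum softmax
probability. The more confident model's argmax is accepted if that
confidence reaches the threshold (default 0.7, boundary-inclusive —
"reaches" is implemented as ≥ so the default is reproducible without
floating-point knife-edges; exact confidence ties go to the memory
model). If neither model reaches the threshold the epoch is rejected as
NC (not classified). Every decision records its source (memory/
no-memory dominant, memory/no-memory only, NC); the five categories
partition the epochs. NC epochs are excluded from all metrics: the
framework trades a small loss of coverage for reliability, and rejected
epochs concentrate in ambiguous stages (N1) and around stage
transitions.

## Evaluation

Leave-one-subject-out cross-validation: per fold, the scaler, T, and
both networks are fitted on the training subjects only, and per-fold
SHA-256 checksums of the fitted scaler and T make the no-leakage
property auditable (they must be invariant to any perturbation of the
held-out subject). Metrics are accuracy, Cohen's κ = (p_o − p_e)/(1 −
p_e), and per-class F1, computed over non-NC epochs, aggregated as
per-subject means ± SE (SD/√n subjects); pooled-epoch versions are also
emitted since both reporting styles appear in the sleep-staging
literature. Undefined values (κ at p_e = 1, F1 of an absent stage, any
metric when every epoch is rejected) are NaN markers, never 0. The
threshold sweep reports accuracy, κ and rejected fraction per subject
then averages (pooled variants available). Permutation importance of
the no-memory model permutes one feature column at a time (default 10
seeded repeats) and reports the mean accuracy drop plus normalized
positive shares.

## Synthetic polysomnography

Expert-scored frontopolar EEG lives in access-restricted archives, so
the package ships a generator reproducing the two properties the method
relies on, and everything — tests and the acceptance script — runs on
it.

**Hypnograms** follow a first-order Markov chain. The default ground
truth is a sticky matrix (diagonal 0.85–0.92, off-diagonal mass on
physiologically adjacent stages: W↔N1, N1↔N2, N2↔N3, REM entered from
N1/N2), giving stage autocorrelation times of minutes, as real
hypnograms show. Every subject starts awake.

**Epochs** are sums of independent band-limited Gaussian noise
components (4th-order Butterworth per band, a 2 s burn-in discarded so
filter transients do not bias band power), scaled so expected power
proportions equal the stage's band weights, with total RMS 30 µV, a
2 µV broadband noise floor, and — for N2 — Gaussian-windowed 13 Hz
spindle bursts at Poisson rate 3/epoch (0.25–0.5 s envelopes, 1.5× RMS
amplitude). Default profiles follow textbook sleep EEG: alpha-dominant
wake, theta-rich N1 and REM (REM with more beta), mixed N2 with sigma
spindles, strongly delta-dominant N3. Per-subject seeds derive from the
master seed by fixed integer offsets.

**Two regimes.** With the well-separated default profiles the pipeline
should be near-ceiling (it is; LOSO accuracy > 0.95), which validates
plumbing, not the memory idea. `overlapping_emissions(separation)`
blends each normalized profile toward the stage-averaged profile;
separation 0 makes stages spectrally identical, 1 restores the
defaults. The default separation 0.1 leaves the waveform weakly
informative, putting the no-memory baseline near the accuracy real
frontopolar single-channel stagers reach — the regime the memory
feature targets. The memory-benefit experiments use 10 studies of 10
subjects × 600 epochs (one per master seed), a problem size the package
chooses to keep the full 10-seed experiment comfortably tractable on a
laptop while leaving well over a hundred stage transitions per
hypnogram.

**What the generator does not emulate** — and what passing tests
therefore do not show about real data: artifacts (blinks, EMG bursts,
electrode pops), within-stage non-stationarity beyond spindles,
K-complexes, inter-subject spectral variability, scorer noise, and
realistic stage-duration distributions beyond geometric sojourns. The
synthetic results validate the machinery and the direction of the
memory effect, not clinical performance numbers.

## Known limitations

* The memory model inherits the usual self-feeding risk: a confident
  wrong prediction biases the next epoch's prior. The confidence fusion
  with the memoryless model is the designed mitigation.
* Within-subject activity z-scoring and subject-level QC need the whole
  recording, so strict real-time deployment would replace them with
  running estimates.
* First-order Markov memory ignores longer sleep-cycle structure
  (~90 min oscillations); t_c analysis shows the first-order term is
  large, not that it is sufficient.
* EDF reading is a thin optional path (via `mne`); only the in-memory
  and synthetic paths are exercised by the test suite.
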