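# Methods

## The decoding problem

A single-option visual oddball interface displays N ∈ [4, 9] symbols;
one flashes at a time (75 ms highlight, 75 ms gap, 150 ms period),
under a no-repeat, equiprobable schedule, while the user attends one
symbol. Each flash yields a stimulus-locked EEG epoch labelled target
(the attended symbol flashed) or non-target, with the structural
imbalance N_nontarget = N_target · (N − 1). The pipeline classifies
single epochs; everything below describes how each stage is defined,
what the synthetic generator does and does not emulate, and the
numerical choices a reimplementer would need.

## Synthetic sessions

`simulate_session` emulates the acquisition: 8 channels (Fz, Cz, P3,
Pz, P4, PO7, PO8, Oz) at 256 Hz, in microvolts. A session is a sequence
of blocks — fixation 2 s, target presentation 2 s, preparation 1 s,
stimulation ≈ 30 s, rest 5 s — appended until the target has flashed at
least `min_target_flashes` (default 280, the protocol's floor) times.
The stimulation phase consists of round(30 / (0.150·N)) complete
shuffled rounds per block (each round a permutation of all symbols,
re-drawn when its first element repeats the previous round's last), so
per-block flash counts are exactly equal and no two consecutive flashes
share a symbol. Flash onsets are spaced round(0.150·fs) = 38 samples.

The signal is a sum of:

- **Evoked template**, added at every target onset: a negative Gaussian
  deflection (default −4 µV at 250 ms) plus a positive one (+6 µV at
  350 ms), both with 45 ms standard deviation, scaled per channel
  (posterior-dominant gain map, Pz = 1.0) and per condition: the
  cartoon-face condition (CF) multiplies the six posterior channels by
  1.4, the frontal/central channels are condition-independent. Gaussian
  deflections are a modelling choice; only the latency windows and the
  posterior CF amplification are constrained by the phenomenology.
- **Steady-state visual response** during stimulation phases: a
  sinusoid at the exact on-grid flash rate fs/38 ≈ 6.737 Hz (default
  amplitude 1.5 µV, same channel gain map). Phase-locking to the flash
  grid matters: a free-running 6.667 Hz tone would drift against the
  38-sample flash spacing and average out of the non-target ERP,
  whereas the physiological steady-state response is stimulus-locked
  and survives averaging.
- **Background noise** with PSD ∝ 1/f^β, default β = 1.5 and RMS 12 µV
  per channel (white and AR(1) surrogates available). β = 1.5 is
  typical of resting EEG over 4–40 Hz; it also interacts with the
  cleaning rules — see below.
- Optional **artifacts** (`inject_artifacts`): flash-aligned transients,
  each engineered to trip one exclusion criterion with margin while
  staying clear of the other two: an eye-blink-like 80 ms half-sine of
  220 µV (peak-to-peak), an 8–12 Hz oscillation of 80 µV amplitude
  (standard deviation), and a 25–35 Hz oscillation of 40 µV (band
  ratio).

The default noise level was calibrated once so that protocol-scale
sessions decode in the 0.7–0.95 balanced-accuracy band that single-trial
P300 pipelines reach on real recordings (the defaults give ≈ 0.75 for
SF and ≈ 0.82 for CF), and then frozen.

What the generator does **not** emulate: volume conduction and channel
covariance structure (noise is independent across channels), latency
and amplitude jitter of the evoked response across trials, eye-blink
and muscle morphology beyond the three stylized artifact classes,
alpha rhythms, and any semantics of the stimulus imagery. Passing tests
therefore certify the pipeline's statistical machinery and its
sensitivity/calibration under a controlled signal model — not
performance on any particular real dataset.

## Cleaning

Epochs span −0.2 to 1.0 s: pre = round(0.2·fs) = 51 samples before and
post = round(1.0·fs) = 256 from the onset (half-open window, 307
samples, t = 0 at index 51). Rejection runs on raw epochs, before
filtering. Per channel: peak-to-peak max−min; sample standard deviation
(ddof = 1); band-power ratio P[20–40]/P[4–40] from a Welch PSD (Hann
window, segment min(Ns, 256), 50 % overlap, trapezoidal band
integration), defined as 0 when the denominator is 0 (a constant epoch
is not a high-frequency artifact). All thresholds are strict
inequalities (200 µV, 50 µV, 0.5); an epoch is discarded if any channel
trips any criterion, and the report records which.

The band-ratio criterion constrains the noise model: spectrally white
noise has an expected ratio of 20/36 ≈ 0.56 and would reject every
epoch; β = 1 leaves the single-segment Welch estimate's upper tail
touching 0.5 (~1 % false rejections at the defaults); β = 1.5 keeps the
mean at ≈ 0.19 with ≈ 0.9 % tail trips, and β = 2 none. The
artifact-fidelity experiment uses β = 2 so that "clean" epochs are
unambiguously clean; the simulation default stays at the more realistic
1.5. Because the 1.2 s epoch window spans ±8 neighbouring flashes,
fidelity (recall/specificity against ground truth) is measured on
every-9th-flash epochs, whose windows do not overlap.

Filtering: windowed-sinc (Hamming) linear-phase FIR band-pass 4–14 Hz,
order ceil(3.3·fs/transition) with 2 Hz transitions, forced odd (423
taps at 256 Hz); applied forward on reflection-padded epochs with the
group delay (211 samples) compensated by shifting. An 8 Hz probe
survives within 5 %; a 30 Hz probe is attenuated by ~37 dB (measured
mid-epoch; the short epoch's edge transients, not the filter's 53 dB
Hamming stopband, set this floor). No baseline
subtraction on the classification path (the 4 Hz high-pass edge removes
offsets); the ERP-statistics path subtracts the pre-stimulus mean for
display and testing only.

## Features: CCA spatial filter

Epochs are trimmed to t ∈ [0, 0.8) and decimated by plain subsampling
by 4 — alias-free because of the prior 14 Hz low-pass — giving
Nd = round(0.8·fs)/4 = 51 samples at an effective 64 Hz. The filter is
learned from training target epochs only: stack them row-wise into X′
((Ntarget·Nd) × Ne) and the replicated target average into X̄′ of equal
shape, and solve the CCA generalized eigenproblem between the two. The
auto-covariances receive a ridge 1e-8·trace/dim because X̄′ is
rank-deficient by construction (its rows repeat every Nd rows). The
returned weight matrix keeps the first Nsf = 3 eigenvectors of the X′
side, unit-normed, each sign-fixed so the filtered target average's
largest-magnitude sample is positive (eigenvector scale and sign are
otherwise arbitrary). Features are the column-major concatenation of
X W (Nd·Nsf = 153 values per epoch). The solver is validated against an
independent whiten-then-SVD CCA on random instances to 1e-6.

## Classifier

Shrinkage LDA: pooled within-class covariance S (each class centred on
its own mean), shrunk as Σ̂ = (1−γ)S + γ(tr S/d)I with the Ledoit–Wolf
closed-form intensity γ — no tuning parameter. Weights
w = Σ̂⁻¹(μ_t − μ_n); the bias puts the decision threshold at the
midpoint of the projected class means, i.e. equal effective priors:
with a 1:(N−1) imbalance, empirical priors would trade target recall
for raw accuracy, while the evaluation metric is balanced accuracy.

Stepwise selection starts from the empty model (score 0.5). The scorer
is 5-fold stratified cross-validated balanced accuracy *within the
training data* (no leakage into the outer evaluation); per-fold class
means, Gram and squared-Gram matrices are cached so each candidate
subset costs one small solve. The forward step adds the best candidate
when it improves the score by more than tol = 0.01 (ties go to the
lowest index); the backward step removes the feature whose removal
costs at most tol; sweeps repeat until stable, with a visited-set guard
against add/remove cycles and a max_features cap (30) as a runtime
guard. The tolerance is set at one balanced-accuracy point because the
inner-CV score has granularity ≈ 1/fold-size; a much smaller tol only
admits noise. On pure-noise features the selection stays small (median
≤ 3 — the max-over-candidates step is positively biased, so an
occasional spurious feature is expected) and generalizes at chance; if
no feature ever improves on the empty model, the single best feature is
kept.

## Evaluation

Five-fold cross-validation refits the entire chain — spatial filter,
stepwise selection, LDA — on the four training folds and scores the
held-out fold; folds are stratified by class (the protocol's random
allocation, plus the guarantee that both classes appear in every fold).
Note the epochs of neighbouring flashes overlap in time, so fold
samples are not strictly independent; this reproduces the evaluation
design of the experimental literature rather than blocking by time, and
the permutation test shares the same structure, keeping the comparison
fair. A pure-noise (zero-gain) session decodes at ≈ 0.48–0.52,
confirming no leakage through the per-fold refits.

The permutation test reruns the full cross-validated chain (including
selection) on m label permutations — the null must experience the same
selection flexibility as the observed statistic — with the add-one
p-value (1 + #{null ≥ observed})/(m + 1); m ≥ 19 is enforced (0.05
resolution), default m = 200. Ties between the discrete null and
observed accuracies make the test mildly conservative (null rejection
≈ 0.02–0.03 at α = 0.05).

Transfer evaluation fits the chain on one full dataset and scores
another once (condition swap or symbol-count grid). Training on the
high-gain (CF-like) condition and testing on the low-gain one collapses
CA_target while CA_nontarget holds — the transferred discriminant
expects larger responses than the test condition delivers — reproducing
the direction of the published transfer asymmetry.

Rank tests dispatch by design: Wilcoxon rank-sum (two unpaired groups),
signed-rank (paired), Kruskal–Wallis (> 2 groups), all two-sided at
α = 0.05, no multiple-comparison correction (matching the reference
analyses). The symbol-count insensitivity experiment feeds the test
independent replicate sessions per symbol count (per-fold accuracies
within one session are correlated and would make the test liberal).

## ERP statistics

The KDE significance test fits a Gaussian-kernel density (Silverman
bandwidth) to each channel's 51 pre-stimulus samples of the averaged
ERP, integrates it to a CDF on a 512-point grid, and flags each
post-stimulus sample whose CDF value exceeds 1 − α/2 (positive) or
falls below α/2 (negative); it is invariant to adding a constant to the
whole waveform. Using the averaged ERP's own baseline (rather than
single-epoch distributions) matches the single-trace usage the test is
meant for. On null (baseline-distributed) data the flagged fraction
sits near α with an upward KDE-smoothing bias, within [α/2, 2α]. The
zero-phase FIR spreads large evoked responses into the pre-stimulus
interval, inflating the baseline distribution and saturating the
flagged count at high gain — the test's monotonicity in effect size
holds below that regime.

`erp_snr` (10·log10 of the target/non-target mean-square ratio over
[0, 0.8] s) is a summary metric defined by this package for reporting —
not a standard quantity — and is labelled as such wherever it appears.

## Published reference tables

The bundled TSVs carry the per-participant balanced-accuracy summaries
published with the 19-participant, 3-session study whose raw EEG is
deposited as OpenNeuro ds003190. Aggregations (column means ± sd,
medians, win counts and percentages, column-mean extremes, the
CA_total = 0.5·(CA_target + CA_nontarget) identity) are recomputed from
the cells. One internal inconsistency of the published transfer table
is preserved as printed: the CF→SF total prints 0.619 while the
balanced mean of its printed per-class cells is 0.6145 (consistent with
per-participant averaging before rounding); the aggregation here
reports what the cells imply and tolerates the 0.005 gap.

## Problem sizes and reproducibility

The reproduction script (`scripts/acceptance.py`) uses: the full
280-target flagship session for the in-band check; 100-target sessions
for the 10-replicate condition comparison and the 3-point gain ladder;
150-target sessions for the transfer asymmetry; 40-target sessions,
3 per symbol count, for the 10 Kruskal–Wallis batches; 1000
non-overlapping epochs at 10 % contamination for rejection fidelity;
500 null waveforms for KDE calibration; and 200 replicates of a reduced
(features + LDA) pipeline with m = 99 for permutation calibration —
sizes chosen to keep a full run in the minutes range on one CPU while
leaving every statistical check well-powered. All randomness in the
package flows through numpy `default_rng` seeds; every experiment
driver takes an explicit seed and is exactly reproducible.

## Known limitations

- The generator's independence of noise across channels makes the CCA
  spatial filter's job easier than on real EEG, where correlated noise
  dominates; absolute accuracies should not be read as predictions for
  real data.
- Decimation assumes the band-pass has run first; `trim_decimate`
  refuses unfiltered epochs rather than silently aliasing.
- Reading arbitrary third-party BIDS EEG datasets is out of scope; the
  reader targets the layout this package writes (an adapter for a
  specific deposited dataset should be written against its actual event
  vocabulary).
- Symbol-level spelling (aggregating multiple flashes into a symbol
  decision) and online/closed-loop operation are out of scope; the
  pipeline classifies single trials.
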