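# Methods

## Problem setting

Two kinaesthetic motor-imagery tasks — imagined right-hand vs right-foot
movement — modulate scalp EEG band power. If the two induced states can be
discriminated from a patient's EEG, the tasks can carry a yes/no code:
hand imagery for "yes", foot imagery for "no". The pipeline quantifies (a)
how well the two imagery states separate (Imagery Trial) and (b) how
reliably whole answers can be decoded (pre-Communication Trial), in both
healthy participants and patients with disorders of consciousness.

## Feature model

Every analysis unit ("parameter") is the 4-vector of band powers
(θ 4–8, α 8–13, β 13–25, γ 25–40 Hz; half-open intervals so the shared
boundaries 8 and 13 Hz count once) of one electrode over one averaged
PSD window.

* Epochs are 2 s (512 samples at 256 /s), non-overlapping, starting 5 s
  into each protocol section so task-onset transients are excluded.
* Epoch PSDs use a Blackman–Harris-tapered FFT periodogram with density
  normalisation: the taper's power loss is compensated, so white noise of
  variance σ² integrates to σ² in expectation (verified to 5%).
  The grid is one-sided, 0.5 Hz resolution, 0–128 Hz.
* Eight consecutive epoch PSDs are averaged (16 s of data). For 30-s
  answer sections the window hops one epoch, giving 12 − 8 + 1 = 5
  parameters per answer; a 10-s hop (one window per answer) is available
  via the `hop` setting. The five-per-answer default is required for
  majority voting over an odd count.
* Imagery sections yield one parameter each by default (the mean PSD over
  all eligible epochs of the section): 10 per task per electrode for a
  healthy session, 7 for a patient session. A windowed alternative is
  available.

## Preprocessing

Zero-phase Butterworth band-pass, 3–60 Hz. The default order is 6 because
a forward–backward order-4 design misses the ≥ 40 dB stop-band target at
80 Hz (36.8 dB measured), while order 6 gives 55 dB there and ~75 dB at
1.5 Hz; pass-band gain at 10 Hz is unity within 5%. Artifact handling is
reproducible rather than expert-driven: annotation-driven masking, or an
absolute-amplitude scan (default 100 µV, 0.5-s windows, 0.25-s padding)
whose masked intervals are simply excluded from epoching — unmasked
samples are never altered. ICA cleaning (FastICA; removal by excess
kurtosis above 10, or by correlation with annotated artifact intervals)
is available but off by default because synthetic recordings are clean;
the algorithm, component count and rejection rule are explicit settings,
not defaults hidden in the pipeline.

## Electrode selection

Per subject × session × electrode × band, a one-way fixed-effects ANOVA
on two levels (hand/foot) at p < 0.05; with 5 subjects × 2 sessions × 31
electrodes × 4 bands this is 1240 tests. An electrode earns one unit per
subject-session significant in *at least one* band (not one per band);
the eight highest totals form the best-electrode (BE) set. Ties at rank k
break by the count of significant electrode-band cells, then by montage
order. No multiple-testing correction is applied by default — the
selection procedure is deliberately liberal, since the nested CV
downstream provides the actual error control — but a Bonferroni flag
exists for sensitivity analyses. The same machinery applied to
answer-labelled patient data (5 patients × 8 BE × 4 bands = 160 tests)
reports the sign of the yes-minus-no power difference alongside p.

The default montage resolves a defect in the acquisition channel list,
which names C4 twice: the second occurrence is read as P4, the parietal
site symmetric to P3.

## Classification

Linear soft-margin SVM, C = 1, on fold-standardised features (zero mean,
unit variance, statistics from the training rows only — required by the
no-leak contract since SVM margins are scale-sensitive).

* **Imagery:** external leave-one-out over parameters; ICA = fraction of
  correctly classified parameters.
* **Communication:** external leave-five-out over question instances;
  each held-out answer is the majority vote of its five parameter
  predictions (ties, possible only under non-default even window counts,
  count as errors); CCA = fraction of correctly decoded answers.

Inside every external training set, an internal CV of the same shape
scores all 255 subsets of the 8 BE (8, 28, 56, 70, 56, 28, 8, 1 subsets
at cardinalities 1..8) and selects the best subset: highest internal
accuracy, then smaller cardinality, then first in lexicographic order.
The model is retrained on the full external training set with that subset
and applied to the held-out unit. Reported accuracies: per cardinality
(using each fold's internally best subset of that cardinality), the
nested accuracy (globally best subset per fold), and the
best-configuration accuracy (maximum over cardinalities — an optimistic
summary, labelled as such). Session-level summaries take mean ± SD of
per-session values per cardinality ("mean of best", not "best of mean").

Chance level uses the exact binomial tail: the smallest k/n with
P(X ≥ k | n, ½) ≤ α (α = 0.05); n is the parameter count (imagery) or the
answer count (communication). For n = 12 this is 10/12 ≈ 0.833.

### SVM solver

The exhaustive search retrains a tiny SVM ~10⁵–10⁶ times per study, so
the C-SVM dual is solved by a JIT-compiled SMO loop (maximal-violating-
pair selection, analytic pair update, KKT-gap stop) rather than through a
general fitting API whose per-call overhead dominates at this size. It is
the same optimisation problem libsvm solves; the test suite checks
prediction-identical behaviour against `sklearn.svm.SVC(kernel="linear")`
on randomised problems at tolerance 1e-6. The pipeline default stopping
tolerance is 1e-3 (libsvm's own default). Two refinements keep the search
fast without changing results: subset Gram matrices are built
incrementally along a depth-first subset order (the Gram of a feature
block is the sum of per-electrode Grams), and each subset's solve warm-
starts from its parent subset's dual solution. A least-squares variant
(ridge onto ±1 targets, the classic simplification of "least-squares
separating hyperplane") is available via `solver="lstsq"`.

## Synthetic data

Recordings are drawn section by section in the frequency domain: FFT
coefficients are complex Gaussians scaled so the expected one-sided
periodogram equals the model PSD, then inverse-transformed. The
background model is `scale/f^exponent + alpha peak (Gaussian) + floor`
(µV²/Hz). Presets: *healthy* (exponent 1.2, scale 20, alpha amplitude 15
at 10 Hz, σ 1.5 Hz, floor 0.5) shows the posterior-alpha peak typical of
awake, eyes-closed EEG; *DoC-like* (exponent 1.8, scale 60, no alpha
peak, floor 0.2) has the delta/theta-dominated, monotonically decaying
spectrum typical of vegetative/minimally-conscious patients. Task effects
are multiplicative on the PSD in one (electrode, band) during sections of
one task, so the expected between-class band-power ratio equals the
factor exactly — the recovery oracle used throughout the tests.

What the generator does *not* emulate: volume conduction and inter-channel
correlation (channels are independent), non-stationarity within sections,
evoked potentials, and physiologically structured artifacts (only generic
high-amplitude transients are injected). Passing tests therefore show the
*procedure* is correct and well calibrated, not that real patients would
reach any particular accuracy; the original study's headline accuracies
(ICA ~82–85%, CCA ~81–92%) came from human recordings that were never
deposited and are not reproducible here.

Study-condition defaults follow the protocol: healthy sessions have 10
imagery repetitions *per task* (the protocol wording is ambiguous between
10 total and 10 per task; per-task is the default because it balances the
classes and matches the "ten parameters per set" bookkeeping, and both
readings are configurable) of 60 s, and 6 questions × 5 repetitions;
patients 7 × 30 s per task and 6 questions × 2. Intended answers default
to alternating yes/no across the six questions so decoding ground truth
is fixed. The planted-effect default is a factor of 4 on three central
electrodes (C3 alpha and C4 beta for hand, Cz beta for foot) — large
enough that a correct pipeline recovers the planted set nearly always,
which is what makes recovery failures diagnostic.

## Numerical and scale choices

* Validation experiments run on reduced problem sizes chosen to keep the
  whole suite comfortably interactive: the ANOVA-bookkeeping cohort uses
  two repetitions per task (cell counts depend only on cohort shape), the
  recovery experiment averages 10 healthy imagery sessions on an
  8-channel montage, permutation calibration uses 100 shuffles of a
  patient-sized session, and type-I calibration uses 10 000 null
  simulations.
* Degenerate ANOVA inputs: zero within-group variance gives F = 0, p = 1
  for equal means and F = ∞, p = 0 otherwise; groups smaller than 2 are
  rejected.
* Internal folds whose training half lacks a class are skipped; subsets
  that could not be evaluated are excluded from selection.
* Standard-deviation summaries use the n−1 normalisation.

## Known limitations

* Channels are simulated independently; spatial-filtering methods (CSP,
  source localisation) would show artificially poor performance on these
  data and are out of scope.
* The amplitude-threshold artifact detector is a stand-in for expert
  marking; it only catches high-amplitude transients.
* The best-configuration accuracy is selected post hoc over cardinalities
  and is optimistically biased; the nested accuracy is the honest
  generalisation estimate and both are reported side by side.
* EDF import/export is not provided; recordings round-trip through plain
  CSV with YAML/JSON plan sidecars and BED-like interval files.
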