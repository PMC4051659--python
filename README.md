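# micomm

Motor-imagery EEG classification and yes/no answer decoding for
brain–computer-interface feasibility studies, aimed at detecting covert
command-following in patients with disorders of consciousness (vegetative
or minimally conscious state).

The package reimplements, as a tested and reusable pipeline, an EEG
procedure in which a participant answers simple yes/no questions by
kinaesthetic motor imagery — imagining a right-hand movement for "yes" and
a right-foot movement for "no" — and a classifier decodes the answer from
scalp band power alone:

1. **Band-power parameters.** 31-channel EEG (10–20 layout, 256 samples/s)
   is band-pass filtered to 3–60 Hz, artifact segments are rejected, and
   each protocol section is cut into non-overlapping 2-s epochs (the first
   5 s discarded). Epoch PSDs come from a Blackman–Harris modified
   periodogram; eight consecutive PSDs are averaged into 16-s windows, and
   each window yields one *parameter* per electrode: the power 4-vector
   (θ 4–8 Hz, α 8–13 Hz, β 13–25 Hz, γ 25–40 Hz).
2. **Best-electrode (BE) search.** Per subject, session, electrode and
   band, a one-way two-level ANOVA (hand vs foot, p < 0.05) tests for a
   task effect; an electrode scores one unit per subject-session in which
   any band is significant, and the eight highest-scoring electrodes
   become the BE set (1240 ANOVAs for 5 subjects × 2 sessions × 31
   electrodes × 4 bands).
3. **Nested cross-validated SVM.** A linear soft-margin SVM (C = 1) is
   evaluated by nested leave-one-out: the external loop measures
   generalisation; inside each external training set an internal CV
   exhaustively searches all 255 electrode subsets of the 8 BE
   (8-28-56-70-56-28-8-1 per cardinality) and picks the best. Imagery
   accuracy (ICA) counts correctly classified parameters; communication
   accuracy (CCA) counts correctly decoded *answers*, each decided by
   majority vote over the five parameters of a held-out question
   (leave-five-out).
4. **Chance level.** Accuracies are compared with the exact-binomial
   Müller-Putz threshold: the smallest k/n with P(X ≥ k | n, ½) ≤ 0.05.

The original recordings were never deposited, so the package ships a
synthetic EEG generator that reproduces the session protocol
(healthy: 10 one-minute imagery repetitions per task and 6 questions × 5
repetitions; patients: 7 × 30-s repetitions and 6 questions × 2), 1/f-like
background spectra with or without an alpha peak, and known multiplicative
band-power effects at chosen electrodes — giving every stage a ground
truth to recover.

## Worked example

```python
from micomm import (
    BackgroundSpectrumModel, ChannelMontage, Effect, EffectSpec,
    bandpass, build_parameter_table, make_session_plan, mueller_putz_threshold,
    nested_lfo_communication, synthesize_recording,
)

montage = ChannelMontage(("C3", "C4", "Cz", "Fz", "P3", "P4", "O1", "O2"))
effects = EffectSpec((
    Effect("C3", "alpha", "hand", 4.0),   # hand imagery quadruples alpha at C3
    Effect("Cz", "beta", "foot", 4.0),    # foot imagery quadruples beta at Cz
))
plan = make_session_plan("patient", "pre-communication", seed=13)
rec = bandpass(synthesize_recording(plan, BackgroundSpectrumModel.healthy(),
                                    effects, seed=99, montage=montage))
table = build_parameter_table(rec, plan)
report = nested_lfo_communication(table, list(montage))
print(f"answers decoded: {report.n_external}")
print(f"communication accuracy (best configuration): {report.best_accuracy:.2f}")
print(f"chance threshold: {report.chance_threshold:.3f} "
      f"-> significant: {report.significant}")
```

prints

```
answers decoded: 12
communication accuracy (best configuration): 1.00
chance threshold: 0.833 -> significant: True
```

Twelve question instances (6 questions × 2 repetitions) each contribute
five band-power parameters; with factor-4 planted effects every majority
vote is correct, and 12/12 exceeds the n = 12 chance threshold of 10/12 ≈
0.833, so the session would count as successful communication.

The same workflow is available from the shell:

```
micomm simulate --cohort patient --trial pre-communication --seed 13 --out rec.csv
micomm preprocess rec.csv --out clean.csv
micomm features clean.csv --out params.csv
micomm run-study --subjects 2 --sessions 1 --patients 2 --seed 0 --out study/
```

## Layout

| module | contents |
| --- | --- |
| `micomm.simulate` | session plans, spectrum models, effect specs, EEG synthesis, artifact injection |
| `micomm.preprocess` | zero-phase band-pass, artifact-segment rejection, optional ICA cleaning |
| `micomm.features` | epoching, modified periodogram, PSD averaging, band powers, parameter tables |
| `micomm.selection` | two-level ANOVA, unit scoring, best-electrode ranking |
| `micomm.svm` | deterministic soft-margin linear SVM (JIT SMO solver, least-squares variant) |
| `micomm.classify` | subset enumeration, nested LOO/LFO CV, majority voting, chance threshold |
| `micomm.pipeline` / `micomm.cli` | full-study orchestration, reports, command-line interface |
| `micomm.experiments` | end-to-end validation experiments behind the acceptance checks |

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
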