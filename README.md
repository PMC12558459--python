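# keeneye

Computerized dual-task assessment of visual hemispatial neglect: trial
protocol, scoring, diagnostic classification, spatial analyses, and a
generative patient simulator.

## The problem

Visual neglect — the failure to consciously perceive stimuli in the
hemispace opposite a brain lesion, most often left space after
right-hemisphere stroke — is frequently under-detected by paper-and-pencil
cancellation tests, especially in compensated patients. A dual-task
computerized paradigm loads attention harder: on each trial the patient must
simultaneously detect a briefly flashed peripheral circle (left, right, or
both sides, 14 possible positions spanning three vertical bands) and
identify a central digit. The attentional competition between the central
and peripheral tasks unmasks subtle spatial biases that single-task testing
misses.

`keeneye` implements the full analysis stack for this paradigm, for
clinical researchers who run the task and for methodologists who want to
study its statistical behavior: a 75-trial main series (42 unilateral + 33
bilateral presentations, each of 25 configurations shown 3 times), all
error counts and laterality coefficients, the published diagnostic
thresholds and a from-scratch CART inducer, vertical/positional analyses,
and a calibrated Bernoulli simulator so that every stage is testable without
patient data.

## The statistics at the core

From a scored session with miss counts LSU/RSU (unilateral left/right),
LSB/RSB (bilateral), hallucination counts RH/LH, and the protocol constants
BP = 33 bilateral trials and LP = 54 lateralized presentations per side:

```
KA_bilateral  = (LSB − RSB) / (2·BP − RSB − LSB)            ∈ [−1, 1]
KPrL_bilateral = (BP − LSB) / BP                             ∈ [0, 1]
KA_all        = (LSB + LSU − RSB − RSU)
                / (2·LP − RSB − RSU − LSB − LSU)             ∈ [−1, 1]
KEf_all       = (D − H) / (D + H),   D = detections, H = RH + LH
KPrL_all      = (LP − LSB − LSU) / LP                        ∈ [0, 1]
```

(and the right-side KPr analogues). KA = 0 means no lateral bias, KA = +1
complete left neglect; KPr is the share of circles caught on a side; KEf
penalizes mislocalized reports (allochiria). Diagnostic classification uses
either the published single-feature thresholds (**LSB ≥ 14** or
**KA_all ≥ 0.17** ⇒ neglect) or a Gini-impurity CART grown with
rpart-style controls (minsplit 20, minbucket 7, cp 0.01) and evaluated by
stratified 10-fold cross-validation.

## Worked example

```python
import keeneye as ke

schedule = ke.generate_main_schedule(seed=42)
profile = ke.PatientProfile(p_base_left=0.25, p_base_right=0.85,
                            extinction_penalty=0.5, vertical_penalty=0.8,
                            h_right=0.08, d_correct_uni=0.6, d_correct_bi=0.6,
                            label="neglect")
record = ke.simulate_session(profile, schedule, seed=7)
sheet = ke.score_session(record)
print(f"LSU={sheet.LSU} LSB={sheet.LSB} RSU={sheet.RSU} RSB={sheet.RSB} RH={sheet.RH}")
print(f"KA_all={sheet.KA_all:.3f}  KA_bilateral={sheet.KA_bilateral:.3f}  "
      f"KPrL_bilateral={sheet.KPrL_bilateral:.3f}  KEf_all={sheet.KEf_all:.3f}")
print("LSB14 ->", ke.classify_rule(sheet, "LSB14"))
print("KA017 ->", ke.classify_rule(sheet, "KA017"))
```

prints

```
LSU=17 LSB=28 RSU=3 RSB=11 RH=3
KA_all=0.633  KA_bilateral=0.630  KPrL_bilateral=0.152  KEf_all=0.885
LSB14 -> neglect
KA017 -> neglect
```

The simulated patient (left detection 25%, halved again under bilateral
competition) misses 17 of 21 unilateral-left and 28 of 33 bilateral-left
circles, a strong rightward asymmetry (KA_all 0.63); both published rules
classify the session as neglect.

Cohort-level work goes through the statsmodels-style model object:

```python
cohort = ke.simulate_cohort(ke.study_cohort_spec(38, 64, seed=0))
sheets = [ke.score_session(r) for r, _ in cohort]
labels = [l for _, l in cohort]
results = ke.NeglectTreeModel.from_scoresheets(
    sheets, labels, features=ke.RAW_COUNT_FEATURES).fit()
print(results.summary())          # fitted tree + resubstitution metrics
print(results.cross_validate()["pooled_metrics"])
```

A command-line interface mirrors the library:
`keeneye schedule | validate | score | classify | fit-tree | analyze | simulate`.

## Documentation

`docs/methods.md` describes the generative model, the coefficient
definitions, the tree-growing rules, calibration of the built-in cohort
presets, numerical conventions, and known limitations.
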