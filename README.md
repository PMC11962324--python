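# moodcast

Forecasting **emotional valence** and **PHQ-9 depression-item responses**
from passively sensed daily behavior, with day-level detection of
emotional-state changes.

Continuous clinical assessment of mood is hard: self-reports are sparse,
subjective, and often stop exactly when a patient deteriorates. Smartphones
and wearables, however, passively record daily behavior — step count,
covered distance, sleep hours, app use, time at home, visited-places count,
and whether sport was practiced. `moodcast` turns those seven incomplete
daily summaries into forecasts a clinician could act on: the next day's
emotional valence (negative / neutral / positive), per-item PHQ-9 answers,
and a running score for "this patient's emotional state is about to
change". It is aimed at digital-phenotyping and computational-psychiatry
researchers working with daily-summary behavioral tables.

## The model

Three stages, trained on disjoint patient subsets (30% / 40% / 30%) to
prevent leakage:

1. **Heterogeneous HMM with exact missing-data marginalization.** Daily
   features follow per-state diagonal Gaussians (continuous) and a
   Bernoulli (sport), driven by a hidden first-order chain λ = (π, A, B).
   Because emissions factorize given the state, a missing feature drops out
   of the likelihood exactly — no imputation. The smoothed posterior
   γₜ = P(state | all observed days) is the daily embedding. Fitting is
   Baum–Welch with observed-weighted sufficient statistics; K is chosen by
   AIC/BIC (`select_K`), default K = 7.

2. **Encoder–decoder transformer** (embedding 32, 4 heads, 3+3 layers,
   feed-forward 128, dropout 0.3, sinusoidal positions, causal decoder
   masking), trained self-supervised to predict the posterior sequence one
   day ahead from 30 encoder + 20 decoder days, teacher-forced, Adam, MSE,
   early stopping. Inference is autoregressive; outputs are projected to
   the simplex by softmax. Implemented on a small in-repo numpy autodiff
   engine — no GPU or deep-learning framework required.

3. **Windowed classification heads** (XGBoost by default): next-day valence
   from the 7-day window of decoder outputs; nine independent binary
   PHQ-9 item classifiers over three feature sources (decoder outputs,
   decoder outputs + predicted valence distributions, or valence
   distributions alone).

Change detection scores each day from the predicted valence distributions:
windowed Shannon entropy H(x) = −Σ pᵢ log₂ pᵢ over the 3 preceding days,
and the Jensen–Shannon divergence between the present-day distribution and
the window mean (a symmetrized-KL variant is also provided). Both are
evaluated by ROC against ground-truth change days.

Because the clinical data stream such a pipeline is built for is
proprietary, the package ships a first-class **synthetic cohort generator**
(`moodcast.synthetic`) that reproduces the study conditions — regime-driven
mixed-type features, 52–70% per-feature missingness, valence reported on a
few percent of days with a 45.8/23.7/30.4 negative/neutral/positive split,
sporadic PHQ-9 responses (~25-day gaps) — with full ground truth, so every
stage is testable end to end.

## Worked example

Run the full pipeline on the built-in planted-signal benchmark (150
synthetic patients, ~130 days each, strong regime→valence coupling):

```python
import warnings
import moodcast.forecaster as fc
from moodcast import synthetic as syn
from moodcast.pipeline import PipelineConfig, run_pipeline

spec = syn.planted_signal_spec(seed=0)
keys = ("transition_matrix", "start_probs", "emission_means",
        "emission_sds", "valence_coupling", "valence_renewal_rate")
cfg = PipelineConfig(
    n_patients=spec.n_patients, seq_length_mean=spec.seq_length_mean,
    seq_length_sd=spec.seq_length_sd, valence_report_rate=spec.valence_report_rate,
    cohort_overrides={k: getattr(spec, k) for k in keys},
    n_states=3, em_restarts=3, classifier_test_fraction=0.4,
    forecaster=fc.ForecasterConfig(epochs=20, patience=20),
    seed=0, out_dir="runs/demo",
)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    art = run_pipeline(cfg)

vm = art["valence_metrics"]
print(f"valence  accuracy {vm.accuracy:.3f}  macro-F1 {vm.macro_f1:.3f}  "
      f"macro ROC AUC {vm.macro_roc_auc:.3f}  (n={vm.n})")
print(f"change   JS AUC {art['change_rocs']['js']['auc']:.3f}  "
      f"entropy AUC {art['change_rocs']['entropy']['auc']:.3f}")
print(art["state_match"].round(3).to_string(index=False))
```

prints (exact numbers; the run is deterministic under the seed):

```
valence  accuracy 0.837  macro-F1 0.839  macro ROC AUC 0.918  (n=786)
change   JS AUC 0.723  entropy AUC 0.554
 horizon   hmm  transformer  difference
       0 1.000        0.951      -0.049
       1 0.943        0.945       0.002
       2 0.883        0.885       0.001
       3 0.840        0.842       0.001
       4 0.785        0.786       0.001
       5 0.762        0.763       0.001
       6 0.725        0.726       0.001
       7 0.683        0.685       0.001
```

Reading the output: on held-out patients the pipeline predicts the next
day's valence from passive data alone with ~0.84 accuracy and macro-F1;
divergence-based change scores rank true change days well above stable
days (AUC 0.72), and divergence beats entropy — relative disorder between
today's distribution and the recent window carries more signal than
overall disorder within the window. The state-match table compares
autoregressive forecasting of the behavioral state by the transformer
against the HMM transition-power baseline γₜAʰ for horizons 0–7 (on this
first-order benchmark the two track each other; the transformer's
advantage appears under longer-range regime structure — see
`synthetic.forecasting_benchmark_spec` and `docs/methods.md`).

A default desk-scale run (60 patients, K = 7 states) is available from the
shell, optionally with a YAML config overriding any `PipelineConfig` field:

```bash
moodcast run-all --seed 0 --out runs/demo
moodcast simulate --n-patients 50 --seed 1 --out runs/cohort
```

`run-all` writes the cohort CSVs, fitted HMM (JSON), forecaster checkpoint,
per-day valence predictions, change scores and ROC points, PHQ-9 metrics,
the state-match comparison (CSV + plot), and a manifest with the patient
subsets and stage seeds. Re-running with the same seed reproduces every CSV
byte-for-byte.

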