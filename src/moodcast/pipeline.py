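"""End-to-end orchestration: simulate -> preprocess -> HMM -> transformer ->
classifiers -> change detection -> metrics.

The three model stages are trained on disjoint patient subsets (30% HMM, 40%
transformer, 30% classifiers) to prevent leakage between training phases;
classifier metrics are computed on held-out patients within the classifier
subset. All randomness fans out from one root seed, and re-running with the
same config reproduces every CSV output bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from moodcast import change as change_mod
from moodcast import classifiers as clf_mod
from moodcast import evaluation as eval_mod
from moodcast import forecaster as fc_mod
from moodcast import hmm as hmm_mod
from moodcast import preprocessing as prep
from moodcast import synthetic as syn

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Desk-scale defaults: a 60-patient cohort with ~150-day sequences and a
    20% valence report rate keeps every stage CPU-friendly while leaving
    enough labeled days for stable metrics. The HMM uses 7 states and the
    transformer the 30/20-day encoder/decoder windows."""

    n_patients: int = 60
    seq_length_mean: float = 150.0
    seq_length_sd: float = 50.0
    valence_report_rate: float = 0.2
    cohort_overrides: dict = field(default_factory=dict)

    n_states: int = 7
    em_restarts: int = 2
    em_max_iter: int = 50

    forecaster: fc_mod.ForecasterConfig = field(
        default_factory=lambda: fc_mod.ForecasterConfig(epochs=15, patience=5)
    )

    classifier_kind: str = "XGB"
    valence_window: int = 7
    phq9_window: int = 7
    phq9_sources: tuple = ("embeddings", "embeddings+emotion", "emotion")
    classifier_test_fraction: float = 0.3
    change_window: int = 3
    anchor_stride: int = 5
    max_horizon: int = 7
    seed: int = 0
    out_dir: str | Path | None = None

    def cohort_spec(self, seed: int) -> syn.CohortSpec:
        overrides = {
            "n_patients": self.n_patients,
            "seq_length_mean": self.seq_length_mean,
            "seq_length_sd": self.seq_length_sd,
            "valence_report_rate": self.valence_report_rate,
            "seed": seed,
            **self.cohort_overrides,
        }
        return syn.CohortSpec(**overrides)


def _stage_seeds(seed: int, n: int = 10) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in np.random.SeedSequence(seed).spawn(n)]


def _feature_matrices(df: pd.DataFrame) -> dict[str, np.ndarray]:
    out = {}
    for pid, group in df.groupby("patient_id", sort=True):
        out[pid] = group.sort_values("date")[prep.FEATURES].to_numpy(dtype=float)
    return out


def _predict_distribution_series(
    clf: clf_mod.ValenceClassifier, source: np.ndarray, window: int
) -> np.ndarray:
    """(T, 3) predicted valence distributions; NaN where the window is incomplete."""
    T = len(source)
    out = np.full((T, 3), np.nan)
    rows, days = [], []
    for t in range(window, T):
        win = source[t - window : t]
        if np.isnan(win).any():
            continue
        rows.append(win.ravel())
        days.append(t)
    if rows:
        out[np.array(days)] = clf.predict_distribution(np.asarray(rows))
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the artifact bundle.

    Returns a dict with the cohort, split, fitted models, per-patient
    posterior and prediction series, metric tables, and (if ``out_dir`` is
    set) the paths of all written files. Raises with the stage name on
    failure; artifacts computed so far are kept on the exception via the
    ``partial`` attribute.
    """
    seeds = _stage_seeds(config.seed)
    artifacts: dict = {"config": config, "stage_seeds": seeds}
    timings: dict[str, float] = {}

    def stage(name):
        logger.info("pipeline stage: %s", name)
        timings[name] = time.perf_counter()
        return name

    try:
        # -- simulate ---------------------------------------------------------
        stage("simulate")
        spec = config.cohort_spec(seeds[0])
        cohort = syn.generate_cohort(spec)
        artifacts["cohort"] = cohort

        # -- preprocess -------------------------------------------------------
        stage("preprocess")
        daily = cohort.to_daily_frame()
        daily = prep.quality_control(daily)
        patients = pd.DataFrame({"patient_id": cohort.patient_ids, "cohort": "synthetic"})
        split = prep.split_patients(patients, seed=seeds[1])
        artifacts["split"] = split
        subset_ids = {s: split.index[split == s].tolist() for s in prep.SUBSETS}

        standardizer = prep.fit_standardizer(daily, subset_ids["hmm"])
        daily_std = prep.apply_standardizer(standardizer, daily)
        artifacts["standardizer"] = standardizer
        features = _feature_matrices(daily_std)

        # -- fit HMM ----------------------------------------------------------
        stage("fit_hmm")
        hmm_seqs = [features[pid] for pid in subset_ids["hmm"]]
        params, ll_trace = hmm_mod.fit_em(
            hmm_seqs,
            K=config.n_states,
            seed=seeds[2],
            n_restarts=config.em_restarts,
            max_iter=config.em_max_iter,
            feature_names=prep.FEATURES,
        )
        artifacts["hmm_params"] = params
        artifacts["hmm_loglik_trace"] = ll_trace

        # -- posteriors -------------------------------------------------------
        stage("posteriors")
        gammas = {pid: hmm_mod.forward_backward(params, features[pid]).gamma for pid in cohort.patient_ids}
        artifacts["posteriors"] = gammas

        # -- train forecaster -------------------------------------------------
        stage("train_forecaster")
        fc_cfg = dataclasses.replace(config.forecaster, seed=seeds[3])
        windows = fc_mod.make_windows(
            [gammas[pid] for pid in subset_ids["transformer"]], fc_cfg.enc_len, fc_cfg.dec_len
        )
        model, history = fc_mod.train_forecaster(windows[:3], fc_cfg, n_states=config.n_states)
        artifacts["forecaster"] = model
        artifacts["forecaster_history"] = history

        # -- decoder one-step predictions -------------------------------------
        stage("decoder_outputs")
        decoder_outputs = {pid: fc_mod.one_step_predictions(model, gammas[pid]) for pid in cohort.patient_ids}
        artifacts["decoder_outputs"] = decoder_outputs

        # -- valence classifier -----------------------------------------------
        stage("train_classifier")
        clf_ids = subset_ids["classifier"]
        rng = np.random.default_rng(seeds[4])
        order = rng.permutation(len(clf_ids))
        n_test = max(1, int(round(len(clf_ids) * config.classifier_test_fraction)))
        test_ids = [clf_ids[i] for i in order[:n_test]]
        train_ids = [clf_ids[i] for i in order[n_test:]]
        artifacts["classifier_split"] = {"train": train_ids, "test": test_ids}

        labels = {pid: cohort.observed_valence[pid] for pid in clf_ids}
        train_windows = clf_mod.build_windows(
            {pid: decoder_outputs[pid] for pid in train_ids},
            {pid: labels[pid] for pid in train_ids},
            config.valence_window,
        )
        valence_clf = clf_mod.train_valence(train_windows, config.classifier_kind, seed=seeds[5])
        artifacts["valence_classifier"] = valence_clf

        test_windows = clf_mod.build_windows(
            {pid: decoder_outputs[pid] for pid in test_ids},
            {pid: labels[pid] for pid in test_ids},
            config.valence_window,
        )
        valence_metrics = None
        if len(test_windows.y) and len(np.unique(test_windows.y)) >= 2:
            proba = valence_clf.predict_distribution(test_windows.X)
            valence_metrics = eval_mod.classification_metrics(test_windows.y, proba, classes=[0, 1, 2])
        artifacts["valence_metrics"] = valence_metrics

        valence_dists = {
            pid: _predict_distribution_series(valence_clf, decoder_outputs[pid], config.valence_window)
            for pid in clf_ids
        }
        artifacts["valence_distributions"] = valence_dists

        # -- change detection -------------------------------------------------
        stage("change_detection")
        change_labels = syn.inject_change_labels(cohort)
        score_frames = []
        for pid in clf_ids:
            df = change_mod.score_series(valence_dists[pid], change_labels[pid], config.change_window)
            df.insert(0, "patient_id", pid)
            df.insert(1, "day", np.arange(len(df)))
            score_frames.append(df)
        scores = pd.concat(score_frames, ignore_index=True)
        artifacts["change_scores"] = scores
        change_rocs = {}
        for scorer in ("entropy", "js", "jeffreys"):
            try:
                change_rocs[scorer] = change_mod.detection_roc(
                    scores[scorer].to_numpy(), scores["label"].to_numpy()
                )["all"]
            except ValueError:
                change_rocs[scorer] = None
        artifacts["change_rocs"] = change_rocs

        # -- PHQ-9 classifiers ------------------------------------------------
        stage("phq9")
        phq9_results = {}
        phq9_labels_by_q = {}
        for q in range(1, 10):
            per_patient = {}
            for pid in clf_ids:
                T = len(cohort.true_states[pid])
                lab = np.full(T, np.nan)
                for day, items in cohort.phq9_items[pid]:
                    lab[day] = items[q - 1]
                per_patient[pid] = lab
            phq9_labels_by_q[q] = per_patient
        for source in config.phq9_sources:
            feats = clf_mod.combine_sources(
                {pid: decoder_outputs[pid] for pid in clf_ids},
                valence_dists,
                source,
            )
            per_q_train = {
                q: clf_mod.build_windows(
                    {pid: feats[pid] for pid in train_ids},
                    {pid: phq9_labels_by_q[q][pid] for pid in train_ids},
                    config.phq9_window,
                )
                for q in range(1, 10)
            }
            import warnings as _warnings

            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                phq9_clf = clf_mod.train_phq9(per_q_train, config.classifier_kind, seed=seeds[6], source=source)
            rows = []
            for q, est in sorted(phq9_clf.estimators.items()):
                fw = clf_mod.build_windows(
                    {pid: feats[pid] for pid in test_ids},
                    {pid: phq9_labels_by_q[q][pid] for pid in test_ids},
                    config.phq9_window,
                )
                if len(fw.y) == 0:
                    continue
                p1 = phq9_clf.predict_proba(q, fw.X)
                acc = float(((p1 >= 0.5).astype(int) == fw.y).mean())
                if len(np.unique(fw.y)) == 2:
                    from sklearn.metrics import roc_auc_score

                    auc = float(roc_auc_score(fw.y, p1))
                else:
                    auc = np.nan
                rows.append({"question": q, "source": source, "accuracy": acc, "roc_auc": auc, "n": len(fw.y)})
            phq9_results[source] = pd.DataFrame(rows)
        artifacts["phq9_metrics"] = phq9_results

        # -- state-match forecasting comparison -------------------------------
        stage("state_match")
        curves = state_match_comparison(
            model,
            params,
            {pid: gammas[pid] for pid in clf_ids},
            max_horizon=config.max_horizon,
            stride=config.anchor_stride,
        )
        artifacts["state_match"] = curves

        # -- outputs ----------------------------------------------------------
        stage("write_outputs")
        if config.out_dir is not None:
            artifacts["paths"] = _write_outputs(config, artifacts)
    except Exception as exc:
        exc.partial = artifacts  # type: ignore[attr-defined]
        last = list(timings)[-1] if timings else "init"
        raise RuntimeError(f"pipeline failed in stage {last!r}: {exc}") from exc
    return artifacts


def state_match_comparison(
    model: fc_mod.PosteriorForecaster,
    params: hmm_mod.HHMMParams,
    gammas: dict[str, np.ndarray],
    max_horizon: int = 7,
    stride: int = 5,
) -> pd.DataFrame:
    """Fig-5-style comparison: transformer autoregressive forecasts vs the
    HMM transition-power baseline, scored as state-match accuracy per horizon.

    Anchors are days t with a full encoder context behind them and
    ``max_horizon`` truth days ahead; horizon 0 is same-day reconstruction
    (the transformer's one-step prediction of day t from data through t-1;
    the smoothed posterior itself for the HMM baseline).
    """
    enc = model.config.enc_len
    contexts, recon_contexts, truths, anchors_gamma = [], [], [], []
    for pid in sorted(gammas):
        g = gammas[pid]
        T = len(g)
        for t in range(enc, T - max_horizon, stride):
            contexts.append(g[t - enc + 1 : t + 1])
            recon_contexts.append(g[t - enc : t])
            truths.append(g[t : t + max_horizon + 1])
            anchors_gamma.append(g[t])
    if not contexts:
        raise ValueError("no anchors available for state-match evaluation")
    contexts = np.stack(contexts)
    recon_contexts = np.stack(recon_contexts)
    truths = np.stack(truths)
    anchors_gamma = np.stack(anchors_gamma)

    future, _ = fc_mod.forecast_batch(model, contexts, max_horizon)
    recon, _ = fc_mod.forecast_batch(model, recon_contexts, 1)
    tf_preds = np.concatenate([recon, future], axis=1)  # (B, H+1, K)

    Ah = np.stack(
        [np.linalg.matrix_power(params.transition, h) for h in range(max_horizon + 1)]
    )  # (H+1, K, K)
    hmm_preds = np.einsum("bk,hkj->bhj", anchors_gamma, Ah)

    tf_curve = fc_mod.state_match_curve(list(tf_preds), list(truths), range(max_horizon + 1))
    hmm_curve = fc_mod.state_match_curve(list(hmm_preds), list(truths), range(max_horizon + 1))
    return eval_mod.compare_forecasters(hmm_curve, tf_curve)


def _write_outputs(config: PipelineConfig, artifacts: dict) -> dict[str, str]:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    cohort: syn.SyntheticCohort = artifacts["cohort"]

    for name, path in cohort.write_csv(out / "cohort").items():
        paths[f"cohort_{name}"] = str(path)

    artifacts["hmm_params"].to_json(out / "hmm.json")
    paths["hmm"] = str(out / "hmm.json")

    artifacts["forecaster"].save(out / "forecaster.pkl")
    artifacts["forecaster_history"].to_csv(out / "forecaster_history.csv", index=False)
    paths["forecaster_history"] = str(out / "forecaster_history.csv")

    if artifacts["valence_metrics"] is not None:
        artifacts["valence_metrics"].to_frame().to_csv(out / "valence_metrics.csv", index=False)
        paths["valence_metrics"] = str(out / "valence_metrics.csv")

    pred_rows = []
    for pid, dists in artifacts["valence_distributions"].items():
        start = cohort.start_dates[pid]
        for t, row in enumerate(dists):
            if np.isnan(row).any():
                continue
            pred_rows.append(
                {
                    "patient_id": pid,
                    "date": (start + pd.Timedelta(days=t)).strftime("%Y-%m-%d"),
                    "p_neg": row[0],
                    "p_neu": row[1],
                    "p_pos": row[2],
                    "argmax": int(row.argmax()),
                }
            )
    pd.DataFrame(pred_rows).to_csv(out / "valence_predictions.csv", index=False)
    paths["valence_predictions"] = str(out / "valence_predictions.csv")

    artifacts["change_scores"].to_csv(out / "change_scores.csv", index=False)
    paths["change_scores"] = str(out / "change_scores.csv")

    roc_rows = []
    for scorer, roc in artifacts["change_rocs"].items():
        if roc is None:
            continue
        for f, t in zip(roc["fpr"], roc["tpr"]):
            roc_rows.append({"scorer": scorer, "fpr": f, "tpr": t, "auc": roc["auc"]})
    pd.DataFrame(roc_rows).to_csv(out / "change_roc.csv", index=False)
    paths["change_roc"] = str(out / "change_roc.csv")

    phq9_frames = [df for df in artifacts["phq9_metrics"].values() if len(df)]
    if phq9_frames:
        pd.concat(phq9_frames, ignore_index=True).to_csv(out / "phq9_metrics.csv", index=False)
        paths["phq9_metrics"] = str(out / "phq9_metrics.csv")

    artifacts["state_match"].to_csv(out / "state_match.csv", index=False)
    paths["state_match"] = str(out / "state_match.csv")
    eval_mod.compare_forecasters(
        artifacts["state_match"][["horizon", "hmm"]].rename(columns={"hmm": "accuracy"}),
        artifacts["state_match"][["horizon", "transformer"]].rename(columns={"transformer": "accuracy"}),
        plot_path=out / "state_match.png",
    )

    manifest = {
        "seed": config.seed,
        "stage_seeds": artifacts["stage_seeds"],
        "subsets": {s: artifacts["split"].index[artifacts["split"] == s].tolist() for s in prep.SUBSETS},
        "classifier_split": artifacts["classifier_split"],
        "n_states": config.n_states,
        "forecaster": dataclasses.asdict(config.forecaster),
        "files": sorted(paths),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    paths["manifest"] = str(out / "manifest.json")
    return paths
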