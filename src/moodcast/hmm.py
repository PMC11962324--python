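"""Heterogeneous hidden Markov model over mixed continuous/binary features.

Per-state emissions are diagonal-covariance Gaussians for the continuous
features and a Bernoulli for the binary feature; the features are
conditionally independent given the state, so missing fields are marginalized
exactly by dropping their terms from the emission likelihood — no imputation.

Fitting is Baum-Welch (EM) with scaled forward-backward recursions and an
observed-weighted M-step; posterior state probabilities (gamma) double as the
daily behavioral embedding passed to the sequence forecaster.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

_LOG2PI = float(np.log(2.0 * np.pi))
_BERN_EPS = 1e-6


@dataclass
class HHMMParams:
    """lambda = (pi, A, B): start vector, transition matrix, and per-state
    emission parameters (Gaussian mean/SD per continuous feature, Bernoulli
    success probability for the binary feature)."""

    start_probs: np.ndarray  # (K,)
    transition: np.ndarray  # (K, K)
    gauss_means: np.ndarray  # (K, F)
    gauss_sds: np.ndarray  # (K, F)
    bern_p: np.ndarray | None = None  # (K,) or None if no binary feature
    sd_floor: float = 1e-3
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.start_probs = np.asarray(self.start_probs, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        self.gauss_means = np.atleast_2d(np.asarray(self.gauss_means, dtype=float))
        self.gauss_sds = np.atleast_2d(np.asarray(self.gauss_sds, dtype=float))
        if self.bern_p is not None:
            self.bern_p = np.asarray(self.bern_p, dtype=float)

    @property
    def K(self) -> int:
        return len(self.start_probs)

    @property
    def n_continuous(self) -> int:
        return self.gauss_means.shape[1]

    @property
    def n_features(self) -> int:
        return self.n_continuous + (1 if self.bern_p is not None else 0)

    def n_free_params(self) -> int:
        K = self.K
        n_bin = 1 if self.bern_p is not None else 0
        return (K - 1) + K * (K - 1) + 2 * self.n_continuous * K + n_bin * K

    def validate(self) -> None:
        K = self.K
        if self.transition.shape != (K, K):
            raise ValueError("transition must be KxK")
        if not np.isclose(self.start_probs.sum(), 1.0, atol=1e-9) or np.any(self.start_probs < 0):
            raise ValueError("start_probs must be a simplex")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-9) or np.any(self.transition < 0):
            raise ValueError("transition rows must be stochastic")
        if self.gauss_means.shape != self.gauss_sds.shape or self.gauss_means.shape[0] != K:
            raise ValueError("gaussian parameter shapes inconsistent")
        if np.any(self.gauss_sds < self.sd_floor):
            raise ValueError(f"gauss_sds below sd_floor {self.sd_floor}")
        if self.bern_p is not None:
            if self.bern_p.shape != (K,):
                raise ValueError("bern_p must be length K")
            if np.any(self.bern_p < _BERN_EPS) or np.any(self.bern_p > 1 - _BERN_EPS):
                raise ValueError("bern_p must be clamped to [eps, 1-eps]")

    def drop_continuous_feature(self, f: int) -> "HHMMParams":
        """Reduced model without continuous feature ``f`` (for marginalization
        cross-checks: a fully missing feature contributes nothing)."""
        keep = [j for j in range(self.n_continuous) if j != f]
        return HHMMParams(
            start_probs=self.start_probs.copy(),
            transition=self.transition.copy(),
            gauss_means=self.gauss_means[:, keep],
            gauss_sds=self.gauss_sds[:, keep],
            bern_p=None if self.bern_p is None else self.bern_p.copy(),
            sd_floor=self.sd_floor,
        )

    def to_json(self, path: str | Path | None = None, extra: dict | None = None) -> str:
        doc = {
            "format": "moodcast-hhmm",
            "version": 1,
            "start_probs": self.start_probs.tolist(),
            "transition": self.transition.tolist(),
            "gauss_means": self.gauss_means.tolist(),
            "gauss_sds": self.gauss_sds.tolist(),
            "bern_p": None if self.bern_p is None else self.bern_p.tolist(),
            "sd_floor": self.sd_floor,
            "feature_names": self.feature_names,
        }
        if extra:
            doc.update(extra)
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "HHMMParams":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = json.loads(text)
        if doc.get("format") != "moodcast-hhmm":
            raise ValueError("not a moodcast HHMM document")
        return cls(
            start_probs=np.array(doc["start_probs"]),
            transition=np.array(doc["transition"]),
            gauss_means=np.array(doc["gauss_means"]),
            gauss_sds=np.array(doc["gauss_sds"]),
            bern_p=None if doc["bern_p"] is None else np.array(doc["bern_p"]),
            sd_floor=doc.get("sd_floor", 1e-3),
            feature_names=doc.get("feature_names"),
        )


@dataclass
class PosteriorSequence:
    """T x K matrix of per-day hidden-state posteriors plus the observed mask."""

    gamma: np.ndarray  # (T, K), rows on the simplex
    mask: np.ndarray  # (T, F) bool, True where the feature was observed
    log_likelihood: float = field(default=np.nan)


def _split(params: HHMMParams, seq: np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
    seq = np.atleast_2d(np.asarray(seq, dtype=float))
    Fc = params.n_continuous
    if seq.shape[1] != params.n_features:
        raise ValueError(f"sequence has {seq.shape[1]} features, model expects {params.n_features}")
    cont = seq[:, :Fc]
    binary = seq[:, Fc] if params.bern_p is not None else None
    return cont, binary


def emission_loglik(params: HHMMParams, record: np.ndarray) -> np.ndarray:
    """K-vector of per-state emission log-densities for one day.

    Only observed features contribute; a fully missing day returns zeros (the
    empty product), so emissions are uninformative and the posterior follows
    the chain alone.
    """
    record = np.asarray(record, dtype=float)
    if record.ndim != 1:
        raise ValueError("record must be a 1-D feature vector")
    return emission_loglik_seq(params, record[None, :])[0]


def emission_loglik_seq(params: HHMMParams, seq: np.ndarray) -> np.ndarray:
    """(T, K) matrix of emission log-densities with missing-feature marginalization."""
    cont, binary = _split(params, seq)
    obs = ~np.isnan(cont)
    if np.any(~np.isfinite(cont[obs])):
        raise ValueError("non-finite (non-NaN) feature value in sequence")
    x = np.where(obs, cont, 0.0)  # placeholder; masked out below
    mu = params.gauss_means[None, :, :]  # (1, K, F)
    sd = params.gauss_sds[None, :, :]
    z = (x[:, None, :] - mu) / sd
    ll = -0.5 * (z**2) - np.log(sd) - 0.5 * _LOG2PI  # (T, K, F)
    ll = np.where(obs[:, None, :], ll, 0.0)
    out = ll.sum(axis=2)
    if binary is not None:
        b_obs = ~np.isnan(binary)
        if np.any(~np.isfinite(binary[b_obs])):
            raise ValueError("non-finite (non-NaN) binary value in sequence")
        p = np.clip(params.bern_p, _BERN_EPS, 1 - _BERN_EPS)[None, :]
        xb = np.where(b_obs, binary, 0.0)[:, None]
        bl = xb * np.log(p) + (1 - xb) * np.log1p(-p)
        out = out + np.where(b_obs[:, None], bl, 0.0)
    return out


def _forward_backward_core(
    params: HHMMParams, log_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Scaled forward-backward given the (T, K) emission log-likelihoods.

    Returns (gamma, alpha_hat, beta_hat, log_likelihood). Emission rows are
    shifted by their max before exponentiation, which cancels in the
    normalized recursions and is reabsorbed into the log-likelihood.
    """
    T, K = log_b.shape
    shift = log_b.max(axis=1)
    b = np.exp(log_b - shift[:, None])  # (T, K), max entry 1
    A = params.transition

    alpha = np.empty((T, K))
    c = np.empty(T)
    a0 = params.start_probs * b[0]
    c[0] = a0.sum()
    alpha[0] = a0 / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * b[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]

    beta = np.empty((T, K))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (b[t + 1] * beta[t + 1])) / c[t + 1]

    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    loglik = float(np.log(c).sum() + shift.sum())
    return gamma, alpha, beta, loglik


def forward_backward(params: HHMMParams, seq: np.ndarray) -> PosteriorSequence:
    """Posterior state probabilities and total log-likelihood for one sequence."""
    params.validate()
    seq = np.atleast_2d(np.asarray(seq, dtype=float))
    if len(seq) < 1:
        raise ValueError("sequence must have length >= 1")
    log_b = emission_loglik_seq(params, seq)
    gamma, _, _, loglik = _forward_backward_core(params, log_b)
    return PosteriorSequence(gamma=gamma, mask=~np.isnan(seq), log_likelihood=loglik)


def sequence_loglik(params: HHMMParams, seq: np.ndarray) -> float:
    return forward_backward(params, seq).log_likelihood


def _e_step(params: HHMMParams, seq: np.ndarray):
    log_b = emission_loglik_seq(params, seq)
    gamma, alpha, beta, loglik = _forward_backward_core(params, log_b)
    T, K = gamma.shape
    shift = log_b.max(axis=1)
    b = np.exp(log_b - shift[:, None])
    A = params.transition
    xi_sum = np.zeros((K, K))
    for t in range(T - 1):
        xi = alpha[t][:, None] * A * (b[t + 1] * beta[t + 1])[None, :]
        xi_sum += xi / xi.sum()
    return gamma, xi_sum, loglik


def _kmeans_init(
    X: np.ndarray, K: int, rng: np.random.Generator, sd_floor: float
) -> tuple[np.ndarray, np.ndarray]:
    """Cluster complete-case days for initial Gaussian means; days with any
    missing field are filled with feature means for initialization only."""
    from sklearn.cluster import KMeans

    complete = X[~np.isnan(X).any(axis=1)]
    if len(complete) < max(20, 5 * K):
        col_means = np.nanmean(X, axis=0)
        filled = np.where(np.isnan(X), col_means, X)
        complete = filled[np.isfinite(filled).all(axis=1)]
    if len(complete) < K:
        means = rng.standard_normal((K, X.shape[1]))
    else:
        km = KMeans(n_clusters=K, n_init=1, random_state=int(rng.integers(2**31 - 1)))
        km.fit(complete)
        means = km.cluster_centers_
    sds = np.maximum(np.nanstd(X, axis=0), 10 * sd_floor)
    sds = np.tile(sds, (K, 1))
    return means, sds


def fit_em(
    sequences: list[np.ndarray],
    K: int,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-4,
    n_restarts: int = 5,
    sd_floor: float = 1e-3,
    n_binary: int = 1,
    feature_names: list[str] | None = None,
) -> tuple[HHMMParams, np.ndarray]:
    """Baum-Welch over a set of sequences; returns the best restart.

    Missing features are marginalized in the E-step and the M-step weights
    each sufficient statistic by the observation mask, so parameters are
    estimated from observed values only. The per-iteration total
    log-likelihood trace of the winning restart is returned alongside the
    parameters; it is non-decreasing up to numerical tolerance.

    Starved states (expected occupancy below a small fraction of the total)
    are re-seeded from a random observed day with a warning.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    sequences = [np.atleast_2d(np.asarray(s, dtype=float)) for s in sequences]
    if not sequences:
        raise ValueError("need at least one sequence")
    n_feat = sequences[0].shape[1]
    if n_binary not in (0, 1):
        raise ValueError("n_binary must be 0 or 1")
    Fc = n_feat - n_binary
    stacked = np.vstack(sequences)
    cont_all = stacked[:, :Fc]
    bin_all = stacked[:, Fc] if n_binary else None

    root = np.random.SeedSequence(seed)
    restart_seeds = root.spawn(n_restarts)

    best: tuple[float, HHMMParams, list[float]] | None = None
    for r in range(n_restarts):
        rng = np.random.default_rng(restart_seeds[r])
        means, sds = _kmeans_init(cont_all, K, rng, sd_floor)
        means = means + 0.05 * sds * rng.standard_normal(means.shape) * (r > 0)
        params = HHMMParams(
            start_probs=np.full(K, 1.0 / K),
            transition=(0.8 * np.eye(K) + 0.2 / K) / (0.8 + 0.2),
            gauss_means=means,
            gauss_sds=np.maximum(sds, sd_floor),
            bern_p=(np.clip(rng.uniform(0.3, 0.7, K), _BERN_EPS, 1 - _BERN_EPS) if n_binary else None),
            sd_floor=sd_floor,
            feature_names=feature_names,
        )
        params.transition /= params.transition.sum(axis=1, keepdims=True)
        trace: list[float] = []
        prev = -np.inf
        for _ in range(max_iter):
            params, loglik = _em_iteration(params, sequences, rng)
            trace.append(loglik)
            if np.isfinite(prev) and loglik - prev < tol:
                break
            prev = loglik
        final = trace[-1]
        if best is None or final > best[0]:
            best = (final, params, trace)
    assert best is not None
    return best[1], np.asarray(best[2])


def _em_iteration(
    params: HHMMParams, sequences: list[np.ndarray], rng: np.random.Generator
) -> tuple[HHMMParams, float]:
    K = params.K
    Fc = params.n_continuous
    total_ll = 0.0
    start_acc = np.zeros(K)
    xi_acc = np.zeros((K, K))
    gamma_acc = np.zeros(K)
    cont_num = np.zeros((K, Fc))
    cont_sq = np.zeros((K, Fc))
    cont_den = np.zeros((K, Fc))
    bern_num = np.zeros(K)
    bern_den = np.zeros(K)

    for seq in sequences:
        gamma, xi_sum, ll = _e_step(params, seq)
        total_ll += ll
        start_acc += gamma[0]
        xi_acc += xi_sum
        gamma_acc += gamma.sum(axis=0)
        cont, binary = _split(params, seq)
        obs = ~np.isnan(cont)
        x = np.where(obs, cont, 0.0)
        w = gamma[:, :, None] * obs[:, None, :]  # (T, K, F)
        cont_num += (w * x[:, None, :]).sum(axis=0)
        cont_sq += (w * (x**2)[:, None, :]).sum(axis=0)
        cont_den += w.sum(axis=0)
        if binary is not None:
            b_obs = ~np.isnan(binary)
            xb = np.where(b_obs, binary, 0.0)
            wb = gamma * b_obs[:, None]
            bern_num += (wb * xb[:, None]).sum(axis=0)
            bern_den += wb.sum(axis=0)

    # Starvation guard: re-seed states that collect almost no occupancy.
    starved = gamma_acc < 1e-3 * gamma_acc.sum() / K
    if starved.any():
        warnings.warn(f"re-seeding starved states {np.where(starved)[0].tolist()}", stacklevel=2)

    start = start_acc / start_acc.sum()
    trans = xi_acc / np.maximum(xi_acc.sum(axis=1, keepdims=True), 1e-300)
    trans = np.maximum(trans, 1e-12)
    trans /= trans.sum(axis=1, keepdims=True)

    den = np.maximum(cont_den, 1e-12)
    means = cont_num / den
    var = cont_sq / den - means**2
    sds = np.maximum(np.sqrt(np.maximum(var, 0.0)), params.sd_floor)
    if params.bern_p is not None:
        bern = np.clip(bern_num / np.maximum(bern_den, 1e-12), _BERN_EPS, 1 - _BERN_EPS)
    else:
        bern = None

    if starved.any():
        stacked = np.vstack(sequences)
        cont_all = stacked[:, :Fc]
        candidates = cont_all[~np.isnan(cont_all).all(axis=1)]
        for k in np.where(starved)[0]:
            day = candidates[rng.integers(len(candidates))]
            col = np.nanmean(cont_all, axis=0)
            means[k] = np.where(np.isnan(day), col, day)
            sds[k] = np.maximum(np.nanstd(cont_all, axis=0), 10 * params.sd_floor)
            if bern is not None:
                bern[k] = 0.5

    new = HHMMParams(
        start_probs=start,
        transition=trans,
        gauss_means=means,
        gauss_sds=sds,
        bern_p=bern,
        sd_floor=params.sd_floor,
        feature_names=params.feature_names,
    )
    return new, total_ll


def select_K(
    sequences: list[np.ndarray],
    K_range,
    seed: int = 0,
    n_binary: int = 1,
    **fit_kwargs,
):
    """Fit candidate state counts and score them with AIC and BIC.

    AIC = 2p - 2l and BIC = p ln(n) - 2l, with p the free-parameter count
    (K-1 start, K(K-1) transitions, 2 Gaussian parameters per continuous
    feature and state, one Bernoulli per state) and n the number of observed
    feature values. Returns a DataFrame with per-K rows; the AIC/BIC argmins
    are stored in ``df.attrs``.
    """
    import pandas as pd

    K_range = list(K_range)
    if not K_range:
        raise ValueError("K_range must be non-empty")
    stacked = np.vstack([np.atleast_2d(s) for s in sequences])
    n_obs = int((~np.isnan(stacked)).sum())
    rows = []
    for K in K_range:
        params, trace = fit_em(sequences, K, seed=seed, n_binary=n_binary, **fit_kwargs)
        ll = float(trace[-1])
        p = params.n_free_params()
        rows.append(
            {"K": K, "log_likelihood": ll, "n_params": p, "AIC": 2 * p - 2 * ll, "BIC": p * np.log(n_obs) - 2 * ll}
        )
    df = pd.DataFrame(rows)
    df.attrs["n_observed"] = n_obs
    df.attrs["best_AIC"] = int(df.loc[df["AIC"].idxmin(), "K"])
    df.attrs["best_BIC"] = int(df.loc[df["BIC"].idxmin(), "K"])
    return df


def hmm_forecast(params: HHMMParams, gamma_t: np.ndarray, horizon: int) -> np.ndarray:
    """Propagate a state distribution ``horizon`` days ahead: gamma_t A^h.

    h = 0 returns the input unchanged; the result stays on the simplex.
    """
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    gamma_t = np.asarray(gamma_t, dtype=float)
    if gamma_t.shape[-1] != params.K or not np.allclose(gamma_t.sum(axis=-1), 1.0, atol=1e-6):
        raise ValueError("gamma_t must be a K-simplex")
    Ah = np.linalg.matrix_power(params.transition, horizon)
    out = gamma_t @ Ah
    return out / out.sum(axis=-1, keepdims=True)


def posterior_csv(post: PosteriorSequence, path: str | Path) -> None:
    """Write a posterior sequence as CSV with one probability column per state."""
    import pandas as pd

    K = post.gamma.shape[1]
    pd.DataFrame(post.gamma, columns=[f"state_{k}" for k in range(K)]).to_csv(path, index=False)
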