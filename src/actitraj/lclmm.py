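"""Latent class linear mixed models for multivariate longitudinal outcomes.

Model
-----
Each subject i contributes K outcomes observed at the same set of times
t_i (missing waves simply absent).  Given latent class g (probabilities
pi_g), outcome k follows a linear mixed model with class-specific fixed
intercept and slope and outcome-specific correlated random intercept and
slope shared across classes:

    y_ik | g  ~  N( X_i beta_kg,  X_i D_k X_i' + sigma2_k I ),   X_i = [1, t_i]

Outcomes are conditionally independent given class, so the marginal
log-likelihood is

    LL = sum_i log sum_g pi_g  prod_k  phi(y_ik; X_i beta_kg, V_ik).

Estimation is by EM treating class labels and random effects as missing
data, with a generalized M-step (coordinate updates of beta, D and sigma2
against the expected complete-data log-likelihood), which keeps the
observed-data log-likelihood monotone.  Multiple starts (one k-means start
on per-subject least-squares intercept/slope summaries plus seeded random
starts) guard against local maxima; classes are reported in descending
pi_g order to pin down label switching.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.special import logsumexp

LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class LclmmSpec:
    n_classes: int
    outcomes: tuple[str, ...]
    id_col: str = "participant_id"
    time_col: str = "time_years"
    n_starts: int = 4
    seed: int = 0
    max_iter: int = 500
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if len(self.outcomes) < 1:
            raise ValueError("need at least one outcome")
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")


@dataclass
class LclmmParams:
    """pi (G,), beta (G, K, 2), re_cov (K, 2, 2), sigma2 (K,)."""

    pi: np.ndarray
    beta: np.ndarray
    re_cov: np.ndarray
    sigma2: np.ndarray

    def validate(self) -> None:
        if (self.sigma2 <= 0).any():
            raise ValueError("residual variances must be positive")
        for k, D in enumerate(self.re_cov):
            if np.linalg.eigvalsh(D).min() <= 0:
                raise ValueError(f"random-effect covariance for outcome {k} not positive definite")

    def permuted(self, order: np.ndarray) -> "LclmmParams":
        return LclmmParams(
            pi=self.pi[order], beta=self.beta[order],
            re_cov=self.re_cov.copy(), sigma2=self.sigma2.copy(),
        )


@dataclass
class _Pattern:
    """Subjects sharing an observation-time vector, stacked for vectorisation."""

    times: np.ndarray       # (n_t,)
    X: np.ndarray           # (n_t, 2)
    Y: np.ndarray           # (m, n_t, K)
    idx: np.ndarray         # (m,) subject positions


def _prepare(data: pd.DataFrame, spec: LclmmSpec) -> tuple[list[_Pattern], list]:
    cols = [spec.id_col, spec.time_col, *spec.outcomes]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"data missing columns: {missing}")
    df = data[cols].sort_values([spec.id_col, spec.time_col])
    ids = sorted(df[spec.id_col].unique().tolist())
    pos = {sid: i for i, sid in enumerate(ids)}
    buckets: dict[tuple, list] = {}
    for sid, grp in df.groupby(spec.id_col, sort=True):
        t = tuple(np.round(grp[spec.time_col].to_numpy(dtype=float), 10))
        buckets.setdefault(t, []).append((pos[sid], grp[list(spec.outcomes)].to_numpy(dtype=float)))
    patterns = []
    for t, members in buckets.items():
        times = np.asarray(t)
        X = np.column_stack([np.ones_like(times), times])
        Y = np.stack([y for _, y in members])
        idx = np.asarray([i for i, _ in members])
        patterns.append(_Pattern(times=times, X=X, Y=Y, idx=idx))
    return patterns, ids


def _class_logdensity(patterns: list[_Pattern], params: LclmmParams, n_subjects: int) -> np.ndarray:
    """(N, G) matrix of per-subject, per-class log joint outcome densities."""
    G, K = params.beta.shape[0], params.beta.shape[1]
    out = np.zeros((n_subjects, G))
    for pat in patterns:
        n_t = len(pat.times)
        contrib = np.zeros((len(pat.idx), G))
        for k in range(K):
            V = pat.X @ params.re_cov[k] @ pat.X.T + params.sigma2[k] * np.eye(n_t)
            cho = cho_factor(V, lower=True)
            logdet = 2.0 * np.log(np.diag(cho[0])).sum()
            for g in range(G):
                R = pat.Y[:, :, k] - pat.X @ params.beta[g, k]       # (m, n_t)
                quad = np.einsum("mt,tm->m", R, cho_solve(cho, R.T))
                contrib[:, g] += -0.5 * (n_t * LOG2PI + logdet + quad)
        out[pat.idx] = contrib
    return out


def loglikelihood(spec: LclmmSpec, data: pd.DataFrame, params: LclmmParams) -> float:
    """Observed-data log-likelihood of the mixture at the given parameters."""
    params.validate()
    patterns, ids = _prepare(data, spec)
    logf = _class_logdensity(patterns, params, len(ids))
    return float(logsumexp(logf + np.log(params.pi), axis=1).sum())


def _em(
    patterns: list[_Pattern],
    params: LclmmParams,
    max_iter: int,
    tol: float,
) -> tuple[LclmmParams, float, np.ndarray, bool, np.ndarray]:
    G, K = params.beta.shape[0], params.beta.shape[1]
    N = sum(len(p.idx) for p in patterns)
    total_obs = sum(len(p.idx) * len(p.times) for p in patterns)
    ll_trace = []
    converged = False
    post = np.full((N, G), 1.0 / G)
    for _ in range(max_iter):
        # E-step
        logf = _class_logdensity(patterns, params, N)
        mix = logf + np.log(np.maximum(params.pi, 1e-300))
        norm = logsumexp(mix, axis=1)
        ll = float(norm.sum())
        post = np.exp(mix - norm[:, None])
        ll_trace.append(ll)
        if len(ll_trace) > 1:
            prev = ll_trace[-2]
            if abs(ll - prev) <= tol * max(1.0, abs(prev)):
                converged = True
                break

        # M-step (generalized): pi, then per-outcome beta, D, sigma2
        pi = post.mean(axis=0)
        pi = np.maximum(pi, 1e-12)
        pi = pi / pi.sum()

        # conditional random-effect moments per pattern/class/outcome
        beta_new = np.empty_like(params.beta)
        D_new = np.zeros_like(params.re_cov)
        sigma2_new = np.zeros_like(params.sigma2)
        cache = []  # per pattern: (C (K,2,2), M (G,K,m,2))
        for pat in patterns:
            XtX = pat.X.T @ pat.X
            C = np.empty((K, 2, 2))
            M = np.empty((G, K, len(pat.idx), 2))
            for k in range(K):
                Dk_inv = np.linalg.inv(params.re_cov[k])
                C[k] = np.linalg.inv(Dk_inv + XtX / params.sigma2[k])
                for g in range(G):
                    R = pat.Y[:, :, k] - pat.X @ params.beta[g, k]
                    M[g, k] = (R @ pat.X) @ C[k].T / params.sigma2[k]
            cache.append((C, M))

        for g in range(G):
            A = np.zeros((2, 2))
            b = np.zeros((K, 2))
            for pat, (C, M) in zip(patterns, cache):
                w = post[pat.idx, g]
                A += w.sum() * (pat.X.T @ pat.X)
                for k in range(K):
                    resid_mean = pat.Y[:, :, k] - M[g, k] @ pat.X.T   # (m, n_t)
                    b[k] += pat.X.T @ (w @ resid_mean)
            for k in range(K):
                beta_new[g, k] = np.linalg.solve(A, b[k])

        for pat, (C, M) in zip(patterns, cache):
            ZCZ_tr = np.array([np.trace(pat.X @ C[k] @ pat.X.T) for k in range(K)])
            for g in range(G):
                w = post[pat.idx, g]
                for k in range(K):
                    D_new[k] += np.einsum("m,ma,mb->ab", w, M[g, k], M[g, k]) + w.sum() * C[k]
                    res = pat.Y[:, :, k] - pat.X @ beta_new[g, k] - M[g, k] @ pat.X.T
                    sigma2_new[k] += float(w @ np.einsum("mt,mt->m", res, res)) + w.sum() * ZCZ_tr[k]
        D_new /= N
        sigma2_new = np.maximum(sigma2_new / total_obs, 1e-10)
        for k in range(K):
            D_new[k] = 0.5 * (D_new[k] + D_new[k].T)
            ev = np.linalg.eigvalsh(D_new[k]).min()
            if ev < 1e-10:
                D_new[k] += (1e-10 - ev) * np.eye(2)
        params = LclmmParams(pi=pi, beta=beta_new, re_cov=D_new, sigma2=sigma2_new)
    return params, ll_trace[-1], np.asarray(ll_trace), converged, post


def _subject_ols(patterns: list[_Pattern], n_subjects: int, K: int) -> np.ndarray:
    """Per-subject (intercept, slope) least-squares summaries, (N, 2K)."""
    S = np.zeros((n_subjects, 2 * K))
    for pat in patterns:
        if len(pat.times) >= 2:
            coef, *_ = np.linalg.lstsq(pat.X, pat.Y.reshape(len(pat.idx), len(pat.times), K).transpose(1, 0, 2).reshape(len(pat.times), -1), rcond=None)
            coef = coef.reshape(2, len(pat.idx), K)
            for j, i in enumerate(pat.idx):
                S[i, 0::2] = coef[0, j]
                S[i, 1::2] = coef[1, j]
        else:
            for j, i in enumerate(pat.idx):
                S[i, 0::2] = pat.Y[j, 0]
                S[i, 1::2] = 0.0
    return S


def _params_from_labels(
    patterns: list[_Pattern], labels: np.ndarray, G: int, K: int, N: int
) -> LclmmParams:
    labels = labels.copy()
    # guarantee every class non-empty
    for g in range(G):
        if not (labels == g).any():
            labels[np.argmax(np.bincount(labels, minlength=G)[labels])] = g
    pi = np.bincount(labels, minlength=G).astype(float)
    pi = np.maximum(pi, 0.5) / np.maximum(pi, 0.5).sum()
    beta = np.zeros((G, K, 2))
    resid_var = np.zeros(K)
    for k in range(K):
        sse, n_obs = 0.0, 0
        for g in range(G):
            Xs, ys = [], []
            for pat in patterns:
                sel = np.isin(pat.idx, np.flatnonzero(labels == g))
                if sel.any():
                    m = int(sel.sum())
                    Xs.append(np.tile(pat.X, (m, 1)))
                    ys.append(pat.Y[sel, :, k].ravel())
            X_all = np.vstack(Xs) if Xs else np.zeros((0, 2))
            y_all = np.concatenate(ys) if ys else np.zeros(0)
            if len(y_all) >= 2 and np.linalg.matrix_rank(X_all) == 2:
                coef, *_ = np.linalg.lstsq(X_all, y_all, rcond=None)
            elif len(y_all):
                coef = np.array([y_all.mean(), 0.0])
            else:
                coef = np.zeros(2)
            beta[g, k] = coef
            sse += float(((y_all - X_all @ coef) ** 2).sum())
            n_obs += len(y_all)
        resid_var[k] = max(sse / max(n_obs - 2 * G, 1), 1e-6)
    re_cov = np.stack([np.diag([0.4 * v, 0.1 * v]) for v in resid_var])
    sigma2 = 0.6 * resid_var
    return LclmmParams(pi=pi, beta=beta, re_cov=re_cov, sigma2=sigma2)


def relative_entropy(posterior: np.ndarray) -> float:
    """1 minus the normalized mean posterior uncertainty; in [0, 1].

    Degenerate 0/1 posteriors give 1; uniform posteriors give 0; defined as
    1 when there is a single class.
    """
    post = np.asarray(posterior, dtype=float)
    n, G = post.shape
    if G == 1:
        return 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(post > 0, post * np.log(post), 0.0)
    return float(1.0 + plogp.sum() / (n * np.log(G)))


def classify(posterior: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Modal assignment plus per-class mean posterior among members.

    Returns (assignments, per-class mean posterior with NaN for empty
    classes, lowest mean posterior over non-empty classes).  Ties go to the
    lowest class index.
    """
    post = np.asarray(posterior, dtype=float)
    assignments = post.argmax(axis=1)
    G = post.shape[1]
    means = np.full(G, np.nan)
    for g in range(G):
        members = assignments == g
        if members.any():
            means[g] = post[members, g].mean()
    lowest = float(np.nanmin(means))
    return assignments, means, lowest


@dataclass
class LclmmFit:
    spec: LclmmSpec
    params: LclmmParams
    loglik: float
    n_params: int
    aic: float
    bic: float
    posterior: np.ndarray
    assignments: np.ndarray
    subject_ids: list
    entropy: float
    class_mean_posterior: np.ndarray
    lowest_mean_posterior: float
    converged: bool
    best_start: int
    n_iter: int
    ll_trace: np.ndarray
    degenerate_classes: list[int] = field(default_factory=list)

    @property
    def class_sizes(self) -> np.ndarray:
        return np.bincount(self.assignments, minlength=self.spec.n_classes)

    def to_json(self, path: str | Path) -> None:
        K = len(self.spec.outcomes)
        payload = {
            "n_classes": self.spec.n_classes,
            "outcomes": list(self.spec.outcomes),
            "pi": self.params.pi.tolist(),
            "beta": {
                outcome: {
                    f"class_{g + 1}": {
                        "intercept": self.params.beta[g, k, 0],
                        "slope_per_year": self.params.beta[g, k, 1],
                    }
                    for g in range(self.spec.n_classes)
                }
                for k, outcome in enumerate(self.spec.outcomes)
            },
            "random_effects": {
                outcome: {
                    "var_intercept": self.params.re_cov[k][0, 0],
                    "var_slope": self.params.re_cov[k][1, 1],
                    "correlation": self.params.re_cov[k][0, 1]
                    / max(np.sqrt(self.params.re_cov[k][0, 0] * self.params.re_cov[k][1, 1]), 1e-300),
                    "residual_variance": self.params.sigma2[k],
                }
                for k, outcome in enumerate(self.spec.outcomes)
            },
            "loglik": self.loglik,
            "n_params": self.n_params,
            "aic": self.aic,
            "bic": self.bic,
            "entropy": self.entropy,
            "class_mean_posterior": self.class_mean_posterior.tolist(),
            "lowest_mean_posterior": self.lowest_mean_posterior,
            "converged": self.converged,
            "best_start": self.best_start,
            "class_sizes": self.class_sizes.tolist(),
            "degenerate_classes": self.degenerate_classes,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    def posterior_frame(self) -> pd.DataFrame:
        G = self.spec.n_classes
        df = pd.DataFrame(
            self.posterior, columns=[f"posterior_class_{g + 1}" for g in range(G)]
        )
        df.insert(0, "participant_id", self.subject_ids)
        df["assigned_class"] = self.assignments + 1
        return df


def n_parameters(G: int, K: int) -> int:
    """Mixing proportions + class/outcome fixed effects + per-outcome
    variance components (2 variances, 1 covariance, 1 residual)."""
    return (G - 1) + 2 * K * G + 4 * K


def fit(spec: LclmmSpec, data: pd.DataFrame) -> LclmmFit:
    """Maximum-likelihood fit by multistart EM; see the module docstring."""
    patterns, ids = _prepare(data, spec)
    N, G, K = len(ids), spec.n_classes, len(spec.outcomes)
    if N < G:
        raise ValueError("fewer subjects than classes")
    rng = np.random.default_rng(spec.seed)

    starts: list[np.ndarray] = []
    if G == 1:
        starts.append(np.zeros(N, dtype=int))
    else:
        S = _subject_ols(patterns, N, K)
        scale = S.std(axis=0, ddof=0)
        scale[scale == 0] = 1.0
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=G, n_init=10, random_state=spec.seed)
        starts.append(km.fit_predict(S / scale))
        for _ in range(spec.n_starts - 1):
            starts.append(rng.integers(0, G, size=N))

    best = None
    for s_idx, labels in enumerate(starts):
        init = _params_from_labels(patterns, np.asarray(labels), G, K, N)
        params, ll, trace, converged, post = _em(patterns, init, spec.max_iter, spec.tol)
        if best is None or ll > best[1] + 1e-9:
            best = (params, ll, trace, converged, post, s_idx)
    params, ll, trace, converged, post, s_idx = best

    order = np.argsort(-params.pi, kind="stable")
    params = params.permuted(order)
    post = post[:, order]
    assignments, class_means, lowest = classify(post)
    k_par = n_parameters(G, K)
    degenerate = [int(g) for g in range(G) if params.pi[g] < 1.0 / (2 * N)]
    return LclmmFit(
        spec=spec,
        params=params,
        loglik=ll,
        n_params=k_par,
        aic=-2.0 * ll + 2.0 * k_par,
        bic=-2.0 * ll + k_par * np.log(N),
        posterior=post,
        assignments=assignments,
        subject_ids=ids,
        entropy=relative_entropy(post),
        class_mean_posterior=class_means,
        lowest_mean_posterior=lowest,
        converged=converged,
        best_start=s_idx,
        n_iter=len(trace),
        ll_trace=trace,
        degenerate_classes=degenerate,
    )
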