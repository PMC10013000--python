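"""Muscle synergy extraction by multiplicative-update NNMF, with the
amplitude and shape metrics used to compare support levels.

The grand-average envelopes of the four support levels (200 samples x m
muscles each) are stacked into an (s*k) x m matrix (800 x 24 for the full
muscle set) and factorised as ``X ~ P_cat @ W.T`` with non-negative
temporal patterns ``P_cat`` ((s*k) x n, one 200-row block per level) and
spatial weighting coefficients ``W`` (m x n) shared across levels. The
number of synergies is the smallest n in 1..7 whose reconstruction quality

    lambda(n) = (1 - ||X - P W'||_F^2 / ||X||_F^2) * 100%

reaches the criterion (88%) within every level's 200-row block.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .datatypes import LEVELS

logger = logging.getLogger(__name__)

_EPS = 1e-12


# ---------------------------------------------------------------------------
# estimator


class MuscleSynergyNMF(BaseEstimator):
    """Non-negative matrix factorisation by Lee-Seung multiplicative updates.

    Factorises a non-negative matrix ``X`` (samples x muscles) as
    ``X ~ H @ W.T`` with temporal activations ``H`` (samples x n_components)
    and muscle weights ``W`` (muscles x n_components), minimising the squared
    Frobenius error. The best of ``n_restarts`` random non-negative
    initialisations (by reconstruction quality) is kept. After fitting, each
    weight column is scaled to unit maximum with the compensating rescale
    applied to ``H``, so the reconstruction is unchanged but weights are
    comparable across fits.

    Parameters
    ----------
    n_components : int
        Number of synergies n (1 <= n <= number of muscles).
    n_restarts : int, default 20
        Random initialisations; the solution with the lowest objective wins.
    max_iter : int, default 2000
        Multiplicative-update iterations per restart.
    tol : float, default 1e-8
        Stop a restart when the relative objective decrease per iteration
        falls below this.
    random_state : int or numpy Generator, optional
        Seeds the initialisations.

    Attributes
    ----------
    weights_ : ndarray (n_muscles, n_components)
        Spatial weighting coefficients, columns scaled to unit maximum.
    patterns_ : ndarray (n_samples, n_components)
        Temporal activations compensating the weight scaling.
    reconstruction_quality_ : float
        lambda of the kept solution, in percent.
    n_iter_ : int
        Iterations used by the kept restart.
    converged_ : bool
        Whether the kept restart met ``tol`` before ``max_iter``.
    """

    def __init__(self, n_components: int = 4, n_restarts: int = 20,
                 max_iter: int = 2000, tol: float = 1e-8,
                 random_state=None):
        self.n_components = n_components
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def _validate(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x muscles)")
        if np.any(X < 0):
            raise ValueError("X must be element-wise non-negative")
        if not np.any(X > 0):
            raise ValueError("X must not be all zero")
        if not 1 <= self.n_components <= X.shape[1]:
            raise ValueError("need 1 <= n_components <= number of muscles")
        return X

    def _run_mu(self, X, H, W):
        """Multiplicative updates from a given initialisation.

        Returns (H, W, objective, n_iter, converged). The update pair never
        increases the objective and never produces a negative entry.
        """
        sq_norm = float((X ** 2).sum())
        obj_prev = np.inf
        n_iter = 0
        converged = False
        for n_iter in range(1, self.max_iter + 1):
            XW = X @ W                                   # (samples x n)
            H *= XW / (H @ (W.T @ W) + _EPS)
            XtH = X.T @ H                                # (muscles x n)
            HtH = H.T @ H
            W *= XtH / (W @ HtH + _EPS)
            # objective via the Gram trick: ||X-HW'||^2 = ||X||^2 - 2<X'H, W> + <H'H, W'W>
            cross = float((XtH * W).sum())
            quad = float((HtH * (W.T @ W)).sum())
            obj = max(sq_norm - 2.0 * cross + quad, 0.0)
            if np.isfinite(obj_prev) and obj_prev - obj <= self.tol * max(obj_prev, _EPS):
                converged = True
                break
            obj_prev = obj
        return H, W, obj, n_iter, converged

    def fit(self, X, y=None, warm_start: Optional[tuple[np.ndarray, np.ndarray]] = None):
        """Fit the factorisation to ``X``.

        ``warm_start`` optionally adds one extra restart from a given
        ``(H0, W0)`` initialisation (used by the model-order sweep to chain
        solutions across n, which makes lambda(n) non-decreasing).
        """
        X = self._validate(X)
        rng = np.random.default_rng(self.random_state)
        n = self.n_components
        scale = np.sqrt(X.mean() / n)

        inits = []
        for _ in range(max(1, self.n_restarts)):
            inits.append((rng.uniform(_EPS, 1.0, size=(X.shape[0], n)) * scale,
                          rng.uniform(_EPS, 1.0, size=(X.shape[1], n)) * scale))
        if warm_start is not None:
            H0, W0 = warm_start
            if H0.shape != (X.shape[0], n) or W0.shape != (X.shape[1], n):
                raise ValueError("warm_start shapes inconsistent with X / n_components")
            inits.append((np.maximum(H0, _EPS).copy(), np.maximum(W0, _EPS).copy()))

        best = None
        for H0, W0 in inits:
            H, W, obj, n_iter, converged = self._run_mu(X, H0, W0)
            if best is None or obj < best[2]:
                best = (H, W, obj, n_iter, converged)
        H, W, obj, n_iter, converged = best
        if not converged:
            logger.warning("NNMF (n=%d) did not converge in %d iterations", n, self.max_iter)

        # scale indeterminacy: unit-maximum weight columns
        cmax = W.max(axis=0)
        nz = cmax > 0
        W[:, nz] /= cmax[nz]
        H[:, nz] *= cmax[nz]

        self.weights_ = W
        self.patterns_ = H
        self.n_iter_ = n_iter
        self.converged_ = converged
        self.objective_ = obj
        self.reconstruction_quality_ = reconstruction_quality(X, W, H)
        return self

    def fit_transform(self, X, y=None, **fit_params) -> np.ndarray:
        """Fit and return the temporal activations ``patterns_``."""
        return self.fit(X, **fit_params).patterns_

    def inverse_transform(self, H: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "weights_")
        return np.asarray(H) @ self.weights_.T


# ---------------------------------------------------------------------------
# model container and level-aware wrappers


@dataclass
class SynergyModel:
    """A fitted synergy decomposition with per-level temporal patterns."""

    n: int
    W: np.ndarray                       # muscles x n, unit-max columns
    P: dict[str, np.ndarray]            # level -> 200 x n
    lambda_by_level: dict[str, float]
    lambda_overall: float
    order: list[int]                    # permutation applied for reporting
    fit_meta: dict = field(default_factory=dict)
    channels: list[str] = field(default_factory=list)
    criterion_met: bool = True

    @property
    def P_cat(self) -> np.ndarray:
        keys = [lv for lv in LEVELS if lv in self.P] or list(self.P)
        return np.vstack([self.P[lv] for lv in keys])

    def reconstruction(self) -> np.ndarray:
        return self.P_cat @ self.W.T


def concatenate_levels(
    averages: dict[str, "np.ndarray | object"],
) -> tuple[np.ndarray, dict[str, slice]]:
    """Stack the per-level mean envelopes into one (s*k) x m design matrix.

    Levels are stacked in fixed order no -> low -> medium -> high; the
    returned index maps each level to its row block (used to evaluate the
    per-level reconstruction criterion and to split fitted patterns).
    """
    blocks = []
    index: dict[str, slice] = {}
    row = 0
    for lv in LEVELS:
        if lv not in averages:
            raise ValueError(f'support level "{lv}" missing from averages')
        block = averages[lv]
        if not isinstance(block, np.ndarray):  # GrandAverage or similar
            block = block.mean
        block = np.asarray(block, dtype=float)
        blocks.append(block)
        index[lv] = slice(row, row + block.shape[0])
        row += block.shape[0]
    X = np.vstack(blocks)
    if len({b.shape[1] for b in blocks}) != 1:
        raise ValueError("levels disagree on the muscle set")
    return X, index


def reconstruction_quality(
    X: np.ndarray, W: np.ndarray, P_cat: np.ndarray,
    rows: Optional[slice] = None,
) -> float:
    """lambda in percent: share of the squared Frobenius norm reconstructed.

    With ``rows`` given, both the data and the reconstruction are restricted
    to that row block (one support level).
    """
    X = np.asarray(X, dtype=float)
    R = P_cat @ W.T
    if rows is not None:
        X, R = X[rows], R[rows]
    denom = float((X ** 2).sum())
    if denom == 0:
        raise ValueError("zero-norm selection: lambda undefined")
    return float((1.0 - ((X - R) ** 2).sum() / denom) * 100.0)


def _model_from_estimator(est: MuscleSynergyNMF, X, level_index, channels=None) -> SynergyModel:
    W, H = est.weights_, est.patterns_
    lam_lv = {lv: reconstruction_quality(X, W, H, rows=sl) for lv, sl in level_index.items()}
    return SynergyModel(
        n=est.n_components,
        W=W,
        P={lv: H[sl] for lv, sl in level_index.items()},
        lambda_by_level=lam_lv,
        lambda_overall=est.reconstruction_quality_,
        order=list(range(est.n_components)),
        fit_meta={"seed": est.random_state, "restarts": est.n_restarts,
                  "iterations": est.n_iter_, "converged": est.converged_,
                  "objective": est.objective_},
        channels=list(channels) if channels else [],
    )


def nnmf(
    X: np.ndarray, n: int, seed: int = 0, restarts: int = 20,
    max_iter: int = 2000, tol: float = 1e-8,
    level_index: Optional[dict[str, slice]] = None,
    channels: Optional[Sequence[str]] = None,
    warm_start=None,
) -> SynergyModel:
    """Factorise ``X`` into ``n`` synergies; thin wrapper over the estimator."""
    est = MuscleSynergyNMF(n_components=n, n_restarts=restarts, max_iter=max_iter,
                           tol=tol, random_state=seed)
    est.fit(X, warm_start=warm_start)
    if level_index is None:
        level_index = {"all": slice(0, X.shape[0])}
    return _model_from_estimator(est, X, level_index, channels)


def select_n(
    X: np.ndarray, level_index: dict[str, slice],
    n_range: Sequence[int] = range(1, 8), criterion: float = 88.0,
    seed: int = 0, restarts: int = 20, max_iter: int = 2000, tol: float = 1e-8,
    channels: Optional[Sequence[str]] = None,
) -> SynergyModel:
    """Smallest n whose lambda reaches ``criterion`` in every level block.

    Models are fitted for increasing n; each n >= 2 adds one warm-started
    restart chained from the previous solution (padded with a near-zero
    column), which guarantees lambda(n) is non-decreasing. If no n in
    ``n_range`` qualifies, the largest-n model is returned with
    ``criterion_met=False``.
    """
    n_range = sorted(n_range)
    if not n_range:
        raise ValueError("n_range must be non-empty")
    ss = np.random.SeedSequence(seed)
    prev = None
    model = None
    for n, child in zip(n_range, ss.spawn(len(n_range))):
        warm = None
        if prev is not None and n == prev.n + 1:
            pad_h = np.full((X.shape[0], 1), _EPS)
            pad_w = np.full((X.shape[1], 1), _EPS)
            warm = (np.hstack([prev.P_cat, pad_h]), np.hstack([prev.W, pad_w]))
        est = MuscleSynergyNMF(n_components=n, n_restarts=restarts,
                               max_iter=max_iter, tol=tol,
                               random_state=np.random.default_rng(child))
        est.fit(X, warm_start=warm)
        model = _model_from_estimator(est, X, level_index, channels)
        model.fit_meta["seed"] = seed
        if all(lam >= criterion for lam in model.lambda_by_level.values()):
            return model
        prev = model
    model.criterion_met = False
    logger.warning("no n in %s reached lambda >= %.1f%% in every level", list(n_range), criterion)
    return model


def lambda_curve(
    X: np.ndarray, n_range: Sequence[int] = range(1, 8),
    seed: int = 0, restarts: int = 20, max_iter: int = 2000, tol: float = 1e-8,
) -> dict[int, float]:
    """Best-of-restarts lambda(n) over a model-order sweep (diagnostic).

    Uses the same warm-start chaining as :func:`select_n`, so the curve is
    non-decreasing up to floating-point rounding.
    """
    index = {"all": slice(0, np.asarray(X).shape[0])}
    out: dict[int, float] = {}
    prev = None
    ss = np.random.SeedSequence(seed)
    for n, child in zip(sorted(n_range), ss.spawn(len(list(n_range)))):
        warm = None
        if prev is not None and n == prev.n + 1:
            warm = (np.hstack([prev.P_cat, np.full((X.shape[0], 1), _EPS)]),
                    np.hstack([prev.W, np.full((X.shape[1], 1), _EPS)]))
        model = nnmf(X, n, seed=np.random.default_rng(child), restarts=restarts,
                     max_iter=max_iter, tol=tol, level_index=index, warm_start=warm)
        out[n] = model.lambda_overall
        prev = model
    return out


# ---------------------------------------------------------------------------
# ordering, metrics, similarity


def order_synergies(model: SynergyModel, reference_level: str = "no") -> SynergyModel:
    """Sort synergies by the peak time of their no-support temporal pattern.

    Ascending peak sample; ties broken by descending weight-column norm. For
    four locomotor synergies this yields the conventional order right foot
    strike (S1), right stance (S2), left foot strike (S3), left stance (S4).
    """
    if reference_level not in model.P:
        raise ValueError(f"model has no patterns for level {reference_level!r}")
    P_ref = model.P[reference_level]
    peaks = P_ref.argmax(axis=0)
    norms = np.linalg.norm(model.W, axis=0)
    order = sorted(range(model.n), key=lambda i: (peaks[i], -norms[i]))
    return SynergyModel(
        n=model.n,
        W=model.W[:, order],
        P={lv: p[:, order] for lv, p in model.P.items()},
        lambda_by_level=dict(model.lambda_by_level),
        lambda_overall=model.lambda_overall,
        order=order,
        fit_meta=dict(model.fit_meta),
        channels=list(model.channels),
        criterion_met=model.criterion_met,
    )


def circular_xcorr(p: np.ndarray, q: np.ndarray) -> tuple[float, int]:
    """Maximum Pearson correlation between ``p`` and circular shifts of ``q``.

    Returns ``(r_max, lag)`` where ``lag`` is the smallest non-negative shift
    achieving the maximum. Both inputs must have the same length and non-zero
    variance; a pattern correlated with itself gives (1, 0).
    """
    p = np.asarray(p, dtype=float).ravel()
    q = np.asarray(q, dtype=float).ravel()
    if p.shape != q.shape:
        raise ValueError("p and q must have equal length")
    pc, qc = p - p.mean(), q - q.mean()
    sp, sq = np.sqrt((pc ** 2).sum()), np.sqrt((qc ** 2).sum())
    if sp == 0 or sq == 0:
        raise ValueError("circular cross-correlation undefined for zero-variance input")
    # c[k] = sum_t pc[t] * qc[(t - k) mod n] = corr with np.roll(q, k)
    c = np.fft.irfft(np.fft.rfft(pc) * np.conj(np.fft.rfft(qc)), n=p.size)
    r = c / (sp * sq)
    lag = int(np.argmax(r))
    return float(r[lag]), lag


@dataclass
class SynergyMetrics:
    """Amplitude and shape metrics per synergy across support levels."""

    mean_amplitude_change: dict[str, np.ndarray]   # level -> per-synergy %
    peak_normalized_patterns: dict[str, np.ndarray]  # level -> 200 x n
    circ_xcorr: dict[tuple[str, str], np.ndarray]  # (level_a, level_b) -> per-synergy r
    circ_lag: dict[tuple[str, str], np.ndarray]


def amplitude_metrics(model: SynergyModel, reference_level: str = "no") -> SynergyMetrics:
    """Mean-amplitude change vs no support, peak-normalized patterns, and
    circular cross-correlations between all level pairs.

    ``mean_amplitude_change[level][i] = 100 * (mean(P_level_i) - mean(P_no_i))
    / mean(P_no_i)``; undefined entries (zero reference mean or zero maximum)
    are reported as NaN.
    """
    if reference_level not in model.P:
        raise ValueError(f"model has no patterns for level {reference_level!r}")
    ref_mean = model.P[reference_level].mean(axis=0)
    changes: dict[str, np.ndarray] = {}
    normed: dict[str, np.ndarray] = {}
    for lv, P in model.P.items():
        mu = P.mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            changes[lv] = np.where(ref_mean > 0, 100.0 * (mu - ref_mean) / ref_mean, np.nan)
        peak = P.max(axis=0)
        normed[lv] = np.where(peak > 0, P / np.where(peak > 0, peak, 1.0), np.nan)
    xcorr: dict[tuple[str, str], np.ndarray] = {}
    lags: dict[tuple[str, str], np.ndarray] = {}
    present = [lv for lv in LEVELS if lv in model.P]
    for a_i, a in enumerate(present):
        for b in present[a_i + 1:]:
            r = np.empty(model.n)
            g = np.empty(model.n, dtype=int)
            for i in range(model.n):
                r[i], g[i] = circular_xcorr(model.P[a][:, i], model.P[b][:, i])
            xcorr[(a, b)] = r
            lags[(a, b)] = g
    return SynergyMetrics(mean_amplitude_change=changes,
                          peak_normalized_patterns=normed,
                          circ_xcorr=xcorr, circ_lag=lags)


def cosine_similarity_columns(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def match_synergies(W_ref: np.ndarray, W_est: np.ndarray) -> list[int]:
    """Greedy assignment of estimated to reference synergies.

    Repeatedly pairs the globally most cosine-similar (reference, estimate)
    columns. Returns ``perm`` with ``perm[j]`` the estimated column matched
    to reference column ``j``. Deterministic; ties resolved by index order.
    """
    n = W_ref.shape[1]
    if W_est.shape[1] != n:
        raise ValueError("column counts differ")
    sim = np.array([[cosine_similarity_columns(W_ref[:, i], W_est[:, j])
                     for j in range(n)] for i in range(n)])
    perm = [-1] * n
    free = sim.copy()
    for _ in range(n):
        i, j = np.unravel_index(np.argmax(free), free.shape)
        perm[i] = int(j)
        free[i, :] = -np.inf
        free[:, j] = -np.inf
    return perm
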