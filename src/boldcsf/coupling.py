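"""Lagged gBOLD-CSF cross-correlation, coupling metrics, and the
subject-shuffling permutation null.

Lag sign convention: for lag k samples the pairs are ``(g[t+k], c[t])``,
so NEGATIVE lag means gBOLD leads CSF.  The physiological pattern is a
positive correlation peak at negative lag and a negative peak at positive
lag; the per-subject headline statistic is the correlation at the fixed
+4 s lag.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np

from .preproc import TimeSeries, negative_derivative

__all__ = [
    "CouplingConfig",
    "CouplingCurve",
    "Peak",
    "CouplingMetrics",
    "NullDistribution",
    "cross_correlation",
    "coupling_strength",
    "find_peaks",
    "derivative_coupling",
    "group_mean_curve",
    "compute_metrics",
    "permutation_null",
]


@dataclass
class CouplingConfig:
    """Lag window and metric-lag settings.

    ``metric_mode`` is ``"fixed-lag"`` (correlation at exactly
    ``+metric_lag_s``) or ``"searched-minimum"`` (minimum correlation over
    positive lags, for sensitivity analysis).
    """

    max_lag_s: float = 10.0
    metric_lag_s: float = 4.0
    metric_mode: str = "fixed-lag"

    def __post_init__(self) -> None:
        if not self.metric_lag_s > 0:
            raise ValueError("metric_lag_s must be positive")
        if self.max_lag_s < self.metric_lag_s:
            raise ValueError("max_lag_s must be >= metric_lag_s")
        if self.metric_mode not in ("fixed-lag", "searched-minimum"):
            raise ValueError(f"unknown metric_mode {self.metric_mode!r}")

    def max_lag_samples(self, dt: float) -> int:
        return int(round(self.max_lag_s / dt))

    def metric_lag_samples(self, dt: float) -> int:
        k = int(round(self.metric_lag_s / dt))
        if abs(k * dt - self.metric_lag_s) > 1e-9:
            warnings.warn(
                f"metric lag {self.metric_lag_s} s not on the dt={dt} s grid; "
                f"rounded to {k * dt} s",
                stacklevel=2,
            )
        return k


@dataclass
class CouplingCurve:
    """Correlation value per lag over a symmetric lag grid (seconds)."""

    lags_s: np.ndarray
    r: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self) -> None:
        self.lags_s = np.asarray(self.lags_s, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)
        if not (self.lags_s.shape == self.r.shape == self.n_pairs.shape):
            raise ValueError("lags_s, r and n_pairs must have equal shapes")
        if self.lags_s.size == 0:
            raise ValueError("empty coupling curve")
        if np.any(np.abs(self.r) > 1.0 + 1e-9):
            raise ValueError("|r| must not exceed 1")

    def value_at(self, lag_s: float) -> float:
        idx = np.flatnonzero(np.isclose(self.lags_s, lag_s, atol=1e-9))
        if idx.size == 0:
            raise ValueError(f"lag {lag_s} s not on the curve grid {self.lags_s}")
        return float(self.r[idx[0]])


@dataclass
class Peak:
    lag_s: float
    r: float


@dataclass
class CouplingMetrics:
    strength: float
    pos_peak: Peak
    neg_peak: Peak
    deriv_peak: Peak
    metric_mode: str = "fixed-lag"


@dataclass
class NullDistribution:
    """Permutation-null summary for the cohort coupling statistic."""

    n_iter: int
    values: np.ndarray
    seed: int
    observed: float
    p_two_sided: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != self.n_iter:
            raise ValueError("values length must equal n_iter")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xm = x - x.mean()
    ym = y - y.mean()
    denom = np.sqrt((xm @ xm) * (ym @ ym))
    if denom == 0:
        raise ValueError("zero variance in overlap segment")
    return float(np.clip((xm @ ym) / denom, -1.0, 1.0))


def _aligned(g: TimeSeries, c: TimeSeries) -> tuple[np.ndarray, np.ndarray, float]:
    if abs(g.dt - c.dt) > 1e-12:
        raise ValueError(f"sampling intervals differ: {g.dt} vs {c.dt}")
    if abs(len(g) - len(c)) > 1:
        raise ValueError(
            f"series lengths {len(g)} and {len(c)} differ by more than one sample"
        )
    n = min(len(g), len(c))
    return g.values[:n], c.values[:n], g.dt


def cross_correlation(g: TimeSeries, c: TimeSeries, cfg: CouplingConfig | None = None) -> CouplingCurve:
    """Per-lag Pearson correlation of ``(g[t+k], c[t])`` over the overlap.

    Each lag's correlation is computed on its own overlapping segment with
    that segment's means and SDs, so ``|r| <= 1`` holds exactly at every
    lag.  Lags run over ``k = -K..K`` samples with ``K = round(max_lag_s / dt)``.
    """
    cfg = cfg or CouplingConfig()
    gv, cv, dt = _aligned(g, c)
    n = gv.size
    K = cfg.max_lag_samples(dt)
    if n <= 2 * K:
        raise ValueError(f"series of length {n} too short for a +/-{K}-sample lag window")
    lags, rs, n_pairs = [], [], []
    for k in range(-K, K + 1):
        if k >= 0:
            x, y = gv[k:], cv[: n - k]
        else:
            x, y = gv[: n + k], cv[-k:]
        lags.append(k * dt)
        rs.append(_pearson(x, y))
        n_pairs.append(x.size)
    return CouplingCurve(lags_s=np.array(lags), r=np.array(rs), n_pairs=np.array(n_pairs))


def coupling_strength(curve: CouplingCurve, cfg: CouplingConfig | None = None) -> float:
    """Per-subject coupling statistic from a curve.

    Fixed-lag mode returns r at exactly ``+metric_lag_s``; searched mode
    returns the minimum r over strictly positive lags up to ``max_lag_s``.
    """
    cfg = cfg or CouplingConfig()
    if cfg.metric_mode == "fixed-lag":
        try:
            return curve.value_at(cfg.metric_lag_s)
        except ValueError:
            pos = curve.lags_s[curve.lags_s > 0]
            if pos.size == 0:
                raise
            nearest = float(pos[np.argmin(np.abs(pos - cfg.metric_lag_s))])
            warnings.warn(
                f"metric lag {cfg.metric_lag_s} s not on the curve grid; "
                f"using nearest positive lag {nearest} s",
                stacklevel=2,
            )
            return curve.value_at(nearest)
    sel = (curve.lags_s > 0) & (curve.lags_s <= cfg.max_lag_s + 1e-9)
    if not sel.any():
        raise ValueError("no positive lags on the curve grid")
    return float(curve.r[sel].min())


def _extreme(curve: CouplingCurve, sign: int) -> Peak:
    # ties broken toward smallest |lag|, then toward negative lag
    order = np.lexsort((curve.lags_s, np.abs(curve.lags_s)))
    vals = sign * curve.r[order]
    best = order[int(np.argmax(vals))]
    return Peak(lag_s=float(curve.lags_s[best]), r=float(curve.r[best]))


def find_peaks(curve: CouplingCurve) -> tuple[Peak, Peak]:
    """(positive peak, negative peak) = (argmax, argmin) over the lag grid."""
    return _extreme(curve, +1), _extreme(curve, -1)


def derivative_coupling(g: TimeSeries, c: TimeSeries, cfg: CouplingConfig | None = None) -> CouplingCurve:
    """Cross-correlation between -dg/dt and the CSF signal.

    The forward-difference derivative is one sample shorter; the CSF
    series is truncated by one trailing sample to align.
    """
    return cross_correlation(negative_derivative(g), c, cfg)


def group_mean_curve(curves: list[CouplingCurve]) -> CouplingCurve:
    """Pointwise arithmetic mean of r over subjects (identical lag grids)."""
    if not curves:
        raise ValueError("no curves to average")
    lags = curves[0].lags_s
    for cu in curves[1:]:
        if cu.lags_s.shape != lags.shape or not np.allclose(cu.lags_s, lags):
            raise ValueError("curves have mismatched lag grids")
    return CouplingCurve(
        lags_s=lags.copy(),
        r=np.mean([cu.r for cu in curves], axis=0),
        n_pairs=curves[0].n_pairs.copy(),
    )


def compute_metrics(g: TimeSeries, c: TimeSeries, cfg: CouplingConfig | None = None) -> CouplingMetrics:
    """All per-subject coupling metrics for one signal pair."""
    cfg = cfg or CouplingConfig()
    curve = cross_correlation(g, c, cfg)
    pos, neg = find_peaks(curve)
    dcurve = derivative_coupling(g, c, cfg)
    dpos, _ = find_peaks(dcurve)
    return CouplingMetrics(
        strength=coupling_strength(curve, cfg),
        pos_peak=pos,
        neg_peak=neg,
        deriv_peak=dpos,
        metric_mode=cfg.metric_mode,
    )


def _random_derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    # rejection sampling; acceptance probability ~ 1/e
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


def _pairwise_fixed_lag_matrix(
    gbold: list[TimeSeries], csf: list[TimeSeries], k: int
) -> np.ndarray:
    """r[i, j] = Pearson of (g_i[t+k], c_j[t]) at fixed positive lag k."""
    n = min(min(len(s) for s in gbold), min(len(s) for s in csf))
    G = np.stack([s.values[:n][k:] for s in gbold])
    C = np.stack([s.values[:n][: n - k] for s in csf])
    G = G - G.mean(axis=1, keepdims=True)
    C = C - C.mean(axis=1, keepdims=True)
    gn = np.linalg.norm(G, axis=1)
    cn = np.linalg.norm(C, axis=1)
    if np.any(gn == 0) or np.any(cn == 0):
        raise ValueError("zero variance in a subject's overlap segment")
    return np.clip((G @ C.T) / np.outer(gn, cn), -1.0, 1.0)


def permutation_null(
    gbold_by_subject: list[TimeSeries],
    csf_by_subject: list[TimeSeries],
    cfg: CouplingConfig | None = None,
    n_iter: int = 10_000,
    seed: int = 0,
    allow_self_pairing: bool = False,
) -> NullDistribution:
    """Subject-shuffling null for the cohort-mean fixed-lag coupling.

    Each iteration draws a random derangement (no subject keeps its own
    CSF; simple permutations via ``allow_self_pairing``), evaluates the
    fixed +4 s lag correlation for every mismatched pair, and averages over
    subjects.  ``p_two_sided = (#{|null| >= |observed|} + 1) / (n_iter + 1)``.
    """
    cfg = cfg or CouplingConfig()
    n_sub = len(gbold_by_subject)
    if n_sub != len(csf_by_subject):
        raise ValueError("gbold and csf subject lists differ in length")
    if n_sub < 3:
        raise ValueError(f"need >= 3 subjects for the permutation null, got {n_sub}")
    dt = gbold_by_subject[0].dt
    k = cfg.metric_lag_samples(dt)
    R = _pairwise_fixed_lag_matrix(gbold_by_subject, csf_by_subject, k)
    observed = float(np.mean(np.diag(R)))
    rng = np.random.default_rng(seed)
    values = np.empty(n_iter)
    idx = np.arange(n_sub)
    for i in range(n_iter):
        perm = rng.permutation(n_sub) if allow_self_pairing else _random_derangement(n_sub, rng)
        values[i] = R[idx, perm].mean()
    p = (np.count_nonzero(np.abs(values) >= abs(observed)) + 1) / (n_iter + 1)
    return NullDistribution(
        n_iter=n_iter, values=values, seed=seed, observed=observed, p_two_sided=float(p)
    )
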