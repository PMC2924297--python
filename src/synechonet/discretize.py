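"""Normalization and trinary discretization of replicate log-ratios.

Each gene in each experiment is called upregulated (+1), downregulated (-1)
or unchanged (0).  The call uses a one-sample Kolmogorov-Smirnov test of the
replicate log2 ratios against a zero-mean reference distribution: if the
null is rejected at level ``alpha`` the state is the sign of the replicate
mean, otherwise 0.  Amplitudes beyond the sign are deliberately ignored —
discretization makes heterogeneous experiments comparable.

The zero-mean reference is a swappable strategy.  The default,
``"fitted"``, is Normal(0, sigma-hat) with sigma-hat the sample standard
deviation of the cell's own replicates, which isolates a pure location
shift; ``"pooled"`` instead uses a per-experiment scale pooled across genes.
Asymptotic KS p-values are used throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy import special, stats

from .io import DiscreteStateMatrix, ExpressionCompendium

ScaleStrategy = Literal["fitted", "pooled"]


@dataclass(frozen=True)
class TwoChannelRecord:
    """One spot of a two-channel array: treatment and control intensities."""

    gene: str
    intensity_treatment: float
    intensity_control: float

    def __post_init__(self) -> None:
        if not (self.intensity_treatment > 0 and self.intensity_control > 0):
            raise ValueError(f"{self.gene}: intensities must be strictly positive")


@dataclass(frozen=True)
class StateCall:
    """A single trinary regulation call with its supporting test."""

    state: int
    p_value: float | None
    n_replicates: int


@dataclass
class DiscretizationResult:
    """Gene-level state matrix plus the experiments unusable at gene level."""

    states: DiscreteStateMatrix
    under_replicated: list[str]


def lowess_normalize(
    records: Sequence[TwoChannelRecord],
    span: float = 0.3,
    robust_iterations: int = 3,
) -> dict[str, float]:
    """Remove intensity-dependent dye bias from two-channel ratios.

    Computes M = log2(T/C) and A = 0.5*log2(T*C), fits a robust locally
    weighted regression of M on A (tricube weights over the ``span``
    fraction of nearest neighbours; ``robust_iterations`` bisquare
    reweighting passes) and returns M minus the fitted trend per gene.
    """
    if len(records) < 10:
        raise ValueError(f"need at least 10 records for a LOWESS fit, got {len(records)}")
    if not (0 < span <= 1):
        raise ValueError("span must be in (0, 1]")
    genes = [r.gene for r in records]
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene identifiers in two-channel records")
    t = np.array([r.intensity_treatment for r in records], float)
    c = np.array([r.intensity_control for r in records], float)
    m = np.log2(t / c)
    a = 0.5 * np.log2(t * c)
    trend = _robust_lowess(a, m, span=span, robust_iterations=robust_iterations)
    return dict(zip(genes, (m - trend).tolist()))


def _robust_lowess(x: np.ndarray, y: np.ndarray, span: float, robust_iterations: int) -> np.ndarray:
    """Locally weighted linear regression with bisquare robustifying passes.

    Tricube weights over the ``span`` fraction of nearest neighbours; after
    each pass, points are reweighted by a bisquare of residuals scaled by
    six times the median absolute residual.  A zero robust scale (exactly
    interpolated bulk) keeps zero-residual points and drops the rest, so an
    isolated outlier cannot absorb the trend at its own position.
    """
    n = x.size
    k = max(2, int(math.ceil(span * n)))
    dist = np.abs(x[:, None] - x[None, :])
    h = np.sort(dist, axis=1)[:, k - 1]
    h = np.where(h > 0, h, 1.0)  # all-coincident window: uniform weights
    tri = np.clip(1.0 - (dist / h[:, None]) ** 3, 0.0, None) ** 3
    delta = np.ones(n)
    fitted = np.zeros(n)
    for _ in range(robust_iterations + 1):
        w = tri * delta[None, :]
        sw = w.sum(axis=1)
        empty = sw == 0
        w[empty] = tri[empty]  # robust weights killed the window; fall back
        sw = w.sum(axis=1)
        xbar = (w * x[None, :]).sum(axis=1) / sw
        ybar = (w * y[None, :]).sum(axis=1) / sw
        dx = x[None, :] - xbar[:, None]
        sxx = (w * dx * dx).sum(axis=1)
        sxy = (w * dx * (y[None, :] - ybar[:, None])).sum(axis=1)
        slope = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), 0.0)
        fitted = ybar + slope * (x - xbar)
        resid = y - fitted
        s = 6.0 * np.median(np.abs(resid))
        if s == 0:
            delta = (resid == 0).astype(float)
        else:
            delta = np.clip(1.0 - (resid / s) ** 2, 0.0, None) ** 2
    return fitted


def _ks_p_asymptotic(values: np.ndarray, ref_sd: float) -> float:
    """Asymptotic one-sample KS p-value of ``values`` against N(0, ref_sd)."""
    n = values.size
    x = np.sort(values)
    cdf = stats.norm.cdf(x, loc=0.0, scale=ref_sd)
    d_plus = np.max(np.arange(1, n + 1) / n - cdf)
    d_minus = np.max(cdf - np.arange(0, n) / n)
    d = max(d_plus, d_minus)
    return float(special.kolmogorov(math.sqrt(n) * d))


def ks_state(
    values: Sequence[float],
    alpha: float = 0.05,
    min_replicates: int = 3,
    scale: float | None = None,
) -> StateCall:
    """Trinary call for one gene in one experiment.

    ``scale`` overrides the reference standard deviation (the pooled-scale
    strategy); by default the sample standard deviation of ``values`` is
    used.  Degenerate inputs: fewer than ``min_replicates`` values -> state
    0 with undefined p; zero reference scale -> the sign of the common value
    (the KS test is undefined there).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size and not np.isfinite(arr).all():
        raise ValueError("non-finite replicate values")
    n = int(arr.size)
    if n < min_replicates:
        return StateCall(0, None, n)
    mean = float(arr.mean())
    if scale is not None:
        ref_sd = float(scale)
    else:
        ref_sd = float(arr.std(ddof=1)) if n >= 2 else 0.0
    if ref_sd == 0.0:
        common = float(arr[0]) if np.all(arr == arr[0]) else mean
        return StateCall(int(np.sign(common)), None, n)
    p = _ks_p_asymptotic(arr, ref_sd)
    state = int(np.sign(mean)) if p < alpha else 0
    return StateCall(state, p, n)


def _pooled_scales(compendium: ExpressionCompendium) -> dict[str, float]:
    # per-experiment replicate scale pooled across genes: sqrt(sum SS / sum dof)
    ss: dict[str, float] = {e: 0.0 for e in compendium.experiments}
    dof: dict[str, int] = {e: 0 for e in compendium.experiments}
    for (g, e), reps in compendium.values.items():
        if len(reps) >= 2:
            arr = np.asarray(reps, float)
            ss[e] += float(((arr - arr.mean()) ** 2).sum())
            dof[e] += len(reps) - 1
    return {e: (math.sqrt(ss[e] / dof[e]) if dof[e] > 0 else 0.0) for e in compendium.experiments}


def discretize_compendium(
    compendium: ExpressionCompendium,
    alpha: float = 0.05,
    min_replicates: int = 3,
    scale_strategy: ScaleStrategy = "fitted",
) -> DiscretizationResult:
    """Apply :func:`ks_state` cell-wise over a compendium.

    Cells with no replicates are missing in the output matrix; cells with
    some but fewer than ``min_replicates`` replicates are state 0.
    Experiments in which no gene reaches ``min_replicates`` are returned as
    ``under_replicated`` — they carry no gene-level information and callers
    are expected to exclude them from gene-level analyses.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    pooled = _pooled_scales(compendium) if scale_strategy == "pooled" else None
    arr = np.full((len(compendium.genes), len(compendium.experiments)), np.nan)
    gi = {g: i for i, g in enumerate(compendium.genes)}
    ei = {e: j for j, e in enumerate(compendium.experiments)}
    usable: dict[str, bool] = {e: False for e in compendium.experiments}
    for (g, e), reps in compendium.values.items():
        if not reps:
            continue
        if len(reps) >= min_replicates:
            usable[e] = True
        scale = pooled[e] if pooled is not None else None
        if scale == 0.0:
            scale = None  # fall back to per-cell scale if the experiment pools to zero
        call = ks_state(reps, alpha=alpha, min_replicates=min_replicates, scale=scale)
        arr[gi[g], ei[e]] = float(call.state)
    import pandas as pd

    matrix = DiscreteStateMatrix(
        pd.DataFrame(arr, index=list(compendium.genes), columns=list(compendium.experiments))
    )
    under = [e for e in compendium.experiments if not usable[e]]
    return DiscretizationResult(states=matrix, under_replicated=under)


def two_channel_log_ratios(
    records_by_experiment: Mapping[str, Iterable[Sequence[TwoChannelRecord]]],
    span: float = 0.3,
    robust_iterations: int = 3,
) -> ExpressionCompendium:
    """Normalize raw two-channel replicates into a log-ratio compendium.

    ``records_by_experiment`` maps experiment id to an iterable of replicate
    arrays, each a sequence of :class:`TwoChannelRecord`.
    """
    experiments = list(records_by_experiment)
    genes: list[str] = []
    values: dict[tuple[str, str], tuple[float, ...]] = {}
    for e, replicate_arrays in records_by_experiment.items():
        per_gene: dict[str, list[float]] = {}
        for recs in replicate_arrays:
            norm = lowess_normalize(list(recs), span=span, robust_iterations=robust_iterations)
            for g, v in norm.items():
                per_gene.setdefault(g, []).append(v)
        for g, vals in per_gene.items():
            if g not in genes:
                genes.append(g)
            values[(g, e)] = tuple(vals)
    return ExpressionCompendium(genes, experiments, values)
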