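"""Cohort validation statistics for deviation-index scores.

Given index values grouped by an ordinal impairment level (or the
distinguished "control" group) this module provides the standard validation
battery: Kolmogorov-Smirnov normality screening per group, stratified
histograms with fitted normal curves and a control-mean marker, one-way
ANOVA between every pair of levels, Kendall's tau-b between the ordinal
scale and the index, and Pearson correlation / ordinary least squares
between two competing indexes.

Pairwise p-values are reported uncorrected by default (each pair tested at
its own alpha); a Holm step-down option is available.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

from .errors import DomainError, InputError

logger = logging.getLogger(__name__)

#: index values keyed by group label (ordinal level as string, or "control")
GroupedScores = Mapping[str, Sequence[float]]


@dataclass(frozen=True)
class NormalityResult:
    statistic: float
    p_value: float
    is_normal: bool
    n: int
    method: str


@dataclass
class PairwiseTestTable:
    """Per-pair one-way ANOVA results plus pairs skipped for being too small."""

    table: pd.DataFrame  # columns: group_a, group_b, f_statistic, p_value, significant
    skipped: list[tuple[str, str, str]]
    alpha: float


@dataclass
class HistogramResult:
    """Stratified histogram: shared bin edges, per-group counts and normal fit."""

    bin_edges: np.ndarray
    counts: dict[str, np.ndarray]
    fitted: dict[str, tuple[float, float]]  # group -> (mean, sd)
    control_mean: float | None
    zero_sd_groups: list[str]


def ks_normality(
    values: Sequence[float], alpha: float = 0.05, method: str = "estimated"
) -> NormalityResult:
    """One-sample KS test of normality with the sample's own mean and SD.

    ``method="estimated"`` (default) uses the Lilliefors correction, which
    accounts for the mean and SD being estimated from the same sample;
    ``method="fixed"`` plugs the sample moments into a plain KS test and
    treats them as known (anti-conservative, but matches common practice).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise InputError(f"normality test requires n >= 3, got n={x.size}")
    if not np.all(np.isfinite(x)):
        raise InputError("normality test input contains non-finite values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DomainError("constant sample: normality test undefined")
    if method == "estimated":
        stat, p = lilliefors(x, dist="norm", pvalmethod="table")
    elif method == "fixed":
        stat, p = sps.kstest(x, "norm", args=(x.mean(), sd))
    else:
        raise InputError(f"unknown normality method {method!r}")
    return NormalityResult(
        statistic=float(stat),
        p_value=float(p),
        is_normal=bool(p >= alpha),
        n=int(x.size),
        method=method,
    )


def pairwise_anova(
    grouped: GroupedScores, alpha: float = 0.05, holm: bool = False
) -> PairwiseTestTable:
    """Two-group one-way ANOVA for every unordered pair of groups.

    For two groups the F statistic is exactly the square of the pooled
    two-sample t statistic.  Groups with fewer than 2 observations are
    skipped with a logged reason rather than failing the whole table.
    """
    if not grouped:
        raise InputError("no groups supplied")
    arrays = {k: np.asarray(v, dtype=float) for k, v in grouped.items()}
    rows = []
    skipped: list[tuple[str, str, str]] = []
    for a, b in itertools.combinations(arrays, 2):
        xa, xb = arrays[a], arrays[b]
        if xa.size < 2 or xb.size < 2:
            small = a if xa.size < 2 else b
            reason = f"group {small!r} has n < 2"
            skipped.append((a, b, reason))
            logger.info("skipping pair (%s, %s): %s", a, b, reason)
            continue
        f, p = sps.f_oneway(xa, xb)
        rows.append(
            {"group_a": a, "group_b": b, "f_statistic": float(f), "p_value": float(p)}
        )
    table = pd.DataFrame(rows, columns=["group_a", "group_b", "f_statistic", "p_value"])
    if holm and len(table):
        order = np.argsort(table["p_value"].to_numpy())
        m = len(table)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * table["p_value"].iloc[idx])
            adj[idx] = min(1.0, running)
        table["p_adjusted"] = adj
        table["significant"] = table["p_adjusted"] < alpha
    elif len(table):
        table["significant"] = table["p_value"] < alpha
    else:
        table["significant"] = pd.Series(dtype=bool)
    return PairwiseTestTable(table=table, skipped=skipped, alpha=alpha)


def kendall_tau_b(ordinal_x: Sequence[float], values_y: Sequence[float]) -> tuple[float, float]:
    """Kendall's tau-b (tie-corrected) and its asymptotic-normal p-value."""
    x = np.asarray(ordinal_x, dtype=float)
    y = np.asarray(values_y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise InputError("tau-b requires two equal-length sequences with n >= 2")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise DomainError("tau-b undefined when either variable is completely tied")
    res = sps.kendalltau(x, y, variant="b", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def pearson_and_regression(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, float]:
    """Pearson r and the ordinary-least-squares line of y on x: (r, slope, intercept)."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 3:
        raise InputError("correlation/regression requires equal-length sequences, n >= 3")
    if np.var(xa) == 0:
        raise DomainError("zero variance in x: regression undefined")
    fit = sps.linregress(xa, ya)
    return float(fit.rvalue), float(fit.slope), float(fit.intercept)


def stratified_histogram(
    grouped: GroupedScores,
    bin_width: float = 5.0,
    control_label: str = "control",
) -> HistogramResult:
    """Histogram each group on shared bins with a per-group normal fit.

    Bin edges are aligned to multiples of ``bin_width`` covering the pooled
    range, so counts are comparable across groups; the fitted parameters are
    each group's sample mean and SD (SD-0 groups are flagged).  The control
    group's mean is exposed as the vertical-marker position.
    """
    if not grouped or all(len(v) == 0 for v in grouped.values()):
        raise InputError("no data to histogram")
    if bin_width <= 0:
        raise InputError("bin_width must be positive")
    pooled = np.concatenate([np.asarray(v, dtype=float) for v in grouped.values() if len(v)])
    lo = np.floor(pooled.min() / bin_width) * bin_width
    hi = np.ceil(pooled.max() / bin_width) * bin_width
    if hi == lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts: dict[str, np.ndarray] = {}
    fitted: dict[str, tuple[float, float]] = {}
    zero_sd = []
    for label, vals in grouped.items():
        arr = np.asarray(vals, dtype=float)
        counts[label], _ = np.histogram(arr, bins=edges)
        mean = float(arr.mean()) if arr.size else float("nan")
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        if sd == 0:
            zero_sd.append(label)
        fitted[label] = (mean, sd)
    control_mean = fitted[control_label][0] if control_label in fitted else None
    return HistogramResult(
        bin_edges=edges,
        counts=counts,
        fitted=fitted,
        control_mean=control_mean,
        zero_sd_groups=zero_sd,
    )


def plot_stratified_histograms(result: HistogramResult, path) -> None:
    """Render the stratified histograms with fitted normal curves to a file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = list(result.counts)
    fig, axes = plt.subplots(
        len(groups), 1, figsize=(6, 2.2 * len(groups)), sharex=True, squeeze=False
    )
    centers = 0.5 * (result.bin_edges[:-1] + result.bin_edges[1:])
    width = result.bin_edges[1] - result.bin_edges[0]
    for ax, label in zip(axes[:, 0], groups):
        counts = result.counts[label]
        ax.bar(centers, counts, width=width * 0.95, color="steelblue", alpha=0.7)
        mean, sd = result.fitted[label]
        if sd > 0 and counts.sum() > 0:
            xs = np.linspace(result.bin_edges[0], result.bin_edges[-1], 200)
            pdf = sps.norm.pdf(xs, mean, sd) * counts.sum() * width
            ax.plot(xs, pdf, "k:", lw=1.5)
        if result.control_mean is not None:
            ax.axvline(result.control_mean, color="black", lw=1.5)
        ax.set_ylabel(label)
    axes[-1, 0].set_xlabel("deviation index")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def group_scores(
    scores: pd.DataFrame, value_column: str = "index"
) -> dict[str, np.ndarray]:
    """Collect a per-stride score table into a GroupedScores mapping."""
    out: dict[str, np.ndarray] = {}
    for label, g in scores.groupby("group_label", sort=False):
        mask = g.get("valid", pd.Series(True, index=g.index)) & g[value_column].notna()
        out[str(label)] = g.loc[mask, value_column].to_numpy(dtype=float)
    return out


def ordinal_pairs(
    scores: pd.DataFrame,
    value_column: str = "index",
    control_label: str = "control",
) -> tuple[np.ndarray, np.ndarray]:
    """(ordinal level, score) pairs for tau-b, excluding the control group.

    Group labels other than the control label must parse as numbers (ordinal
    ranks).
    """
    mask = scores["group_label"].astype(str) != control_label
    sub = scores.loc[mask & scores[value_column].notna()]
    if "valid" in sub.columns:
        sub = sub.loc[sub["valid"]]
    try:
        levels = sub["group_label"].astype(float).to_numpy()
    except ValueError as exc:
        raise InputError(
            "non-control group labels must be numeric ordinal levels for tau-b"
        ) from exc
    return levels, sub[value_column].to_numpy(dtype=float)
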