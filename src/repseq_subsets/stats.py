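"""Statistical layer: summary stats, group-versus-mean testing, FDR, PCA.

The group scheme mirrors the repertoire analyses: an omnibus one-way
ANOVA (or Kruskal-Wallis when any group fails a Shapiro-Wilk normality
check), followed by a per-group two-sample Welch t-test (or Wilcoxon
rank-sum) of each group's values against the pooled values of the
remaining groups, Bonferroni-corrected by the number of groups.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupTestResult",
    "PcaResult",
    "summary_stats",
    "group_vs_mean_tests",
    "welch_vs_pooled",
    "benjamini_hochberg",
    "significance_tier",
    "pca",
]

logger = logging.getLogger(__name__)

TIERS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def summary_stats(values) -> tuple[float, float | None]:
    """(mean, sample SD with n-1 denominator); SD is None when n < 2."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("summary_stats of empty input")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size >= 2 else None
    return mean, sd


def significance_tier(p: float) -> str:
    for threshold, stars in TIERS:
        if p < threshold:
            return stars
    return "ns"


@dataclass
class GroupTestResult:
    omnibus_test: str            # "anova" or "kruskal"
    omnibus_statistic: float
    omnibus_p: float
    per_group_test: str          # "welch" or "wilcoxon"
    groups: list[str] = field(default_factory=list)
    statistics: dict[str, float] = field(default_factory=dict)
    raw_p: dict[str, float] = field(default_factory=dict)
    adjusted_p: dict[str, float] = field(default_factory=dict)
    tiers: dict[str, str] = field(default_factory=dict)


def welch_vs_pooled(group: np.ndarray, pooled: np.ndarray,
                    parametric: bool = True) -> tuple[float, float]:
    """Two-sample Welch t (or Wilcoxon rank-sum) of a group against a pool."""
    if np.ptp(group) == 0 and np.ptp(pooled) == 0 and group[0] == pooled[0]:
        return 0.0, 1.0  # identical constant vectors: no evidence by definition
    if parametric:
        stat, p = sps.ttest_ind(group, pooled, equal_var=False)
    else:
        stat, p = sps.ranksums(group, pooled)
    return float(stat), float(p)


def _normality_ok(groups: dict[str, np.ndarray], alpha: float = 0.05) -> bool:
    for vals in groups.values():
        if np.ptp(vals) == 0:
            return False  # Shapiro undefined for constant input
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p = sps.shapiro(vals)
        if p < alpha:
            return False
    return True


def group_vs_mean_tests(
    values_by_group: dict[str, list[float]],
    parametric: bool | None = None,
    pool: str = "others",
) -> GroupTestResult:
    """Omnibus test plus per-group tests against the pooled distribution.

    Parameters
    ----------
    parametric
        True forces ANOVA/Welch, False forces Kruskal-Wallis/Wilcoxon,
        None (default) gates on per-group Shapiro-Wilk at alpha = 0.05.
    pool
        "others" (default) tests each group against the pooled values of
        the remaining groups; "all" pools every group including the one
        under test (the grand distribution).  The "all" variant is
        conservative because the tested values recur inside the pool.

    Per-group p values are Bonferroni-multiplied by the number of groups
    and capped at 1.
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    dropped = [g for g, v in groups.items() if v.size < 2]
    for g in dropped:
        logger.warning("group %r has n < 2; excluded from testing", g)
        del groups[g]
    if len(groups) < 2:
        raise ValueError("need at least two groups with n >= 2")
    if pool not in ("others", "all"):
        raise ValueError(f"unknown pool convention {pool!r}")

    if parametric is None:
        parametric = _normality_ok(groups)

    samples = list(groups.values())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if parametric:
            omni_stat, omni_p = sps.f_oneway(*samples)
            omni_name, per_name = "anova", "welch"
        else:
            omni_stat, omni_p = sps.kruskal(*samples)
            omni_name, per_name = "kruskal", "wilcoxon"

    k = len(groups)
    result = GroupTestResult(
        omnibus_test=omni_name,
        omnibus_statistic=float(omni_stat),
        omnibus_p=float(omni_p),
        per_group_test=per_name,
        groups=list(groups),
    )
    all_values = np.concatenate(samples)
    for g, vals in groups.items():
        pooled = all_values if pool == "all" else np.concatenate(
            [v for h, v in groups.items() if h != g]
        )
        stat, p = welch_vs_pooled(vals, pooled, parametric=parametric)
        result.statistics[g] = stat
        result.raw_p[g] = p
        adj = min(1.0, k * p)
        result.adjusted_p[g] = adj
        result.tiers[g] = significance_tier(adj)
    return result


def benjamini_hochberg(pvals) -> list[float]:
    """Step-up BH adjusted p values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out.tolist()


@dataclass
class PcaResult:
    n_samples: int
    n_parameters: int
    parameters: list[str]
    scores: np.ndarray            # samples x components
    loadings: np.ndarray          # parameters x components, orthonormal
    explained_variance_ratio: np.ndarray
    dropped_parameters: list[str] = field(default_factory=list)


def pca(features: np.ndarray, parameter_names: list[str] | None = None,
        standardize: bool = True) -> PcaResult:
    """PCA of a samples x parameters matrix via SVD of the (z-scored) data.

    Columns are z-scored by default (correlation PCA — the parameters have
    incommensurate units); constant columns are dropped with a warning.
    Component signs follow a deterministic convention: the largest-magnitude
    loading of each component is positive.  Explained-variance ratios sum
    to 1 over all returned components.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need a 2-D matrix with at least 3 samples")
    if np.isnan(X).any():
        raise ValueError("missing values in feature matrix")
    names = list(parameter_names) if parameter_names is not None else [
        f"p{i}" for i in range(X.shape[1])
    ]
    dropped: list[str] = []
    if standardize:
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.all():
            dropped = [n for n, k in zip(names, keep) if not k]
            logger.warning("dropping constant parameters under standardization: %s", dropped)
            X = X[:, keep]
            names = [n for n, k in zip(names, keep) if k]
            sd = sd[keep]
        X = (X - X.mean(axis=0)) / sd
    else:
        X = X - X.mean(axis=0)

    u, s, vt = np.linalg.svd(X, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(vt.shape[0]):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    scores = u * s
    var = s ** 2
    total = var.sum()
    ratio = var / total if total > 0 else var
    return PcaResult(
        n_samples=X.shape[0],
        n_parameters=X.shape[1],
        parameters=names,
        scores=scores,
        loadings=vt.T,
        explained_variance_ratio=ratio,
        dropped_parameters=dropped,
    )
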