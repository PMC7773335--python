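"""Diversity statistics on normalized repertoires.

The three statistics are meant to be computed after molecule-level
downsampling to a common depth (16,000 by default), which is the caller's
responsibility — see :mod:`repseq_subsets.normalization`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .io import Repertoire

__all__ = [
    "DiversityResult",
    "observed_diversity",
    "chao1",
    "normalized_shannon_wiener",
    "diversity_result",
]


@dataclass(frozen=True)
class DiversityResult:
    observed: int
    chao1: float
    normalized_shannon_wiener: float
    n_molecules: int


def observed_diversity(rep: Repertoire) -> int:
    """Number of distinct clonotypes with count >= 1."""
    return sum(1 for c in rep.clonotypes if c.count >= 1)


def chao1(rep: Repertoire, bias_corrected: bool = True) -> float:
    """Chao1 richness estimator from singleton/doubleton counts.

    The bias-corrected form S_obs + f1(f1-1) / (2(f2+1)) is the default;
    ``bias_corrected=False`` gives the classical S_obs + f1^2/(2 f2)
    (infinite when f2 == 0 and f1 > 0).
    """
    s_obs = observed_diversity(rep)
    f1 = sum(1 for c in rep.clonotypes if c.count == 1)
    f2 = sum(1 for c in rep.clonotypes if c.count == 2)
    if bias_corrected:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f2 == 0:
        return float("inf") if f1 > 0 else float(s_obs)
    return s_obs + f1 * f1 / (2.0 * f2)


def normalized_shannon_wiener(rep: Repertoire) -> float:
    """Shannon entropy of clonotype frequencies normalized by ln(S_obs).

    Defined as 0 for a single-clonotype repertoire.  Frequencies are
    renormalized internally so the index depends only on relative counts.
    """
    freqs = [c.freq for c in rep.clonotypes if c.freq > 0]
    s = len(freqs)
    if s <= 1:
        return 0.0
    total = math.fsum(freqs)
    h = -math.fsum((f / total) * math.log(f / total) for f in freqs)
    return h / math.log(s)


def diversity_result(rep: Repertoire) -> DiversityResult:
    return DiversityResult(
        observed=observed_diversity(rep),
        chao1=chao1(rep),
        normalized_shannon_wiener=normalized_shannon_wiener(rep),
        n_molecules=rep.total_count,
    )
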