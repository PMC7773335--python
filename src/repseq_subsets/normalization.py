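"""Repertoire normalization: UMI downsampling and top-N truncation.

Both normalizations are applied before any cross-sample comparison:
downsampling equalizes sequencing depth at the molecule level (default
16,000 UMI-labeled cDNA molecules), truncation equalizes cloneset size
(default top 20,000 clonotypes for overlap/publicity, top 2,000 for
sharing networks).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import Repertoire

__all__ = [
    "DownsampleSpec",
    "downsample_counts",
    "downsample_umis",
    "top_n_clonotypes",
    "recompute_frequencies",
    "DEFAULT_N_MOLECULES",
    "DEFAULT_TOP_N_OVERLAP",
    "DEFAULT_TOP_N_NETWORK",
]

DEFAULT_N_MOLECULES = 16_000
DEFAULT_TOP_N_OVERLAP = 20_000
DEFAULT_TOP_N_NETWORK = 2_000


@dataclass(frozen=True)
class DownsampleSpec:
    """Target depth and seed for molecule-level downsampling."""

    n_molecules: int = DEFAULT_N_MOLECULES
    seed: int = 0
    #: "hypergeometric" (without replacement, physical molecules) or
    #: "multinomial" (with replacement, sensitivity analyses only)
    model: str = "hypergeometric"


def downsample_counts(counts: np.ndarray, n: int, rng: np.random.Generator,
                      model: str = "hypergeometric") -> np.ndarray:
    """Draw ``n`` molecules from the multiset described by integer ``counts``.

    The hypergeometric model samples without replacement, so every output
    entry is bounded by its input entry and the output sums to ``n`` exactly.
    """
    counts = np.asarray(counts, dtype=np.int64)
    total = int(counts.sum())
    if n > total:
        raise ValueError(f"cannot draw {n} molecules from {total}")
    if model == "hypergeometric":
        if n == total:
            return counts.copy()
        return rng.multivariate_hypergeometric(counts, n, method="marginals")
    if model == "multinomial":
        return rng.multinomial(n, counts / total)
    raise ValueError(f"unknown sampling model {model!r}")


def downsample_umis(rep: Repertoire, spec: DownsampleSpec) -> Repertoire:
    """Downsample a repertoire to ``spec.n_molecules`` UMI-labeled molecules.

    Clonotypes drawn zero times are dropped; frequencies are recomputed
    over the retained set.  Deterministic given ``spec.seed``.

    Raises
    ------
    ValueError
        If the repertoire holds fewer molecules than requested (samples
        below the lower bound are the caller's problem, never upsampled).
    """
    total = rep.total_count
    if total < spec.n_molecules:
        raise ValueError(
            f"{rep.sample_id}: total_count {total} < target {spec.n_molecules}; "
            "refusing to upsample"
        )
    rng = np.random.default_rng(spec.seed)
    new_counts = downsample_counts(np.array(rep.counts()), spec.n_molecules, rng, spec.model)
    clonotypes = [
        replace(c, count=int(k), meta=dict(c.meta))
        for c, k in zip(rep.clonotypes, new_counts)
        if k > 0
    ]
    out = Repertoire(rep.donor_id, rep.subset, rep.chain, clonotypes)
    return recompute_frequencies(out)


def top_n_clonotypes(rep: Repertoire, n: int) -> Repertoire:
    """Retain the ``min(n, len(rep))`` most frequent clonotypes.

    Ties at the cutoff are broken lexicographically on (v_gene, cdr3nt)
    for determinism; frequencies are recomputed over the retained set.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    order = sorted(rep.clonotypes, key=lambda c: (-c.count, c.v_gene, c.cdr3nt))
    kept = order[: min(n, len(order))]
    out = Repertoire(rep.donor_id, rep.subset, rep.chain,
                     [replace(c, meta=dict(c.meta)) for c in kept])
    return recompute_frequencies(out)


def recompute_frequencies(rep: Repertoire) -> Repertoire:
    """Set freq_i = count_i / total; idempotent; errors on an empty repertoire."""
    total = rep.total_count
    if total <= 0:
        raise ValueError(f"{rep.sample_id}: cannot normalize empty repertoire")
    for c in rep.clonotypes:
        c.freq = c.count / total
    return rep
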