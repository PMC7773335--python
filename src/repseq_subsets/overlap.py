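"""Pairwise repertoire overlap and the within-donor sharing network.

Clonotypes are matched at the nucleotide level by identical (V gene,
CDR3nt).  The weighted F2 metric sums the clonotype-wise geometric mean
of shared frequencies; the relative D metric normalizes shared richness
by the product of the compared cloneset sizes.  Both are intended to run
on top-N-truncated clonesets (top 20,000 for pairwise overlap, top 2,000
for the sharing network).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .io import Repertoire
from .normalization import top_n_clonotypes

__all__ = [
    "OverlapResult",
    "SharingNetwork",
    "shared_clonotypes",
    "overlap_f2",
    "overlap_d",
    "overlap_result",
    "build_sharing_network",
]


@dataclass(frozen=True)
class OverlapResult:
    sample_a: str
    sample_b: str
    n_shared: int
    f2: float
    d: float


def shared_clonotypes(a: Repertoire, b: Repertoire) -> list[tuple[tuple[str, str], float, float]]:
    """Keys present in both repertoires with their per-repertoire frequencies.

    The key is (v_gene, cdr3nt); the repertoires must be the same chain.
    """
    if a.chain != b.chain:
        raise ValueError(f"chain mismatch: {a.chain!r} vs {b.chain!r}")
    freq_b = {c.key: c.freq for c in b.clonotypes}
    out = []
    for c in a.clonotypes:
        fb = freq_b.get(c.key)
        if fb is not None:
            out.append((c.key, c.freq, fb))
    return out


def overlap_f2(a: Repertoire, b: Repertoire, variant: str = "sqrt") -> float:
    """Frequency-weighted overlap: sum over shared keys of sqrt(f_a * f_b).

    ``variant="mass"`` instead returns the geometric mean of the two
    shared-mass sums (sensitivity analysis only).
    """
    shared = shared_clonotypes(a, b)
    if variant == "sqrt":
        return math.fsum(math.sqrt(fa * fb) for _, fa, fb in shared)
    if variant == "mass":
        ma = math.fsum(fa for _, fa, _ in shared)
        mb = math.fsum(fb for _, _, fb in shared)
        return math.sqrt(ma * mb)
    raise ValueError(f"unknown F2 variant {variant!r}")


def overlap_d(a: Repertoire, b: Repertoire) -> float:
    """Relative overlap: n_shared / (S_a * S_b) over the (truncated) clonesets."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("overlap_d undefined for empty repertoires")
    n_shared = len(shared_clonotypes(a, b))
    return n_shared / (len(a) * len(b))


def overlap_result(a: Repertoire, b: Repertoire) -> OverlapResult:
    shared = shared_clonotypes(a, b)
    return OverlapResult(
        sample_a=a.sample_id,
        sample_b=b.sample_id,
        n_shared=len(shared),
        f2=math.fsum(math.sqrt(fa * fb) for _, fa, fb in shared),
        d=len(shared) / (len(a) * len(b)) if len(a) and len(b) else float("nan"),
    )


@dataclass
class SharingNetwork:
    """Node/edge tables of clonotype instances shared between subsets.

    Nodes are clonotype instances (one per subset occurrence); edges join
    instances of the same (V, CDR3nt) key in different subsets.  A shared
    clonotype's cloud frequency is the arithmetic mean of its frequencies
    across the maternal subsets.
    """

    nodes: pd.DataFrame = field(default_factory=pd.DataFrame)
    edges: pd.DataFrame = field(default_factory=pd.DataFrame)

    NODE_COLUMNS = ["node_id", "subset", "v_gene", "cdr3nt", "cdr3aa",
                    "freq", "shared", "cloud_freq"]
    EDGE_COLUMNS = ["source", "target", "v_gene", "cdr3nt"]


def build_sharing_network(
    reps: list[Repertoire], top_n: int = 2000, focal_subset: str | None = None
) -> SharingNetwork:
    """Build the within-donor sharing network over top-N-truncated subsets.

    With ``focal_subset`` set, only clonotype clouds containing that subset
    are retained (plus that subset's own unshared nodes).
    """
    if len(reps) < 2:
        raise ValueError("need at least two repertoires to build a sharing network")
    donors = {r.donor_id for r in reps}
    chains = {r.chain for r in reps}
    if len(donors) > 1 or len(chains) > 1:
        raise ValueError("sharing network requires one donor and one chain")
    subsets = [r.subset for r in reps]
    if len(set(subsets)) != len(subsets):
        raise ValueError("duplicate subset labels")
    if focal_subset is not None and focal_subset not in subsets:
        raise ValueError(f"focal subset {focal_subset!r} not among {subsets}")

    truncated = [top_n_clonotypes(r, top_n) for r in reps]
    by_key: dict[tuple[str, str], list[tuple[str, float, str]]] = {}
    aa_by_key: dict[tuple[str, str], str] = {}
    for rep in truncated:
        for c in rep.clonotypes:
            by_key.setdefault(c.key, []).append((rep.subset, c.freq, c.cdr3aa))
            aa_by_key[c.key] = c.cdr3aa

    node_rows, edge_rows = [], []
    for key, members in by_key.items():
        member_subsets = [m[0] for m in members]
        shared = len(members) >= 2
        if focal_subset is not None:
            if shared and focal_subset not in member_subsets:
                continue
            if not shared and member_subsets[0] != focal_subset:
                continue
        cloud_freq = sum(m[1] for m in members) / len(members) if shared else float("nan")
        ids = []
        for subset, freq, _ in members:
            node_id = f"{subset}|{key[0]}|{key[1]}"
            ids.append(node_id)
            node_rows.append({
                "node_id": node_id, "subset": subset,
                "v_gene": key[0], "cdr3nt": key[1], "cdr3aa": aa_by_key[key],
                "freq": freq, "shared": shared, "cloud_freq": cloud_freq,
            })
        if shared:
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    edge_rows.append({
                        "source": ids[i], "target": ids[j],
                        "v_gene": key[0], "cdr3nt": key[1],
                    })
    nodes = pd.DataFrame(node_rows, columns=SharingNetwork.NODE_COLUMNS)
    edges = pd.DataFrame(edge_rows, columns=SharingNetwork.EDGE_COLUMNS)
    return SharingNetwork(nodes=nodes, edges=edges)
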