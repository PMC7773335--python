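"""Cross-donor publicity of amino-acid-defined CDR3 variants.

Two variants match when they are identical or at Hamming distance 1
(one substitution at equal length).  Matching uses a wildcard-mask index:
every string emits its exact form plus L masked variants with one position
replaced by a wildcard, so a 20,000 x 20,000 comparison runs in linear
time.  An edit-distance-1 mode (allowing one indel) is available behind a
flag for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .io import Repertoire
from .normalization import top_n_clonotypes

__all__ = [
    "PublicityResult",
    "hamming1_match_count",
    "publicity_matrix",
    "unique_cdr3aa",
]


@dataclass(frozen=True)
class PublicityResult:
    subset: str
    donor_a: str
    donor_b: str
    #: strings of donor_a matched in donor_b, and vice versa
    n_ab: int
    n_ba: int
    #: symmetrized publicity: mean of the two directional counts
    n_public: float
    convention: str = "mean(directional)"


def _mask_index(strings: set[str]) -> set[tuple[int, str]]:
    """All (length, masked-string) signatures of a set, wildcard '\\x00'."""
    index: set[tuple[int, str]] = set()
    for s in strings:
        L = len(s)
        index.add((L, s))
        for i in range(L):
            index.add((L, s[:i] + "\x00" + s[i + 1:]))
    return index


def hamming1_match_count(set_a: set[str], set_b: set[str], edit: bool = False) -> int:
    """Number of strings in ``set_a`` with a partner in ``set_b`` at distance <= 1.

    Distance is Hamming (equal length, one substitution) by default; each
    string in ``set_a`` is counted once regardless of partner multiplicity.
    With ``edit=True`` a single insertion/deletion also matches.
    """
    if edit:
        return _edit1_match_count(set_a, set_b)
    index = _mask_index(set_b)
    n = 0
    for s in set_a:
        L = len(s)
        if (L, s) in index:
            n += 1
            continue
        if any((L, s[:i] + "\x00" + s[i + 1:]) in index for i in range(L)):
            n += 1
    return n


def _edit1_match_count(set_a: set[str], set_b: set[str]) -> int:
    # deletion signatures: string with one position removed, tagged by length
    del_index: set[str] = set()
    for s in set_b:
        for i in range(len(s)):
            del_index.add(s[:i] + s[i + 1:])
    sub_index = _mask_index(set_b)
    n = 0
    for s in set_a:
        L = len(s)
        if (L, s) in sub_index or any(
            (L, s[:i] + "\x00" + s[i + 1:]) in sub_index for i in range(L)
        ):
            n += 1
            continue
        # s shorter by one: s must equal a deletion variant of some b
        if s in del_index:
            n += 1
            continue
        # s longer by one: some deletion variant of s must be in set_b
        if any(s[:i] + s[i + 1:] in set_b for i in range(L)):
            n += 1
    return n


def unique_cdr3aa(rep: Repertoire, top_n: int | None = None) -> set[str]:
    """Unique amino-acid CDR3 variants, optionally after top-N truncation."""
    if top_n is not None:
        rep = top_n_clonotypes(rep, top_n)
    return {c.cdr3aa for c in rep.clonotypes}


def publicity_matrix(
    reps_by_donor: dict[str, Repertoire], top_n: int = 20_000, edit: bool = False
) -> list[PublicityResult]:
    """Publicity for every unordered donor pair of one subset.

    Each donor's cloneset is truncated to its top-N clonotypes and
    deduplicated on cdr3aa; n_public is the mean of the two directional
    Hamming<=1 match counts (both directions are retained in the output).
    """
    if len(reps_by_donor) < 2:
        raise ValueError("publicity requires at least two donors")
    subsets = {r.subset for r in reps_by_donor.values()}
    if len(subsets) > 1:
        raise ValueError(f"mixed subsets in publicity input: {sorted(subsets)}")
    subset = subsets.pop()
    variants = {d: unique_cdr3aa(r, top_n) for d, r in reps_by_donor.items()}
    out = []
    for da, db in combinations(sorted(variants), 2):
        n_ab = hamming1_match_count(variants[da], variants[db], edit=edit)
        n_ba = hamming1_match_count(variants[db], variants[da], edit=edit)
        out.append(PublicityResult(
            subset=subset, donor_a=da, donor_b=db,
            n_ab=n_ab, n_ba=n_ba, n_public=(n_ab + n_ba) / 2.0,
        ))
    return out
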