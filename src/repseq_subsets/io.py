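"""Clonotype table I/O and the core repertoire data model.

Two tab-separated dialects are supported:

``vdjtools``
    Columns ``count, freq, cdr3nt, cdr3aa, v, d, j, VEnd, DStart, DEnd,
    JStart``.  Extra columns are preserved as opaque per-clonotype metadata.

``airr``
    AIRR Rearrangement TSV.  The standard columns ``duplicate_count,
    junction, junction_aa, v_call, d_call, j_call`` are mapped onto the
    clonotype fields; the CDR3-relative junction markers are carried in the
    non-standard extension columns ``v_end, d_start, d_end, j_start`` so
    that round trips are lossless.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "Clonotype",
    "Repertoire",
    "FormatError",
    "read_clonotype_table",
    "write_clonotype_table",
    "validate_repertoire",
    "translate_cdr3",
]

logger = logging.getLogger(__name__)

VDJTOOLS_COLUMNS = [
    "count", "freq", "cdr3nt", "cdr3aa", "v", "d", "j",
    "VEnd", "DStart", "DEnd", "JStart",
]

AIRR_COLUMNS = [
    "sequence_id", "duplicate_count", "junction", "junction_aa",
    "v_call", "d_call", "j_call", "productive",
    "v_end", "d_start", "d_end", "j_start",
]

#: required subset of the AIRR dialect header
AIRR_REQUIRED = ["duplicate_count", "junction", "junction_aa", "v_call", "d_call", "j_call"]

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
_NT_ALPHABET = set("ACGT")


class FormatError(ValueError):
    """Raised when a clonotype table does not conform to its dialect."""


def translate_cdr3(cdr3nt: str) -> str:
    """Translate an in-frame CDR3 nucleotide sequence (standard code, '*' = stop)."""
    if len(cdr3nt) % 3 != 0:
        raise ValueError(f"sequence length {len(cdr3nt)} not divisible by 3")
    return str(Seq(cdr3nt).translate())


@dataclass(slots=True)
class Clonotype:
    """One rearrangement record.

    Junction markers are 0-based positions within ``cdr3nt``; ``-1`` means
    undefined.  ``d_gene`` may be empty.
    """

    count: int
    freq: float
    cdr3nt: str
    cdr3aa: str
    v_gene: str
    d_gene: str = ""
    j_gene: str = ""
    v_end: int = -1
    d_start: int = -1
    d_end: int = -1
    j_start: int = -1
    meta: dict = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, str]:
        """Nucleotide-level clonotype identity: (V gene, CDR3nt)."""
        return (self.v_gene, self.cdr3nt)

    @property
    def in_frame(self) -> bool:
        return (
            len(self.cdr3nt) > 0
            and len(self.cdr3nt) % 3 == 0
            and "*" not in self.cdr3aa
            and "_" not in self.cdr3aa
        )


@dataclass(slots=True)
class Repertoire:
    """An ordered cloneset for one (donor, subset, chain)."""

    donor_id: str
    subset: str
    chain: str
    clonotypes: list[Clonotype]

    @property
    def total_count(self) -> int:
        return sum(c.count for c in self.clonotypes)

    def __len__(self) -> int:
        return len(self.clonotypes)

    def __iter__(self) -> Iterator[Clonotype]:
        return iter(self.clonotypes)

    @property
    def sample_id(self) -> str:
        return f"{self.donor_id}.{self.subset}.{self.chain}"

    def counts(self) -> list[int]:
        return [c.count for c in self.clonotypes]

    def freqs(self) -> list[float]:
        return [c.freq for c in self.clonotypes]


def _norm_marker(value) -> int:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return -1
    s = str(value).strip()
    if s in ("", ".", "-1", "nan"):
        return -1
    return int(float(s))


def _norm_segment(value) -> str:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ""
    s = str(value).strip()
    return "" if s == "." else s


def _merge_duplicates(clonotypes: list[Clonotype]) -> list[Clonotype]:
    """Merge rows sharing (v_gene, cdr3nt) by summing counts, order-preserving."""
    seen: dict[tuple[str, str], Clonotype] = {}
    out: list[Clonotype] = []
    n_merged = 0
    for c in clonotypes:
        prev = seen.get(c.key)
        if prev is None:
            seen[c.key] = c
            out.append(c)
        else:
            prev.count += c.count
            prev.freq += c.freq
            n_merged += 1
    if n_merged:
        logger.info("merged %d duplicate (v, cdr3nt) rows", n_merged)
    return out


def read_clonotype_table(
    path: str | Path,
    dialect: str = "vdjtools",
    donor_id: str = "",
    subset: str = "",
    chain: str = "",
) -> Repertoire:
    """Read a clonotype table into a :class:`Repertoire`.

    Records with an empty CDR3 nucleotide sequence are dropped (count
    logged).  Duplicate (V, CDR3nt) rows are merged by summing counts.

    Raises
    ------
    FormatError
        If a required column of the declared dialect is missing, or a
        count fails to parse (the offending line is named).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if dialect == "vdjtools":
        required = VDJTOOLS_COLUMNS
    elif dialect == "airr":
        required = AIRR_REQUIRED
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'vdjtools' or 'airr'")
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r} for dialect {dialect!r}")

    clonotypes: list[Clonotype] = []
    n_empty = 0
    count_col = "count" if dialect == "vdjtools" else "duplicate_count"
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        rec = dict(zip(df.columns, row))
        cdr3nt = (rec["cdr3nt"] if dialect == "vdjtools" else rec["junction"]).strip().upper()
        if not cdr3nt:
            n_empty += 1
            continue
        raw_count = rec[count_col]
        try:
            count = int(float(raw_count))
        except ValueError:
            raise FormatError(f"{path}:{i}: non-numeric count {raw_count!r}") from None
        if dialect == "vdjtools":
            freq = float(rec["freq"]) if rec["freq"] else 0.0
            c = Clonotype(
                count=count,
                freq=freq,
                cdr3nt=cdr3nt,
                cdr3aa=rec["cdr3aa"].strip(),
                v_gene=_norm_segment(rec["v"]),
                d_gene=_norm_segment(rec["d"]),
                j_gene=_norm_segment(rec["j"]),
                v_end=_norm_marker(rec["VEnd"]),
                d_start=_norm_marker(rec["DStart"]),
                d_end=_norm_marker(rec["DEnd"]),
                j_start=_norm_marker(rec["JStart"]),
                meta={k: rec[k] for k in df.columns if k not in VDJTOOLS_COLUMNS},
            )
        else:
            c = Clonotype(
                count=count,
                freq=0.0,
                cdr3nt=cdr3nt,
                cdr3aa=rec["junction_aa"].strip(),
                v_gene=_norm_segment(rec["v_call"]),
                d_gene=_norm_segment(rec["d_call"]),
                j_gene=_norm_segment(rec["j_call"]),
                v_end=_norm_marker(rec.get("v_end")),
                d_start=_norm_marker(rec.get("d_start")),
                d_end=_norm_marker(rec.get("d_end")),
                j_start=_norm_marker(rec.get("j_start")),
            )
        clonotypes.append(c)

    if n_empty:
        logger.info("%s: dropped %d records with empty CDR3", path, n_empty)
    clonotypes = _merge_duplicates(clonotypes)
    rep = Repertoire(donor_id=donor_id, subset=subset, chain=chain, clonotypes=clonotypes)
    total = rep.total_count
    if dialect == "airr" and total > 0:
        for c in rep.clonotypes:
            c.freq = c.count / total
    return rep


def write_clonotype_table(rep: Repertoire, path: str | Path, dialect: str = "vdjtools") -> None:
    """Serialize a repertoire; output is re-readable by :func:`read_clonotype_table`."""
    path = Path(path)
    rows = []
    if dialect == "vdjtools":
        for c in rep.clonotypes:
            rows.append({
                "count": c.count,
                "freq": repr(c.freq),
                "cdr3nt": c.cdr3nt,
                "cdr3aa": c.cdr3aa,
                "v": c.v_gene,
                "d": c.d_gene,
                "j": c.j_gene,
                "VEnd": c.v_end,
                "DStart": c.d_start,
                "DEnd": c.d_end,
                "JStart": c.j_start,
                **c.meta,
            })
        columns = VDJTOOLS_COLUMNS + [k for k in (rows[0] if rows else {}) if k not in VDJTOOLS_COLUMNS]
    elif dialect == "airr":
        for i, c in enumerate(rep.clonotypes):
            rows.append({
                "sequence_id": f"{rep.sample_id or 'seq'}-{i + 1}",
                "duplicate_count": c.count,
                "junction": c.cdr3nt,
                "junction_aa": c.cdr3aa,
                "v_call": c.v_gene,
                "d_call": c.d_gene,
                "j_call": c.j_gene,
                "productive": "T" if c.in_frame else "F",
                "v_end": c.v_end,
                "d_start": c.d_start,
                "d_end": c.d_end,
                "j_start": c.j_start,
            })
        columns = AIRR_COLUMNS
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.DataFrame(rows, columns=columns)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def validate_repertoire(rep: Repertoire, freq_tol: float = 1e-6) -> list[str]:
    """Check type invariants; returns one human-readable issue per violation.

    Never raises: a malformed repertoire yields issues, not exceptions.
    """
    issues: list[str] = []
    seen: set[tuple[str, str]] = set()
    freq_sum = 0.0
    for i, c in enumerate(rep.clonotypes):
        if c.count < 1:
            issues.append(f"clonotype {i}: count {c.count} < 1")
        if not (0.0 <= c.freq <= 1.0):
            issues.append(f"clonotype {i}: freq {c.freq} outside [0, 1]")
        freq_sum += c.freq
        if set(c.cdr3nt) - _NT_ALPHABET:
            issues.append(f"clonotype {i}: non-ACGT character in cdr3nt")
        if set(c.cdr3aa) - _AA_ALPHABET - {"*", "_"}:
            issues.append(f"clonotype {i}: invalid character in cdr3aa")
        markers = (c.v_end, c.d_start, c.d_end, c.j_start)
        if all(m >= 0 for m in markers):
            # raw V/D or D/J overlaps are legal (clamped downstream); only
            # inversions that clamping cannot repair are flagged
            if c.j_start < c.v_end or c.d_end < c.d_start:
                issues.append(f"clonotype {i}: junction markers out of order")
        for m in markers:
            if m >= 0 and m > len(c.cdr3nt):
                issues.append(f"clonotype {i}: junction marker {m} beyond cdr3nt length")
        if c.key in seen:
            issues.append(f"clonotype {i}: duplicate (v_gene, cdr3nt) key {c.key}")
        seen.add(c.key)
        if c.in_frame:
            translated = translate_cdr3(c.cdr3nt)
            if translated != c.cdr3aa:
                issues.append(
                    f"clonotype {i}: translation mismatch ({translated!r} != {c.cdr3aa!r})"
                )
    if rep.clonotypes and abs(freq_sum - 1.0) > freq_tol:
        issues.append(f"frequency normalization: sum(freq) = {freq_sum:.6g} != 1")
    return issues


def copy_repertoire(rep: Repertoire) -> Repertoire:
    """Deep-enough copy (clonotypes are cloned, metadata shared shallowly)."""
    return Repertoire(
        donor_id=rep.donor_id,
        subset=rep.subset,
        chain=rep.chain,
        clonotypes=[replace(c, meta=dict(c.meta)) for c in rep.clonotypes],
    )
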