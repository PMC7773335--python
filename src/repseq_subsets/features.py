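"""CDR3 physicochemical features and the 28-parameter repertoire vector.

Physicochemical scales are averaged over the five residues in the middle
of the CDR3 loop (the peptide-contact zone); length and junction-insertion
parameters are computed per clonotype.  Repertoire-level values are
frequency-weighted averages by default, with an unweighted (per-clonotype
mean) mode for sensitivity checks.
"""

from __future__ import annotations

import logging
import math
from importlib import resources

import numpy as np
import pandas as pd

from .io import Clonotype, Repertoire

__all__ = [
    "PropertyTable",
    "load_property_table",
    "middle_region",
    "clonotype_property",
    "repertoire_property_average",
    "junction_insertions",
    "cdr3_length",
    "feature_vector",
    "feature_table",
    "FEATURE_NAMES",
    "PROPERTY_FEATURES",
]

logger = logging.getLogger(__name__)

#: scales averaged over the middle-5 CDR3 residues
PROPERTY_FEATURES = [
    "kf1", "kf2", "kf3", "kf4", "kf5", "kf6", "kf7", "kf8", "kf9", "kf10",
    "strength", "mjenergy", "core", "rim", "volume", "polarity",
    "disorder", "surface", "alpha", "beta", "turn", "charge", "hydropathy",
]

#: the 28 per-cloneset parameters feeding PCA
FEATURE_NAMES = [
    "kf1", "kf2", "kf3", "kf4", "kf5", "kf6", "kf7", "kf8", "kf9", "kf10",
    "strength", "mjenergy",
    "cdr3_length", "ndn_length", "n_insertions", "vdins", "djins",
    "core", "rim", "volume", "polarity", "disorder", "surface",
    "alpha", "beta", "turn", "charge", "hydropathy",
]

_STANDARD_AA = "ARNDCQEGHILKMFPSTWYV"


class PropertyTable:
    """Amino acid x named physicochemical scale lookup.

    Shipped as a versioned TSV resource; the comment header records the
    provenance of every scale.
    """

    def __init__(self, values: dict[str, dict[str, float]], provenance: str = ""):
        self.scales = sorted(values)
        self.provenance = provenance
        for scale, mapping in values.items():
            missing = set(_STANDARD_AA) - set(mapping)
            if missing:
                raise ValueError(f"scale {scale!r} undefined for {sorted(missing)}")
        self._values = values

    def __contains__(self, scale: str) -> bool:
        return scale in self._values

    def value(self, scale: str, aa: str) -> float:
        try:
            mapping = self._values[scale]
        except KeyError:
            raise KeyError(
                f"unknown scale {scale!r}; available: {', '.join(self.scales)}"
            ) from None
        return mapping[aa]

    def scale(self, scale: str) -> dict[str, float]:
        if scale not in self._values:
            raise KeyError(
                f"unknown scale {scale!r}; available: {', '.join(self.scales)}"
            )
        return dict(self._values[scale])


def load_property_table() -> PropertyTable:
    """Load the packaged amino-acid property table."""
    ref = resources.files("repseq_subsets").joinpath("data/aa_properties.tsv")
    with ref.open("r", encoding="utf-8") as fh:
        lines = fh.readlines()
    provenance = "".join(l for l in lines if l.startswith("#"))
    body = [l for l in lines if not l.startswith("#")]
    from io import StringIO

    df = pd.read_csv(StringIO("".join(body)), sep="\t").set_index("aa")
    values = {col: df[col].astype(float).to_dict() for col in df.columns}
    return PropertyTable(values, provenance=provenance)


def middle_region(cdr3aa: str, k: int = 5) -> str:
    """The contiguous middle-``k`` substring of a CDR3 amino-acid sequence.

    For even overhangs the window is left-biased: offset = floor((len-k)/2).
    Sequences shorter than ``k`` are returned whole.
    """
    if not cdr3aa:
        raise ValueError("empty CDR3 amino-acid sequence")
    for pos, ch in enumerate(cdr3aa):
        if ch not in _STANDARD_AA:
            raise ValueError(f"non-standard amino acid {ch!r} at position {pos}")
    n = len(cdr3aa)
    if n < k:
        return cdr3aa
    off = (n - k) // 2
    return cdr3aa[off:off + k]


def clonotype_property(cdr3aa: str, scale: str, table: PropertyTable, k: int = 5) -> float:
    """Arithmetic mean of ``scale`` over the middle-``k`` CDR3 residues."""
    region = middle_region(cdr3aa, k)
    return math.fsum(table.value(scale, aa) for aa in region) / len(region)


def repertoire_property_average(
    rep: Repertoire, scale: str, table: PropertyTable,
    weighted: bool = True, k: int = 5,
) -> float:
    """Cloneset-level average of a middle-region property.

    ``weighted=True`` weights each clonotype by its frequency (equivalent
    to a flat per-molecule average); otherwise a flat per-clonotype mean.
    """
    if len(rep) == 0:
        raise ValueError(f"{rep.sample_id}: empty repertoire")
    vals = np.array([clonotype_property(c.cdr3aa, scale, table, k) for c in rep])
    if weighted:
        w = np.array(rep.freqs(), dtype=float)
        return float(np.dot(vals, w) / w.sum())
    return float(vals.mean())


def junction_insertions(c: Clonotype) -> tuple[int | None, int | None, int | None, int | None]:
    """(ndn_length, n_insertions, vdins, djins) from junction markers.

    ndn_length = j_start - v_end - 1.  With a defined D segment,
    vdins/djins are the V-D and D-J insert sizes, clamped at 0 when the
    germline segments overlap, and n_insertions = vdins + djins.  Without
    a D segment, vdins/djins are None and n_insertions = ndn_length.
    Returns (None, None, None, None) if v_end or j_start is undefined.
    """
    if c.v_end < 0 or c.j_start < 0:
        return (None, None, None, None)
    L = len(c.cdr3nt)
    for m in (c.v_end, c.j_start):
        if m > L:
            raise ValueError(f"junction marker {m} beyond cdr3nt length {L}")
    ndn = max(0, c.j_start - c.v_end - 1)
    if c.d_start >= 0 and c.d_end >= 0:
        if c.d_end > L:
            raise ValueError(f"junction marker {c.d_end} beyond cdr3nt length {L}")
        vdins = max(0, c.d_start - c.v_end - 1)
        djins = max(0, c.j_start - c.d_end - 1)
        return (ndn, vdins + djins, vdins, djins)
    return (ndn, ndn, None, None)


def cdr3_length(c: Clonotype, unit: str = "nt") -> int:
    if unit == "nt":
        return len(c.cdr3nt)
    if unit == "aa":
        return len(c.cdr3aa)
    raise ValueError(f"unknown unit {unit!r}; expected 'nt' or 'aa'")


def feature_vector(
    rep: Repertoire, table: PropertyTable, weighted: bool = True, k: int = 5
) -> dict[str, float]:
    """The 28 named per-cloneset parameters.

    Physicochemical scales are middle-region averages; cdr3_length (nt) and
    the junction parameters are averaged over clonotypes.  All averages are
    frequency-weighted when ``weighted``.  Junction parameters undefined for
    some clonotypes are averaged over the defined subset with renormalized
    weights (NaN if undefined everywhere).
    """
    if len(rep) == 0:
        raise ValueError(f"{rep.sample_id}: empty repertoire")
    out: dict[str, float] = {}
    for scale in PROPERTY_FEATURES:
        out[scale] = repertoire_property_average(rep, scale, table, weighted=weighted, k=k)

    w = np.array(rep.freqs(), dtype=float) if weighted else np.ones(len(rep))
    lengths = np.array([cdr3_length(c, "nt") for c in rep], dtype=float)
    out["cdr3_length"] = float(np.dot(lengths, w) / w.sum())

    junc = [junction_insertions(c) for c in rep]
    for name, idx in (("ndn_length", 0), ("n_insertions", 1), ("vdins", 2), ("djins", 3)):
        vals = np.array([j[idx] if j[idx] is not None else np.nan for j in junc], dtype=float)
        ok = ~np.isnan(vals)
        if not ok.any():
            logger.warning("%s: %s undefined for every clonotype", rep.sample_id, name)
            out[name] = float("nan")
        else:
            out[name] = float(np.dot(vals[ok], w[ok]) / w[ok].sum())
    return {name: out[name] for name in FEATURE_NAMES}


def feature_table(
    reps: list[Repertoire], table: PropertyTable, weighted: bool = True, k: int = 5
) -> pd.DataFrame:
    """One row per repertoire: donor/subset/chain metadata plus the 28 features."""
    rows = []
    for rep in reps:
        row = {"donor": rep.donor_id, "subset": rep.subset, "chain": rep.chain}
        row.update(feature_vector(rep, table, weighted=weighted, k=k))
        rows.append(row)
    return pd.DataFrame(rows, columns=["donor", "subset", "chain", *FEATURE_NAMES])
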