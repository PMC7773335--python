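"""Synthetic multi-donor, multi-subset clonotype cohorts with planted structure.

Every knob of the generator is recorded in a ground-truth ledger so each
pipeline stage can be tested against known structure:

* heavy-tailed clone sizes (log-normal or power-law);
* per-subset physicochemical bias: middle-5 residues are sampled with
  exponentially tilted weights ``w(aa) ∝ exp(beta * scale(aa))``, with
  ``beta`` solved numerically so the expected per-residue scale value
  shifts by a configured delta;
* junction markers yielding Poisson-distributed V-D and D-J insert sizes;
* planted within-donor sharing: clonotypes replicated between subsets
  with identical (V, CDR3nt);
* planted cross-donor public clonotypes: identical CDR3aa (codons drawn
  independently, so nucleotide identity is not implied).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .features import PropertyTable, load_property_table
from .io import Clonotype, Repertoire
from .normalization import recompute_frequencies

__all__ = [
    "GeneratorConfig",
    "CohortTruth",
    "CohortResult",
    "generate_cohort",
    "plant_expansion",
    "tilted_weights",
]

_STANDARD_AA = "ARNDCQEGHILKMFPSTWYV"

# standard-code codons per amino acid (sense codons only)
_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "N": ["AAT", "AAC"],
    "D": ["GAT", "GAC"],
    "C": ["TGT", "TGC"],
    "Q": ["CAA", "CAG"],
    "E": ["GAA", "GAG"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "K": ["AAA", "AAG"],
    "M": ["ATG"],
    "F": ["TTT", "TTC"],
    "P": ["CCT", "CCC", "CCA", "CCG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"],
    "W": ["TGG"],
    "Y": ["TAT", "TAC"],
    "V": ["GTT", "GTC", "GTA", "GTG"],
}

_SEGMENTS = {
    "TRB": (
        [f"TRBV-sim-{i:02d}" for i in range(1, 31)],
        [f"TRBD-sim-{i:02d}" for i in range(1, 3)],
        [f"TRBJ-sim-{i:02d}" for i in range(1, 14)],
    ),
    "TRA": (
        [f"TRAV-sim-{i:02d}" for i in range(1, 31)],
        [],
        [f"TRAJ-sim-{i:02d}" for i in range(1, 14)],
    ),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the cohort simulator; the seed fully determines output."""

    n_donors: int = 3
    subsets: tuple[str, ...] = ("Tfh", "Th1", "Treg")
    clones_per_subset: int = 1000
    chain: str = "TRB"
    #: "lognormal" on counts or "powerlaw"
    clone_size_model: str = "lognormal"
    lognormal_mu: float = 1.0
    lognormal_sigma: float = 1.2
    powerlaw_alpha: float = 2.5
    #: discrete CDR3 amino-acid length distribution (length -> probability);
    #: None = symmetric triangular over 8..20
    cdr3_aa_length_model: dict[int, float] | None = None
    #: scale on which composition bias is planted
    property_scale: str = "strength"
    #: per-subset target shift delta of the expected per-residue scale value
    #: in the middle-5 window (subsets absent from the map get delta = 0)
    composition_bias: dict[str, float] = field(default_factory=dict)
    #: per-subset Poisson lambda for each of vdins and djins
    n_insertion_model: dict[str, float] = field(default_factory=dict)
    default_insertion_lambda: float = 2.0
    #: within-donor replication probabilities {(subset_i, subset_j): p}
    sharing_matrix: dict[tuple[str, str], float] = field(default_factory=dict)
    #: fraction of each subset's clonotypes drawn from a cohort-shared
    #: amino-acid pool (planted identically across donors)
    public_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_donors < 1 or self.clones_per_subset < 1:
            raise ValueError("n_donors and clones_per_subset must be >= 1")
        if not 0.0 <= self.public_fraction <= 1.0:
            raise ValueError("public_fraction must lie in [0, 1]")
        for (i, j), p in self.sharing_matrix.items():
            if i == j:
                raise ValueError("sharing matrix must be zero on the diagonal")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"sharing probability {p} outside [0, 1]")
            if i not in self.subsets or j not in self.subsets:
                raise ValueError(f"sharing entry ({i}, {j}) names unknown subset")
        if self.chain not in _SEGMENTS:
            raise ValueError(f"unknown chain {self.chain!r}")


@dataclass
class CohortTruth:
    """Ground-truth ledger emitted alongside the generated repertoires."""

    table: pd.DataFrame
    property_scale: str
    #: per-subset expected per-residue scale value in the middle-5 window
    target_property_mean: dict[str, float]


@dataclass
class CohortResult:
    repertoires: list[Repertoire]
    truth: CohortTruth

    def __iter__(self):
        return iter(self.repertoires)

    def __len__(self):
        return len(self.repertoires)


def tilted_weights(scale_values: np.ndarray, delta: float) -> np.ndarray:
    """Exponentially tilted sampling weights hitting mean shift ``delta``.

    Solves ``sum_i w_i(beta) s_i = mean(s) + delta`` with
    ``w_i ∝ exp(beta * s_i)``; raises if the target mean is unreachable.
    """
    s = np.asarray(scale_values, dtype=float)
    target = s.mean() + delta
    if not (s.min() < target < s.max()):
        raise ValueError(f"target mean {target:.4g} outside ({s.min():.4g}, {s.max():.4g})")
    if delta == 0.0:
        return np.full(s.size, 1.0 / s.size)

    def gap(beta: float) -> float:
        w = np.exp(beta * (s - s.max()))  # stabilized
        return float(np.dot(w, s) / w.sum() - target)

    lo, hi = -1.0, 1.0
    while gap(lo) > 0:
        lo *= 2.0
    while gap(hi) < 0:
        hi *= 2.0
    beta = brentq(gap, lo, hi, xtol=1e-12)
    w = np.exp(beta * (s - s.max()))
    return w / w.sum()


def _default_length_model() -> tuple[np.ndarray, np.ndarray]:
    lengths = np.arange(8, 21)
    mid = 14.0
    weights = 7.0 - np.abs(lengths - mid)
    return lengths, weights / weights.sum()


def _draw_counts(cfg: GeneratorConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    if cfg.clone_size_model == "lognormal":
        raw = rng.lognormal(cfg.lognormal_mu, cfg.lognormal_sigma, size=n)
    elif cfg.clone_size_model == "powerlaw":
        raw = (1.0 + rng.pareto(cfg.powerlaw_alpha - 1.0, size=n))
    else:
        raise ValueError(f"unknown clone size model {cfg.clone_size_model!r}")
    return np.maximum(1, np.round(raw)).astype(np.int64)


def _make_markers(L_nt: int, lam: float, rng: np.random.Generator
                  ) -> tuple[int, int, int, int]:
    """Junction markers consistent with Poisson(lam) vdins/djins draws."""
    vdins = int(rng.poisson(lam))
    djins = int(rng.poisson(lam))
    d_len = 6
    budget = L_nt - 2  # at least one V and one J nucleotide
    while vdins + djins + d_len > budget and d_len > 3:
        d_len -= 1
    while vdins + djins + d_len > budget:
        if vdins >= djins and vdins > 0:
            vdins -= 1
        elif djins > 0:
            djins -= 1
        else:
            break
    slack = budget - (vdins + djins + d_len)
    extra_v = int(rng.integers(0, slack + 1))
    v_end = extra_v  # v_len = extra_v + 1
    d_start = v_end + 1 + vdins
    d_end = d_start + d_len - 1
    j_start = d_end + 1 + djins
    return v_end, d_start, d_end, j_start


def _sample_cdr3aa(L: int, base_p: np.ndarray, mid_p: np.ndarray,
                   rng: np.random.Generator) -> str:
    aa_idx = rng.choice(20, size=L, p=base_p)
    k = min(5, L)
    off = (L - k) // 2
    aa_idx[off:off + k] = rng.choice(20, size=k, p=mid_p)
    return "".join(_STANDARD_AA[i] for i in aa_idx)


def _back_translate(aa: str, rng: np.random.Generator) -> str:
    return "".join(_CODONS[a][rng.integers(0, len(_CODONS[a]))] for a in aa)


def generate_cohort(cfg: GeneratorConfig, table: PropertyTable | None = None) -> CohortResult:
    """Generate one repertoire per donor x subset plus the ground-truth ledger.

    Public clonotypes are planted deterministically: the first
    ``round(public_fraction * clones_per_subset)`` clonotypes of each
    subset draw their CDR3aa from a cohort-shared, subset-specific pool in
    fixed order, so the same amino-acid variants recur in every donor.
    """
    cfg.validate()
    if table is None:
        table = load_property_table()
    scale = np.array([table.value(cfg.property_scale, a) for a in _STANDARD_AA])
    base_p = np.full(20, 0.05)
    mid_p_by_subset = {
        s: tilted_weights(scale, cfg.composition_bias.get(s, 0.0)) for s in cfg.subsets
    }
    target_mean = {
        s: float(scale.mean() + cfg.composition_bias.get(s, 0.0)) for s in cfg.subsets
    }
    if cfg.cdr3_aa_length_model is not None:
        lengths = np.array(sorted(cfg.cdr3_aa_length_model))
        len_p = np.array([cfg.cdr3_aa_length_model[l] for l in lengths], dtype=float)
        len_p = len_p / len_p.sum()
    else:
        lengths, len_p = _default_length_model()

    rng = np.random.default_rng(cfg.seed)
    v_cat, d_cat, j_cat = _SEGMENTS[cfg.chain]
    n_public = round(cfg.public_fraction * cfg.clones_per_subset)

    # cohort-shared public pools (one per subset, same tilt as the subset)
    pool_rng = np.random.default_rng(rng.integers(0, 2**63))
    public_pool: dict[str, list[str]] = {}
    for s in cfg.subsets:
        pool = []
        Ls = pool_rng.choice(lengths, size=n_public, p=len_p)
        for L in Ls:
            pool.append(_sample_cdr3aa(int(L), base_p, mid_p_by_subset[s], pool_rng))
        public_pool[s] = pool

    donors = [f"sim-D{d + 1}" for d in range(cfg.n_donors)]
    reps: dict[tuple[str, str], list[Clonotype]] = {}
    truth_rows: list[dict] = []

    for donor in donors:
        for s in cfg.subsets:
            clonotypes: list[Clonotype] = []
            counts = _draw_counts(cfg, cfg.clones_per_subset, rng)
            Ls = rng.choice(lengths, size=cfg.clones_per_subset, p=len_p)
            lam = cfg.n_insertion_model.get(s, cfg.default_insertion_lambda)
            for i in range(cfg.clones_per_subset):
                is_public = i < n_public
                aa = public_pool[s][i] if is_public else _sample_cdr3aa(
                    int(Ls[i]), base_p, mid_p_by_subset[s], rng
                )
                nt = _back_translate(aa, rng)
                v_end, d_start, d_end, j_start = _make_markers(len(nt), lam, rng)
                c = Clonotype(
                    count=int(counts[i]),
                    freq=0.0,
                    cdr3nt=nt,
                    cdr3aa=aa,
                    v_gene=v_cat[rng.integers(0, len(v_cat))],
                    d_gene=d_cat[rng.integers(0, len(d_cat))] if d_cat else "",
                    j_gene=j_cat[rng.integers(0, len(j_cat))],
                    v_end=v_end, d_start=d_start, d_end=d_end, j_start=j_start,
                )
                clonotypes.append(c)
                truth_rows.append({
                    "donor": donor, "subset": s,
                    "v_gene": c.v_gene, "cdr3nt": nt, "cdr3aa": aa,
                    "is_public": is_public, "shared_from": "",
                })
            reps[(donor, s)] = clonotypes

        # planted within-donor sharing (identical V + CDR3nt across subsets)
        for (si, sj), p in sorted(cfg.sharing_matrix.items()):
            if p <= 0.0:
                continue
            source = [c for c in reps[(donor, si)]]
            pick = rng.random(len(source)) < p
            for c, hit in zip(source, pick):
                if not hit:
                    continue
                copy = replace(c, count=int(_draw_counts(cfg, 1, rng)[0]), meta={})
                reps[(donor, sj)].append(copy)
                truth_rows.append({
                    "donor": donor, "subset": sj,
                    "v_gene": c.v_gene, "cdr3nt": c.cdr3nt, "cdr3aa": c.cdr3aa,
                    "is_public": False, "shared_from": si,
                })

    repertoires = []
    for donor in donors:
        for s in cfg.subsets:
            clonotypes = _dedupe(reps[(donor, s)])
            rep = Repertoire(donor_id=donor, subset=s, chain=cfg.chain,
                             clonotypes=clonotypes)
            repertoires.append(recompute_frequencies(rep))

    truth = CohortTruth(
        table=pd.DataFrame(truth_rows),
        property_scale=cfg.property_scale,
        target_property_mean=target_mean,
    )
    return CohortResult(repertoires=repertoires, truth=truth)


def _dedupe(clonotypes: list[Clonotype]) -> list[Clonotype]:
    seen: dict[tuple[str, str], Clonotype] = {}
    out = []
    for c in clonotypes:
        prev = seen.get(c.key)
        if prev is None:
            seen[c.key] = c
            out.append(c)
        else:
            prev.count += c.count
    return out


def plant_expansion(rep: Repertoire, k: int, mass: float) -> Repertoire:
    """Concentrate total frequency ``mass`` onto the ``k`` largest clonotypes.

    The selected clonotypes' total frequency is raised to ``mass`` (split
    in proportion to their current frequencies) and the remainder is
    rescaled to ``1 - mass``; if they already hold >= ``mass`` the
    repertoire is returned unchanged, which makes the operation continuous
    as ``mass -> 0``.  Frequencies only are adjusted; integer counts are
    left untouched.  Normalized Shannon-Wiener strictly decreases whenever
    the reassignment is non-trivial.
    """
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie strictly between 0 and 1")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= len(rep):
        raise ValueError("k must be smaller than the repertoire size")
    out = Repertoire(rep.donor_id, rep.subset, rep.chain,
                     [replace(c, meta=dict(c.meta)) for c in rep.clonotypes])
    order = sorted(range(len(out)), key=lambda i: (-out.clonotypes[i].freq,
                                                   out.clonotypes[i].key))
    selected = set(order[:k])
    sel_total = math.fsum(out.clonotypes[i].freq for i in selected)
    if sel_total >= mass:
        return out
    rest_total = math.fsum(c.freq for i, c in enumerate(out.clonotypes)
                           if i not in selected)
    for i, c in enumerate(out.clonotypes):
        if i in selected:
            c.freq = c.freq / sel_total * mass if sel_total > 0 else mass / k
        else:
            c.freq = c.freq / rest_total * (1.0 - mass)
    return out
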