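"""End-to-end orchestration over a directory of clonotype tables.

Given a sample sheet (donor, subset, chain, path), runs
normalize -> features -> diversity -> overlap -> publicity -> network ->
PCA -> stats and writes one long-format TSV report per stage, each with a
commented header block recording the stage parameters.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diversity import diversity_result
from .features import FEATURE_NAMES, feature_table, load_property_table
from .io import Repertoire, read_clonotype_table
from .normalization import (
    DEFAULT_N_MOLECULES, DEFAULT_TOP_N_NETWORK, DEFAULT_TOP_N_OVERLAP,
    DownsampleSpec, downsample_umis, top_n_clonotypes,
)
from .overlap import build_sharing_network, overlap_result
from .publicity import publicity_matrix
from .stats import group_vs_mean_tests, pca

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "read_sample_sheet"]


@dataclass
class PipelineConfig:
    sample_sheet: str | Path
    output_dir: str | Path
    dialect: str = "vdjtools"
    n_molecules: int = DEFAULT_N_MOLECULES
    top_n_overlap: int = DEFAULT_TOP_N_OVERLAP
    top_n_network: int = DEFAULT_TOP_N_NETWORK
    middle_k: int = 5
    weighted: bool = True
    #: PCA layout: "concat" = one row per donor x subset with TRA and TRB
    #: features side by side; "per_chain" = one row per donor x subset x chain
    pca_layout: str = "concat"
    seed: int = 0
    params: dict = field(default_factory=dict)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"donor", "subset", "chain", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    if df.empty:
        raise ValueError("sample sheet has no samples")
    return df


def _write_report(df: pd.DataFrame, path: Path, stage: str, cfg: PipelineConfig,
                  extra: dict | None = None) -> None:
    params = {
        "stage": stage, "version": __version__, "seed": cfg.seed,
        "n_molecules": cfg.n_molecules, "top_n_overlap": cfg.top_n_overlap,
        "top_n_network": cfg.top_n_network, "middle_k": cfg.middle_k,
        "weighted": cfg.weighted, **(extra or {}),
    }
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in params.items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Run every stage; returns {report name: path}.  Raises on stage failure
    (partial outputs are retained on disk)."""
    t0 = time.monotonic()
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sheet = read_sample_sheet(cfg.sample_sheet)
    base = Path(cfg.sample_sheet).parent

    reps: list[Repertoire] = []
    for row in sheet.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = base / p
        reps.append(read_clonotype_table(p, dialect=cfg.dialect, donor_id=row.donor,
                                         subset=row.subset, chain=row.chain))
    logger.info("loaded %d samples in %.1fs", len(reps), time.monotonic() - t0)
    table = load_property_table()
    reports: dict[str, Path] = {}

    def stage(name):
        logger.info("stage %s", name)
        return time.monotonic()

    # features (per-sample 28-parameter vectors)
    t = stage("features")
    feats = feature_table(reps, table, weighted=cfg.weighted, k=cfg.middle_k)
    reports["features"] = out_dir / "features.tsv"
    _write_report(feats, reports["features"], "features", cfg)
    logger.info("features done in %.1fs", time.monotonic() - t)

    # diversity on downsampled clonesets
    t = stage("diversity")
    rows = []
    for rep in reps:
        if rep.total_count < cfg.n_molecules:
            logger.warning("%s: %d molecules < %d, excluded from diversity",
                           rep.sample_id, rep.total_count, cfg.n_molecules)
            continue
        ds = downsample_umis(rep, DownsampleSpec(cfg.n_molecules, cfg.seed))
        d = diversity_result(ds)
        rows.append({"donor": rep.donor_id, "subset": rep.subset, "chain": rep.chain,
                     "observed": d.observed, "chao1": d.chao1,
                     "normalized_shannon_wiener": d.normalized_shannon_wiener,
                     "n_molecules": d.n_molecules})
    reports["diversity"] = out_dir / "diversity.tsv"
    div_cols = ["donor", "subset", "chain", "observed", "chao1",
                "normalized_shannon_wiener", "n_molecules"]
    _write_report(pd.DataFrame(rows, columns=div_cols), reports["diversity"],
                  "diversity", cfg)
    logger.info("diversity done in %.1fs", time.monotonic() - t)

    # pairwise within-donor overlap on top-N clonesets
    t = stage("overlap")
    rows = []
    by_donor_chain: dict[tuple[str, str], list[Repertoire]] = {}
    for rep in reps:
        by_donor_chain.setdefault((rep.donor_id, rep.chain), []).append(rep)
    for (donor, chain), group in sorted(by_donor_chain.items()):
        if len(group) < 2:
            logger.info("donor %s chain %s: <2 subsets, overlap skipped", donor, chain)
            continue
        trunc = {r.subset: top_n_clonotypes(r, cfg.top_n_overlap) for r in group}
        for sa, sb in combinations(sorted(trunc), 2):
            res = overlap_result(trunc[sa], trunc[sb])
            rows.append({"donor": donor, "chain": chain, "subset_a": sa, "subset_b": sb,
                         "n_shared": res.n_shared, "f2": res.f2, "d": res.d})
    reports["overlap"] = out_dir / "overlap.tsv"
    ov_cols = ["donor", "chain", "subset_a", "subset_b", "n_shared", "f2", "d"]
    _write_report(pd.DataFrame(rows, columns=ov_cols), reports["overlap"],
                  "overlap", cfg)
    logger.info("overlap done in %.1fs", time.monotonic() - t)

    # sharing network per donor
    t = stage("network")
    nodes_all, edges_all = [], []
    for (donor, chain), group in sorted(by_donor_chain.items()):
        if len(group) < 2:
            logger.info("donor %s chain %s: <2 subsets, network skipped", donor, chain)
            continue
        net = build_sharing_network(group, top_n=cfg.top_n_network)
        for df_part, sink in ((net.nodes, nodes_all), (net.edges, edges_all)):
            part = df_part.copy()
            part.insert(0, "chain", chain)
            part.insert(0, "donor", donor)
            sink.append(part)
    from .overlap import SharingNetwork
    empty_nodes = pd.DataFrame(columns=["donor", "chain", *SharingNetwork.NODE_COLUMNS])
    empty_edges = pd.DataFrame(columns=["donor", "chain", *SharingNetwork.EDGE_COLUMNS])
    nodes = pd.concat(nodes_all, ignore_index=True) if nodes_all else empty_nodes
    edges = pd.concat(edges_all, ignore_index=True) if edges_all else empty_edges
    reports["network_nodes"] = out_dir / "network_nodes.tsv"
    reports["network_edges"] = out_dir / "network_edges.tsv"
    _write_report(nodes, reports["network_nodes"], "network_nodes", cfg)
    _write_report(edges, reports["network_edges"], "network_edges", cfg)
    logger.info("network done in %.1fs", time.monotonic() - t)

    # cross-donor publicity per subset
    t = stage("publicity")
    rows = []
    by_subset_chain: dict[tuple[str, str], dict[str, Repertoire]] = {}
    for rep in reps:
        by_subset_chain.setdefault((rep.subset, rep.chain), {})[rep.donor_id] = rep
    for (subset, chain), by_donor in sorted(by_subset_chain.items()):
        if len(by_donor) < 2:
            logger.info("subset %s chain %s: <2 donors, publicity skipped", subset, chain)
            continue
        for res in publicity_matrix(by_donor, top_n=cfg.top_n_overlap):
            rows.append({"subset": subset, "chain": chain,
                         "donor_a": res.donor_a, "donor_b": res.donor_b,
                         "n_ab": res.n_ab, "n_ba": res.n_ba, "n_public": res.n_public})
    reports["publicity"] = out_dir / "publicity.tsv"
    pub_cols = ["subset", "chain", "donor_a", "donor_b", "n_ab", "n_ba", "n_public"]
    _write_report(pd.DataFrame(rows, columns=pub_cols), reports["publicity"],
                  "publicity", cfg)
    logger.info("publicity done in %.1fs", time.monotonic() - t)

    # PCA over feature vectors
    t = stage("pca")
    reports["pca_scores"] = out_dir / "pca_scores.tsv"
    reports["pca_loadings"] = out_dir / "pca_loadings.tsv"
    matrix, meta, param_names = _pca_matrix(feats, cfg.pca_layout)
    if matrix is not None and matrix.shape[0] >= 3:
        res = pca(matrix, parameter_names=param_names)
        scores = meta.copy()
        for j in range(res.scores.shape[1]):
            scores[f"PC{j + 1}"] = res.scores[:, j]
        loadings = pd.DataFrame(res.loadings,
                                columns=[f"PC{j + 1}" for j in range(res.loadings.shape[1])])
        loadings.insert(0, "parameter", res.parameters)
        evr = {f"evr_PC{j + 1}": f"{r:.6g}"
               for j, r in enumerate(res.explained_variance_ratio)}
        _write_report(scores, reports["pca_scores"], "pca_scores", cfg, extra=evr)
        _write_report(loadings, reports["pca_loadings"], "pca_loadings", cfg)
    else:
        logger.warning("PCA skipped: fewer than 3 samples")
        _write_report(pd.DataFrame(), reports["pca_scores"], "pca_scores", cfg)
        _write_report(pd.DataFrame(), reports["pca_loadings"], "pca_loadings", cfg)
    logger.info("pca done in %.1fs", time.monotonic() - t)

    # per-parameter group-vs-mean statistics across subsets (per chain)
    t = stage("stats")
    rows = []
    for chain, sub in feats.groupby("chain"):
        for param in FEATURE_NAMES:
            values_by_group = {
                s: g[param].dropna().tolist() for s, g in sub.groupby("subset")
            }
            values_by_group = {s: v for s, v in values_by_group.items() if len(v) >= 2}
            if len(values_by_group) < 2:
                continue
            res = group_vs_mean_tests(values_by_group)
            for g in res.groups:
                rows.append({
                    "chain": chain, "parameter": param, "subset": g,
                    "omnibus_test": res.omnibus_test, "omnibus_p": res.omnibus_p,
                    "test": res.per_group_test, "statistic": res.statistics[g],
                    "p": res.raw_p[g], "p_adjusted": res.adjusted_p[g],
                    "tier": res.tiers[g],
                })
    reports["stats"] = out_dir / "stats.tsv"
    stat_cols = ["chain", "parameter", "subset", "omnibus_test", "omnibus_p",
                 "test", "statistic", "p", "p_adjusted", "tier"]
    _write_report(pd.DataFrame(rows, columns=stat_cols), reports["stats"],
                  "stats", cfg)
    logger.info("pipeline finished in %.1fs", time.monotonic() - t0)
    return reports


def _pca_matrix(feats: pd.DataFrame, layout: str):
    """Assemble the PCA input per the configured layout."""
    if layout == "per_chain":
        meta = feats[["donor", "subset", "chain"]].reset_index(drop=True)
        return feats[FEATURE_NAMES].to_numpy(float), meta, list(FEATURE_NAMES)
    if layout != "concat":
        raise ValueError(f"unknown PCA layout {layout!r}")
    chains = sorted(feats["chain"].unique())
    if len(chains) == 1:
        meta = feats[["donor", "subset", "chain"]].reset_index(drop=True)
        return feats[FEATURE_NAMES].to_numpy(float), meta, list(FEATURE_NAMES)
    wide = None
    names: list[str] = []
    for chain in chains:
        sub = feats[feats["chain"] == chain].set_index(["donor", "subset"])[FEATURE_NAMES]
        sub.columns = [f"{chain}_{c}" for c in FEATURE_NAMES]
        names.extend(sub.columns)
        wide = sub if wide is None else wide.join(sub, how="inner")
    if wide is None or wide.empty:
        return None, None, None
    meta = wide.reset_index()[["donor", "subset"]]
    meta["chain"] = "+".join(chains)
    return wide.to_numpy(float), meta, names
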