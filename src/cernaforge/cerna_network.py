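"""Assemble the circRNA-miRNA-mRNA competing-endogenous-RNA network.

A triplet (circRNA c, miRNA m, mRNA g) is retained when

- m has predicted seed sites on both c and g (target pairs exist),
- Spearman(m, g) < scc threshold and Spearman(m, c) < scc threshold
  (default -0.7: the miRNA is anti-correlated with both sponges),
- Pearson(c, g) > pcc threshold (default 0.9: the sponges co-express),
- the shared-sponge hypergeometric test for (c, g) gives p < alpha
  (default 0.05): the two transcripts share more predicted miRNA
  regulators than expected by chance in the universe of DE miRNAs.

Correlations are computed on group-mean expression profiles (the 12
(sex, tissue) groups of the default design), not on replicate columns;
a replicate-level mode is available.  All threshold inequalities are
strict.  Undefined correlations (constant profiles) count as filter
failures during assembly, not errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    ExpressionMatrix,
    InvalidArgumentError,
    UndefinedCorrelationError,
)
from .seed_targets import TargetPair

DEFAULT_THRESHOLDS = {"scc": -0.7, "pcc": 0.9, "alpha": 0.05}


def _check_vectors(x: Sequence[float], y: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise InvalidArgumentError("need two equal-length vectors of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise InvalidArgumentError("vectors must be finite")
    return x, y


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (average ranks on ties)."""
    x, y = _check_vectors(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation of a constant vector is undefined")
    return float(stats.spearmanr(x, y).statistic)


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation."""
    x, y = _check_vectors(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation of a constant vector is undefined")
    return float(stats.pearsonr(x, y).statistic)


def shared_sponge_test(
    mirnas_of_circ: set[str], mirnas_of_mrna: set[str], universe_size: int
) -> tuple[int, float]:
    """Upper-tail hypergeometric test of shared miRNA regulators.

    With K = |miRNAs targeting the circRNA|, n = |miRNAs targeting the
    mRNA| drawn from a universe of N miRNAs, returns the number shared
    and P[X >= shared] for X ~ Hypergeom(N, K, n).
    """
    union = mirnas_of_circ | mirnas_of_mrna
    if universe_size < len(union):
        raise InvalidArgumentError("universe smaller than the union of the two sets")
    shared = len(mirnas_of_circ & mirnas_of_mrna)
    if shared == 0:
        return 0, 1.0
    p = float(
        stats.hypergeom.sf(
            shared - 1, universe_size, len(mirnas_of_circ), len(mirnas_of_mrna)
        )
    )
    return shared, min(p, 1.0)


@dataclass(frozen=True)
class CorrelationEdge:
    source: str
    target: str
    kind: str  # miRNA-mRNA, miRNA-circRNA, circRNA-mRNA
    scc: float | None
    pcc: float | None
    passes: bool


@dataclass(frozen=True)
class CeRNATriplet:
    circ_id: str
    mirna_id: str
    mrna_id: str
    scc_mir_mrna: float
    scc_mir_circ: float
    pcc_circ_mrna: float
    n_shared_mirnas: int
    hypergeom_p: float
    significant: bool


@dataclass
class CeRNANetwork:
    nodes: dict[str, str]  # id -> node type (circRNA / miRNA / mRNA)
    edges: list[CorrelationEdge]
    triplets: list[CeRNATriplet]
    provenance: dict = field(default_factory=dict)

    def node_type_counts(self) -> tuple[int, int, int]:
        types = list(self.nodes.values())
        return (types.count("circRNA"), types.count("miRNA"), types.count("mRNA"))


def _profiles(
    matrix: ExpressionMatrix, features: Iterable[str], replicate_level: bool
) -> pd.DataFrame:
    data = matrix.counts if replicate_level else matrix.group_means()
    feats = [f for f in features if f in data.index]
    return data.loc[feats]


def _safe_corr(fn, x, y) -> float | None:
    try:
        return fn(x, y)
    except UndefinedCorrelationError:
        return None


def build_network(
    de_circ: set[str],
    de_mirna: set[str],
    de_mrna: set[str],
    profiles: Mapping[str, ExpressionMatrix],
    target_pairs: Iterable[TargetPair],
    scc_threshold: float = DEFAULT_THRESHOLDS["scc"],
    pcc_threshold: float = DEFAULT_THRESHOLDS["pcc"],
    alpha: float = DEFAULT_THRESHOLDS["alpha"],
    universe_size: int | None = None,
    replicate_level: bool = False,
) -> CeRNANetwork:
    """Assemble the ceRNA network from DE feature sets and target pairs.

    ``profiles`` maps {"circ", "mirna", "mrna"} to their expression
    matrices; correlations use group means unless ``replicate_level``.
    ``universe_size`` defaults to the number of DE miRNAs (the sampling
    frame for the shared-sponge test).  Only nodes participating in at
    least one retained triplet appear in the network.
    """
    if not 0 < alpha <= 1:
        raise InvalidArgumentError("alpha must be in (0, 1]")
    targets_of: dict[str, set[str]] = {}  # miRNA -> transcripts
    for tp in target_pairs:
        targets_of.setdefault(tp.mirna_id, set()).add(tp.transcript_id)

    de_circ, de_mirna, de_mrna = set(de_circ), set(de_mirna), set(de_mrna)
    N = universe_size if universe_size is not None else len(de_mirna)

    circ_prof = _profiles(profiles["circ"], sorted(de_circ), replicate_level)
    mir_prof = _profiles(profiles["mirna"], sorted(de_mirna), replicate_level)
    mrna_prof = _profiles(profiles["mrna"], sorted(de_mrna), replicate_level)

    # candidate regulators per transcript: DE miRNAs with predicted sites
    # whose expression anti-correlates with the transcript (SCC filter) --
    # the shared-sponge test asks whether two transcripts share more of
    # these than chance allows
    scc_cache: dict[tuple[str, str], float | None] = {}

    def scc_of(mid: str, tid: str, m_vec, t_vec) -> float | None:
        if (mid, tid) not in scc_cache:
            scc_cache[(mid, tid)] = _safe_corr(spearman, m_vec, t_vec)
        return scc_cache[(mid, tid)]

    sponge_mirnas: dict[str, set[str]] = {}
    for mid, txs in sorted(targets_of.items()):
        if mid not in set(mir_prof.index):
            continue
        m_vec = mir_prof.loc[mid].values
        for tid in sorted(txs):
            prof = circ_prof if tid in de_circ else mrna_prof if tid in de_mrna else None
            if prof is None or tid not in prof.index:
                continue
            s = scc_of(mid, tid, m_vec, prof.loc[tid].values)
            if s is not None and s < scc_threshold:
                sponge_mirnas.setdefault(tid, set()).add(mid)

    triplets: list[CeRNATriplet] = []
    edges: dict[tuple[str, str, str], CorrelationEdge] = {}
    sponge_cache: dict[tuple[str, str], tuple[int, float]] = {}

    for cid in sorted(set(circ_prof.index) & set(sponge_mirnas)):
        c_vec = circ_prof.loc[cid].values
        for mid in sorted(sponge_mirnas[cid]):
            m_vec = mir_prof.loc[mid].values
            scc_mc = scc_cache[(mid, cid)]
            for gid in sorted(targets_of[mid] & set(mrna_prof.index)):
                if mid not in sponge_mirnas.get(gid, set()):
                    continue
                g_vec = mrna_prof.loc[gid].values
                scc_mg = scc_cache[(mid, gid)]
                pcc_cg = _safe_corr(pearson, c_vec, g_vec)
                if pcc_cg is None or not (pcc_cg > pcc_threshold):
                    continue
                if (cid, gid) not in sponge_cache:
                    sponge_cache[(cid, gid)] = shared_sponge_test(
                        sponge_mirnas.get(cid, set()), sponge_mirnas.get(gid, set()), N
                    )
                n_shared, hp = sponge_cache[(cid, gid)]
                sig = hp < alpha
                triplets.append(
                    CeRNATriplet(cid, mid, gid, scc_mg, scc_mc, pcc_cg,
                                 n_shared, hp, sig)
                )
                if sig:
                    edges[("miRNA-circRNA", mid, cid)] = CorrelationEdge(
                        mid, cid, "miRNA-circRNA", scc_mc, None, True
                    )
                    edges[("miRNA-mRNA", mid, gid)] = CorrelationEdge(
                        mid, gid, "miRNA-mRNA", scc_mg, None, True
                    )
                    edges[("circRNA-mRNA", cid, gid)] = CorrelationEdge(
                        cid, gid, "circRNA-mRNA", None, pcc_cg, True
                    )

    retained = [t for t in triplets if t.significant]
    nodes: dict[str, str] = {}
    for t in retained:
        nodes[t.circ_id] = "circRNA"
        nodes[t.mirna_id] = "miRNA"
        nodes[t.mrna_id] = "mRNA"
    provenance = {
        "scc_threshold": scc_threshold,
        "pcc_threshold": pcc_threshold,
        "alpha": alpha,
        "universe_size": N,
        "replicate_level": replicate_level,
        "n_de": {"circ": len(de_circ), "mirna": len(de_mirna), "mrna": len(de_mrna)},
    }
    return CeRNANetwork(
        nodes=dict(sorted(nodes.items())),
        edges=[edges[k] for k in sorted(edges)],
        triplets=retained,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# export / import
# ---------------------------------------------------------------------------

def _fmt(v: float | None) -> str:
    return "" if v is None else f"{v:.10g}"


def export_network(
    network: CeRNANetwork,
    outdir: str | Path,
    heatmap_profiles: ExpressionMatrix | None = None,
) -> dict[str, Path]:
    """Write node/edge/triplet tables, a Sankey link table, and an
    optional row-scaled circRNA group-mean matrix for heatmapping.

    The node/edge/triplet TSVs round-trip losslessly through
    :func:`import_network`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    nodes = pd.DataFrame(
        sorted(network.nodes.items()), columns=["node_id", "node_type"]
    )
    paths["nodes"] = outdir / "nodes.tsv"
    nodes.to_csv(paths["nodes"], sep="\t", index=False)

    edges = pd.DataFrame(
        [
            (e.kind, e.source, e.target, _fmt(e.scc), _fmt(e.pcc), e.passes)
            for e in network.edges
        ],
        columns=["kind", "source", "target", "scc", "pcc", "passes"],
    )
    paths["edges"] = outdir / "edges.tsv"
    edges.to_csv(paths["edges"], sep="\t", index=False)

    trip = pd.DataFrame(
        [
            (
                t.circ_id, t.mirna_id, t.mrna_id,
                f"{t.scc_mir_mrna:.10g}", f"{t.scc_mir_circ:.10g}",
                f"{t.pcc_circ_mrna:.10g}", t.n_shared_mirnas,
                f"{t.hypergeom_p:.10g}", t.significant,
            )
            for t in network.triplets
        ],
        columns=[
            "circ_id", "mirna_id", "mrna_id", "scc_mir_mrna", "scc_mir_circ",
            "pcc_circ_mrna", "n_shared_mirnas", "hypergeom_p", "significant",
        ],
    )
    paths["triplets"] = outdir / "triplets.tsv"
    trip.to_csv(paths["triplets"], sep="\t", index=False)

    # Sankey: circRNA -> miRNA and miRNA -> mRNA links, one row per edge
    links = [
        (e.target, e.source, 1) for e in network.edges if e.kind == "miRNA-circRNA"
    ] + [
        (e.source, e.target, 1) for e in network.edges if e.kind == "miRNA-mRNA"
    ]
    paths["sankey"] = outdir / "sankey.tsv"
    pd.DataFrame(links, columns=["source", "target", "value"]).to_csv(
        paths["sankey"], sep="\t", index=False
    )

    if heatmap_profiles is not None:
        circ_ids = [n for n, t in network.nodes.items() if t == "circRNA"]
        gm = heatmap_profiles.group_means()
        gm = gm.loc[[c for c in circ_ids if c in gm.index]]
        if len(gm):
            centered = gm.sub(gm.mean(axis=1), axis=0)
            sd = gm.std(axis=1).replace(0, 1.0)
            gm = centered.div(sd, axis=0)
        paths["heatmap"] = outdir / "heatmap_matrix.tsv"
        gm.round(6).to_csv(paths["heatmap"], sep="\t", index_label="circ_id")
    return paths


def import_network(indir: str | Path) -> CeRNANetwork:
    indir = Path(indir)
    nodes_df = pd.read_csv(indir / "nodes.tsv", sep="\t", dtype=str)
    nodes = dict(zip(nodes_df.get("node_id", []), nodes_df.get("node_type", [])))
    edges_df = pd.read_csv(indir / "edges.tsv", sep="\t", dtype=str)
    edges = [
        CorrelationEdge(
            r.source, r.target, r.kind,
            None if pd.isna(r.scc) or r.scc == "" else float(r.scc),
            None if pd.isna(r.pcc) or r.pcc == "" else float(r.pcc),
            str(r.passes) == "True",
        )
        for r in edges_df.itertuples(index=False)
    ]
    trip_df = pd.read_csv(indir / "triplets.tsv", sep="\t", dtype=str)
    triplets = [
        CeRNATriplet(
            r.circ_id, r.mirna_id, r.mrna_id,
            float(r.scc_mir_mrna), float(r.scc_mir_circ), float(r.pcc_circ_mrna),
            int(r.n_shared_mirnas), float(r.hypergeom_p), str(r.significant) == "True",
        )
        for r in trip_df.itertuples(index=False)
    ]
    return CeRNANetwork(nodes=nodes, edges=edges, triplets=triplets)
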