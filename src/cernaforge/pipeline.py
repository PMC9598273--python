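"""End-to-end orchestration: simulate -> annotate -> de -> targets ->
network -> enrich (-> qpcr), driven by one YAML config, with a manifest
capturing seeds, thresholds and file digests for provenance.

Re-running with an identical config and seed reproduces byte-identical
outputs; the manifest records no timestamps.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import circ_annotate, de_analysis, enrichment, qpcr, seed_targets
from . import cerna_network as net
from .core import InvalidArgumentError, StudyDesign, sha256_file
from .synthetic_data import BundleSpec, CountSimSpec, SyntheticBundle, generate_bundle

log = logging.getLogger("cernaforge")


@dataclass
class PipelineConfig:
    """Thresholds, design and sizes of one pipeline run.

    Threshold defaults are the study's printed values: |log2FC| >= 1 and
    p < 0.05 for DE; SCC < -0.7, PCC > 0.9 and sponge p < 0.05 for the
    network.
    """

    seed: int = 0
    lfc: float = 1.0
    alpha: float = 0.05
    scc: float = -0.7
    pcc: float = 0.9
    sponge_alpha: float = 0.05
    fdr: bool = False
    tissues: tuple[str, ...] = ("B", "G", "L", "M")
    sexes: tuple[str, ...] = ("F", "M", "PM")
    replicates: int = 3
    bundle: BundleSpec = field(default_factory=BundleSpec)
    input_dir: str | None = None  # read a bundle from disk instead of simulating
    qpcr_ct_table: str | None = None  # optional Ct TSV for the qpcr stage
    qpcr_calibrator: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1 or not 0 < self.sponge_alpha <= 1:
            raise InvalidArgumentError("alpha thresholds must be in (0, 1]")
        if self.lfc < 0:
            raise InvalidArgumentError("lfc threshold must be >= 0")

    def design(self) -> StudyDesign:
        return StudyDesign(tuple(self.tissues), tuple(self.sexes),
                           self.replicates, self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        bundle_raw = raw.pop("bundle", {})
        counts_raw = bundle_raw.pop("counts", {}) if bundle_raw else {}
        cfg = cls(**{k: tuple(v) if k in ("tissues", "sexes") else v for k, v in raw.items()})
        if bundle_raw or counts_raw:
            cfg.bundle = BundleSpec(**bundle_raw)
            if counts_raw:
                cfg.bundle.counts = CountSimSpec(**counts_raw)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        # json round-trip coerces numpy scalars and tuples to plain types
        d = json.loads(json.dumps(dataclasses.asdict(self), default=float))
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute all stages in dependency order; returns the manifest.

    Outputs land in per-stage subdirectories of ``outdir``; the manifest
    (``manifest.json``) records the config, per-file SHA-256 digests and
    headline result counts.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(config), "stages": {}, "files": {}}
    stage = "simulate"
    try:
        # --- inputs -------------------------------------------------------
        if config.input_dir:
            bundle = SyntheticBundle.read(config.input_dir)
        else:
            bundle = generate_bundle(config.bundle, config.design(), config.seed)
            bundle.write(outdir / "bundle")
        manifest["stages"]["simulate"] = {
            "n_circ": len(bundle.circ_records),
            "n_mirna": len(bundle.counts["mirna"].features),
            "n_mrna": len(bundle.counts["mrna"].features),
        }

        # --- annotate -----------------------------------------------------
        stage = "annotate"
        adir = outdir / "annotate"
        adir.mkdir(exist_ok=True)
        summary = circ_annotate.summarize(bundle.circ_records, bundle.annotation)
        summary.to_tsv(adir / "circ_summary.tsv")
        manifest["stages"]["annotate"] = {"type_fractions": summary.type_fractions}

        # --- de -----------------------------------------------------------
        stage = "de"
        ddir = outdir / "de"
        ddir.mkdir(exist_ok=True)
        de_sets = {}
        for kind in ("circ", "mirna", "mrna"):
            results = de_analysis.run_all_comparisons(
                bundle.counts[kind], config.lfc, config.alpha, fdr=config.fdr
            )
            for key, res in results.items():
                de_analysis.de_table(res).to_csv(
                    ddir / f"{kind}_{key.replace(':', '_')}.tsv", sep="\t", index=False
                )
            de_sets[kind] = de_analysis.significant_union(results)
            per_comp = {
                k: {r.feature_id for r in v if r.significant} for k, v in results.items()
            }
            if kind == "circ":
                # Venn over the three gonad comparisons, the tissue with the
                # richest DE signal in this design
                gonad = {k: v for k, v in per_comp.items() if k.startswith("G:")}
                if len(gonad) >= 2:
                    regions = de_analysis.intersect_de_sets(gonad)
                    de_analysis.intersection_table(regions).to_csv(
                        ddir / "circ_gonad_venn.tsv", sep="\t", index=False
                    )
        manifest["stages"]["de"] = {k: len(v) for k, v in de_sets.items()}

        # --- targets ------------------------------------------------------
        stage = "targets"
        tdir = outdir / "targets"
        tdir.mkdir(exist_ok=True)
        mirna_seqs = {k: v for k, v in bundle.sequences.items() if k.startswith("mir_")}
        transcripts = {
            k: v for k, v in bundle.sequences.items()
            if k.startswith(("circ_", "mrna_"))
        }
        sites = seed_targets.scan_all(transcripts, mirna_seqs)
        pairs = seed_targets.build_target_pairs(sites)
        seed_targets.sites_table(sites).to_csv(tdir / "sites.tsv", sep="\t", index=False)
        seed_targets.pairs_table(pairs).to_csv(tdir / "pairs.tsv", sep="\t", index=False)
        manifest["stages"]["targets"] = {"n_sites": len(sites), "n_pairs": len(pairs)}

        # --- network ------------------------------------------------------
        stage = "network"
        ndir = outdir / "network"
        network = net.build_network(
            de_sets["circ"], de_sets["mirna"], de_sets["mrna"],
            bundle.counts, pairs,
            scc_threshold=config.scc, pcc_threshold=config.pcc,
            alpha=config.sponge_alpha,
        )
        net.export_network(network, ndir, heatmap_profiles=bundle.counts["circ"])
        manifest["stages"]["network"] = {
            "node_counts": network.node_type_counts(),
            "n_triplets": len(network.triplets),
        }

        # --- enrich -------------------------------------------------------
        stage = "enrich"
        edir = outdir / "enrich"
        edir.mkdir(exist_ok=True)
        background = set(bundle.counts["mrna"].features)
        tm = enrichment.TermMap(
            bundle.term_map,
            {t: t for t in bundle.term_map},
            background,
        )
        network_mrnas = {n for n, t in network.nodes.items() if t == "mRNA"}
        if network_mrnas:
            res = enrichment.ora(network_mrnas, tm)
            enrichment.enrichment_table(res).to_csv(
                edir / "enrichment.tsv", sep="\t", index=False
            )
            manifest["stages"]["enrich"] = {"n_terms_tested": len(res)}
        else:
            manifest["stages"]["enrich"] = {"n_terms_tested": 0}

        # --- qpcr (optional) ---------------------------------------------
        if config.qpcr_ct_table:
            stage = "qpcr"
            qdir = outdir / "qpcr"
            qdir.mkdir(exist_ok=True)
            ct = pd.read_csv(config.qpcr_ct_table, sep="\t")
            rel = qpcr.ddct(ct, config.qpcr_calibrator)
            qpcr.relexpr_table(rel).to_csv(qdir / "relative_expression.tsv",
                                           sep="\t", index=False)
            manifest["stages"]["qpcr"] = {"n_rows": len(rel)}
    except Exception as exc:  # halt with a stage-tagged error + partial manifest
        manifest["failed_stage"] = stage
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        _finalize_manifest(manifest, outdir)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    _finalize_manifest(manifest, outdir)
    return manifest


def _finalize_manifest(manifest: dict, outdir: Path) -> None:
    for p in sorted(outdir.rglob("*.tsv")) + sorted(outdir.rglob("*.gff3")) + sorted(
        outdir.rglob("*.bed")
    ) + sorted(outdir.rglob("*.fasta")):
        manifest["files"][str(p.relative_to(outdir))] = sha256_file(p)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=list)
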