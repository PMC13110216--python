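"""End-to-end orchestration: simulate -> de -> trn -> rank -> targets -> morpho -> qpcr.

Every run writes its resolved configuration and a manifest (stage outputs +
SHA-256 checksums) next to the outputs, so reruns with the same seed are
byte-identical and verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import centrality, diffexpr, morpho, qpcr, trn
from .simdata import (
    SimConfig,
    make_tss_table,
    simulate_chip_peaks,
    simulate_counts,
    simulate_morphologies,
    simulate_qpcr,
    write_bundle,
)
from .simdata.chip import write_bed
from .targets import assign_peaks_to_tss, intersect_targets

log = logging.getLogger("trnkit.pipeline")

__all__ = ["PipelineConfig", "run_all"]


@dataclass
class PipelineConfig:
    outdir: str = "trnkit_run"
    seed: int = 0
    # simulate
    sim: SimConfig = field(default_factory=SimConfig)
    # de
    lfc_min: float = 1.0
    padj_max: float = 0.01
    # trn
    n_perm: int = 500
    p_cut: float = 0.005
    n_boot: int = 100
    consensus: float = 0.75
    dpi_tolerance: float = 0.0
    bins: int = 4
    # rank
    top_n: int = 10
    margin: float = 0.45
    # targets
    window_bp: int = 1000
    decoy_frac: float = 0.2
    # morpho
    step_um: float = 1.0
    n_cells: int = 8
    # qpcr
    qpcr_noise_sd: float = 0.1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        return cls(sim=sim, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"] = asdict(self.sim)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(cfg: PipelineConfig) -> dict:
    """Execute all stages on synthetic data; returns the run manifest."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": {}, "checksums": {}}
    written: list[Path] = []

    def record(stage: str, *paths: Path) -> None:
        # relative paths keep manifests byte-identical across output locations
        manifest["stages"][stage] = [str(Path(p).relative_to(out)) for p in paths]
        written.extend(paths)

    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)

    stage = "simulate"
    try:
        log.info("stage %s", stage)
        sim_cfg = SimConfig(**{**asdict(cfg.sim), "seed": cfg.seed})
        counts, annotation, truth = simulate_counts(sim_cfg)
        paths = write_bundle(out, counts, annotation, truth)
        record(stage, *paths.values())

        stage = "de"
        log.info("stage %s", stage)
        contrast = (sim_cfg.conditions[3], sim_cfg.conditions[0])
        de_table = diffexpr.nb_wald_test(counts, annotation, contrast)
        de_path = out / "de.tsv"
        de_table.to_csv(de_path, sep="\t")
        up = diffexpr.filter_degs(de_table, cfg.lfc_min, cfg.padj_max, "up")
        record(stage, de_path)

        stage = "trn"
        log.info("stage %s", stage)
        tf_list = sorted(truth.regulons.regulons)
        edges = trn.infer_candidate_edges(
            counts,
            tf_list,
            n_perm=cfg.n_perm,
            p_cut=cfg.p_cut,
            n_boot=cfg.n_boot,
            consensus=cfg.consensus,
            seed=cfg.seed,
            bins=cfg.bins,
        )
        regulons = trn.apply_dpi(edges, tf_list, tolerance=cfg.dpi_tolerance)
        regulons.provenance.update(
            n_perm=cfg.n_perm, p_cut=cfg.p_cut, n_boot=cfg.n_boot,
            consensus=cfg.consensus, seed=cfg.seed,
        )
        reg_path = out / "regulons.tsv"
        regulons.to_frame().to_csv(reg_path, sep="\t", index=False)
        activity, _ = trn.regulon_activity(counts, regulons)
        norm_act = trn.normalize_activity(activity)
        act_path = out / "activity.tsv"
        norm_act.to_csv(act_path, sep="\t")
        record(stage, reg_path, act_path)

        stage = "rank"
        log.info("stage %s", stage)
        graph = centrality.build_graph(regulons)
        scores = centrality.betweenness(graph)
        ranking = centrality.rank_regulators(
            scores, regulons, activity=norm_act, annotation=annotation,
            top_n=min(cfg.top_n, len(regulons.regulons)), margin=cfg.margin,
            conditions=tuple(sim_cfg.conditions),
        )
        rank_path = out / "ranking.tsv"
        ranking.to_csv(rank_path, sep="\t")
        sif_path = centrality.export_sif(graph, out / "trn.sif")
        rank_json = out / "ranking.json"
        rank_json.write_text(json.dumps(ranking.reset_index().to_dict("records"), indent=1))
        record(stage, rank_path, sif_path, rank_json)

        stage = "targets"
        log.info("stage %s", stage)
        tss = make_tss_table(list(counts.index), seed=cfg.seed)
        peaks, key = simulate_chip_peaks(
            truth.chip_targets, tss, window_bp=cfg.window_bp,
            decoy_frac=cfg.decoy_frac, seed=cfg.seed,
        )
        bed_path = write_bed(peaks, out / "peaks.bed")
        tss_path = out / "tss.tsv"
        tss.to_csv(tss_path, sep="\t", index=False)
        bound = assign_peaks_to_tss(peaks, tss, window_bp=cfg.window_bp)
        venns = {}
        for tf, genes in bound.items():
            common, venn = intersect_targets(genes, up)
            venns[tf] = {**venn, "common": sorted(common)}
        venn_path = out / "venn.json"
        venn_path.write_text(json.dumps(venns, indent=1, sort_keys=True))
        record(stage, bed_path, tss_path, venn_path)

        stage = "morpho"
        log.info("stage %s", stage)
        rows = []
        sholl_groups = {}
        for arche in ("differentiated", "hyperbranched"):
            cells, truths = simulate_morphologies(
                cfg.n_cells, arche, seed=cfg.seed, outdir=out / "swc" / arche
            )
            profiles = []
            for t in truths:
                m = morpho.parse_swc(t["swc"])
                metrics = morpho.morpho_metrics(m)
                profiles.append(morpho.sholl_profile(m, cfg.step_um))
                cat, grouping = morpho.classify_cell(
                    m.soma_area, t["well_defined_fraction"]
                )
                rows.append(
                    {
                        "archetype": arche,
                        "swc": str(Path(t["swc"]).relative_to(out)),
                        "soma_area": m.soma_area,
                        "category": cat,
                        "grouping": grouping,
                        **{k: v for k, v in metrics.items() if k != "primary_lengths"},
                    }
                )
            sholl_groups[arche] = profiles
        d_stat, p_val = morpho.compare_sholl(
            sholl_groups["differentiated"], sholl_groups["hyperbranched"]
        )
        morpho_path = out / "morpho.tsv"
        pd.DataFrame(rows).to_csv(morpho_path, sep="\t", index=False)
        ks_path = out / "sholl_ks.json"
        ks_path.write_text(json.dumps({"D": d_stat, "p": p_val}, indent=1))
        record(stage, morpho_path, ks_path)

        stage = "qpcr"
        log.info("stage %s", stage)
        fc = {("GeneA", "treated"): 4.0, ("GeneB", "treated"): 0.25}
        ct = simulate_qpcr(
            ["GeneA", "GeneB"], ["control", "treated"], fc,
            reps=3, seed=cfg.seed, noise_sd=cfg.qpcr_noise_sd,
        )
        ct_path = out / "ct.tsv"
        ct.to_csv(ct_path, sep="\t", index=False)
        rel = qpcr.ddct(ct, ref_gene="Actb", ref_condition="control")
        rel_path = out / "qpcr.tsv"
        rel.to_csv(rel_path, sep="\t", index=False)
        record(stage, ct_path, rel_path)
    except Exception as exc:  # noqa: BLE001 - annotate failing stage, keep partials
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    for p in sorted(set(written)):
        manifest["checksums"][str(Path(p).relative_to(out))] = _sha256(Path(p))
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
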