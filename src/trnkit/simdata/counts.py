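"""Planted-regulon negative-binomial count simulator."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ..trn import Edge, RegulonSet
from .config import PATTERNS, SimConfig

__all__ = ["GroundTruth", "simulate_counts", "write_bundle"]

_POISSON_ALPHA = 1e-8  # below this, NB degenerates to Poisson


@dataclass
class GroundTruth:
    """Machine-readable record of everything the simulator planted."""

    regulons: RegulonSet
    activity_pattern: dict[str, str]
    de_genes: dict[str, dict[str, float]]  # contrast -> gene -> planted log2FC
    chip_targets: dict[str, set[str]]
    expected_means: pd.DataFrame | None = None  # gene x condition mean parameters
    morph_truth: list[dict] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "regulons": {
                tf: [[g, mi, mode] for (g, mi, mode) in targets]
                for tf, targets in self.regulons.regulons.items()
            },
            "activity_pattern": self.activity_pattern,
            "de_genes": self.de_genes,
            "chip_targets": {tf: sorted(s) for tf, s in self.chip_targets.items()},
            "morph_truth": self.morph_truth,
        }


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Draw NB counts with variance mu + alpha*mu^2 (Poisson when alpha ~ 0)."""
    out = np.empty(mu.shape, dtype=np.int64)
    tiny = alpha < _POISSON_ALPHA
    if tiny.any():
        out[tiny] = rng.poisson(mu[tiny])
    big = ~tiny
    if big.any():
        size = 1.0 / alpha[big]
        p = size / (size + mu[big])
        out[big] = rng.negative_binomial(size, p)
    return out


def simulate_counts(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate a gene x sample count matrix with planted regulons.

    Regulator mRNA equals its latent activity (no post-transcriptional layer):
    per sample, activity = pattern shift + N(0, activity_sd); the regulator's
    mean is baseline * 2**activity and each target's mean is
    baseline * 2**(mode * coupling * activity). Counts are NB(mu, alpha).

    Returns (counts, sample annotation, ground truth).
    """
    rng = np.random.default_rng(cfg.seed)

    tf_names = [f"TF{i:03d}" for i in range(1, cfg.n_tfs + 1)]
    target_names = {
        tf: [f"G{i:03d}_{j:03d}" for j in range(1, cfg.targets_per_tf + 1)]
        for i, tf in enumerate(tf_names, start=1)
    }
    nontarget_names = [f"N{j:04d}" for j in range(1, cfg.n_nontarget_genes + 1)]
    genes = (
        tf_names
        + [g for tf in tf_names for g in target_names[tf]]
        + nontarget_names
    )

    samples, conds = [], []
    for cond in cfg.conditions:
        for r in range(1, cfg.reps_per_condition + 1):
            samples.append(f"{cond}_r{r}")
            conds.append(cond)
    annotation = pd.DataFrame({"sample": samples, "condition": conds}).set_index("sample")

    # planted pattern and per-target modes
    pattern = {tf: cfg.pattern_cycle[i % len(cfg.pattern_cycle)] for i, tf in enumerate(tf_names)}
    modes: dict[str, dict[str, int]] = {}
    for tf in tf_names:
        n_t = cfg.targets_per_tf
        n_neg = int(round(cfg.mode_neg_fraction * n_t))
        mode_vec = np.array([1] * (n_t - n_neg) + [-1] * n_neg)
        rng.shuffle(mode_vec)
        modes[tf] = dict(zip(target_names[tf], mode_vec.tolist()))

    # optional target sharing across consecutive regulons
    shared_targets: dict[str, list[str]] = {tf: [] for tf in tf_names}
    if cfg.overlap_fraction > 0 and cfg.n_tfs > 1:
        k = int(round(cfg.overlap_fraction * cfg.targets_per_tf))
        for i, tf in enumerate(tf_names[:-1]):
            nxt = tf_names[i + 1]
            shared = target_names[tf][:k]
            shared_targets[nxt] = shared
            for g in shared:
                modes[nxt][g] = modes[tf][g]

    cond_index = {c: i for i, c in enumerate(cfg.conditions)}
    shift = {
        tf: np.array(PATTERNS[pattern[tf]]) * cfg.effect_log2fc for tf in tf_names
    }

    # latent activity: (tf, sample)
    A = np.empty((cfg.n_tfs, len(samples)))
    for i, tf in enumerate(tf_names):
        base = np.array([shift[tf][cond_index[c]] for c in conds])
        A[i] = base + rng.normal(0.0, cfg.activity_sd, size=len(samples))

    # mean matrix (gene x sample) and per-condition expected means
    mu = np.full((len(genes), len(samples)), cfg.baseline_mean)
    exp_means = np.full((len(genes), len(cfg.conditions)), cfg.baseline_mean)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for i, tf in enumerate(tf_names):
        mu[gene_pos[tf]] = cfg.baseline_mean * 2.0 ** A[i]
        exp_means[gene_pos[tf]] = cfg.baseline_mean * 2.0 ** shift[tf]
        for g in target_names[tf] + shared_targets[tf]:
            m = modes[tf][g]
            contrib = m * cfg.coupling * A[i]
            if cfg.target_noise_sd > 0:
                contrib = contrib + rng.normal(0.0, cfg.target_noise_sd, size=len(samples))
            mu[gene_pos[g]] = cfg.baseline_mean * 2.0 ** contrib
            exp_means[gene_pos[g]] = cfg.baseline_mean * 2.0 ** (m * cfg.coupling * shift[tf])

    alpha = cfg.dispersion * rng.lognormal(0.0, 0.25, size=len(genes))
    if cfg.dispersion < _POISSON_ALPHA:
        alpha = np.full(len(genes), 0.0)
    counts = _nb_sample(rng, mu, np.repeat(alpha[:, None], len(samples), axis=1))
    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=samples)

    # ground truth
    edges = [
        Edge(tf, g, cfg.coupling, modes[tf][g])
        for tf in tf_names
        for g in target_names[tf] + shared_targets[tf]
    ]
    regulons = RegulonSet.from_edges(edges, provenance={"planted": True, "seed": cfg.seed})

    ref = cfg.conditions[0]
    de_genes: dict[str, dict[str, float]] = {}
    for cond in cfg.conditions[1:]:
        contrast = f"{cond}_vs_{ref}"
        table: dict[str, float] = {}
        for i, tf in enumerate(tf_names):
            lfc = shift[tf][cond_index[cond]] - shift[tf][cond_index[ref]]
            if lfc != 0.0:
                table[tf] = float(lfc)
            for g in target_names[tf] + shared_targets[tf]:
                g_lfc = modes[tf][g] * cfg.coupling * lfc
                if g_lfc != 0.0:
                    table[g] = float(g_lfc)
        de_genes[contrast] = table

    truth = GroundTruth(
        regulons=regulons,
        activity_pattern=pattern,
        de_genes=de_genes,
        chip_targets={tf: set(target_names[tf]) for tf in tf_names},
        expected_means=pd.DataFrame(
            exp_means, index=pd.Index(genes, name="gene"), columns=list(cfg.conditions)
        ),
    )
    return counts_df, annotation, truth


def write_bundle(
    outdir: str | Path,
    counts: pd.DataFrame,
    annotation: pd.DataFrame,
    truth: GroundTruth,
) -> dict[str, Path]:
    """Write counts.tsv, samples.tsv and truth.json; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "samples": outdir / "samples.tsv",
        "truth": outdir / "truth.json",
    }
    counts.to_csv(paths["counts"], sep="\t")
    annotation.to_csv(paths["samples"], sep="\t")
    with open(paths["truth"], "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=1, sort_keys=True)
    return paths
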