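"""Synthetic ChIP peak intervals around gene TSSs, with an answer key."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["make_tss_table", "simulate_chip_peaks", "write_bed"]


def make_tss_table(genes: list[str], spacing: int = 10_000, chrom: str = "chr1",
                   seed: int = 0) -> pd.DataFrame:
    """Evenly spaced TSS table (gene, chrom, tss, strand), 0-based coordinates."""
    rng = np.random.default_rng(seed)
    strands = rng.choice(["+", "-"], size=len(genes))
    return pd.DataFrame(
        {
            "gene": genes,
            "chrom": chrom,
            "tss": [spacing * (i + 1) for i in range(len(genes))],
            "strand": strands,
        }
    )


def simulate_chip_peaks(
    chip_targets: dict[str, set[str]],
    tss_table: pd.DataFrame,
    window_bp: int = 1000,
    decoy_frac: float = 0.0,
    seed: int = 0,
    peak_halfwidth: int = 75,
) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """Place one peak near each intended target TSS plus decoys outside all windows.

    True peaks are centered within +/- window_bp of the target's TSS so they
    always overlap the closed promoter window; with ``window_bp == 0`` the
    peak midpoint coincides with the TSS. Decoys (``round(decoy_frac * n_true)``
    per regulator) are rejected-sampled strictly outside every gene's window.
    Intervals are BED-style 0-based half-open. Returns (peaks, answer key).
    """
    if not 0.0 <= decoy_frac <= 1.0:
        raise ValueError("decoy_frac must be in [0, 1]")
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    known = set(tss_table["gene"])
    missing = sorted(
        {g for targets in chip_targets.values() for g in targets} - known
    )
    if missing:
        raise ValueError(f"genes absent from tss_table: {missing}")

    rng = np.random.default_rng(seed)
    tss_by_gene = tss_table.set_index("gene")
    all_tss = tss_table["tss"].to_numpy()
    hi = int(all_tss.max()) + 10 * (window_bp + peak_halfwidth) + 100_000
    chrom = tss_table["chrom"].iloc[0]

    rows = []
    key: dict[str, set[str]] = {}
    for tf in sorted(chip_targets):
        targets = sorted(chip_targets[tf])
        key[tf] = set(targets)
        for g in targets:
            tss = int(tss_by_gene.loc[g, "tss"])
            off = int(rng.integers(-window_bp, window_bp + 1)) if window_bp else 0
            center = tss + off
            start = max(0, center - peak_halfwidth)
            end = center + peak_halfwidth  # midpoint = center (= TSS when window_bp == 0)
            rows.append((str(tss_by_gene.loc[g, "chrom"]), start, end, tf))
        n_decoys = int(round(decoy_frac * len(targets)))
        placed = 0
        while placed < n_decoys:
            pos = int(rng.integers(0, hi))
            # decoy peak [pos-hw, pos+hw+1) must miss every closed window
            if np.any(np.abs(all_tss - pos) <= window_bp + peak_halfwidth + 1):
                continue
            rows.append((chrom, max(0, pos - peak_halfwidth), pos + peak_halfwidth, tf))
            placed += 1
    peaks = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    return peaks, key


def write_bed(peaks: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    peaks.to_csv(path, sep="\t", header=False, index=False)
    return path
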