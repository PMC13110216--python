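"""Promoter peak assignment, DEG intersection, and hypergeometric enrichment."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "read_bed",
    "read_tss_table",
    "assign_peaks_to_tss",
    "intersect_targets",
    "combine_tf_targets",
    "hypergeometric_enrichment",
]


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a 4-column BED (chrom, start, end, name), 0-based half-open.

    Raises ValueError with the offending line number on malformed input.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected >=4 BED columns")
            chrom, start, end, name = parts[0], parts[1], parts[2], parts[3]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            if start_i < 0 or end_i <= start_i:
                raise ValueError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            rows.append((chrom, start_i, end_i, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def read_tss_table(path: str | Path) -> pd.DataFrame:
    tss = pd.read_csv(path, sep="\t")
    required = {"gene", "chrom", "tss", "strand"}
    missing = required - set(tss.columns)
    if missing:
        raise ValueError(f"tss table missing columns: {sorted(missing)}")
    return tss


def assign_peaks_to_tss(
    peaks: pd.DataFrame, tss: pd.DataFrame, window_bp: int = 1000
) -> dict[str, set[str]]:
    """Per-regulator set of genes with a peak in the closed +/-window around the TSS.

    Peaks are 0-based half-open [start, end); the promoter window
    [tss - window_bp, tss + window_bp] is closed and strand-independent
    (the TSS coordinate itself is assumed strand-aware). A gene is bound by a
    regulator iff any of that regulator's peaks overlaps its window.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    tss_genes = tss["gene"].to_numpy()
    tss_chrom = tss["chrom"].to_numpy()
    tss_pos = tss["tss"].to_numpy(dtype=np.int64)

    bound: dict[str, set[str]] = {}
    for tf, group in peaks.groupby("name"):
        hits: set[str] = set()
        for chrom, start, end in zip(group["chrom"], group["start"], group["end"]):
            on_chrom = tss_chrom == chrom
            # overlap of [start, end) with closed [tss-w, tss+w]
            lo = tss_pos - window_bp
            hi = tss_pos + window_bp
            mask = on_chrom & (start <= hi) & (end - 1 >= lo)
            hits.update(tss_genes[mask])
        bound[str(tf)] = hits
    return bound


def intersect_targets(
    bound: set[str], degs: set[str]
) -> tuple[set[str], dict[str, int]]:
    """Exact intersection plus Venn counts {A, B, AB}."""
    common = set(bound) & set(degs)
    venn = {"A": len(bound), "B": len(degs), "AB": len(common)}
    return common, venn


def combine_tf_targets(
    sets: list[set[str]], mode: str = "union"
) -> tuple[set[str], dict[str, list[int]]]:
    """Union or intersection of gene sets, with per-gene source provenance."""
    if not sets:
        raise ValueError("need at least one set")
    if mode not in ("union", "intersection"):
        raise ValueError(f"mode must be union/intersection, got {mode!r}")
    provenance: dict[str, list[int]] = {}
    for i, s in enumerate(sets):
        for g in s:
            provenance.setdefault(g, []).append(i)
    if mode == "union":
        result = set(provenance)
    else:
        result = {g for g, src in provenance.items() if len(src) == len(sets)}
    return result, {g: provenance[g] for g in result}


def hypergeometric_enrichment(
    query: set[str],
    annotation: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric test of `query` against each annotation term.

    Terms are intersected with the universe; p = P(overlap >= k) for a draw of
    n = |query| from N = |universe| containing K term genes. BH across tested
    terms. Rows sorted by (padj, -gene_ratio).
    """
    if not universe:
        raise ValueError("empty universe")
    if not set(query) <= set(universe):
        raise ValueError("query must be a subset of the universe")
    n = len(query)
    N = len(universe)
    rows = []
    for term, genes in annotation.items():
        term_genes = set(genes) & universe
        K = len(term_genes)
        if K == 0:
            continue
        k = len(term_genes & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, n, N, min(p, 1.0), k / K))
    table = pd.DataFrame(
        rows, columns=["term", "k", "K", "n", "N", "p", "gene_ratio"]
    )
    if not table.empty:
        table["padj"] = multipletests(table["p"], method="fdr_bh")[1]
        table = table.sort_values(
            ["padj", "gene_ratio"], ascending=[True, False]
        ).reset_index(drop=True)
    else:
        table["padj"] = []
    return table
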