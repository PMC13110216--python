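"""Betweenness-centrality ranking of regulators and activity-pattern classes."""

from __future__ import annotations

import math
import warnings
from pathlib import Path

import networkx as nx
import pandas as pd

from .trn import RegulonSet

__all__ = [
    "build_graph",
    "betweenness",
    "classify_activity_pattern",
    "rank_regulators",
    "compare_regulator_sets",
    "export_sif",
    "export_gml",
    "PATTERN_CLASSES",
]

PATTERN_CLASSES = ("orange", "magenta", "red", "blue", "turquoise")


def build_graph(regulons: RegulonSet) -> nx.Graph:
    """Simple undirected graph with one edge per retained regulator-target pair."""
    if not regulons.regulons:
        raise ValueError("empty RegulonSet")
    g = nx.Graph()
    for tf in regulons.regulons:
        g.add_node(tf, kind="regulator")
    for e in regulons.edges():
        if e.target not in g:
            g.add_node(e.target, kind="target")
        g.add_edge(e.regulator, e.target, mi=e.mi, mode=e.mode)
    return g


def betweenness(graph: nx.Graph) -> dict[str, float]:
    """Unnormalized betweenness over unordered node pairs (Brandes)."""
    return nx.betweenness_centrality(graph, normalized=False)


def classify_activity_pattern(
    a_astro: float, a_mir124: float, a_isx9: float, margin: float = 0.0
) -> str:
    """Classify a regulator's condition-activity ordering into one of five classes.

    `a_astro` is the mean of the two astrocyte-condition activities. Classes:
    orange (isx9 > mir124 > astro), magenta (mir124 > isx9 > astro),
    red (isx9 up while mir124 stays within `margin` of astro),
    blue (astro > mir124 > isx9), turquoise (astro > isx9 > mir124),
    else "unclassified".
    """
    vals = (a_astro, a_mir124, a_isx9)
    if not all(math.isfinite(v) for v in vals):
        raise ValueError(f"non-finite activity values: {vals}")
    if margin < 0:
        raise ValueError("margin must be >= 0")
    # red is the only margin-sensitive rule, so it is evaluated first;
    # with margin = 0 the outcome is identical to checking orange first
    if a_isx9 > a_astro + margin and a_mir124 <= a_astro + margin:
        return "red"
    if a_isx9 > a_mir124 > a_astro:
        return "orange"
    if a_mir124 > a_isx9 > a_astro:
        return "magenta"
    if a_astro > a_mir124 > a_isx9:
        return "blue"
    if a_astro > a_isx9 > a_mir124:
        return "turquoise"
    return "unclassified"


def _condition_activity_means(
    activity: pd.DataFrame, annotation: pd.DataFrame
) -> pd.DataFrame:
    cond = annotation["condition"]
    return activity.T.groupby(cond).mean().T


def rank_regulators(
    scores: dict[str, float],
    regulons: RegulonSet,
    activity: pd.DataFrame | None = None,
    annotation: pd.DataFrame | None = None,
    top_n: int | None = None,
    margin: float = 0.0,
    conditions: tuple[str, str, str, str] = (
        "astro_d1",
        "astro_d7",
        "mir124_d7",
        "mir124_isx9_d7",
    ),
) -> pd.DataFrame:
    """Rank regulators by descending betweenness; ties break lexicographically.

    Targets are excluded. When a normalized `activity` matrix and a sample
    `annotation` are supplied, the per-regulator activity class is attached.
    """
    regs = sorted(regulons.regulons)
    missing = [tf for tf in regs if tf not in scores]
    if missing:
        raise ValueError(f"scores missing for regulators: {missing}")
    ordered = sorted(regs, key=lambda tf: (-scores[tf], tf))
    if top_n is not None:
        if top_n > len(ordered):
            warnings.warn(
                f"top_n={top_n} exceeds regulator count {len(ordered)}; returning all",
                stacklevel=2,
            )
        ordered = ordered[: max(top_n, 0)]

    classes = {}
    if activity is not None and annotation is not None:
        cmeans = _condition_activity_means(activity, annotation)
        astro1, astro7, mir, isx = conditions
        for tf in ordered:
            if tf in cmeans.index:
                row = cmeans.loc[tf]
                a_astro = float((row[astro1] + row[astro7]) / 2.0)
                classes[tf] = classify_activity_pattern(
                    a_astro, float(row[mir]), float(row[isx]), margin=margin
                )

    sizes = regulons.sizes()
    return pd.DataFrame(
        {
            "regulator": ordered,
            "score": [scores[tf] for tf in ordered],
            "rank": list(range(1, len(ordered) + 1)),
            "class": [classes.get(tf, "unclassified") for tf in ordered],
            "regulon_size": [sizes.get(tf, 0) for tf in ordered],
        }
    ).set_index("regulator")


def compare_regulator_sets(
    set_a: set[str], set_b: set[str]
) -> tuple[set[str], set[str], set[str]]:
    """Exact partition into (common, unique to a, unique to b)."""
    a, b = set(set_a), set(set_b)
    return a & b, a - b, b - a


def export_sif(graph: nx.Graph, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for u, v, data in sorted(graph.edges(data=True)):
            rel = "activates" if data.get("mode", 1) > 0 else "represses"
            fh.write(f"{u}\t{rel}\t{v}\n")
    return path


def export_gml(graph: nx.Graph, path: str | Path) -> Path:
    path = Path(path)
    nx.write_gml(graph, path)
    return path
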