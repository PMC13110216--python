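"""Neurite morphometry from SWC reconstructions.

Parses SWC trees, computes Sholl intersection profiles at fixed radial
increments from the soma, extracts branch-point and primary-neurite metrics,
classifies cells into the four soma-area categories, and provides the
two-sample statistics used to compare groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

__all__ = [
    "Morphology",
    "ShollProfile",
    "parse_swc",
    "sholl_profile",
    "morpho_metrics",
    "classify_cell",
    "compare_sholl",
    "welch_t",
    "CATEGORY_BINS",
]

#: soma-area category bins (a.u.): [85,200) -> 1, [200,500) -> 2,
#: [500,1000) -> 3, [1000,1600] -> 4 (excluded/failed-to-reprogram)
CATEGORY_BINS = ((85.0, 200.0), (200.0, 500.0), (500.0, 1000.0), (1000.0, 1600.0))


@dataclass
class Morphology:
    """Validated single-root SWC tree."""

    ids: np.ndarray
    types: np.ndarray
    xyz: np.ndarray  # (n, 3) um
    radii: np.ndarray
    parents: np.ndarray  # parent id per point, -1 at root
    children: dict[int, list[int]] = field(repr=False, default_factory=dict)
    root: int = 1

    @property
    def n_points(self) -> int:
        return len(self.ids)

    def index_of(self, point_id: int) -> int:
        return int(np.searchsorted(self.ids, point_id))

    @property
    def soma_center(self) -> np.ndarray:
        """Centroid of type-1 points."""
        soma = self.types == 1
        if not soma.any():
            return self.xyz[self.index_of(self.root)]
        return self.xyz[soma].mean(axis=0)

    @property
    def soma_area(self) -> float:
        """Area implied by the root radius (pi * r^2), on the input's scale."""
        return float(math.pi * self.radii[self.index_of(self.root)] ** 2)


@dataclass
class ShollProfile:
    radii: np.ndarray
    intersections: np.ndarray

    def as_samples(self) -> np.ndarray:
        """Radii repeated by intersection count (pooled-distribution form)."""
        return np.repeat(self.radii, self.intersections)


def parse_swc(path: str | Path) -> Morphology:
    """Parse and validate an SWC file (single root, no cycles, no dangling parents)."""
    path = Path(path)
    recs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise ValueError(f"{path}:{lineno}: expected 7 SWC fields")
            try:
                recs.append(
                    (
                        int(parts[0]),
                        int(parts[1]),
                        float(parts[2]),
                        float(parts[3]),
                        float(parts[4]),
                        float(parts[5]),
                        int(parts[6]),
                        lineno,
                    )
                )
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed SWC record") from None
    if not recs:
        raise ValueError(f"{path}: empty SWC file")

    recs.sort(key=lambda r: r[0])
    ids = np.array([r[0] for r in recs])
    if len(np.unique(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate point ids")
    id_set = set(ids.tolist())
    line_of = {r[0]: r[7] for r in recs}

    roots = [r[0] for r in recs if r[6] == -1]
    if len(roots) != 1:
        raise ValueError(f"{path}: expected exactly one root (parent -1), found {len(roots)}")
    for r in recs:
        if r[6] != -1 and r[6] not in id_set:
            raise ValueError(f"{path}:{line_of[r[0]]}: dangling parent id {r[6]}")

    parent_of = {r[0]: r[6] for r in recs}
    # cycle check by walking each node to the root with a visited budget
    resolved: set[int] = set()
    for start in ids.tolist():
        seen = []
        node = start
        while node != -1 and node not in resolved:
            if node in seen:
                raise ValueError(f"{path}:{line_of[node]}: parent cycle at id {node}")
            seen.append(node)
            node = parent_of[node]
        resolved.update(seen)

    children: dict[int, list[int]] = {int(i): [] for i in ids}
    for r in recs:
        if r[6] != -1:
            children[r[6]].append(r[0])

    return Morphology(
        ids=ids,
        types=np.array([r[1] for r in recs]),
        xyz=np.array([[r[2], r[3], r[4]] for r in recs]),
        radii=np.array([r[5] for r in recs]),
        parents=np.array([r[6] for r in recs]),
        children=children,
        root=roots[0],
    )


def write_swc(m: Morphology, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for i in range(m.n_points):
            x, y, z = m.xyz[i]
            fh.write(
                f"{m.ids[i]} {m.types[i]} {x:.4f} {y:.4f} {z:.4f} "
                f"{m.radii[i]:.4f} {m.parents[i]}\n"
            )
    return path


def sholl_profile(m: Morphology, step_um: float = 1.0) -> ShollProfile:
    """Intersection counts with concentric spheres at radii step, 2*step, ...

    A tree segment whose endpoint distances from the soma centroid straddle a
    radius strictly (d_min < r < d_max) counts one intersection; tangency
    counts zero. Single-point morphologies yield an all-zero profile.
    """
    if step_um <= 0:
        raise ValueError("step_um must be > 0")
    center = m.soma_center
    d = np.linalg.norm(m.xyz - center, axis=1)
    pos = {int(i): k for k, i in enumerate(m.ids)}

    seg_lo, seg_hi = [], []
    for k, parent in enumerate(m.parents):
        if parent == -1:
            continue
        d1, d2 = d[pos[int(parent)]], d[k]
        seg_lo.append(min(d1, d2))
        seg_hi.append(max(d1, d2))

    max_extent = float(d.max())
    n_shells = int(math.floor(max_extent / step_um)) + 1
    radii = step_um * np.arange(1, max(n_shells, 1) + 1)
    if not seg_lo:
        return ShollProfile(radii=radii, intersections=np.zeros(len(radii), dtype=int))
    lo = np.array(seg_lo)
    hi = np.array(seg_hi)
    counts = np.array([(np.count_nonzero((lo < r) & (r < hi))) for r in radii])
    return ShollProfile(radii=radii, intersections=counts)


def morpho_metrics(m: Morphology) -> dict:
    """Branch points, primary-neurite count and per-neurite maximal path lengths.

    A primary neurite is the subtree rooted at a child of the soma; its length
    is the maximal soma-to-tip path length. A branch point is a non-soma node
    with >= 2 children.
    """
    pos = {int(i): k for k, i in enumerate(m.ids)}
    soma_ids = set(m.ids[m.types == 1].tolist())

    branch_points = sum(
        1
        for nid, ch in m.children.items()
        if nid not in soma_ids and len(ch) >= 2
    )

    def seg_length(parent_id: int, child_id: int) -> float:
        return float(
            np.linalg.norm(m.xyz[pos[child_id]] - m.xyz[pos[parent_id]])
        )

    primary_roots = [c for c in m.children.get(m.root, []) if c not in soma_ids]
    lengths = []
    for root_child in primary_roots:
        best = 0.0
        stack = [(root_child, seg_length(m.root, root_child))]
        while stack:
            nid, acc = stack.pop()
            best = max(best, acc)
            for c in m.children[nid]:
                stack.append((c, acc + seg_length(nid, c)))
        lengths.append(best)

    return {
        "branch_points": branch_points,
        "primary_neurite_count": len(primary_roots),
        "primary_lengths": lengths,
        "max_length": max(lengths) if lengths else 0.0,
        "avg_length": float(np.mean(lengths)) if lengths else 0.0,
    }


def classify_cell(
    soma_area: float,
    well_defined_fraction: float,
    cat2_min_fraction: float = 0.5,
) -> tuple[int | str, str]:
    """Map (soma area, well-defined-neurite fraction) to the four categories.

    Bins are left-closed/right-open except the last, closed at 1600 a.u.
    Returns (category, grouping) where grouping is one of
    differentiated / transitory / excluded / out-of-range.
    """
    if soma_area <= 0:
        raise ValueError("soma_area must be > 0")
    if not 0.0 <= well_defined_fraction <= 1.0:
        raise ValueError("well_defined_fraction must be in [0, 1]")
    if soma_area < CATEGORY_BINS[0][0] or soma_area > CATEGORY_BINS[3][1]:
        return "out-of-range", "out-of-range"
    if soma_area < CATEGORY_BINS[0][1]:
        cat = 1 if well_defined_fraction >= 1.0 else 2
    elif soma_area < CATEGORY_BINS[1][1]:
        cat = 2
    elif soma_area < CATEGORY_BINS[2][1]:
        cat = 3
    else:
        cat = 4
    grouping = {1: "differentiated", 2: "differentiated", 3: "transitory", 4: "excluded"}
    return cat, grouping[cat]


def compare_sholl(
    profiles_a: list[ShollProfile], profiles_b: list[ShollProfile]
) -> tuple[float, float]:
    """Two-sample KS test on pooled intersection-weighted radius distributions."""
    if not profiles_a or not profiles_b:
        raise ValueError("both groups need at least one profile")
    a = np.concatenate([p.as_samples() for p in profiles_a])
    b = np.concatenate([p.as_samples() for p in profiles_b])
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty pooled distribution")
    res = stats.ks_2samp(a, b, method="auto")
    return float(res.statistic), float(res.pvalue)


def welch_t(group_a, group_b) -> tuple[float, float, float]:
    """Welch two-sample t statistic, Satterthwaite df and two-sided p."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        return math.inf, float(len(a) + len(b) - 2), 0.0
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)
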