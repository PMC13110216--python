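"""Synthetic neurite morphologies (SWC trees) with exact geometric ground truth.

Archetypes mirror the four reprogramming soma-area categories: small-soma
well-differentiated cells, larger transitory cells, very-large astrocyte-like
cells with few processes, and a hyper-branched multipolar variant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["ARCHETYPES", "SWCPoint", "simulate_morphologies", "write_swc"]


@dataclass(frozen=True)
class SWCPoint:
    id: int
    type: int
    x: float
    y: float
    z: float
    radius: float
    parent: int


#: archetype -> (soma-area range, primary-neurite count range, nodes per
#: neurite range, step-length range (um), per-node branch probability,
#: well-defined fraction)
ARCHETYPES: dict[str, dict] = {
    "differentiated": {
        "soma_area": (85.0, 500.0),
        "n_primary": (2, 4),
        "n_nodes": (20, 40),
        "step": (3.0, 5.0),
        "branch_p": 0.04,
        "well_defined": 1.0,
    },
    "transitory": {
        "soma_area": (500.0, 1000.0),
        "n_primary": (4, 7),
        "n_nodes": (8, 18),
        "step": (2.0, 4.0),
        "branch_p": 0.10,
        "well_defined": 0.4,
    },
    "astrocyte_like": {
        "soma_area": (1000.0, 1600.0),
        "n_primary": (1, 2),
        "n_nodes": (3, 6),
        "step": (1.5, 3.0),
        "branch_p": 0.0,
        "well_defined": 0.0,
    },
    "hyperbranched": {
        "soma_area": (200.0, 500.0),
        "n_primary": (5, 8),
        "n_nodes": (10, 25),
        "step": (2.0, 4.0),
        "branch_p": 0.30,
        "well_defined": 0.6,
    },
}


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _random_direction(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return _unit(v)


def _jitter(rng: np.random.Generator, d: np.ndarray, sd: float) -> np.ndarray:
    return _unit(d + rng.normal(0.0, sd, size=3))


def _grow_cell(rng: np.random.Generator, spec: dict) -> tuple[list[SWCPoint], dict]:
    soma_area = float(rng.uniform(*spec["soma_area"]))
    soma_radius = math.sqrt(soma_area / math.pi)
    points = [SWCPoint(1, 1, 0.0, 0.0, 0.0, soma_radius, -1)]
    next_id = 2
    n_primary = int(rng.integers(spec["n_primary"][0], spec["n_primary"][1] + 1))

    children: dict[int, list[int]] = {1: []}
    parent_of: dict[int, int] = {}
    seg_len: dict[int, float] = {}  # edge length (parent -> node)
    primary_roots: list[int] = []

    for _ in range(n_primary):
        direction = _random_direction(rng)
        pos = np.zeros(3)
        # active tips: (node id, position, direction, nodes left to grow)
        budget = int(rng.integers(spec["n_nodes"][0], spec["n_nodes"][1] + 1))
        tips = [(1, pos, direction, budget)]
        first = True
        while tips:
            pid, ppos, pdir, left = tips.pop()
            if left <= 0:
                continue
            step = float(rng.uniform(*spec["step"]))
            d = _jitter(rng, pdir, 0.08)
            npos = ppos + step * d
            nid = next_id
            next_id += 1
            points.append(SWCPoint(nid, 3, *npos.tolist(), 0.5, pid))
            children.setdefault(nid, [])
            children[pid].append(nid)
            parent_of[nid] = pid
            seg_len[nid] = step
            if first:
                primary_roots.append(nid)
                first = False
            tips.append((nid, npos, d, left - 1))
            if left > 2 and rng.random() < spec["branch_p"]:
                tips.append((nid, npos, _jitter(rng, d, 0.6), left - 1))

    # ground truth from the emitted tree structure
    branch_points = sum(
        1 for nid, ch in children.items() if nid != 1 and len(ch) >= 2
    )

    def subtree_depth(root: int) -> float:
        best = 0.0
        stack = [(root, seg_len[root])]
        while stack:
            nid, acc = stack.pop()
            best = max(best, acc)
            for c in children[nid]:
                stack.append((c, acc + seg_len[c]))
        return best

    primary_lengths = [subtree_depth(r) for r in primary_roots]
    truth = {
        "soma_area": soma_area,
        "branch_points": branch_points,
        "primary_neurite_count": n_primary,
        "primary_lengths": primary_lengths,
        "well_defined_fraction": spec["well_defined"],
    }
    return points, truth


def write_swc(points: list[SWCPoint], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for p in points:
            fh.write(
                f"{p.id} {p.type} {p.x:.4f} {p.y:.4f} {p.z:.4f} {p.radius:.4f} {p.parent}\n"
            )
    return path


def simulate_morphologies(
    n_cells: int,
    archetype: str,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> tuple[list[list[SWCPoint]], list[dict]]:
    """Generate `n_cells` SWC trees of the given archetype plus exact truth.

    Each morphology is a single-root connected tree; truth records soma area,
    branch-point count, primary-neurite count and lengths, and the archetype's
    well-defined-neurite fraction. With `outdir`, files cell_000.swc... are
    written and their paths recorded in the truth entries.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if archetype not in ARCHETYPES:
        raise ValueError(
            f"unknown archetype {archetype!r}; expected one of {sorted(ARCHETYPES)}"
        )
    rng = np.random.default_rng(seed)
    spec = ARCHETYPES[archetype]
    cells, truths = [], []
    for i in range(n_cells):
        points, truth = _grow_cell(rng, spec)
        truth["archetype"] = archetype
        if outdir is not None:
            path = Path(outdir) / f"cell_{i:03d}.swc"
            Path(outdir).mkdir(parents=True, exist_ok=True)
            write_swc(points, path)
            truth["swc"] = str(path)
        cells.append(points)
        truths.append(truth)
    return cells, truths
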