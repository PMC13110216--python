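"""Mutual-information regulatory-network inference and regulon activity scoring.

The inference chain is: per-regulator MI against all candidate targets,
permutation filtering of non-significant associations, bootstrap filtering of
unstable associations, and triplet-wise pruning of likely-indirect edges
(data-processing-inequality rule). Surviving edges form a :class:`RegulonSet`,
which can be scored per sample with a two-tailed running-sum enrichment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Edge",
    "RegulonSet",
    "mutual_information",
    "infer_candidate_edges",
    "apply_dpi",
    "regulon_activity",
    "normalize_activity",
]


@dataclass(frozen=True)
class Edge:
    """A regulator-target association with its MI and mode of regulation."""

    regulator: str
    target: str
    mi: float
    mode: int = 1  # +1 activation, -1 repression

    def key(self) -> frozenset:
        return frozenset((self.regulator, self.target))


@dataclass
class RegulonSet:
    """Mapping regulator -> list of (target, mi, mode) plus inference provenance.

    Invariants: no self-edges, MI >= 0, mode in {+1, -1}.
    """

    regulons: dict[str, list[tuple[str, float, int]]]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tf, targets in self.regulons.items():
            for (g, mi, mode) in targets:
                if g == tf:
                    raise ValueError(f"self-edge on regulator {tf!r}")
                if mi < 0:
                    raise ValueError(f"negative MI on edge {tf!r}->{g!r}")
                if mode not in (1, -1):
                    raise ValueError(f"mode must be +1/-1, got {mode!r}")

    @property
    def regulators(self) -> list[str]:
        return list(self.regulons)

    def targets_of(self, tf: str) -> set[str]:
        return {g for (g, _, _) in self.regulons.get(tf, [])}

    def edges(self) -> list[Edge]:
        return [
            Edge(tf, g, mi, mode)
            for tf, targets in self.regulons.items()
            for (g, mi, mode) in targets
        ]

    def sizes(self) -> dict[str, int]:
        return {tf: len(t) for tf, t in self.regulons.items()}

    def n_edges(self) -> int:
        return sum(len(t) for t in self.regulons.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (tf, g, mi, mode)
            for tf, targets in self.regulons.items()
            for (g, mi, mode) in targets
        ]
        return pd.DataFrame(rows, columns=["regulator", "target", "mi", "mode"])

    @classmethod
    def from_edges(cls, edges: list[Edge], provenance: dict | None = None) -> "RegulonSet":
        regs: dict[str, list[tuple[str, float, int]]] = {}
        for e in edges:
            regs.setdefault(e.regulator, []).append((e.target, e.mi, e.mode))
        return cls(regulons=regs, provenance=provenance or {})


# ---------------------------------------------------------------------------
# Mutual information
# ---------------------------------------------------------------------------

def _equal_frequency_bins(x: np.ndarray, bins: int) -> np.ndarray:
    """Rank-based equal-frequency discretization into `bins` labels 0..bins-1.

    Stable argsort keeps the map invariant under strictly monotone transforms.
    """
    n = len(x)
    order = np.argsort(x, kind="mergesort")
    labels = np.empty(n, dtype=np.int64)
    labels[order] = (np.arange(n) * bins) // n
    return labels


def _default_bins(n: int) -> int:
    return max(2, math.ceil(math.sqrt(n)))


def _mi_from_joint(joint: np.ndarray) -> float:
    """Plug-in MI in bits from a joint count table."""
    n = joint.sum()
    if n == 0:
        return 0.0
    p = joint / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (px * py))
    return float(np.nansum(terms))


def mutual_information(x, y, bins: int | None = None) -> float:
    """Plug-in mutual information (bits) after rank equal-frequency binning.

    Symmetric in its arguments and invariant to strictly monotone transforms
    of either input. A constant vector yields MI = 0 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 8:
        raise ValueError(f"need at least 8 observations, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant input vector: MI set to 0", stacklevel=2)
        return 0.0
    b = bins if bins is not None else _default_bins(n)
    dx = _equal_frequency_bins(x, b)
    dy = _equal_frequency_bins(y, b)
    if dx.tobytes() > dy.tobytes():
        dx, dy = dy, dx  # canonical orientation -> bit-exact symmetry
    joint = np.bincount(dx * b + dy, minlength=b * b).reshape(b, b).astype(float)
    return _mi_from_joint(joint)


def _mi_profile(t: np.ndarray, D: np.ndarray, bins: int) -> np.ndarray:
    """MI (bits) between one discretized vector and every row of a discretized matrix.

    Vectorized over rows: for each regulator bin b, count target-bin occupancy
    among the samples falling in b.
    """
    n_genes, n = D.shape
    joint = np.zeros((n_genes, bins, bins))
    for b in range(bins):
        cols = D[:, t == b]  # (n_genes, n_b)
        for v in range(bins):
            joint[:, b, v] = (cols == v).sum(axis=1)
    p = joint / n
    px = p.sum(axis=2, keepdims=True)
    py = p.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (px * py))
    return np.nansum(terms, axis=(1, 2))


# ---------------------------------------------------------------------------
# Candidate-edge inference: permutation + bootstrap
# ---------------------------------------------------------------------------

def infer_candidate_edges(
    counts: pd.DataFrame,
    tf_list: list[str],
    n_perm: int = 1000,
    p_cut: float = 0.01,
    n_boot: int = 0,
    consensus: float = 0.75,
    seed: int = 0,
    bins: int | None = None,
    bh: bool = False,
) -> list[Edge]:
    """Infer significant, stable regulator->gene edges from an expression matrix.

    Per regulator, a permutation null is built by shuffling the sample labels
    of the regulator vector; an edge is kept when its add-one empirical p-value
    (r+1)/(n_perm+1) is below `p_cut` (optionally BH-adjusted). With
    ``n_boot > 0``, a kept edge is retained only if it is re-inferred (MI above
    the regulator's permutation-null `p_cut`-quantile) in at least
    ``consensus * n_boot`` sample bootstraps. ``n_boot = 0`` is the
    permutation-only output. Mode of regulation is the sign of the Spearman
    correlation (ties assigned +1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if p_cut <= 1.0 / (n_perm + 1):
        raise ValueError(
            f"p_cut={p_cut} is below the permutation resolution 1/(n_perm+1); "
            f"increase n_perm"
        )
    missing = [tf for tf in tf_list if tf not in counts.index]
    if missing:
        raise ValueError(f"regulators absent from matrix: {missing}")

    rng = np.random.default_rng(seed)
    genes = counts.index.to_numpy()
    X = counts.to_numpy(dtype=float)
    n = X.shape[1]
    b = bins if bins is not None else _default_bins(n)
    D = np.vstack([_equal_frequency_bins(row, b) for row in X])
    gene_pos = {g: i for i, g in enumerate(genes)}

    edges: list[Edge] = []
    for tf in tf_list:
        ti = gene_pos[tf]
        t = D[ti]
        mask = np.ones(len(genes), dtype=bool)
        mask[ti] = False
        cand_idx = np.flatnonzero(mask)
        Dc = D[cand_idx]
        obs = _mi_profile(t, Dc, b)

        null = np.empty((n_perm, len(cand_idx)))
        tp = t.copy()
        for p in range(n_perm):
            rng.shuffle(tp)
            null[p] = _mi_profile(tp, Dc, b)
        r = (null >= obs[None, :]).sum(axis=0)
        pvals = (r + 1) / (n_perm + 1)
        if bh:
            keep = multipletests(pvals, alpha=p_cut, method="fdr_bh")[0]
        else:
            keep = pvals < p_cut

        if n_boot > 0 and keep.any():
            # MI threshold at the null's upper p_cut quantile (pooled over
            # genes and permutations) -- recovery criterion per bootstrap.
            thresh = float(np.quantile(null.ravel(), 1.0 - p_cut))
            hits = np.zeros(len(cand_idx), dtype=int)
            for _ in range(n_boot):
                cols = rng.integers(0, n, size=n)
                Xb = X[:, cols]
                Db_tf = _equal_frequency_bins(Xb[ti], b)
                Db = np.vstack([_equal_frequency_bins(Xb[j], b) for j in cand_idx])
                hits += _mi_profile(Db_tf, Db, b) > thresh
            keep &= hits >= consensus * n_boot

        for j in np.flatnonzero(keep):
            g = genes[cand_idx[j]]
            rho = spearmanr(X[ti], X[cand_idx[j]]).statistic
            mode = 1 if (not np.isfinite(rho) or rho >= 0) else -1
            edges.append(Edge(tf, str(g), float(obs[j]), mode))
    return edges


# ---------------------------------------------------------------------------
# DPI pruning
# ---------------------------------------------------------------------------

def apply_dpi(edges: list[Edge], tf_list: list[str], tolerance: float = 0.0) -> RegulonSet:
    """Prune likely-indirect edges with the data-processing-inequality rule.

    For every triplet (TF1-TF2, TF1-g, TF2-g all present in the input), the
    minimum-MI edge is removed when its MI < (1 - tolerance) x the second
    smallest MI of the triplet. All removals are evaluated against the
    pre-pruning network, so the result is order-independent.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    tf_set = set(tf_list)
    mi_of: dict[frozenset, float] = {}
    for e in edges:
        mi_of[e.key()] = e.mi  # symmetric duplicates carry the same MI

    neighbors: dict[str, set[str]] = {}
    for e in edges:
        neighbors.setdefault(e.regulator, set()).add(e.target)
        neighbors.setdefault(e.target, set()).add(e.regulator)

    to_remove: set[frozenset] = set()
    tfs = sorted(tf_set & set(neighbors))
    for i, tf1 in enumerate(tfs):
        for tf2 in tfs[i + 1:]:
            k12 = frozenset((tf1, tf2))
            if k12 not in mi_of:
                continue
            common = (neighbors[tf1] & neighbors[tf2]) - {tf1, tf2}
            for g in common:
                k1g = frozenset((tf1, g))
                k2g = frozenset((tf2, g))
                trip = sorted([k12, k1g, k2g], key=lambda k: mi_of[k])
                if mi_of[trip[0]] < (1.0 - tolerance) * mi_of[trip[1]]:
                    to_remove.add(trip[0])

    kept = [e for e in edges if e.key() not in to_remove]
    prov = {"dpi_tolerance": tolerance, "n_removed": len(edges) - len(kept)}
    return RegulonSet.from_edges(kept, provenance=prov)


# ---------------------------------------------------------------------------
# Regulon activity
# ---------------------------------------------------------------------------

def expression_signature(counts: pd.DataFrame, size_factors: np.ndarray | None = None) -> pd.DataFrame:
    """Per-gene cross-sample z-score of log2(normalized count + 1)."""
    X = counts.to_numpy(dtype=float)
    if size_factors is not None:
        X = X / np.asarray(size_factors)[None, :]
    L = np.log2(X + 1.0)
    mu = L.mean(axis=1, keepdims=True)
    sd = L.std(axis=1, ddof=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = (L - mu) / sd
    Z[~np.isfinite(Z)] = 0.0
    return pd.DataFrame(Z, index=counts.index, columns=counts.columns)


def _running_sum_es(order: np.ndarray, member: np.ndarray) -> float:
    """Signed maximum deviation of the KS-style running sum along `order`."""
    m = member[order]
    nm = int(m.sum())
    n = len(order)
    if nm == 0 or nm == n:
        return 0.0
    steps = np.where(m, 1.0 / nm, -1.0 / (n - nm))
    cs = np.cumsum(steps)
    i = int(np.argmax(np.abs(cs)))
    return float(cs[i])


def regulon_activity(
    counts: pd.DataFrame,
    regulons: RegulonSet,
    min_targets: int = 5,
) -> tuple[pd.DataFrame, dict[str, bool]]:
    """Two-tailed running-sum enrichment of each regulon in each sample.

    Genes are z-scored (log2 normalized expression vs. the gene's cross-sample
    mean) and ranked per sample; the activity is the enrichment of
    positive-mode targets minus that of negative-mode targets. Returns the raw
    activity matrix and a per-regulon low-confidence flag (< `min_targets`
    usable targets). Targets absent from the matrix are dropped with a warning.
    """
    sig = expression_signature(counts)
    Z = sig.to_numpy()
    genes = list(counts.index)
    gene_pos = {g: i for i, g in enumerate(genes)}
    n_samples = Z.shape[1]

    # descending signature rank per sample, stable in gene order
    orders = [np.argsort(-Z[:, s], kind="mergesort") for s in range(n_samples)]

    act = np.zeros((len(regulons.regulons), n_samples))
    flags: dict[str, bool] = {}
    for i, (tf, targets) in enumerate(regulons.regulons.items()):
        usable = [(g, mode) for (g, _, mode) in targets if g in gene_pos]
        if len(usable) < len(targets):
            warnings.warn(
                f"regulon {tf!r}: {len(targets) - len(usable)} targets absent from matrix",
                stacklevel=2,
            )
        flags[tf] = len(usable) < min_targets
        pos = np.zeros(len(genes), dtype=bool)
        neg = np.zeros(len(genes), dtype=bool)
        for g, mode in usable:
            (pos if mode > 0 else neg)[gene_pos[g]] = True
        for s in range(n_samples):
            if Z[:, s].max() == Z[:, s].min():
                continue  # flat signature carries no enrichment signal
            es = _running_sum_es(orders[s], pos)
            if neg.any():
                es -= _running_sum_es(orders[s], neg)
            act[i, s] = es

    frame = pd.DataFrame(act, index=list(regulons.regulons), columns=counts.columns)
    return frame, flags


def normalize_activity(activity: pd.DataFrame) -> pd.DataFrame:
    """Z-score each regulon across samples; constant rows are set to 0."""
    A = activity.to_numpy(dtype=float)
    mu = A.mean(axis=1, keepdims=True)
    sd = A.std(axis=1, ddof=0, keepdims=True)
    out = np.zeros_like(A)
    nz = sd[:, 0] > 0
    out[nz] = (A[nz] - mu[nz]) / sd[nz]
    return pd.DataFrame(out, index=activity.index, columns=activity.columns)
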