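import itertools
import math

import numpy as np
import pandas as pd
import pytest

from trnkit.simdata import SimConfig, simulate_counts
from trnkit.trn import (
    Edge,
    RegulonSet,
    _running_sum_es,
    apply_dpi,
    infer_candidate_edges,
    mutual_information,
    regulon_activity,
    normalize_activity,
)


def mi_bruteforce(dx, dy, bins):
    """Direct plug-in MI over the empirical joint table (independent oracle)."""
    n = len(dx)
    mi = 0.0
    for a in range(bins):
        for b in range(bins):
            pab = np.mean((dx == a) & (dy == b))
            if pab == 0:
                continue
            pa = np.mean(dx == a)
            pb = np.mean(dy == b)
            mi += pab * math.log2(pab / (pa * pb))
    return mi


class TestMutualInformation:
    def test_perfect_two_state_dependence_is_one_bit(self):
        x = np.array([0.0] * 8 + [1.0] * 8)
        assert mutual_information(x, x.copy(), bins=2) == pytest.approx(1.0)

    def test_constant_vector_warns_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            assert mutual_information(np.ones(10), np.arange(10.0)) == 0.0

    def test_symmetry_exact(self, rng):
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        assert mutual_information(x, y) == mutual_information(y, x)

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=64)
        y = rng.normal(size=64)
        assert mutual_information(x, y) == pytest.approx(
            mutual_information(np.exp(x), y**3), abs=1e-12
        )

    def test_matches_bruteforce_small_sample(self, rng):
        """[DERIVED] n=16, 2 bins: equals direct summation over the 2x2 joint."""
        x = rng.normal(size=16)
        y = x + rng.normal(size=16)
        dx = (np.argsort(np.argsort(x, kind="mergesort"), kind="mergesort") * 2) // 16
        dy = (np.argsort(np.argsort(y, kind="mergesort"), kind="mergesort") * 2) // 16
        assert mutual_information(x, y, bins=2) == pytest.approx(
            mi_bruteforce(dx, dy, 2), abs=1e-12
        )

    def test_null_calibration(self):
        """Shuffled y: MI below its own permutation 95th pct ~95% of seeds."""
        hits = 0
        n_trials = 60
        for seed in range(n_trials):
            r = np.random.default_rng(seed)
            x = r.normal(size=100)
            y = r.permutation(r.normal(size=100))
            obs = mutual_information(x, y)
            null = np.array(
                [mutual_information(x, r.permutation(y)) for _ in range(60)]
            )
            hits += obs < np.quantile(null, 0.95)
        assert hits / n_trials > 0.80

    def test_dpi_on_markov_chain(self, rng):
        """MI(X,Z) <= min(MI(X,Y), MI(Y,Z)) + 0.05 bits on X->Y->Z chains."""
        ok = 0
        trials = 200
        for seed in range(trials):
            r = np.random.default_rng(seed)
            x = r.normal(size=60)
            y = x + r.normal(scale=0.7, size=60)
            z = y + r.normal(scale=0.7, size=60)
            mxz = mutual_information(x, z, bins=4)
            bound = min(
                mutual_information(x, y, bins=4), mutual_information(y, z, bins=4)
            )
            ok += mxz <= bound + 0.05
        assert ok / trials >= 0.95

    def test_too_short_vectors(self):
        with pytest.raises(ValueError, match="at least 8"):
            mutual_information(np.arange(4.0), np.arange(4.0))


class TestInferCandidateEdges:
    def test_missing_tf_listed(self, small_sim):
        _, counts, _, _ = small_sim
        with pytest.raises(ValueError, match="NOPE"):
            infer_candidate_edges(counts, ["NOPE"], n_perm=100)

    def test_n_perm_floor(self, small_sim):
        _, counts, _, _ = small_sim
        with pytest.raises(ValueError, match="n_perm"):
            infer_candidate_edges(counts, ["TF001"], n_perm=10)

    def test_null_retention_rate(self):
        """[DERIVED] no coupling: retained edges <= 1.5 * p_cut * tested pairs."""
        rates = []
        for seed in range(5):
            cfg = SimConfig(
                n_tfs=4, targets_per_tf=5, n_nontarget_genes=40,
                reps_per_condition=8, seed=seed,
                effect_log2fc=0.0, coupling=0.0, activity_sd=0.0,
                target_noise_sd=0.0,
            )
            counts, _, truth = simulate_counts(cfg)
            tfs = sorted(truth.regulons.regulons)
            edges = infer_candidate_edges(counts, tfs, n_perm=200, p_cut=0.01, seed=seed)
            rates.append(len(edges) / (len(tfs) * (cfg.n_genes - 1)))
        assert np.mean(rates) <= 1.5 * 0.01

    def test_strong_coupling_recovery(self, strong_sim):
        """[DERIVED] planted recall and precision >= 0.8 on strong coupling."""
        _, counts, _, truth = strong_sim
        tfs = sorted(truth.regulons.regulons)
        edges = infer_candidate_edges(
            counts, tfs, n_perm=500, p_cut=0.005, n_boot=100,
            consensus=0.75, seed=1, bins=4,
        )
        regs = apply_dpi(edges, tfs)
        planted = {(e.regulator, e.target) for e in truth.regulons.edges()}
        got = {(e.regulator, e.target) for e in regs.edges()}
        tp = len(planted & got)
        assert tp / len(planted) >= 0.8
        assert tp / len(got) >= 0.8

    def test_zero_bootstrap_is_permutation_only(self, small_sim):
        _, counts, _, truth = small_sim
        tfs = sorted(truth.regulons.regulons)
        e0 = infer_candidate_edges(counts, tfs, n_perm=100, p_cut=0.01, n_boot=0, seed=3)
        e1 = infer_candidate_edges(counts, tfs, n_perm=100, p_cut=0.01, n_boot=0, seed=3)
        assert [(e.regulator, e.target) for e in e0] == [
            (e.regulator, e.target) for e in e1
        ]


def dpi_oracle(edges, tf_list, tolerance):
    """Exhaustive triplet enumeration applying the same pruning rule."""
    mi = {frozenset((e.regulator, e.target)): e.mi for e in edges}
    tfs = sorted(set(tf_list))
    nodes = {n for e in edges for n in (e.regulator, e.target)}
    removed = set()
    for tf1, tf2 in itertools.combinations(tfs, 2):
        if frozenset((tf1, tf2)) not in mi:
            continue
        for g in nodes - {tf1, tf2}:
            k1, k2 = frozenset((tf1, g)), frozenset((tf2, g))
            if k1 in mi and k2 in mi:
                trip = sorted(
                    [frozenset((tf1, tf2)), k1, k2], key=lambda k: mi[k]
                )
                if mi[trip[0]] < (1 - tolerance) * mi[trip[1]]:
                    removed.add(trip[0])
    return {e.key() for e in edges} - removed


class TestApplyDpi:
    def test_triplet_rule(self):
        edges = [
            Edge("TF1", "TF2", 0.9),
            Edge("TF1", "g", 0.8),
            Edge("TF2", "g", 0.3),
        ]
        regs = apply_dpi(edges, ["TF1", "TF2"], tolerance=0.0)
        kept = {(e.regulator, e.target) for e in regs.edges()}
        assert ("TF2", "g") not in kept
        assert ("TF1", "g") in kept
        assert ("TF1", "TF2") in kept

    def test_no_tf_tf_edges_identity(self):
        edges = [Edge("TF1", "a", 0.5), Edge("TF2", "b", 0.1), Edge("TF2", "a", 0.05)]
        regs = apply_dpi(edges, ["TF1", "TF2"])
        assert regs.n_edges() == 3

    def test_negative_tolerance(self):
        with pytest.raises(ValueError, match="tolerance"):
            apply_dpi([], [], tolerance=-0.1)

    @pytest.mark.parametrize("tolerance", [0.0, 0.1])
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_oracle(self, seed, tolerance):
        """[DERIVED] random <=12-node networks vs exhaustive enumeration."""
        r = np.random.default_rng(seed)
        tfs = [f"T{i}" for i in range(4)]
        genes = [f"g{i}" for i in range(8)]
        edges = []
        for tf in tfs:
            for other in tfs + genes:
                if other != tf and r.random() < 0.45:
                    key = {(e.regulator, e.target) for e in edges}
                    if (other, tf) not in key:
                        edges.append(Edge(tf, other, float(r.uniform(0.01, 1.0))))
        regs = apply_dpi(edges, tfs, tolerance=tolerance)
        kept = {e.key() for e in regs.edges()}
        assert kept == dpi_oracle(edges, tfs, tolerance)
        assert kept <= {e.key() for e in edges}  # subset invariant


class TestRegulonActivity:
    def test_sign_contract(self):
        # sample s1: +mode targets at top, -mode at bottom
        genes = [f"g{i}" for i in range(10)]
        X = pd.DataFrame(
            np.ones((10, 8)), index=genes, columns=[f"s{i}" for i in range(8)]
        )
        X.loc[["g0", "g1", "g2"], "s0"] = 100.0
        X.loc[["g7", "g8", "g9"], "s0"] = 0.0
        regs = RegulonSet(
            {
                "R": [("g0", 1.0, 1), ("g1", 1.0, 1), ("g2", 1.0, 1),
                       ("g7", 1.0, -1), ("g8", 1.0, -1), ("g9", 1.0, -1)]
            }
        )
        act, _ = regulon_activity(X, regs)
        assert act.loc["R", "s0"] > 0
        assert act.loc["R", "s0"] == act.loc["R"].max()

    def test_constant_expression_zero_activity(self):
        X = pd.DataFrame(
            np.full((12, 6), 7.0),
            index=[f"g{i}" for i in range(12)],
            columns=[f"s{i}" for i in range(6)],
        )
        regs = RegulonSet({"R": [(f"g{i}", 1.0, 1) for i in range(5)]})
        act, _ = regulon_activity(X, regs)
        assert np.allclose(act.to_numpy(), 0.0)

    def test_running_sum_matches_hand_oracle(self):
        """[DERIVED] 6-member set on a 10-gene ranked list, KS running sum."""
        member = np.zeros(10, dtype=bool)
        member[[0, 1, 4, 5, 8, 9]] = True
        order = np.arange(10)
        # hand computation: steps +1/6 (member) or -1/4 (non-member)
        steps = [1 / 6, 1 / 6, -1 / 4, -1 / 4, 1 / 6, 1 / 6, -1 / 4, -1 / 4, 1 / 6, 1 / 6]
        cs = np.cumsum(steps)
        expected = cs[np.argmax(np.abs(cs))]
        assert _running_sum_es(order, member) == pytest.approx(expected, abs=1e-12)

    def test_low_confidence_flag(self):
        X = pd.DataFrame(
            np.random.default_rng(0).poisson(50, (8, 6)).astype(float),
            index=[f"g{i}" for i in range(8)],
            columns=[f"s{i}" for i in range(6)],
        )
        regs = RegulonSet({"R": [("g0", 1.0, 1), ("g1", 1.0, 1)]})
        _, flags = regulon_activity(X, regs)
        assert flags["R"] is True

    def test_missing_targets_warn(self):
        X = pd.DataFrame(
            np.random.default_rng(0).poisson(50, (4, 6)).astype(float),
            index=[f"g{i}" for i in range(4)],
            columns=[f"s{i}" for i in range(6)],
        )
        regs = RegulonSet({"R": [("g0", 1.0, 1), ("zz", 1.0, 1)]})
        with pytest.warns(UserWarning, match="absent"):
            regulon_activity(X, regs)


class TestNormalizeActivity:
    def test_rows_zero_mean_unit_sd(self, rng):
        A = pd.DataFrame(rng.normal(size=(5, 12)))
        N = normalize_activity(A)
        assert np.all(np.abs(N.mean(axis=1)) < 1e-9)
        assert np.allclose(N.std(axis=1, ddof=0), 1.0)

    def test_constant_rows_zeroed(self):
        A = pd.DataFrame([[3.0, 3.0, 3.0], [1.0, 2.0, 3.0]])
        N = normalize_activity(A)
        assert np.allclose(N.iloc[0], 0.0)


class TestRegulonSet:
    def test_self_edge_rejected(self):
        with pytest.raises(ValueError, match="self-edge"):
            RegulonSet({"A": [("A", 0.5, 1)]})

    def test_bad_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            RegulonSet({"A": [("b", 0.5, 2)]})
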