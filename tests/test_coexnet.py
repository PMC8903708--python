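"""Weighted co-expression core: adjacency, topological overlap, static-cut
module detection, eigengenes and module-trait association."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from circscreen import coexnet, synthdata
from circscreen.coexnet import (
    ModuleAssignment,
    adjacency_matrix,
    detect_modules,
    module_eigengenes,
    module_trait_association,
    soft_threshold_scan,
    topological_overlap,
)
from circscreen.errors import AnalysisError, ContractError


def tom_oracle(a):
    """Literal triple-loop topological overlap."""
    n = a.shape[0]
    k = a.sum(axis=1)
    tom = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n))
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


def random_adjacency(rng, n):
    a = rng.uniform(0, 1, size=(n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0.0)
    return a


def blocks_dataset(make_dataset, seed, n_blocks=2, size=30, cor=0.8, n_samples=40,
                   n_noise=0):
    rng = np.random.default_rng(seed)
    n = n_blocks * size + n_noise
    log2x = rng.normal(4, 1, size=(n, n_samples))
    truth = ["noise"] * n
    for b in range(n_blocks):
        f = rng.normal(size=n_samples)
        sl = slice(b * size, (b + 1) * size)
        log2x[sl] = 4 + np.sqrt(cor) * f + np.sqrt(1 - cor) * rng.normal(size=(size, n_samples))
        for i in range(b * size, (b + 1) * size):
            truth[i] = f"B{b}"
    return make_dataset(log2x), truth


class TestAdjacency:
    def test_power_one_is_absolute_correlation(self, make_dataset):
        rng = np.random.default_rng(0)
        data = make_dataset(rng.normal(3, 1, size=(6, 12)))
        adj = adjacency_matrix(data, power=1).to_numpy()
        cor = np.abs(np.corrcoef(np.log2(data.values.to_numpy() + 1)))
        np.fill_diagonal(cor, 0.0)
        assert np.allclose(adj, cor)

    def test_connectivity_matches_brute_sum(self, make_dataset):
        rng = np.random.default_rng(1)
        data = make_dataset(rng.normal(3, 1, size=(3, 10)))
        adj = adjacency_matrix(data, power=6).to_numpy()
        k = adj.sum(axis=1)
        for i in range(3):
            assert k[i] == pytest.approx(sum(adj[i, j] for j in range(3) if j != i))

    def test_powering_never_increases_entries(self, make_dataset):
        rng = np.random.default_rng(2)
        data = make_dataset(rng.normal(3, 1, size=(8, 15)))
        prev = adjacency_matrix(data, power=1).to_numpy()
        for beta in (2, 4, 8):
            cur = adjacency_matrix(data, power=beta).to_numpy()
            assert (cur <= prev + 1e-12).all()
            prev = cur


class TestSoftThresholdScan:
    def test_mean_connectivity_non_increasing(self, make_dataset):
        rng = np.random.default_rng(3)
        data = make_dataset(rng.normal(3, 1, size=(40, 20)))
        scan = soft_threshold_scan(data)
        assert all(
            a >= b - 1e-12
            for a, b in zip(scan.mean_connectivity, scan.mean_connectivity[1:])
        )

    def test_hub_network_fit_improves_with_power(self, make_dataset):
        # one hub strongly correlated with many leaves: powering heavy-tails
        # the connectivity distribution, improving the scale-free fit
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n_samples = 60
            hub = rng.normal(size=n_samples)
            log2x = np.empty((51, n_samples))
            log2x[0] = 4 + hub
            for i in range(1, 51):
                log2x[i] = 4 + np.sqrt(0.81) * hub + np.sqrt(0.19) * rng.normal(size=n_samples)
            data = make_dataset(log2x)
            scan = soft_threshold_scan(data)
            r2_at_1 = scan.fit_r2[scan.powers.index(1)]
            r2_at_chosen = scan.fit_r2[scan.powers.index(scan.chosen_power)]
            if r2_at_chosen >= r2_at_1:
                wins += 1
        assert wins == 10

    def test_too_few_samples_rejected(self, make_dataset):
        data = make_dataset(np.random.default_rng(0).normal(3, 1, size=(10, 3)))
        with pytest.raises(AnalysisError):
            soft_threshold_scan(data)


class TestTopologicalOverlap:
    def test_two_node_closed_form(self):
        a = np.array([[0.0, 0.4], [0.4, 0.0]])
        tom = topological_overlap(pd.DataFrame(a, index=["x", "y"], columns=["x", "y"]))
        assert tom.loc["x", "y"] == pytest.approx(0.4)
        assert tom.loc["x", "x"] == 1.0

    def test_empty_graph(self):
        a = np.zeros((4, 4))
        ids = list("abcd")
        tom = topological_overlap(pd.DataFrame(a, index=ids, columns=ids)).to_numpy()
        off = tom[~np.eye(4, dtype=bool)]
        assert (off == 0).all()

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(5)
        for n in (5, 6, 7, 8):
            for _ in range(5):
                a = random_adjacency(rng, n)
                ids = [f"n{i}" for i in range(n)]
                tom = topological_overlap(pd.DataFrame(a, index=ids, columns=ids)).to_numpy()
                assert np.abs(tom - tom_oracle(a)).max() < 1e-12

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(6)
        a = random_adjacency(rng, 7)
        ids = [f"n{i}" for i in range(7)]
        tom = topological_overlap(pd.DataFrame(a, index=ids, columns=ids)).to_numpy()
        assert np.allclose(tom, tom.T)
        assert tom.min() >= 0 and tom.max() <= 1 + 1e-12

    def test_asymmetric_input_rejected(self):
        a = np.array([[0.0, 0.5], [0.2, 0.0]])
        with pytest.raises(ContractError):
            topological_overlap(pd.DataFrame(a, index=["x", "y"], columns=["x", "y"]))


class TestDetectModules:
    def test_two_planted_blocks_recovered_exactly(self, make_dataset):
        for seed in range(5):
            data, truth = blocks_dataset(make_dataset, seed)
            tom = topological_overlap(adjacency_matrix(data, power=6))
            assignment = detect_modules(tom)
            assert len(assignment.module_names) == 2
            pred = [assignment.modules[p] for p in data.probe_ids]
            assert adjusted_rand_score(truth, pred) == 1.0

    def test_unstructured_data_is_all_grey(self, make_dataset):
        rng = np.random.default_rng(0)
        data = make_dataset(rng.normal(4, 1, size=(60, 20)))
        tom = topological_overlap(adjacency_matrix(data, power=6))
        assignment = detect_modules(tom)
        assert assignment.module_names == []

    def test_default_preset_yields_seven_modules(self):
        data = synthdata.gen_expression(synthdata.coexpression_preset(seed=0))
        tom = topological_overlap(adjacency_matrix(data, power=6))
        assignment = detect_modules(tom)
        assert len(assignment.module_names) == 7
        assert assignment.module_names[0] == "turquoise"  # largest first

    def test_probe_order_invariance(self, make_dataset):
        data, _ = blocks_dataset(make_dataset, seed=1)
        tom = topological_overlap(adjacency_matrix(data, power=6))
        perm = np.random.default_rng(3).permutation(len(tom))
        tom_perm = tom.iloc[perm, perm]
        a1 = detect_modules(tom)
        a2 = detect_modules(tom_perm)
        members1 = {m: frozenset(a1.members(m)) for m in a1.module_names}
        members2 = {m: frozenset(a2.members(m)) for m in a2.module_names}
        assert members1 == members2

    def test_planted_partition_recovery_at_stated_settings(self, make_dataset):
        # within-module correlation 0.7, module size 20, 40 samples
        for seed in range(3):
            data, truth = blocks_dataset(
                make_dataset, seed=seed + 10, n_blocks=4, size=20, cor=0.7,
                n_samples=40, n_noise=40,
            )
            tom = topological_overlap(adjacency_matrix(data, power=6))
            assignment = detect_modules(tom)
            pred = [assignment.modules[p] for p in data.probe_ids]
            truth_grey = [t if t != "noise" else "grey" for t in truth]
            assert adjusted_rand_score(truth_grey, pred) >= 0.9

    def test_tiny_input_goes_grey_with_warning(self):
        ids = ["a", "b"]
        tom = pd.DataFrame(np.eye(2), index=ids, columns=ids)
        with pytest.warns(UserWarning):
            assignment = detect_modules(tom, min_module_size=10)
        assert set(assignment.modules.values()) == {"grey"}


class TestModuleEigengenes:
    def test_identical_probes_give_perfectly_correlated_eigengene(self, make_dataset):
        rng = np.random.default_rng(0)
        row = rng.normal(3, 1, size=15)
        data = make_dataset(np.tile(row, (4, 1)))
        assignment = ModuleAssignment(modules={p: "turquoise" for p in data.probe_ids})
        eig = module_eigengenes(data, assignment)
        x = np.log2(data.values.to_numpy()[0] + 1)
        assert abs(np.corrcoef(eig.loc["turquoise"], x)[0, 1]) == pytest.approx(1.0)
        assert np.corrcoef(eig.loc["turquoise"], x)[0, 1] > 0  # orientation

    def test_sign_flip_restores_positive_orientation(self, make_dataset):
        rng = np.random.default_rng(1)
        f = rng.normal(size=20)
        log2x = 4 + np.vstack([f + 0.1 * rng.normal(size=20) for _ in range(5)])
        data = make_dataset(log2x)
        flipped = make_dataset(8 - log2x)
        assignment = ModuleAssignment(modules={p: "blue" for p in data.probe_ids})
        e1 = module_eigengenes(data, assignment).loc["blue"]
        e2 = module_eigengenes(flipped, assignment).loc["blue"]
        # each eigengene correlates positively with its own members
        m1 = np.log2(data.values.to_numpy() + 1)
        m2 = np.log2(flipped.values.to_numpy() + 1)
        assert np.mean([np.corrcoef(e1, r)[0, 1] for r in m1]) > 0
        assert np.mean([np.corrcoef(e2, r)[0, 1] for r in m2]) > 0

    def test_matches_eigendecomposition_oracle(self, make_dataset):
        rng = np.random.default_rng(2)
        log2x = rng.normal(3, 1, size=(4, 12))
        data = make_dataset(log2x)
        assignment = ModuleAssignment(modules={p: "brown" for p in data.probe_ids})
        eig = module_eigengenes(data, assignment).loc["brown"].to_numpy()
        x = np.log2(2.0**log2x + 1)
        z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
        w, v = np.linalg.eigh(z.T @ z)
        pc1 = v[:, -1]
        pc1 = pc1 / pc1.std()
        agreement = abs(np.corrcoef(eig, pc1)[0, 1])
        assert agreement == pytest.approx(1.0, abs=1e-9)

    def test_unit_variance(self, make_dataset):
        rng = np.random.default_rng(3)
        data = make_dataset(rng.normal(3, 1, size=(6, 10)))
        assignment = ModuleAssignment(modules={p: "red" for p in data.probe_ids})
        eig = module_eigengenes(data, assignment).loc["red"].to_numpy()
        assert eig.std() == pytest.approx(1.0)


class TestModuleTraitAssociation:
    def test_eigengene_equal_to_indicator(self):
        trait = {f"s{j}": j % 2 for j in range(10)}
        eig = pd.DataFrame(
            [[trait[f"s{j}"] for j in range(10)]], index=["m1"],
            columns=[f"s{j}" for j in range(10)],
        )
        res = module_trait_association(eig, trait)[0]
        assert res.correlation == pytest.approx(1.0)
        assert res.trait_up

    def test_constant_trait_rejected(self):
        eig = pd.DataFrame([[1.0, 2.0]], index=["m"], columns=["a", "b"])
        with pytest.raises(AnalysisError):
            module_trait_association(eig, {"a": 1, "b": 1})

    def test_planted_trait_modules_recovered(self):
        # eigengenes on the true module assignment: the two planted IgD-up
        # modules are flagged in every seed; false flags stay within the
        # binomial expectation at alpha = 0.05
        false_flags = 0
        for seed in range(5):
            data = synthdata.gen_expression(synthdata.coexpression_preset(seed=seed))
            tm = data.truth["module"]
            assignment = ModuleAssignment(
                modules={p: (tm[p] if tm[p] else "grey") for p in data.probe_ids}
            )
            eig = module_eigengenes(data, assignment)
            trait = {s: int(data.groups[s] == "IgD") for s in data.sample_ids}
            flagged = {
                t.module for t in module_trait_association(eig, trait) if t.trait_up
            }
            assert {"M1", "M2"} <= flagged
            false_flags += len(flagged - {"M1", "M2"})
        assert false_flags <= 3

    def test_null_flag_rate_calibrated(self):
        # independent eigengene and trait: flag rate ~ 2.5% (positive half
        # of the 5% two-sided level)
        rng = np.random.default_rng(0)
        n = 30
        trait = {f"s{j}": int(j < 15) for j in range(n)}
        cols = [f"s{j}" for j in range(n)]
        eig = pd.DataFrame(
            rng.normal(size=(1000, n)), index=[f"m{i}" for i in range(1000)], columns=cols
        )
        res = module_trait_association(eig, trait)
        rate = np.mean([r.trait_up for r in res])
        assert abs(rate - 0.025) < 0.015
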