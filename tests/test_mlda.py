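import numpy as np
import pytest
from scipy.linalg import block_diag

from modlda import (
    BlockSpec,
    GeneModule,
    ModuleSet,
    SimulationDesign,
    dlda_fit,
    dlda_predict,
    estimate_block_covariance,
    invert_block,
    mlda_fit,
    mlda_predict,
    simulate,
)
from conftest import make_dataset, probe_like


def eq34_direct(data, members, shrinkage=True):
    """Independent entrywise implementation of the pooled + shrunken block
    covariance, written with explicit loops as an oracle."""
    members = list(members)
    xa = data.values[np.ix_(members, np.flatnonzero(data.labels == "A"))]
    xb = data.values[np.ix_(members, np.flatnonzero(data.labels == "B"))]
    na, nb = xa.shape[1], xb.shape[1]
    p_c = len(members)
    pooled = np.empty((p_c, p_c))
    for i in range(p_c):
        for j in range(p_c):
            sa = np.sum((xa[i] - xa[i].mean()) * (xa[j] - xa[j].mean())) / (na - 1)
            sb = np.sum((xb[i] - xb[i].mean()) * (xb[j] - xb[j].mean())) / (nb - 1)
            pooled[i, j] = ((na - 1) * sa + (nb - 1) * sb) / (na + nb - 2)
    if not shrinkage or p_c == 1:
        return pooled
    sd = np.sqrt(np.diagonal(pooled))
    pairs = [
        pooled[i, j] / (sd[i] * sd[j]) for i in range(p_c) for j in range(i + 1, p_c)
    ]
    r_hat = float(np.median(pairs))
    out = np.empty((p_c, p_c))
    for i in range(p_c):
        for j in range(p_c):
            out[i, j] = sd[i] ** 2 if i == j else sd[i] * sd[j] * r_hat
    return out


def random_module_set(p, sizes, rng):
    genes = list(rng.permutation(p))
    modules, pos = [], 0
    for size in sizes:
        members = tuple(sorted(int(g) for g in genes[pos : pos + size]))
        modules.append(GeneModule(members[0], members, 0.5, 1.0))
        pos += size
    return ModuleSet(tuple(modules))


class TestBlockCovariance:
    def test_matches_independent_direct_implementation(self, rng):
        data = make_dataset(rng.normal(size=(8, 20)))
        module = GeneModule(1, (1, 3, 5, 7), 0.5, 1.0)
        block = estimate_block_covariance(data, module)
        expected = eq34_direct(data, module.members)
        np.testing.assert_allclose(block.sigma, expected, rtol=1e-12)

    def test_singleton_module_equals_dlda_variance(self, rng):
        data = make_dataset(rng.normal(size=(3, 14)))
        block = estimate_block_covariance(data, GeneModule(2, (2,), 0.95, 1.0))
        dlda = dlda_fit(data)
        assert block.sigma.shape == (1, 1)
        assert block.sigma[0, 0] == pytest.approx(dlda.var_pooled[2], rel=1e-14)

    def test_two_gene_module_offdiagonal_is_exact(self, rng):
        data = make_dataset(rng.normal(size=(2, 16)))
        block = estimate_block_covariance(data, GeneModule(0, (0, 1), 0.5, 1.0))
        pooled = eq34_direct(data, (0, 1), shrinkage=False)
        r12 = pooled[0, 1] / np.sqrt(pooled[0, 0] * pooled[1, 1])
        assert block.median_corr == pytest.approx(r12, rel=1e-14)
        assert block.sigma[0, 1] == pytest.approx(
            np.sqrt(pooled[0, 0] * pooled[1, 1]) * r12, rel=1e-14
        )

    def test_zero_variance_gene_is_named(self):
        values = np.vstack([np.ones(8), np.arange(8.0)])
        data = make_dataset(values)
        with pytest.raises(ValueError, match="g0"):
            estimate_block_covariance(data, GeneModule(0, (0, 1), 0.5, 1.0))


class TestInvertBlock:
    def test_identity_and_hand_2x2(self):
        np.testing.assert_allclose(invert_block(np.eye(3)), np.eye(3), atol=1e-14)
        inv = invert_block(np.array([[2.0, 1.0], [1.0, 2.0]]))
        np.testing.assert_allclose(
            inv, [[2 / 3, -1 / 3], [-1 / 3, 2 / 3]], atol=1e-14
        )

    def test_rank_one_matrix_gets_moore_penrose_pseudoinverse(self):
        a = np.ones((2, 2))
        pinv = invert_block(a)
        np.testing.assert_allclose(pinv, np.full((2, 2), 0.25), atol=1e-14)
        np.testing.assert_allclose(a @ pinv @ a, a, atol=1e-12)
        np.testing.assert_allclose(pinv @ a @ pinv, pinv, atol=1e-12)

    def test_well_conditioned_matches_exact_inverse(self, rng):
        x = rng.normal(size=(6, 30))
        sigma = x @ x.T / 30
        np.testing.assert_allclose(
            invert_block(sigma), np.linalg.inv(sigma), rtol=1e-9
        )

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            invert_block(np.array([[1.0, 2.0], [0.0, 1.0]]))

    def test_rank_zero_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            invert_block(np.zeros((2, 2)))


class TestMLDAPredict:
    def test_block_additive_lp_equals_whole_matrix_oracle(self, rng):
        data, _ = simulate(SimulationDesign(n_a=15, n_b=15, p=12, blocks=()), 3)
        modules = random_module_set(12, [4, 3, 3, 2], rng)
        model = mlda_fit(data, modules)
        new = probe_like(data, rng.normal(size=(12, 7)))
        _, lp = mlda_predict(model, new)

        # oracle: assemble the full block-diagonal covariance, invert it whole
        order = [g for mod in modules.modules for g in mod.members]
        full = block_diag(*[b.sigma for b in model.blocks])
        mu_a = np.concatenate([b.mu_a for b in model.blocks])
        mu_b = np.concatenate([b.mu_b for b in model.blocks])
        x = new.values[order]
        expected = (
            (x - 0.5 * (mu_a + mu_b)[:, None]).T
            @ np.linalg.inv(full)
            @ (mu_a - mu_b)
        )
        np.testing.assert_allclose(lp, expected, rtol=1e-10)

    def test_class_a_mean_and_midpoint_go_to_a_at_equal_class_sizes(self, rng):
        data = make_dataset(rng.normal(size=(4, 20)))
        modules = random_module_set(4, [2, 2], rng)
        model = mlda_fit(data, modules)
        assert model.threshold == 0.0
        mu_a = {g: m for b in model.blocks for g, m in zip(b.gene_ids, b.mu_a)}
        mid = {
            g: 0.5 * (ma + mb)
            for b in model.blocks
            for g, ma, mb in zip(b.gene_ids, b.mu_a, b.mu_b)
        }
        # a single-sample dataset needs n >= 2; duplicate the column
        at_mu_a = make_dataset(
            np.tile([[mu_a[f"g{i}"]] for i in range(4)], 2), labels=["A", "B"]
        )
        labels, lp = mlda_predict(model, at_mu_a)
        assert lp[0] >= 0 and labels[0] == "A"
        at_mid = make_dataset(
            np.tile([[mid[f"g{i}"]] for i in range(4)], 2), labels=["A", "B"]
        )
        labels, lp = mlda_predict(model, at_mid)
        assert lp[0] == 0.0  # exact: x - (mu_a+mu_b)/2 cancels bitwise
        assert labels[0] == "A"  # boundary goes to A

    def test_label_swap_negates_lp_and_flips_predictions(self, rng):
        data, _ = simulate(SimulationDesign(n_a=12, n_b=18, p=6, blocks=()), 9)
        modules = random_module_set(6, [3, 3], rng)
        model = mlda_fit(data, modules)
        swapped = probe_like(
            data, data.values, ["B" if l == "A" else "A" for l in data.labels]
        )
        model_swapped = mlda_fit(swapped, modules)
        new = probe_like(data, np.random.default_rng(4).normal(size=(6, 50)))
        labels, lp = mlda_predict(model, new)
        labels_s, lp_s = mlda_predict(model_swapped, new)
        np.testing.assert_allclose(lp_s, -lp, rtol=1e-9)
        off_boundary = np.abs(lp - model.threshold) > 1e-9
        flipped = np.where(np.array(labels) == "A", "B", "A")
        assert (np.array(labels_s)[off_boundary] == flipped[off_boundary]).all()

    def test_missing_gene_is_named(self, rng):
        data = make_dataset(rng.normal(size=(3, 10)))
        model = mlda_fit(data, random_module_set(3, [3], rng))
        incomplete = make_dataset(rng.normal(size=(2, 4)))
        with pytest.raises(KeyError, match="g2"):
            mlda_predict(model, incomplete)


class TestLimitingCases:
    def test_single_full_module_without_shrinkage_is_classical_lda(self):
        data, _ = simulate(SimulationDesign(n_a=30, n_b=30, p=8, blocks=()), 21)
        all_genes = GeneModule(0, tuple(range(8)), 0.5, 1.0)
        model = mlda_fit(data, ModuleSet((all_genes,)), shrinkage=False)
        test = probe_like(data, np.random.default_rng(8).normal(size=(8, 40)))
        labels, lp = mlda_predict(model, test)

        # classical full LDA with the pooled covariance, computed directly
        xa = data.values[:, data.class_mask("A")]
        xb = data.values[:, data.class_mask("B")]
        mu_a, mu_b = xa.mean(axis=1), xb.mean(axis=1)
        ca, cb = xa - mu_a[:, None], xb - mu_b[:, None]
        sigma = (ca @ ca.T + cb @ cb.T) / (60 - 2)
        lp_lda = (
            (test.values - 0.5 * (mu_a + mu_b)[:, None]).T
            @ np.linalg.inv(sigma)
            @ (mu_a - mu_b)
        )
        np.testing.assert_allclose(lp, lp_lda, rtol=1e-9)
        assert list(labels) == list(np.where(lp_lda >= 0, "A", "B"))

    def test_all_singleton_modules_reproduce_dlda(self, rng):
        data, _ = simulate(SimulationDesign(n_a=14, n_b=20, p=10, blocks=()), 22)
        singletons = ModuleSet(
            tuple(GeneModule(i, (i,), 0.95, 1.0) for i in range(10))
        )
        model = mlda_fit(data, singletons)
        dlda = dlda_fit(data)
        test = probe_like(data, rng.normal(size=(10, 100)))
        labels_m, lp_m = mlda_predict(model, test)
        labels_d, lp_d = dlda_predict(dlda, test)
        np.testing.assert_allclose(lp_m, lp_d, rtol=1e-10)
        assert list(labels_m) == list(labels_d)


class TestSeparationPower:
    def test_error_shrinks_as_the_planted_shift_grows(self):
        def test_error(delta, seed):
            design = SimulationDesign(
                n_a=50,
                n_b=50,
                p=40,
                blocks=tuple(BlockSpec(5, 0.8, delta) for _ in range(4)),
            )
            train, _ = simulate(design, seed)
            test, _ = simulate(design, seed + 1000)
            from modlda import (
                build_module_set,
                correlation_matrix,
                select_seeds,
                t_statistic,
            )

            scores = t_statistic(train)
            modules = build_module_set(
                select_seeds(scores, 4), correlation_matrix(train), scores
            )
            model = mlda_fit(train, modules)
            labels, _ = mlda_predict(model, test)
            return np.mean(labels != test.labels)

        errors = [np.mean([test_error(d, s) for s in (1, 2, 3)]) for d in (1.0, 2.0, 3.0)]
        assert errors[1] < 0.05 and errors[2] < 0.05
        assert errors[2] <= errors[0] + 0.05  # monotone within Monte-Carlo error
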