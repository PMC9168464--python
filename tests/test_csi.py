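import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from regulonkit import (CSIParams, compute_csi, detect_modules,
                        drop_zero_variance, module_activity, pairwise_pcc,
                        sankey_table)
from tests.conftest import make_activity, make_annotation


def oracle_csi(pcc, variant):
    """Exhaustive double-loop enumeration of both CSI definitions."""
    p = np.asarray(pcc, dtype=float)
    p = 0.5 * (p + p.T)
    K = p.shape[0]
    out = np.zeros_like(p)
    pairs = [(x, y) for x in range(K) for y in range(x + 1, K)]
    N = len(pairs)
    for a in range(K):
        for b in range(K):
            if a == b:
                out[a, b] = 1.0
                continue
            v = p[a, b]
            if variant == "literal":
                n = sum(1 for x, y in pairs
                        if {x, y} != {a, b} and p[x, y] < v)
                out[a, b] = n / N
            else:
                n = sum(1 for c in range(K) if p[a, c] < v and p[b, c] < v)
                out[a, b] = n / K
    return out


def random_pcc(rng, k):
    """Symmetric correlation-like matrix via actual correlations of noise."""
    data = rng.normal(size=(k, 40))
    return pd.DataFrame(np.corrcoef(data),
                        index=[f"R{i}(+)" for i in range(k)],
                        columns=[f"R{i}(+)" for i in range(k)])


class TestPairwisePcc:
    def test_self_correlation_one_and_negation_minus_one(self):
        rng = np.random.default_rng(0)
        base = rng.random(40)
        act = make_activity(np.vstack([base, base, 1.0 - base]))
        pcc = pairwise_pcc(act)
        assert pcc.iloc[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert pcc.iloc[0, 2] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(1)
        values = rng.random((6, 40))
        pcc = pairwise_pcc(make_activity(values)).to_numpy()
        centered = values - values.mean(axis=1, keepdims=True)
        denom = np.sqrt((centered**2).sum(axis=1))
        expected = (centered @ centered.T) / np.outer(denom, denom)
        assert np.abs(pcc - expected).max() < 1e-12

    def test_zero_variance_row_is_hard_error(self):
        act = make_activity([[0.5, 0.5, 0.5], [0.1, 0.2, 0.3]])
        with pytest.raises(ValueError, match="zero-variance"):
            pairwise_pcc(act)

    def test_drop_zero_variance_reports_names(self):
        act = make_activity([[0.5, 0.5, 0.5], [0.1, 0.2, 0.3]])
        kept, dropped = drop_zero_variance(act)
        assert dropped == ["R0(+)"]
        assert kept.regulon_names == ["R1(+)"]


class TestComputeCsi:
    def test_unique_maximal_pair_scores_n_minus_one_over_n(self):
        pcc = random_pcc(np.random.default_rng(2), 6)
        p = pcc.to_numpy()
        iu = np.triu_indices(6, 1)
        N = len(p[iu])
        amax = np.argmax(p[iu])
        a, b = iu[0][amax], iu[1][amax]
        csi = compute_csi(pcc, "literal").to_numpy()
        assert csi[a, b] == pytest.approx((N - 1) / N)

    def test_unique_minimal_pair_scores_zero(self):
        pcc = random_pcc(np.random.default_rng(3), 6)
        p = pcc.to_numpy()
        iu = np.triu_indices(6, 1)
        amin = np.argmin(p[iu])
        a, b = iu[0][amin], iu[1][amin]
        csi = compute_csi(pcc, "literal").to_numpy()
        assert csi[a, b] == 0.0

    @pytest.mark.parametrize("variant", ["literal", "neighbor"])
    def test_matches_enumeration_oracle_exactly(self, variant):
        rng = np.random.default_rng(4)
        for _ in range(5):
            k = int(rng.integers(5, 13))
            pcc = random_pcc(rng, k)
            got = compute_csi(pcc, variant).to_numpy()
            expected = oracle_csi(pcc, variant)
            assert np.array_equal(got, expected)

    def test_literal_values_on_grid_and_monotone(self):
        rng = np.random.default_rng(5)
        pcc = random_pcc(rng, 8)
        csi = compute_csi(pcc, "literal").to_numpy()
        K = 8
        N = K * (K - 1) // 2
        iu = np.triu_indices(K, 1)
        assert np.allclose(csi[iu] * N, np.round(csi[iu] * N), atol=1e-9)
        # monotone: higher PCC never gets lower CSI
        p = pcc.to_numpy()[iu]
        c = csi[iu]
        order = np.argsort(p)
        assert (np.diff(c[order]) >= -1e-12).all()

    def test_symmetric_with_unit_diagonal(self):
        pcc = random_pcc(np.random.default_rng(6), 7)
        for variant in ("literal", "neighbor"):
            csi = compute_csi(pcc, variant).to_numpy()
            assert np.allclose(csi, csi.T)
            assert (np.diag(csi) == 1.0).all()
            assert csi.min() >= 0.0 and csi.max() <= 1.0

    def test_unknown_variant_rejected(self):
        pcc = random_pcc(np.random.default_rng(7), 5)
        with pytest.raises(ValueError, match="variant"):
            compute_csi(pcc, "bogus")


class TestDetectModules:
    def test_block_diagonal_recovered_exactly(self):
        blocks = [3, 4, 5]
        mats = []
        for i, size in enumerate(blocks):
            row = np.full(sum(blocks), 0.1)
            mats.append(np.tile(row, (size, 1)))
        csi = np.vstack(mats)
        start = 0
        truth = []
        for i, size in enumerate(blocks):
            csi[start:start + size, start:start + size] = 0.9
            truth += [i] * size
            start += size
        np.fill_diagonal(csi, 1.0)
        names = [f"R{i}(+)" for i in range(sum(blocks))]
        got = detect_modules(pd.DataFrame(csi, index=names, columns=names),
                             CSIParams(n_modules=3))
        assert adjusted_rand_score(truth, [got[n] for n in names]) == 1.0
        # M1 is the largest block
        assert [got[n] for n in names[-5:]] == ["M1"] * 5

    def test_n_modules_equal_k_gives_singletons(self):
        pcc = random_pcc(np.random.default_rng(8), 5)
        csi = compute_csi(pcc, "neighbor")
        got = detect_modules(csi, CSIParams(n_modules=5))
        assert len(set(got.values())) == 5

    def test_n_modules_above_k_rejected(self):
        pcc = random_pcc(np.random.default_rng(9), 4)
        with pytest.raises(ValueError, match="exceeds"):
            detect_modules(compute_csi(pcc, "neighbor"),
                           CSIParams(n_modules=5))

    def test_invariant_to_regulon_input_order(self):
        rng = np.random.default_rng(10)
        base = np.repeat(np.eye(3), [4, 4, 4], axis=0)
        data = np.clip(
            0.5 * np.repeat(base, 20, axis=1) + rng.normal(0.3, 0.1, (12, 60)),
            0.0, 1.0)
        act = make_activity(data, cell_ids=[f"cell{j}" for j in range(60)])
        csi = compute_csi(pairwise_pcc(act), "neighbor")
        a = detect_modules(csi, CSIParams(n_modules=3))
        perm = rng.permutation(12)
        names = [csi.index[i] for i in perm]
        csi_p = csi.loc[names, names]
        b = detect_modules(csi_p, CSIParams(n_modules=3))
        ari = adjusted_rand_score([a[n] for n in names], [b[n] for n in names])
        assert ari == 1.0


class TestModuleActivity:
    def test_single_module_single_type_is_grand_mean(self):
        act = make_activity([[0.1, 0.2], [0.3, 0.4]])
        annot = make_annotation(["A", "A"])
        assignment = {"R0(+)": "M1", "R1(+)": "M1"}
        by_type, per_cell = module_activity(act, annot, assignment)
        assert by_type.loc["M1", "A"] == pytest.approx(0.25)
        assert per_cell.loc["cell0", "M1"] == pytest.approx(0.2)

    def test_all_ones_gives_ones(self):
        act = make_activity(np.ones((3, 4)))
        annot = make_annotation(["A", "A", "B", "B"])
        assignment = {"R0(+)": "M1", "R1(+)": "M1", "R2(+)": "M2"}
        by_type, _ = module_activity(act, annot, assignment)
        assert np.allclose(by_type.to_numpy(), 1.0)

    def test_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(11)
        values = rng.random((6, 30))
        types = rng.choice(["A", "B", "C"], size=30).tolist()
        act = make_activity(values)
        annot = make_annotation(types)
        assignment = {f"R{i}(+)": f"M{i % 2 + 1}" for i in range(6)}
        by_type, _ = module_activity(act, annot, assignment)
        for mod in ("M1", "M2"):
            rows = [i for i in range(6) if assignment[f"R{i}(+)"] == mod]
            for t in set(types):
                cols = [j for j, ty in enumerate(types) if ty == t]
                expected = np.mean([values[i, j] for i in rows for j in cols])
                assert by_type.loc[mod, t] == pytest.approx(expected, abs=1e-12)


class TestSankeyTable:
    def test_single_module_labels_everything(self):
        rss = pd.DataFrame([[0.9], [0.5]], index=["A(+)", "B(+)"],
                           columns=["SMC"])
        table = sankey_table(rss, {"A(+)": "M1", "B(+)": "M1"}, top_k=2)
        assert (table["module"] == "M1").all()
        assert table["rank"].tolist() == [1, 2]

    def test_top_k_saturation_warns(self):
        rss = pd.DataFrame([[0.9]], index=["A(+)"], columns=["SMC"])
        with pytest.warns(UserWarning, match="exceeds"):
            table = sankey_table(rss, {"A(+)": "M1"}, top_k=5)
        assert len(table) == 1
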