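import numpy as np
import pandas as pd
import pytest

from bloodpanel.covariates import age_correlation, sex_stratified_fc
from bloodpanel.network import build_network, connected_components, pearson_matrix
from bloodpanel.simulate import Block, CohortSpec, generate_cohort


class TestPearsonMatrix:
    def test_diagonal_and_anticorrelation(self, rng):
        x = rng.normal(0, 1, 20)
        expr = pd.DataFrame([x + 8, -x + 8], index=["GA", "GB"],
                            columns=[f"s{j}" for j in range(20)])
        pcc = pearson_matrix(expr)
        assert pcc.loc["GA", "GA"] == pytest.approx(1.0)
        assert pcc.loc["GA", "GB"] == pytest.approx(-1.0)

    def test_textbook_formula_oracle(self, rng):
        x = rng.normal(8, 1, 5)
        y = rng.normal(8, 1, 5)
        expr = pd.DataFrame([x, y], index=["GA", "GB"],
                            columns=[f"s{j}" for j in range(5)])
        pcc = pearson_matrix(expr)
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert pcc.loc["GA", "GB"] == pytest.approx(num / den, abs=1e-12)

    def test_symmetric_with_unit_diagonal(self, rng):
        expr = pd.DataFrame(rng.normal(8, 1, size=(6, 12)),
                            index=[f"G{i}" for i in range(6)])
        pcc = pearson_matrix(expr)
        pd.testing.assert_frame_equal(pcc, pcc.T)
        assert np.allclose(np.diag(pcc), 1.0)

    def test_zero_variance_gene_undefined(self, rng):
        expr = pd.DataFrame(
            [np.full(10, 8.0), rng.normal(8, 1, 10)], index=["FLAT", "GB"])
        pcc = pearson_matrix(expr)
        assert np.isnan(pcc.loc["FLAT", "GB"])

    def test_pairwise_complete_missing_handling(self, rng):
        x = rng.normal(8, 1, 30)
        expr = pd.DataFrame([x, x * 2], index=["GA", "GB"],
                            columns=[f"s{j}" for j in range(30)])
        expr.iloc[0, :5] = np.nan
        pcc = pearson_matrix(expr)
        assert pcc.loc["GA", "GB"] == pytest.approx(1.0)

    def test_too_few_samples_rejected(self):
        expr = pd.DataFrame([[1.0, 2.0]], index=["G"])
        with pytest.raises(ValueError, match="3 samples"):
            pearson_matrix(expr)


class TestBuildNetwork:
    def test_no_edges_below_cutoff(self, rng):
        pcc = pd.DataFrame(np.eye(4) * 0.5 + 0.3, index=list("ABCD"),
                           columns=list("ABCD"))
        net = build_network(pcc, cutoff=0.5)
        assert net.number_of_edges() == 0
        assert len(connected_components(net)) == 4

    def test_cutoff_one_keeps_nothing(self):
        pcc = pd.DataFrame(np.ones((3, 3)), index=list("ABC"), columns=list("ABC"))
        assert build_network(pcc, cutoff=1.0).number_of_edges() == 0

    def test_edge_set_monotone_in_cutoff(self, rng):
        expr = pd.DataFrame(rng.normal(8, 1, size=(10, 40)),
                            index=[f"G{i}" for i in range(10)])
        pcc = pearson_matrix(expr)
        prev = None
        for cutoff in (0.0, 0.3, 0.5, 0.8):
            edges = set(map(frozenset, build_network(pcc, cutoff).edges()))
            if prev is not None:
                assert edges <= prev
            prev = edges

    def test_planted_blocks_form_two_components(self):
        vrg = [f"V{i}" for i in range(10)]
        brg = [f"B{i}" for i in range(10)]
        spec = CohortSpec(
            n_genes=20, n_case=100, n_control=100, noise_sd=0.3,
            coexpression_blocks=(Block(tuple(vrg), 0.8), Block(tuple(brg), 0.8)),
            gene_names=tuple(vrg + brg), seed=11,
        )
        cohort = generate_cohort(spec)
        pcc = pearson_matrix(cohort.genes)
        net = build_network(pcc, cutoff=0.5)
        comps = [c for c in connected_components(net) if len(c) > 1]
        assert len(comps) == 2
        assert any(set(vrg) == c for c in comps)
        assert any(set(brg) == c for c in comps)

    def test_within_block_edge_recall(self):
        vrg = [f"V{i}" for i in range(10)]
        spec = CohortSpec(
            n_genes=10, n_case=100, n_control=100, noise_sd=0.3,
            coexpression_blocks=(Block(tuple(vrg), 0.8),),
            gene_names=tuple(vrg), seed=13,
        )
        cohort = generate_cohort(spec)
        net = build_network(pearson_matrix(cohort.genes), cutoff=0.5)
        assert net.number_of_edges() >= 0.9 * 45  # 10-choose-2 possible


class TestSexStratifiedFc:
    def make_cohort(self, male_fc, female_fc, rng, n=40):
        genes = ["GENE1"]
        half = n // 2
        cols, rows, groups, sexes = [], [], [], []
        vals = []
        for i in range(n):
            sex = "male" if i % 2 == 0 else "female"
            case = i < half
            fc = male_fc if sex == "male" else female_fc
            base = 8.0 + rng.normal(0, 0.05)
            vals.append(base + (np.log2(fc) if case else 0.0))
            cols.append(f"s{i}")
            groups.append("case" if case else "control")
            sexes.append(sex)
        expr = pd.DataFrame([vals], index=genes, columns=cols)
        meta = pd.DataFrame({"group": groups, "class_label": ["x"] * n,
                             "sex": sexes},
                            index=pd.Index(cols, name="sample_id"))
        return expr, meta

    def test_identical_effect_ratio_unity(self, rng):
        expr, meta = self.make_cohort(4.0, 4.0, rng)
        rep = sex_stratified_fc(expr, meta, ["GENE1"])
        assert rep.loc["GENE1", "sex_ratio"] == pytest.approx(1.0, abs=0.1)
        assert not rep.loc["GENE1", "flagged"]

    def test_doubled_female_effect_flagged(self, rng):
        expr, meta = self.make_cohort(3.0, 6.0, rng)
        rep = sex_stratified_fc(expr, meta, ["GENE1"])
        assert rep.loc["GENE1", "sex_ratio"] == pytest.approx(2.0, abs=0.2)
        assert rep.loc["GENE1", "flagged"]  # exceeds the 1.4 reporting ratio

    def test_empty_stratum_undefined_not_flagged(self, rng):
        expr, meta = self.make_cohort(3.0, 3.0, rng)
        meta = meta[meta["sex"] == "female"]
        expr = expr[meta.index]
        with pytest.warns(UserWarning, match="male stratum"):
            rep = sex_stratified_fc(expr, meta, ["GENE1"])
        assert np.isnan(rep.loc["GENE1", "fc_male"])
        assert not rep.loc["GENE1", "flagged"]


class TestAgeCorrelation:
    def make_aged(self, slope, rng, n=120, noise=1.0):
        age = rng.uniform(10, 80, n)
        expr = pd.DataFrame([8.0 + slope * age + rng.normal(0, noise, n)],
                            index=["NELL2"], columns=[f"s{i}" for i in range(n)])
        meta = pd.DataFrame({"group": ["case"] * n, "class_label": ["x"] * n,
                             "age": age},
                            index=pd.Index(expr.columns, name="sample_id"))
        return expr, meta

    def test_independent_expression_near_zero(self, rng):
        expr, meta = self.make_aged(0.0, rng, n=500)
        pcc = age_correlation(expr, meta, ["NELL2"])
        assert abs(pcc["NELL2"]) < 0.1

    def test_planted_decline_in_reported_weak_band(self, rng):
        # slope/noise chosen so the population pcc is ~-0.37 (weak band);
        # n large enough that sampling error stays inside the band
        expr, meta = self.make_aged(-0.02, rng, n=1000, noise=1.0)
        pcc = age_correlation(expr, meta, ["NELL2"])
        assert -0.47 <= pcc["NELL2"] <= -0.29

    def test_invariant_to_affine_age_rescale(self, rng):
        expr, meta = self.make_aged(-0.02, rng)
        base = age_correlation(expr, meta, ["NELL2"])
        meta2 = meta.copy()
        meta2["age"] = meta2["age"] * 12 + 3  # months, offset
        rescaled = age_correlation(expr, meta2, ["NELL2"])
        assert base["NELL2"] == pytest.approx(rescaled["NELL2"], abs=1e-12)

    def test_constant_age_rejected(self, rng):
        expr, meta = self.make_aged(0.0, rng, n=10)
        meta["age"] = 42.0
        with pytest.raises(ValueError, match="constant"):
            age_correlation(expr, meta, ["NELL2"])
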