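import numpy as np
import pandas as pd
import pytest

from bloodpanel.panels import (
    SelectionRules,
    build_panel,
    find_specific_genes,
    frequency_table,
    select_brgs,
    select_candidates,
    select_vrgs,
)


def freq_from(fc_dict):
    """fc_dict: gene -> list of per-dataset FCs (dataset ids d0, d1, ...)."""
    n = len(next(iter(fc_dict.values())))
    by_ds = {
        f"d{j}": pd.Series({g: v[j] for g, v in fc_dict.items()})
        for j in range(n)
    }
    return frequency_table(by_ds)


class TestFrequencyTable:
    def test_threshold_counting(self):
        freq = freq_from({"GA": [2.5, 0.4, 1.1]})
        assert freq.n_significant["GA"] == 2
        assert freq.n_up["GA"] == 1 and freq.n_down["GA"] == 1

    def test_never_significant(self):
        freq = freq_from({"GA": [1.2, 0.8, 1.9]})
        assert freq.n_significant["GA"] == 0

    def test_counts_sum_invariant(self, rng):
        fc = {f"G{i}": list(rng.uniform(0.2, 5.0, size=8)) for i in range(30)}
        freq = freq_from(fc)
        assert (freq.n_up + freq.n_down).equals(freq.n_significant)

    def test_planted_frequency(self):
        vals = [4.0] * 12 + [1.0] * 8
        freq = freq_from({"GX": vals, "GY": [1.0] * 20})
        assert freq.n_significant["GX"] == 12

    def test_permutation_invariant_over_dataset_order(self, rng):
        fc = {f"G{i}": list(rng.uniform(0.2, 5.0, size=6)) for i in range(10)}
        by_ds = {f"d{j}": pd.Series({g: v[j] for g, v in fc.items()}) for j in range(6)}
        a = frequency_table(by_ds)
        rev = dict(reversed(list(by_ds.items())))
        b = frequency_table(rev)
        assert a.n_significant.equals(b.n_significant)


class TestSelectCandidates:
    def test_at_least_eight_boundary(self):
        freq = freq_from({
            "IN8": [3.0] * 8 + [1.0] * 12,
            "OUT7": [3.0] * 7 + [1.0] * 13,
        })
        assert select_candidates(freq) == ["IN8"]

    def test_fifty_five_gene_construction(self, rng):
        fc = {}
        for i in range(55):
            fc[f"HIT{i:02d}"] = [4.0] * 9 + [1.0] * 11
        for i in range(45):
            fc[f"BG{i:02d}"] = [4.0] * 5 + [1.0] * 15
        freq = freq_from(fc)
        assert len(select_candidates(freq)) == 55

    def test_empty_result_warns(self):
        freq = freq_from({"GA": [1.0] * 8})
        with pytest.warns(UserWarning, match="no candidate"):
            assert select_candidates(freq) == []


def panel_freq():
    """20 datasets: d0-d3 viral, d4-d7 bacterial, d8-d19 mixed.

    10 V-genes high in viral + 6 mixed; 12 B-genes with graded bacterial FC.
    """
    fc = {}
    for i in range(10):
        viral_fc = 17.0 - i  # distinct viral means 17..8
        fc[f"V{i:02d}"] = [viral_fc] * 4 + [1.1] * 4 + [3.0] * 6 + [1.0] * 6
    # bacterial genes: 5 high (mean > 8), 5 mid [5,8] with n_sig 10,
    # 1 rescue (low bacterial FC but 13 significant), 1 near-miss mid with n_sig 9
    for i in range(5):
        fc[f"BH{i}"] = [1.1] * 4 + [9.1 + i] * 4 + [3.0] * 6 + [1.0] * 6
    for i in range(5):
        fc[f"BM{i}"] = [1.1] * 4 + [6.0 + 0.1 * i] * 4 + [3.0] * 6 + [1.0] * 6
    fc["RESCUE"] = [1.1] * 4 + [3.0] * 4 + [3.0] * 9 + [1.0] * 3
    fc["NEARMISS"] = [1.1] * 4 + [6.0] * 4 + [3.0] * 1 + [1.0] * 11
    for i in range(20):
        fc[f"BG{i:02d}"] = [1.0] * 20
    return frequency_table({
        f"d{j}": pd.Series({g: v[j] for g, v in fc.items()}) for j in range(20)
    })


VIRAL = [f"d{j}" for j in range(4)]
BACT = [f"d{j}" for j in range(4, 8)]


class TestVrgSelection:
    def test_top_ten_by_viral_mean_fc(self):
        freq = panel_freq()
        cands = select_candidates(freq)
        vrg = select_vrgs(freq, cands, VIRAL)
        assert vrg == [f"V{i:02d}" for i in range(10)]

    def test_tie_broken_by_frequency_then_name(self):
        fc = {
            "TIE_B": [5.0] * 4 + [1.0] * 4 + [3.0] * 6 + [1.0] * 6,
            "TIE_A": [5.0] * 4 + [1.0] * 4 + [3.0] * 4 + [1.0] * 8,
        }
        freq = frequency_table({
            f"d{j}": pd.Series({g: v[j] for g, v in fc.items()}) for j in range(20)
        })
        rules = SelectionRules(n_viral_top=2)
        got = select_vrgs(freq, list(fc), VIRAL, rules)
        # equal mean viral FC: TIE_B has more significant datasets
        assert got == ["TIE_B", "TIE_A"]

    def test_short_pool_warns(self):
        freq = panel_freq()
        with pytest.warns(UserWarning, match="viral candidates"):
            got = select_vrgs(freq, ["V00", "V01"], VIRAL)
        assert got == ["V00", "V01"]


class TestBrgSelection:
    def test_rules_cover_high_mid_and_rescue(self):
        freq = panel_freq()
        cands = select_candidates(freq)
        vrg = select_vrgs(freq, cands, VIRAL)
        rules = SelectionRules(exclude=("BM0",))  # the manual deselection step
        brg = select_brgs(freq, cands, BACT, rules, already_selected=vrg)
        assert len(brg) == 10
        assert set(f"BH{i}" for i in range(5)) <= set(brg)
        assert "RESCUE" in brg
        assert "NEARMISS" not in brg  # mid-range FC but only 9 significant...
        assert "BM0" not in brg  # excluded by override
        assert set(brg) & {f"BM{i}" for i in range(1, 5)} == {f"BM{i}" for i in range(1, 5)}

    def test_mid_range_needs_ten_datasets(self):
        freq = panel_freq()
        cands = select_candidates(freq)
        brg = select_brgs(freq, cands, BACT, SelectionRules())
        assert "NEARMISS" not in brg

    def test_disjoint_from_vrgs(self):
        freq = panel_freq()
        cands = select_candidates(freq)
        vrg = select_vrgs(freq, cands, VIRAL)
        brg = select_brgs(freq, cands, BACT, already_selected=vrg)
        assert not set(vrg) & set(brg)

    def test_include_override_forces_candidate_gene(self):
        # WEAK is a candidate (10 significant datasets) but fails every
        # bacterial FC rule; an include override pulls it in anyway
        fc = {
            "WEAK": [1.1] * 4 + [3.0] * 4 + [3.0] * 6 + [1.0] * 6,
            "FILLER": [1.1] * 4 + [4.0] * 4 + [3.0] * 6 + [1.0] * 6,
        }
        for i in range(5):
            fc[f"BH{i}"] = [1.1] * 4 + [9.1 + i] * 4 + [3.0] * 6 + [1.0] * 6
        freq = frequency_table({
            f"d{j}": pd.Series({g: v[j] for g, v in fc.items()}) for j in range(20)
        })
        cands = select_candidates(freq)
        # without the override, padding prefers FILLER (higher bacterial FC)
        brg_no = select_brgs(freq, cands, BACT, SelectionRules(n_bacterial=6))
        assert "FILLER" in brg_no and "WEAK" not in brg_no
        brg = select_brgs(freq, cands, BACT, SelectionRules(n_bacterial=6, include=("WEAK",)))
        assert "WEAK" in brg and "FILLER" not in brg


class TestBuildPanel:
    def test_panel_with_provenance(self):
        freq = panel_freq()
        panel = build_panel(freq, VIRAL, BACT, SelectionRules(exclude=("BM0",)))
        assert len(panel.vrg) == 10 and len(panel.brg) == 10
        prov = panel.provenance["V00"]
        assert prov["panel"] == "vrg"
        assert prov["mean_fc_viral"] == pytest.approx(17.0)
        assert prov["n_significant"] == 10


class TestSpecificGenes:
    def test_target_only_gene_found(self):
        fc = {
            "SPECIFIC": [4.0, 4.0, 4.0] + [1.0] * 17,
            "PARTIAL": [4.0, 4.0, 1.0] + [1.0] * 17,
            "COMMON": [4.0] * 20,
        }
        freq = frequency_table({
            f"d{j}": pd.Series({g: v[j] for g, v in fc.items()}) for j in range(20)
        })
        hits = find_specific_genes(freq, ["d0", "d1", "d2"], max_background_count=0)
        assert hits == ["SPECIFIC"]

    def test_background_tolerance(self):
        fc = {"G1": [4.0] * 3 + [4.0] * 2 + [1.0] * 15}
        freq = frequency_table({
            f"d{j}": pd.Series({g: v[j] for g, v in fc.items()}) for j in range(20)
        })
        assert find_specific_genes(freq, ["d0", "d1", "d2"], 1) == []
        assert find_specific_genes(freq, ["d0", "d1", "d2"], 2) == ["G1"]
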