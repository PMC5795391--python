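import itertools

import numpy as np
import pandas as pd
import pytest

from asciteome.calls import (
    abundant_media_table,
    assign_tier,
    call_celltype_selective,
    call_expressed_protein,
    call_expressed_rna,
    call_secretome_detected,
    call_tiers,
    permutation_fold_change_test,
    venn_partition,
)
from asciteome.containers import Layer

from conftest import make_annotation, make_matrix


def _three_types(n_per=3):
    samples, cts = [], []
    for ct in ("TU", "TAM", "TAT"):
        for i in range(n_per):
            samples.append(f"{ct}{i}")
            cts.append(ct)
    return samples, cts


class TestExpressedProtein:
    def test_uniform_matrix_nothing_expressed(self):
        samples, cts = _three_types(2)
        m = make_matrix(np.full((4, 6), 7.0), samples=samples)
        calls, thr = call_expressed_protein(m, make_annotation(samples, cts))
        assert thr == 7.0
        assert not calls.to_numpy().any()  # strict >

    def test_median_above_threshold_is_expressed(self):
        samples, cts = _three_types(3)
        vals = np.full((2, 9), 4e7)
        vals[0, :3] = 6e7  # TU median 6e7
        m = make_matrix(vals, samples=samples)
        calls, thr = call_expressed_protein(m, make_annotation(samples, cts))
        assert thr < 6e7
        assert calls.loc["g0", "TU"]

    def test_matches_sort_based_oracle(self, rng):
        samples, cts = _three_types(3)
        vals = rng.lognormal(17, 2, size=(300, 9))
        m = make_matrix(vals, samples=samples)
        ann = make_annotation(samples, cts)
        calls, thr = call_expressed_protein(m, ann, quantile=0.25)
        assert thr == pytest.approx(np.quantile(vals, 0.25))
        for gi, g in enumerate(m.gene_ids):
            for ct, cols in (("TU", [0, 1, 2]), ("TAM", [3, 4, 5]), ("TAT", [6, 7, 8])):
                med = float(np.median(vals[gi, cols]))
                assert calls.loc[g, ct] == (med > thr)


class TestVennPartition:
    def test_everywhere_expressed_center_only(self):
        calls = pd.DataFrame({"TU": [True], "TAM": [True], "TAT": [True]})
        counts = venn_partition(calls)
        assert counts["TU&TAM&TAT"] == 1
        assert sum(counts.values()) == 1

    def test_two_region_example(self):
        calls = pd.DataFrame({"TU": [True, True], "TAM": [False, True],
                              "TAT": [False, False]}, index=["A", "B"])
        counts = venn_partition(calls)
        assert counts["TU"] == 1 and counts["TU&TAM"] == 1

    def test_matches_truth_table_oracle(self, rng):
        calls = pd.DataFrame(rng.random((1000, 3)) < 0.5, columns=["TU", "TAM", "TAT"])
        counts = venn_partition(calls)
        oracle = {}
        for tu, tam, tat in itertools.product([False, True], repeat=3):
            if not (tu or tam or tat):
                continue
            key = "&".join(n for n, f in zip(("TU", "TAM", "TAT"), (tu, tam, tat)) if f)
            oracle[key] = int(((calls["TU"] == tu) & (calls["TAM"] == tam)
                               & (calls["TAT"] == tat)).sum())
        assert counts == oracle
        assert sum(counts.values()) == int(calls.any(axis=1).sum())


class TestCelltypeSelective:
    def _calls(self, medians, fold=5.0):
        # one sample per cell type -> median == value
        samples = ["TU0", "TAM0", "TAT0"]
        m = make_matrix(np.asarray([medians]), samples=samples)
        ann = make_annotation(samples, ["TU", "TAM", "TAT"])
        return call_celltype_selective(m, ann, fold=fold).iloc[0]

    def test_equal_medians_all_expressed(self):
        c = self._calls([6e7, 6e7, 6e7])
        assert c["TU"] and c["TAM"] and c["TAT"]

    def test_crosscontamination_guard(self):
        c = self._calls([6e7, 4e8, 0.0])  # TAM > 5x TU
        assert not c["TU"] and c["TAM"] and not c["TAT"]

    def test_within_fold_kept(self):
        c = self._calls([6e7, 2e8, 0.0])
        assert c["TU"] and c["TAM"]

    def test_matches_direct_rule_oracle(self, rng):
        samples, cts = _three_types(3)
        ann = make_annotation(samples, cts)
        for _ in range(20):
            vals = rng.lognormal(17.5, 1.5, size=(40, 9))
            m = make_matrix(vals, samples=samples)
            calls = call_celltype_selective(m, ann)
            meds = {ct: np.median(vals[:, cols], axis=1)
                    for ct, cols in (("TU", [0, 1, 2]), ("TAM", [3, 4, 5]), ("TAT", [6, 7, 8]))}
            for gi in range(40):
                for ct in meds:
                    want = meds[ct][gi] > 5e7 and all(
                        meds[o][gi] <= 5.0 * meds[ct][gi] for o in meds if o != ct)
                    assert bool(calls.iloc[gi][ct]) == want


class TestPermutationFoldChange:
    def test_identical_groups_give_p_one(self):
        vals = np.tile(np.array([[1e8, 2e8, 3e8]]), (5, 2))
        m = make_matrix(vals, samples=[f"s{i}" for i in range(6)])
        res = permutation_fold_change_test(m, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert (res.table["p"] == 1.0).all()

    def test_exhaustive_for_three_vs_three(self, rng):
        m = make_matrix(rng.lognormal(18, 1, size=(30, 6)),
                        samples=[f"s{i}" for i in range(6)])
        res = permutation_fold_change_test(m, ["s0", "s1", "s2"], ["s3", "s4", "s5"],
                                           iters=1000)
        assert res.exhaustive and res.n_permutations == 20
        assert set(np.round(res.table["p"] * 20).astype(int)) <= set(range(1, 21))

    def test_sampled_matches_exhaustive_within_mc_error(self, rng):
        m = make_matrix(rng.lognormal(18, 1.5, size=(40, 6)),
                        samples=[f"s{i}" for i in range(6)])
        a, b = ["s0", "s1", "s2"], ["s3", "s4", "s5"]
        ex = permutation_fold_change_test(m, a, b, iters=1000)
        sm = permutation_fold_change_test(m, a, b, iters=4000, seed=3,
                                          method="sampled")
        assert not sm.exhaustive
        # 3-sigma Monte-Carlo bound on the add-one estimate
        se = np.sqrt(ex.table["p"] * (1 - ex.table["p"]) / 4000) + 1e-3
        assert (np.abs(sm.table["p"] - ex.table["p"]) <= 3 * se + 3e-3).all()

    def test_fold_change_is_median_ratio(self):
        vals = np.array([[100.0, 100, 100, 50, 50, 50]])
        m = make_matrix(vals, samples=[f"s{i}" for i in range(6)])
        res = permutation_fold_change_test(m, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert res.table["fold_change"].iloc[0] == pytest.approx(2.0)

    def test_degenerate_groups_error(self):
        m = make_matrix(np.ones((3, 4)), samples=list("abcd"))
        with pytest.raises(ValueError, match=">= 2"):
            permutation_fold_change_test(m, ["a"], ["b", "c", "d"])


class TestRnaCallsAndTiers:
    @pytest.mark.parametrize("median,frac,tier", [
        (60.0, 1.0, "high"),
        (51.0, 1.0, "high"),
        (50.0, 1.0, "intermediate"),
        (11.0, 1.0, "intermediate"),
        (3.0, 1.0, "low"),
        (2.0, 0.0, "none"),          # boundary is strict
        (1.0, 1 / 29, "sporadic"),   # rare but present
        (1.0, 0.0, "none"),
        (1.0, 0.2, "none"),          # too widespread for sporadic, too low for a tier
    ])
    def test_tier_assignment(self, median, frac, tier):
        assert assign_tier(median, frac) == tier

    def test_tier_monotone_in_median(self):
        order = ["none", "low", "intermediate", "high"]
        tiers = [assign_tier(m, 0.0) for m in (1, 5, 20, 100)]
        assert [order.index(t) for t in tiers] == sorted(order.index(t) for t in tiers)

    def test_expressed_rna_threshold(self):
        samples, cts = _three_types(1)
        vals = np.array([[5.0, 1.0, 2.0]] * 1)
        m = make_matrix(np.tile(vals, (1, 3))[:, :3], samples=samples, layer=Layer.TPM)
        calls = call_expressed_rna(m, make_annotation(samples, cts))
        assert calls.loc["g0", "TU"] and not calls.loc["g0", "TAM"]
        assert calls.loc["g0", "TAT"]  # 2.0 >= min TPM of 2

    def test_call_tiers_table(self, rng):
        samples, cts = _three_types(5)
        vals = rng.lognormal(1, 2, size=(50, 15))
        m = make_matrix(vals, samples=samples, layer=Layer.TPM)
        tiers = call_tiers(m, make_annotation(samples, cts))
        for ct, cols in (("TU", range(0, 5)), ("TAM", range(5, 10))):
            sub = vals[:, list(cols)]
            for gi in range(50):
                want = assign_tier(float(np.median(sub[gi])), float((sub[gi] > 3).mean()))
                assert tiers.iloc[gi][ct] == want


class TestMedia:
    def _media(self, present_pattern):
        samples = [f"TU{i}" for i in range(5)]
        vals = np.asarray([[10.0 if p else 0.0 for p in present_pattern]])
        m = make_matrix(vals, samples=samples, layer=Layer.MEDIA)
        ann = make_annotation(samples, ["TU"] * 5, assay="secretome_media")
        return m, ann

    def test_three_of_five_detected(self):
        m, ann = self._media([1, 1, 1, 0, 0])
        assert call_secretome_detected(m, ann).loc["g0", "TU"]

    def test_two_of_five_not_detected(self):
        m, ann = self._media([1, 1, 0, 0, 0])
        assert not call_secretome_detected(m, ann).loc["g0", "TU"]

    def test_all_zero_not_detected(self):
        m, ann = self._media([0, 0, 0, 0, 0])
        assert not call_secretome_detected(m, ann).loc["g0", "TU"]

    def test_abundant_requires_both_filters(self, rng):
        samples = [f"TU{i}" for i in range(4)]
        ann = make_annotation(samples, ["TU"] * 4, assay="secretome_media")
        vals = rng.lognormal(15, 2, size=(60, 4))
        vals[rng.random(vals.shape) < 0.4] = 0.0
        m = make_matrix(vals, samples=samples, layer=Layer.MEDIA)
        table = abundant_media_table(m, ann)
        meds = np.median(vals, axis=1)
        med_of_meds = np.median(meds)
        expected = {
            g for g, row, med in zip(m.gene_ids, vals, meds)
            if (row > 0).mean() >= 0.5 and med > med_of_meds
        }
        assert set(table["gene_id"]) == expected
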