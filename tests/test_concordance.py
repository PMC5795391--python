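import numpy as np
import pandas as pd
import pytest
from scipy import stats

from asciteome.concordance import (
    detection_curve,
    detection_deficit_pvalue,
    gene_concordance,
)
from asciteome.containers import Layer

from conftest import make_matrix


def _pairing(n):
    return {f"s{i}": f"t{i}" for i in range(n)}


def _layers(lfq_vals, tpm_vals):
    lfq = make_matrix(lfq_vals, samples=[f"s{i}" for i in range(np.shape(lfq_vals)[1])])
    tpm = make_matrix(tpm_vals, samples=[f"t{i}" for i in range(np.shape(tpm_vals)[1])],
                      layer=Layer.TPM)
    return lfq, tpm


class TestGeneConcordance:
    def test_monotone_gene_has_rho_one(self):
        tpm = [[1, 2, 3, 4, 5]]
        lfq = [[2, 4, 6, 8, 10]]
        res = gene_concordance(*_layers(lfq, tpm), _pairing(5))
        assert res.per_gene["rho"].iloc[0] == pytest.approx(1.0)
        assert res.fraction_positive == 1.0

    def test_antimonotone_gene_has_rho_minus_one(self):
        res = gene_concordance(*_layers([[10, 8, 6, 4, 2]], [[1, 2, 3, 4, 5]]),
                               _pairing(5))
        assert res.per_gene["rho"].iloc[0] == pytest.approx(-1.0)

    def test_ties_match_scipy_oracle(self, rng):
        lfq_v = rng.integers(0, 4, size=(40, 6)).astype(float)
        tpm_v = rng.integers(0, 4, size=(40, 6)).astype(float)
        res = gene_concordance(*_layers(lfq_v, tpm_v), _pairing(6))
        for i in range(40):
            want = stats.spearmanr(lfq_v[i], tpm_v[i]).statistic
            got = res.per_gene["rho"].iloc[i]
            if np.isnan(want):
                assert not res.per_gene["defined"].iloc[i]
            else:
                assert got == pytest.approx(want, abs=1e-12)

    def test_zero_variance_gene_undefined_and_excluded(self):
        res = gene_concordance(*_layers([[5, 5, 5, 5, 5], [1, 2, 3, 4, 5]],
                                        [[1, 2, 3, 4, 5], [1, 2, 3, 4, 5]]),
                               _pairing(5))
        assert res.n_undefined == 1 and res.n_defined == 1
        assert res.median_rho == pytest.approx(1.0)

    def test_too_few_pairs_errors(self):
        with pytest.raises(ValueError, match=">=3"):
            gene_concordance(*_layers([[1, 2]], [[1, 2]]), _pairing(2))

    def test_sign_fractions_sum_to_one(self, rng):
        res = gene_concordance(*_layers(rng.random((100, 6)), rng.random((100, 6))),
                               _pairing(6))
        total = res.fraction_positive + res.fraction_negative + res.fraction_zero
        assert total == pytest.approx(1.0)


class TestDetectionCurve:
    def test_all_detected_fraction_one(self):
        genes = ["a", "b", "c"]
        c = detection_curve(genes, dict.fromkeys(genes, True),
                            {"a": 1.0, "b": 10.0, "c": 100.0})
        frac = c.table["fraction_detected"].dropna()
        assert (frac == 1.0).all()

    def test_none_detected_fraction_zero(self):
        genes = ["a", "b"]
        c = detection_curve(genes, dict.fromkeys(genes, False), {"a": 1.0, "b": 2.0})
        assert (c.table["fraction_detected"].dropna() == 0.0).all()

    def test_matches_double_loop_oracle(self, rng):
        genes = [f"g{i}" for i in range(300)]
        tpm = pd.Series(rng.lognormal(0, 2, 300), index=genes)
        det = pd.Series(rng.random(300) < 0.6, index=genes)
        grid = np.geomspace(tpm.min(), tpm.max(), 12)
        c = detection_curve(genes, det, tpm, grid=grid)
        for k, t in enumerate(grid):
            rem = sum(1 for g in genes if tpm[g] >= t)
            ndet = sum(1 for g in genes if tpm[g] >= t and det[g])
            assert c.table["n_remaining"].iloc[k] == rem
            assert c.table["n_detected"].iloc[k] == ndet

    def test_remaining_non_increasing(self, rng):
        genes = [f"g{i}" for i in range(50)]
        tpm = pd.Series(rng.lognormal(0, 1, 50), index=genes)
        det = pd.Series(rng.random(50) < 0.5, index=genes)
        c = detection_curve(genes, det, tpm)
        assert (np.diff(c.table["n_remaining"]) <= 0).all()

    def test_empty_gene_set_errors(self):
        with pytest.raises(ValueError, match="empty"):
            detection_curve([], {}, {})


class TestDetectionDeficit:
    def _universe(self, rng, n=800, deficit_idx=None, odds_factor=1.0):
        genes = [f"g{i}" for i in range(n)]
        lntpm = rng.normal(0.5, 1.8, n)
        logit = lntpm / 1.1
        if deficit_idx is not None:
            logit = logit.copy()
            logit[deficit_idx] -= np.log(odds_factor)
        det = rng.random(n) < 1 / (1 + np.exp(-logit))
        return genes, pd.Series(det, index=genes), pd.Series(np.exp(lntpm), index=genes)

    def test_query_equals_universe_gives_p_one(self, rng):
        genes, det, tpm = self._universe(rng, n=100)
        res = detection_deficit_pvalue(genes, genes, det, tpm, n_draws=50, seed=1)
        assert res.pvalue == 1.0

    def test_query_larger_than_universe_errors(self, rng):
        genes, det, tpm = self._universe(rng, n=50)
        with pytest.raises(ValueError, match="outside universe"):
            detection_deficit_pvalue(genes + ["extra"], genes, det, tpm, n_draws=10)

    def test_planted_deficit_beats_random_query(self, rng):
        genes, det, tpm = self._universe(rng, n=2000)
        idx = rng.choice(2000, 150, replace=False)
        genes2, det2, tpm2 = self._universe(rng, n=2000, deficit_idx=idx, odds_factor=8.0)
        deficit_p = detection_deficit_pvalue([genes2[i] for i in idx], genes2, det2,
                                             tpm2, n_draws=500, seed=2).pvalue
        rand_q = [genes[i] for i in rng.choice(2000, 150, replace=False)]
        null_p = detection_deficit_pvalue(rand_q, genes, det, tpm,
                                          n_draws=500, seed=3).pvalue
        assert deficit_p < 0.1 < null_p

    def test_deterministic_given_seed(self, rng):
        genes, det, tpm = self._universe(rng, n=300)
        q = genes[:50]
        a = detection_deficit_pvalue(q, genes, det, tpm, n_draws=200, seed=11).pvalue
        b = detection_deficit_pvalue(q, genes, det, tpm, n_draws=200, seed=11).pvalue
        assert a == b

    def test_floor_reported_below_resolution(self, rng):
        genes, det, tpm = self._universe(rng, n=2000)
        idx = np.arange(150)
        genes2, det2, tpm2 = self._universe(rng, n=2000, deficit_idx=idx, odds_factor=50.0)
        res = detection_deficit_pvalue([genes2[i] for i in idx], genes2, det2, tpm2,
                                       n_draws=300, seed=5)
        if res.is_floor:
            assert res.pvalue == 0.0 and res.p_string.startswith("<")

    def test_ties_rule_never_smaller_than_strict(self, rng):
        genes, det, tpm = self._universe(rng, n=500)
        q = genes[:80]
        strict = detection_deficit_pvalue(q, genes, det, tpm, n_draws=200, seed=9).pvalue
        ties = detection_deficit_pvalue(q, genes, det, tpm, n_draws=200, seed=9,
                                        tie_rule="ties").pvalue
        assert ties >= strict
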