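import numpy as np
import pandas as pd
import pytest
from scipy import stats

from asciteome.containers import Layer
from asciteome.coexpression import (
    coexpress_with_surrogate,
    matched_pair_coexpression,
    minmax_scale_rows,
    precog_surrogate_groups,
    surrogate_score,
)

from conftest import make_matrix


def _tam_matrix(rows, genes, n=29):
    return make_matrix(np.asarray(rows), genes=genes,
                       samples=[f"TAM{i}" for i in range(n)], layer=Layer.TPM)


class TestSurrogateScore:
    def test_identical_markers_reproduce_marker_ranks(self, rng):
        v = rng.lognormal(3, 1, 29)
        m = _tam_matrix([v, v], ["CD163", "MRC1"])
        score = surrogate_score(m)
        np.testing.assert_allclose(score.to_numpy(), stats.rankdata(v))

    def test_anticorrelated_markers_near_constant(self):
        v = np.arange(1.0, 30.0)
        m = _tam_matrix([v, v[::-1]], ["CD163", "MRC1"])
        score = surrogate_score(m)
        assert score.std() == pytest.approx(0.0)

    def test_matches_independent_rank_mean_oracle(self, rng):
        a, b = rng.lognormal(3, 1, 29), rng.lognormal(3, 1, 29)
        m = _tam_matrix([a, b], ["CD163", "MRC1"])
        score = surrogate_score(m)
        oracle = (stats.rankdata(a) + stats.rankdata(b)) / 2.0
        assert list(np.argsort(score.to_numpy())) == list(np.argsort(oracle))

    def test_missing_marker_errors(self, rng):
        m = _tam_matrix([rng.random(29)], ["CD163"])
        with pytest.raises(ValueError, match="MRC1"):
            surrogate_score(m)


class TestCoexpressionScreen:
    def _score(self, n=29):
        return pd.Series(np.arange(n, dtype=float), index=[f"TAM{i}" for i in range(n)])

    def test_candidate_equal_to_score_is_perfect_hit(self):
        score = self._score()
        m = _tam_matrix([score.to_numpy()], ["X"])
        hits, table = coexpress_with_surrogate(m, score, ["X"])
        assert hits[0].direction == "positive"
        assert hits[0].rho == pytest.approx(1.0)

    def test_null_genes_rarely_cross_thresholds(self, rng):
        score = self._score()
        vals = rng.random((1000, 29))
        m = _tam_matrix(vals, [f"n{i}" for i in range(1000)])
        hits, _ = coexpress_with_surrogate(m, score, list(m.gene_ids))
        assert len(hits) / 1000 < 0.02

    def test_planted_candidates_recovered(self, rng):
        score = self._score()
        base = stats.zscore(score.to_numpy())
        recovered = 0
        for rep in range(200):
            cand = 0.813 * base + np.sqrt(1 - 0.813**2) * rng.normal(size=29)
            m = _tam_matrix([cand - cand.min() + 0.1], ["planted"])
            hits, _ = coexpress_with_surrogate(m, score, ["planted"])
            recovered += bool(hits and hits[0].direction == "positive")
        assert recovered / 200 >= 0.95

    def test_constant_candidate_skipped(self, rng):
        score = self._score()
        m = _tam_matrix([np.full(29, 3.0)], ["flat"])
        hits, table = coexpress_with_surrogate(m, score, ["flat"])
        assert hits == [] and table.empty


class TestMatchedPair:
    def _setup(self, tu_vals, n=10):
        tu_samples = [f"TU{i}" for i in range(n)]
        tam_samples = [f"TAM{i}" for i in range(n)]
        patients = {s: f"P{i}" for i, s in enumerate(tu_samples)}
        patients.update({s: f"P{i}" for i, s in enumerate(tam_samples)})
        score = pd.Series(np.arange(n, dtype=float), index=tam_samples)
        m = make_matrix(np.asarray(tu_vals), genes=["X"], samples=tu_samples,
                        layer=Layer.TPM)
        return m, score, patients

    def test_exact_tracker_rho_one(self):
        m, score, pat = self._setup([np.arange(10.0) + 1])
        hits, _ = matched_pair_coexpression(m, score, pat, pat)
        assert hits[0].rho == pytest.approx(1.0)
        assert hits[0].direction == "positive"

    def test_inverse_tracker(self):
        m, score, pat = self._setup([np.arange(10.0, 0.0, -1.0)])
        hits, _ = matched_pair_coexpression(m, score, pat, pat)
        assert hits[0].rho == pytest.approx(-1.0)
        assert hits[0].direction == "inverse"

    def test_matches_rank_formula_oracle(self, rng):
        vals = rng.lognormal(1, 1, size=(20, 10))
        tu_samples = [f"TU{i}" for i in range(10)]
        m, score, pat = self._setup(vals[:1])
        m = make_matrix(vals, genes=[f"g{i}" for i in range(20)],
                        samples=tu_samples, layer=Layer.TPM)
        _, table = matched_pair_coexpression(m, score, pat, pat,
                                             pos_thr=0.1, neg_thr=-0.1)
        for _, row in table.iterrows():
            want = stats.spearmanr(
                m.data.loc[row["gene_id"]].to_numpy(), score.to_numpy()).statistic
            assert row["rho"] == pytest.approx(want, abs=1e-12)

    def test_unmatched_samples_dropped(self, rng):
        vals = rng.random((1, 12))
        tu_samples = [f"TU{i}" for i in range(12)]
        m = make_matrix(vals, genes=["X"], samples=tu_samples, layer=Layer.TPM)
        tam_samples = [f"TAM{i}" for i in range(10)]
        score = pd.Series(np.arange(10.0), index=tam_samples)
        pat = {f"TU{i}": f"P{i}" for i in range(12)}
        pat.update({f"TAM{i}": f"P{i}" for i in range(10)})
        hits, table = matched_pair_coexpression(m, score, pat, pat,
                                                pos_thr=0.99, neg_thr=-0.99)
        assert len(table) == 1  # ran on the 10 matched pairs


class TestSurrogateGroups:
    def _proteome(self, rng, blocks, n_extra=150, n_samples=12, noise=0.0):
        rows, genes = [], []
        z = {}
        for bi, size in enumerate(blocks):
            profile = rng.normal(size=n_samples)
            for m in range(size):
                g = f"B{bi}_{m}"
                genes.append(g)
                rows.append(18 + rng.uniform(0.8, 2.0) * profile
                            + rng.normal(0, noise, n_samples))
                z[g] = 5.0 if bi % 2 == 0 else -5.0
        for i in range(n_extra):
            g = f"E{i}"
            genes.append(g)
            rows.append(rng.normal(18, 1, n_samples))
            z[g] = float(rng.normal(0, 1.5))
        lfq = make_matrix(np.exp(np.asarray(rows)), genes=genes,
                          samples=[f"TU{i}_P" for i in range(n_samples)])
        # mRNA mirrors protein so the concordance filter passes
        tpm = make_matrix(np.exp(np.asarray(rows) - 16), genes=genes,
                          samples=[f"TU{i}_R" for i in range(n_samples)],
                          layer=Layer.TPM)
        pairing = {f"TU{i}_P": f"TU{i}_R" for i in range(n_samples)}
        return lfq, tpm, pd.Series(z), pairing

    def test_duplicated_seed_profile_forms_one_group(self, rng):
        lfq, tpm, z, pairing = self._proteome(rng, [10], n_extra=50)
        merged, _ = precog_surrogate_groups(lfq, tpm, z, pairing=pairing)
        assert len(merged) == 1
        assert len(merged[0].members) == 10

    def test_two_disjoint_blocks_recovered(self, rng):
        lfq, tpm, z, pairing = self._proteome(rng, [10, 10])
        merged, premerge = precog_surrogate_groups(lfq, tpm, z, pairing=pairing)
        assert sorted(len(g.members) for g in merged) == [10, 10]
        assert len(premerge) == 20  # one retained neighborhood per seed

    def test_seven_gene_block_not_retained(self, rng):
        lfq, tpm, z, pairing = self._proteome(rng, [7])
        merged, _ = precog_surrogate_groups(lfq, tpm, z, pairing=pairing)
        assert merged == []

    def test_recovery_degrades_monotonically_with_noise(self, rng):
        sizes = []
        for noise in (0.0, 0.5, 2.0):
            ok = 0
            for rep in range(5):
                lfq, tpm, z, pairing = self._proteome(rng, [10], noise=noise)
                merged, _ = precog_surrogate_groups(lfq, tpm, z, pairing=pairing)
                ok += sum(len(g.members) for g in merged)
            sizes.append(ok)
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_minmax_scaling_does_not_change_membership(self, rng):
        lfq, tpm, z, pairing = self._proteome(rng, [10])
        scaled = minmax_scale_rows(lfq.data)
        assert ((scaled.max(axis=1) <= 1.0) & (scaled.min(axis=1) >= 0.0)).all()

    def test_no_seed_returns_empty(self, rng):
        lfq, tpm, z, pairing = self._proteome(rng, [], n_extra=30)
        merged, premerge = precog_surrogate_groups(lfq, tpm, z, pairing=pairing)
        assert merged == [] and premerge == []


class TestSpearmanInvariance:
    def test_invariant_under_monotone_transforms(self, rng):
        score = pd.Series(rng.random(20), index=[f"s{i}" for i in range(20)])
        vals = rng.lognormal(0, 1, size=(30, 20))
        m = make_matrix(vals, samples=list(score.index), layer=Layer.TPM)
        _, base = coexpress_with_surrogate(m, score, list(m.gene_ids),
                                           pos_thr=2, neg_thr=-2)
        m2 = make_matrix(np.exp(vals / vals.max()), samples=list(score.index),
                         layer=Layer.TPM)
        _, trans = coexpress_with_surrogate(m2, score.rank() ** 3, list(m.gene_ids),
                                            pos_thr=2, neg_thr=-2)
        np.testing.assert_allclose(base["rho"], trans["rho"], atol=1e-12)
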