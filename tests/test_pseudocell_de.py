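import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from explorekit.pseudocell_de import (
    NucleusCounts,
    PseudocellMatrix,
    background_genes,
    bh_adjust,
    build_pseudocells,
    call_trgs,
    cp100k_log2,
    disruption_regression,
    moderated_t_de,
    read_counts,
    rob_scores,
    trg_correlation,
    write_counts,
)
from explorekit.synthetic_data import CountsSpec, gen_counts


def make_nuclei(counts, sample_ids, conditions, cell_type="neuron", pct_mt=None):
    counts = sp.csc_matrix(np.asarray(counts))
    n = counts.shape[1]
    meta = pd.DataFrame(
        {
            "cell_type": [cell_type] * n,
            "sample_id": sample_ids,
            "condition": conditions,
            "cre_status": ["n/a"] * n,
            "pct_mt": pct_mt if pct_mt is not None else np.linspace(1, 3, n),
            "n_genes": np.asarray((counts > 0).sum(axis=0)).ravel(),
        }
    )
    genes = np.array([f"g{i}" for i in range(counts.shape[0])])
    return NucleusCounts(counts=counts, genes=genes, meta=meta)


@pytest.fixture(scope="module")
def spiked_dataset():
    spec = CountsSpec(n_genes=1500, spike_fraction=0.05, seed=11)
    return gen_counts(spec)


class TestBuildPseudocells:
    def test_partition_arithmetic_and_conservation(self, rng):
        counts = rng.integers(0, 5, size=(50, 90))
        nuclei = make_nuclei(counts, ["sA"] * 90, ["T3"] * 90)
        pcs = build_pseudocells(nuclei, "neuron", seed=1, min_pseudocells=3)
        assert not pcs.excluded
        assert len(pcs.meta) == 3
        assert (pcs.meta["n_member_nuclei"] == 30).all()
        # column-wise count conservation
        assert pcs.counts.sum() == counts.sum()
        np.testing.assert_array_equal(
            np.asarray(pcs.counts.sum(axis=1)).ravel(), counts.sum(axis=1)
        )

    def test_cell_type_below_min_nuclei_excluded(self, rng):
        counts = rng.integers(0, 5, size=(20, 14))
        nuclei = make_nuclei(counts, ["sA"] * 14, ["T3"] * 14)
        pcs = build_pseudocells(nuclei, "neuron", seed=0)
        assert pcs.excluded and "14 nuclei" in pcs.exclusion_reason

    def test_too_few_pseudocells_excluded(self, rng):
        # 5 strata x 1 pseudocell each = 5 < 6
        counts = rng.integers(0, 5, size=(20, 100))
        sids = [f"s{i // 20}" for i in range(100)]
        conds = ["T3" if i < 60 else "control" for i in range(100)]
        nuclei = make_nuclei(counts, sids, conds)
        pcs = build_pseudocells(nuclei, "neuron", seed=0)
        assert pcs.excluded and "5 pseudocells" in pcs.exclusion_reason

    def test_every_pseudocell_meets_minimum(self, rng):
        counts = rng.integers(0, 3, size=(30, 400))
        sids = [f"s{i % 4}" for i in range(400)]
        conds = ["T3" if i % 4 < 2 else "control" for i in range(400)]
        nuclei = make_nuclei(counts, sids, conds)
        pcs = build_pseudocells(nuclei, "neuron", seed=5)
        assert (pcs.meta["n_member_nuclei"] >= 15).all()

    def test_seed_determinism(self, rng):
        counts = rng.integers(0, 5, size=(30, 120))
        nuclei = make_nuclei(counts, ["sA"] * 120, ["T3"] * 120)
        a = build_pseudocells(nuclei, "neuron", seed=9, min_pseudocells=2)
        b = build_pseudocells(nuclei, "neuron", seed=9, min_pseudocells=2)
        assert (a.counts != b.counts).nnz == 0


class TestBackgroundGenes:
    def test_two_percent_included(self):
        counts = np.zeros((1, 100))
        counts[0, :2] = 1
        nuclei = make_nuclei(counts, ["s"] * 100, ["T3"] * 100)
        assert background_genes(nuclei).tolist() == [True]

    def test_exactly_one_percent_excluded(self):
        counts = np.zeros((1, 100))
        counts[0, 0] = 1
        nuclei = make_nuclei(counts, ["s"] * 100, ["T3"] * 100)
        assert background_genes(nuclei).tolist() == [False]

    def test_empty_matrix(self):
        nuclei = make_nuclei(np.zeros((3, 10)), ["s"] * 10, ["T3"] * 10)
        assert background_genes(nuclei).sum() == 0


class TestBhAdjust:
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_matches_step_up_oracle(self, pvals):
        p = np.array(pvals)
        # brute-force step-up definition
        n = len(p)
        order = np.argsort(p, kind="mergesort")
        oracle = np.empty(n)
        running = 1.0
        for rank in range(n, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * n / rank)
            oracle[i] = running
        np.testing.assert_allclose(bh_adjust(p), oracle, rtol=1e-12)

    def test_monotone_with_p_ranks(self, rng):
        p = rng.random(200)
        fdr = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(fdr[order]) >= -1e-12).all()


class TestModeratedT:
    def _pseudocells(self, Y_counts, conditions, sample_ids=None):
        k = Y_counts.shape[1]
        meta = pd.DataFrame(
            {
                "sample_id": sample_ids if sample_ids is not None else [f"s{i}" for i in range(k)],
                "condition": conditions,
                "cre_status": ["n/a"] * k,
                "n_member_nuclei": [30] * k,
                "pct_mt": np.linspace(1, 2, k),
                "n_genes": (np.asarray(Y_counts) > 0).sum(axis=0),
            }
        )
        return PseudocellMatrix(
            counts=sp.csc_matrix(np.asarray(Y_counts)),
            genes=np.array([f"g{i}" for i in range(Y_counts.shape[0])]),
            meta=meta,
        )

    def test_shrinkage_disabled_equals_ordinary_t(self, rng):
        """Oracle: with d0=0 the moderated statistic must equal a plain OLS
        t-test on the same normalized data, gene by gene (statsmodels)."""
        import statsmodels.api as sm

        counts = rng.integers(0, 40, size=(60, 10))
        conds = ["T3"] * 5 + ["control"] * 5
        pcs = self._pseudocells(counts, conds)
        de = moderated_t_de(pcs, prior_df=0)
        Y = cp100k_log2(pcs.counts)
        X = np.column_stack(
            [
                np.ones(10),
                np.array([1.0 if c == "T3" else 0.0 for c in conds]),
                pcs.meta["pct_mt"].to_numpy(),
                np.log2(pcs.meta["n_genes"].to_numpy(float)),
            ]
        )
        kept = {g: i for i, g in enumerate(de["gene"])}
        for gi, gene in enumerate(pcs.genes):
            if gene not in kept or Y[gi].sum() == 0:
                continue
            fit = sm.OLS(Y[gi], X).fit()
            row = de.iloc[kept[gene]]
            assert row["log2fc"] == pytest.approx(fit.params[1], rel=1e-8)
            assert row["t_mod"] == pytest.approx(fit.tvalues[1], rel=1e-6)
            assert row["p"] == pytest.approx(fit.pvalues[1], rel=1e-6)

    def test_constant_covariate_dropped(self, rng):
        counts = rng.integers(0, 30, size=(40, 8))
        conds = ["T3"] * 4 + ["control"] * 4
        pcs = self._pseudocells(counts, conds)
        pcs.meta["pct_mt"] = 2.5  # constant
        de_with = moderated_t_de(pcs, prior_df=0)
        pcs2 = self._pseudocells(counts, conds)
        de_without = moderated_t_de(pcs2, covariates=("log2_n_genes",), prior_df=0)
        np.testing.assert_allclose(de_with["log2fc"], de_without["log2fc"], rtol=1e-10)

    def test_singular_design_raises(self, rng):
        counts = rng.integers(1, 30, size=(20, 6))
        conds = ["T3"] * 3 + ["control"] * 3
        pcs = self._pseudocells(counts, conds)
        pcs.meta["pct_mt"] = [1.0 if c == "T3" else 0.0 for c in conds]  # aliases condition
        with pytest.raises(np.linalg.LinAlgError):
            moderated_t_de(pcs, covariates=("pct_mt",))

    def test_requires_two_per_condition(self, rng):
        counts = rng.integers(0, 30, size=(20, 3))
        pcs = self._pseudocells(counts, ["T3", "control", "control"])
        with pytest.raises(ValueError):
            moderated_t_de(pcs)

    def test_spike_estimates_unbiased(self, spiked_dataset):
        nuclei, truth = spiked_dataset
        pcs = build_pseudocells(nuclei, "neuron", seed=2)
        de = moderated_t_de(pcs, background=background_genes(nuclei, "neuron"))
        merged = de.merge(truth, on="gene", suffixes=("", "_true"))
        spiked = merged[merged["spiked"]]
        # pseudocount attenuation is negligible only for decently expressed genes
        expressed = spiked[spiked["base_mean"] >= 0.5]
        err = expressed["log2fc"] - expressed["log2fc_true"]
        assert abs(err.mean()) < 0.2  # unbiased within Monte-Carlo error
        # strong spikes overwhelmingly significant
        strong = spiked[spiked["log2fc_true"].abs() >= 1.0]
        assert (strong["fdr"] < 0.05).mean() > 0.8


class TestRobScores:
    def _pcs_from_sample_means(self, t3_means, ctl_means):
        """One pseudocell per sample with counts proportional to the target
        mean (equal column sums keep normalization monotone)."""
        cols = []
        sids, conds = [], []
        for j, v in enumerate(t3_means):
            cols.append(v)
            sids.append(f"t{j}")
            conds.append("T3")
        for j, v in enumerate(ctl_means):
            cols.append(v)
            sids.append(f"c{j}")
            conds.append("control")
        mat = np.array(cols, dtype=float).T  # genes x samples
        meta = pd.DataFrame(
            {
                "sample_id": sids,
                "condition": conds,
                "cre_status": ["n/a"] * len(sids),
                "n_member_nuclei": [30] * len(sids),
                "pct_mt": [1.0] * len(sids),
                "n_genes": (mat > 0).sum(axis=0),
            }
        )
        return PseudocellMatrix(
            counts=sp.csc_matrix(mat),
            genes=np.array([f"g{i}" for i in range(mat.shape[0])]),
            meta=meta,
        )

    def test_full_concordance(self):
        # gene 0 higher in every T3 sample; gene 1 balances column sums
        t3 = [[10, 10]] * 4
        ctl = [[2, 18]] * 4
        rs = rob_scores(self._pcs_from_sample_means(t3, ctl))
        assert rs.loc[rs["gene"] == "g0", "robscore_logfc"].iloc[0] == 1.0

    def test_twelve_of_sixteen_gives_half(self):
        # gene 0 up in 3 of 4 T3 samples vs all controls: 12 up, 4 down
        t3 = [[10, 10], [10, 10], [10, 10], [2, 18]]
        ctl = [[5, 15]] * 4
        rs = rob_scores(self._pcs_from_sample_means(t3, ctl))
        assert rs.loc[rs["gene"] == "g0", "robscore_logfc"].iloc[0] == pytest.approx(0.5)

    def test_balanced_gives_zero(self):
        t3 = [[10, 10], [10, 10], [2, 18], [2, 18]]
        ctl = [[5, 15]] * 4
        rs = rob_scores(self._pcs_from_sample_means(t3, ctl))
        assert rs.loc[rs["gene"] == "g0", "robscore_logfc"].iloc[0] == 0.0

    def test_condition_swap_negates_score(self, spiked_dataset):
        nuclei, _ = spiked_dataset
        pcs = build_pseudocells(nuclei, "neuron", seed=3)
        rs = rob_scores(pcs)
        swapped = PseudocellMatrix(
            counts=pcs.counts, genes=pcs.genes, meta=pcs.meta.copy()
        )
        swapped.meta["condition"] = swapped.meta["condition"].map(
            {"T3": "control", "control": "T3"}
        )
        rs2 = rob_scores(swapped)
        np.testing.assert_allclose(
            rs["robscore_logfc"], -rs2["robscore_logfc"], atol=1e-12
        )

    def test_missing_condition_errors(self, rng):
        pcs = self._pcs_from_sample_means([[1, 1]] * 4, [])
        with pytest.raises(ValueError):
            rob_scores(pcs)


class TestCallTrgs:
    def _table(self, fdr, rob):
        return pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(len(fdr))],
                "log2fc": np.ones(len(fdr)),
                "t_mod": np.ones(len(fdr)),
                "p": fdr,
                "fdr": fdr,
                "mean_expr": np.arange(len(fdr), dtype=float),
                "robscore_logfc": rob,
                "robscore_pct": rob,
            }
        )

    def test_criteria_matrix(self):
        de, _ = call_trgs(self._table([0.01, 0.01, 0.2], [0.6, 0.4, 1.0]))
        assert de["is_trg"].tolist() == [True, False, False]

    def test_negative_robscore_counts(self):
        de, _ = call_trgs(self._table([0.01], [-0.7]))
        assert de["is_trg"].iloc[0]

    def test_non_trg_reference_set(self):
        de = self._table([0.5, 0.01, 0.5, 0.5], [0.0, 0.0, 0.0, 0.3])
        _, non = call_trgs(de, n_top_expressed=2)
        # g1 fails fdr>0.05; g3 has nonzero robscore; top-2 by expression of {g0, g2}
        assert set(non["gene"]) == {"g0", "g2"}


class TestTrgCorrelation:
    def test_identical_vectors_correlate_fully(self, rng):
        v = rng.normal(size=30)
        fc = pd.DataFrame(
            [v, v, -v], index=["a", "b", "c"], columns=[f"g{i}" for i in range(30)]
        )
        trgs = {ct: {f"g{i}" for i in range(30)} for ct in "abc"}
        corr, Z, order = trg_correlation(fc, trgs)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert corr.loc["a", "c"] == pytest.approx(-1.0)

    def test_matches_rank_then_correlate_and_ward_oracles(self, rng):
        mat = rng.normal(size=(4, 30))
        fc = pd.DataFrame(mat, index=list("abcd"), columns=[f"g{i}" for i in range(30)])
        trgs = {ct: {f"g{i}" for i in range(30)} for ct in "abcd"}
        corr, Z, order = trg_correlation(fc, trgs)
        # rank-then-Pearson oracle
        for i, ci in enumerate("abcd"):
            for j, cj in enumerate("abcd"):
                ri = stats.rankdata(mat[i])
                rj = stats.rankdata(mat[j])
                expected = np.corrcoef(ri, rj)[0, 1]
                assert corr.iloc[i, j] == pytest.approx(expected, abs=1e-12)
        # brute-force Ward (ward.D2 / Lance-Williams) agglomeration oracle
        pts = corr.to_numpy()
        clusters = {i: [i] for i in range(4)}
        d2 = {
            (i, j): np.sum((pts[i] - pts[j]) ** 2)
            for i in range(4)
            for j in range(i + 1, 4)
        }
        heights = []
        sizes = {i: 1 for i in range(4)}
        nxt = 4
        while len(clusters) > 1:
            (i, j), dij = min(d2.items(), key=lambda kv: kv[1])
            heights.append(np.sqrt(dij))
            ni, nj = sizes[i], sizes[j]
            new = {}
            for (a, b), val in d2.items():
                if i in (a, b) or j in (a, b):
                    continue
                new[(a, b)] = val
            for k in clusters:
                if k in (i, j):
                    continue
                dik = d2[tuple(sorted((i, k)))]
                djk = d2[tuple(sorted((j, k)))]
                nk = sizes[k]
                new[tuple(sorted((nxt, k)))] = (
                    (ni + nk) * dik + (nj + nk) * djk - nk * dij
                ) / (ni + nj + nk)
            clusters[nxt] = clusters.pop(i) + clusters.pop(j)
            sizes[nxt] = ni + nj
            d2 = new
            nxt += 1
        np.testing.assert_allclose(Z[:, 2], heights, rtol=1e-10)

    def test_requires_two_cell_types_with_trgs(self, rng):
        fc = pd.DataFrame(rng.normal(size=(2, 5)), index=["a", "b"],
                          columns=[f"g{i}" for i in range(5)])
        with pytest.raises(ValueError):
            trg_correlation(fc, {"a": {"g0"}, "b": set()})


class TestDisruptionRegression:
    def test_full_reversal_signature(self, rng):
        orig = pd.Series(rng.normal(size=40), index=[f"g{i}" for i in range(40)])
        res = disruption_regression(orig, -1.0 * orig)
        assert res.slope == pytest.approx(-1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_independent_noise_gives_null(self, rng):
        orig = pd.Series(rng.normal(size=3000), index=[f"g{i}" for i in range(3000)])
        noise = pd.Series(rng.normal(size=3000), index=orig.index)
        res = disruption_regression(orig, noise)
        assert abs(res.slope) < 0.1
        assert res.r_squared < 0.01

    def test_disrupted_set_thresholds(self):
        orig = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        # +30%, +10%, +30% fractional change
        delta = pd.Series(np.log2([1.30, 1.10, 1.30]), index=["a", "b", "c"])
        fdr = pd.Series([0.01, 0.01, 0.2], index=["a", "b", "c"])
        res = disruption_regression(orig, delta, contrast_fdr=fdr)
        assert res.disrupted_genes == ["a"]

    def test_too_few_genes(self):
        s = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            disruption_regression(s, s)


class TestMtxRoundTrip:
    def test_round_trip(self, tmp_path, rng):
        counts = rng.integers(0, 5, size=(20, 30))
        nuclei = make_nuclei(counts, ["s0"] * 15 + ["s1"] * 15, ["T3"] * 15 + ["control"] * 15)
        write_counts(nuclei, tmp_path / "c.mtx", tmp_path / "g.tsv", tmp_path / "m.tsv")
        back = read_counts(tmp_path / "c.mtx", tmp_path / "g.tsv", tmp_path / "m.tsv")
        assert (back.counts != nuclei.counts).nnz == 0
        np.testing.assert_array_equal(back.genes, nuclei.genes)
        assert back.meta["condition"].tolist() == nuclei.meta["condition"].tolist()
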