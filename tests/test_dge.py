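import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ncounter_reject as nr
from ncounter_reject.dge import (
    adjust_by,
    dge_table,
    median_log2fc,
    retest_correlation,
    top_degs,
    volcano_frame,
    wilcoxon_de,
)
from ncounter_reject.synthetic import fast_spec, generate_matrix

from conftest import make_norm


def by_oracle(p):
    """Step-up Benjamini–Yekutieli from the definition."""
    p = np.asarray(p, float)
    m = len(p)
    c_m = sum(1.0 / i for i in range(1, m + 1))
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running = min(running, m * c_m * p[idx] / rank_from_top)
        adjusted[idx] = running
    return adjusted


class TestMedianLog2FC:
    def test_plain_median_ratio(self):
        norm = make_norm({1: [8, 8, 8, 2, 2, 2]}, ["AMR"] * 3 + ["NoRejection"] * 3)
        fc = median_log2fc(norm, "AMR", "NoRejection")
        assert fc["E1"] == pytest.approx(2.0)

    def test_identical_groups_zero(self):
        norm = make_norm({1: [5, 7, 9, 5, 7, 9]}, ["AMR"] * 3 + ["NoRejection"] * 3)
        assert median_log2fc(norm, "AMR", "NoRejection")["E1"] == 0.0

    def test_zero_median_uses_pseudocount(self):
        norm = make_norm({1: [0, 0, 0, 3, 3, 3]}, ["AMR"] * 3 + ["NoRejection"] * 3)
        fc = median_log2fc(norm, "AMR", "NoRejection")
        assert fc["E1"] == pytest.approx(np.log2(0.5 / 3.5), abs=1e-4)

    def test_empty_group_rejected(self):
        norm = make_norm({1: [1, 2, 3]}, ["AMR"] * 3)
        with pytest.raises(ValueError):
            median_log2fc(norm, "AMR", "NoRejection")


class TestWilcoxon:
    def test_complete_separation_exact_p(self):
        norm = make_norm({1: [1, 2, 3, 10, 11, 12]},
                         ["AMR"] * 3 + ["NoRejection"] * 3)
        # exact two-sided: 2 / C(6,3) = 0.1
        assert wilcoxon_de(norm, "AMR", "NoRejection")["E1"] == pytest.approx(0.1)

    def test_constant_gene_p_one(self):
        norm = make_norm({1: [4, 4, 4, 4, 4, 4]}, ["AMR"] * 3 + ["NoRejection"] * 3)
        assert wilcoxon_de(norm, "AMR", "NoRejection")["E1"] == 1.0

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(5)
        vals = rng.lognormal(4, 1, size=12)
        labels = ["AMR"] * 6 + ["NoRejection"] * 6
        p_raw = wilcoxon_de(make_norm({1: vals}, labels), "AMR", "NoRejection")
        p_exp = wilcoxon_de(make_norm({1: np.exp(vals / 50)}, labels),
                            "AMR", "NoRejection")
        assert p_raw["E1"] == pytest.approx(p_exp["E1"])

    def test_null_pvalues_valid_and_near_uniform(self):
        # rank-test p-values are discrete and (with continuity correction)
        # slightly conservative, so check type-I validity at several levels
        # rather than strict continuous uniformity
        rng = np.random.default_rng(17)
        n_genes = 1000
        vals = {i + 1: rng.lognormal(5, 0.5, size=30) for i in range(n_genes)}
        norm = make_norm(vals, ["AMR"] * 15 + ["NoRejection"] * 15)
        p = wilcoxon_de(norm, "AMR", "NoRejection").values
        for alpha in (0.01, 0.05, 0.1, 0.2):
            frac = (p < alpha).mean()
            margin = 3 * np.sqrt(alpha * (1 - alpha) / n_genes)
            assert frac <= alpha + margin
            assert frac >= alpha / 2 - margin
        assert 0.45 < p.mean() < 0.58


class TestAdjustBY:
    def test_single_pvalue_unchanged(self):
        assert adjust_by([0.042])[0] == pytest.approx(0.042)

    def test_two_value_hand_computation(self):
        # c(2) = 1.5: BH gives (0.02, 0.04); BY scales to (0.03, 0.06)
        assert adjust_by([0.01, 0.04]) == pytest.approx([0.03, 0.06])

    def test_matches_definition_oracle_and_dominates_bh(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(8)
        for _ in range(10):
            p = rng.uniform(size=rng.integers(5, 60))
            by = adjust_by(p)
            assert by == pytest.approx(by_oracle(p), abs=1e-12)
            bh = multipletests(p, method="fdr_bh")[1]
            assert np.all(by >= bh - 1e-15) and np.all(bh >= p - 1e-15)
            # monotone: same ordering as raw p
            order = np.argsort(p)
            assert np.all(np.diff(by[order]) >= -1e-15)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            adjust_by([0.5, 1.7])


class TestTopAndRetest:
    def _table(self, fdr, fc):
        genes = [f"G{i}" for i in range(len(fdr))]
        df = pd.DataFrame(
            {
                "probe_id": genes,
                "median_a": 1.0,
                "median_b": 1.0,
                "log2fc": fc,
                "p_raw": fdr,
                "fdr_p": fdr,
                "significant": np.asarray(fdr) < 0.05,
            },
            index=pd.Index(genes, name="gene_symbol"),
        )
        return nr.DGETable(("AMR", "NoRejection"), df)

    def test_smallest_fdr_first(self):
        t = self._table([0.5, 0.01, 0.2], [1.0, 1.0, 1.0])
        assert top_degs(t, 2) == ["G1", "G2"]

    def test_all_tied_orders_by_effect_size(self):
        t = self._table([0.1, 0.1, 0.1], [0.5, 3.0, -2.0])
        assert top_degs(t, 3) == ["G1", "G2", "G0"]

    def test_k_larger_than_table_warns(self):
        t = self._table([0.1, 0.2], [1.0, 2.0])
        with pytest.warns(UserWarning):
            assert len(top_degs(t, 10)) == 2

    def test_retest_identity_and_negation(self):
        t = self._table([0.01, 0.02, 0.03, 0.04], [1.0, -2.0, 0.5, 3.0])
        assert retest_correlation(t, t) == pytest.approx(1.0)
        neg = self._table([0.01, 0.02, 0.03, 0.04], [-1.0, 2.0, -0.5, -3.0])
        assert retest_correlation(t, neg) == pytest.approx(-1.0)

    def test_too_few_shared_genes_rejected(self):
        t = self._table([0.01, 0.02], [1.0, 2.0])
        with pytest.raises(ValueError):
            retest_correlation(t, t, shared_genes=["G0"])


class TestRecovery:
    def test_planted_effects_dominate_top_list(self):
        spec = fast_spec(
            seed=33,
            n_per_group={"NoRejection": 30, "BLorTCMR": 10, "AMR": 30},
            n_endogenous=200,
            group_effects={"AMR": {f"G{i:04d}": 2.0 for i in range(1, 21)}},
        )
        matrix, truth = generate_matrix(spec)
        report = nr.lane_qc(matrix)
        kept = nr.filter_samples(matrix, report)
        bg = nr.apply_probe_filter(kept)
        gn = nr.genorm_rank(bg.kept_matrix)
        norm = nr.normalize(bg.kept_matrix, gn.selected_references)
        table = dge_table(norm, "AMR", "NoRejection")
        top = set(top_degs(table, 20))
        planted = set(truth.true_de_genes["AMR_vs_NoRejection"])
        assert len(top & planted) >= 16

    def test_volcano_frame_axes(self, fast_bundle):
        table = dge_table(fast_bundle["norm"], "AMR", "NoRejection")
        vol = volcano_frame(table)
        assert list(vol.columns) == ["log2fc", "neg_log10_fdr"]
        assert (vol["neg_log10_fdr"] >= 0).all()
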