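"""RVIS: counting rules, studentization vs a leave-one-out oracle, outliers."""

import numpy as np
import pandas as pd
import pytest

import rviskit as rk
from rviskit.rvis import GeneCounts, compute_rvis, count_gene_variants, remove_outliers
from rviskit.qc import VariantRecord
from rviskit.synthetic import counts_from_truth, simulate_truth

from conftest import loo_studentized_oracle

GM = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1000], "gene": ["G1"]})


def var(effect, af, gene="G1"):
    return VariantRecord(chrom="chr1", pos=10, ref="A", alt="G", qual=40,
                         depth=30, allele_freq=af, gene=gene, effect=effect)


def test_counting_definitions():
    """x = all coding; y = functional with AF above the common threshold."""
    records = [var("missense", 0.05), var("synonymous", 0.3), var("lof", 0.0002)]
    (c,) = count_gene_variants(records, GM, maf_threshold=0.001)
    assert (c.x_total_coding, c.y_common_functional) == (3, 1)


def test_gene_with_no_variants_scores_zero_counts():
    (c,) = count_gene_variants([], GM)
    assert (c.x_total_coding, c.y_common_functional) == (0, 0)


def test_noncoding_excluded_from_both_counts():
    (c,) = count_gene_variants([var("noncoding", 0.3)], GM)
    assert (c.x_total_coding, c.y_common_functional) == (0, 0)


def test_unknown_gene_warned_but_counted():
    with pytest.warns(UserWarning, match="absent from gene models"):
        counts = count_gene_variants([var("missense", 0.1, gene="NEW")], GM)
    by_gene = {c.gene: c for c in counts}
    assert by_gene["NEW"].x_total_coding == 1
    assert by_gene["G1"].x_total_coding == 0


def test_counts_reject_y_above_x():
    with pytest.raises(ValueError):
        GeneCounts("G", 2, 3)


def test_perfect_fit_is_degenerate_with_zero_scores():
    counts = [GeneCounts(f"G{i}", 10 * i, 2 * i) for i in range(1, 6)]
    t = compute_rvis(counts)
    assert t.degenerate_variance
    assert np.allclose(t.table["raw_residual"], 0, atol=1e-9)
    assert np.allclose(t.table["rvis"], 0)


def test_studentized_matches_loo_oracle_small_case():
    counts = [GeneCounts("a", 10, 4), GeneCounts("b", 20, 8),
              GeneCounts("c", 30, 12), GeneCounts("d", 40, 20)]
    t = compute_rvis(counts)
    oracle = loo_studentized_oracle([10, 20, 30, 40], [4, 8, 12, 20])
    np.testing.assert_allclose(t.table["studentized"], oracle, atol=1e-8)


@pytest.mark.parametrize("n,seed", [(5, 0), (12, 1), (25, 2), (50, 3)])
def test_studentized_matches_loo_oracle_random(n, seed):
    rng = np.random.default_rng(seed)
    x = rng.integers(1, 100, n)
    y = np.minimum(rng.binomial(x, 0.3), x)
    x = x + rng.permutation(n)  # ensure variation in x
    counts = [GeneCounts(f"G{i:03d}", int(xi), int(min(yi, xi)))
              for i, (xi, yi) in enumerate(zip(x, y))]
    t = compute_rvis(counts)
    # table is sorted by gene label == construction order here
    oracle = loo_studentized_oracle(t.table["x"], t.table["y"])
    np.testing.assert_allclose(t.table["studentized"], oracle, atol=1e-8)


def test_fitted_scores_have_mean_zero():
    truth = simulate_truth(rk.SimConfig(n_genes=500, seed=2))
    t = compute_rvis(counts_from_truth(truth))
    assert abs(t.scores().mean()) < 1e-6


def test_identical_counts_get_identical_scores():
    counts = [GeneCounts("a", 10, 3), GeneCounts("b", 10, 3),
              GeneCounts("c", 30, 9), GeneCounts("d", 50, 30)]
    t = compute_rvis(counts)
    s = t.scores()
    assert s["a"] == s["b"]


def test_order_invariance():
    truth = simulate_truth(rk.SimConfig(n_genes=100, seed=4))
    counts = counts_from_truth(truth)
    t1 = compute_rvis(counts)
    t2 = compute_rvis(list(reversed(counts)))
    pd.testing.assert_frame_equal(t1.table, t2.table)


def test_shifting_all_y_moves_intercept_not_scores():
    truth = simulate_truth(rk.SimConfig(n_genes=100, seed=6))
    counts = counts_from_truth(truth)
    t1 = compute_rvis(counts)
    shifted = [GeneCounts(c.gene, c.x_total_coding + 10,
                          c.y_common_functional + 10) for c in counts]
    # shift x and y by the same constant: residuals of y+10 on x+10 equal
    # residuals of y on x (intercept absorbs the shift, slope unchanged)
    t2 = compute_rvis(shifted)
    np.testing.assert_allclose(t1.table["studentized"], t2.table["studentized"],
                               atol=1e-10)
    assert abs(t2.slope - t1.slope) < 1e-10


def test_score_strictly_increases_in_y():
    rng = np.random.default_rng(8)
    x = rng.integers(10, 100, 40)
    y = rng.binomial(x, 0.3)
    prev = None
    for y0 in (2, 6, 10, 14):
        counts = [GeneCounts(f"G{i:02d}", int(xi), int(yi))
                  for i, (xi, yi) in enumerate(zip(x, y))]
        counts[0] = GeneCounts("G00", int(x[0]), y0)
        score = compute_rvis(counts).scores()["G00"]
        if prev is not None:
            assert score > prev
        prev = score


def test_degenerate_inputs_raise():
    with pytest.raises(ValueError, match=">= 3"):
        compute_rvis([GeneCounts("a", 1, 0), GeneCounts("b", 2, 1)])
    with pytest.raises(ValueError, match="identical"):
        compute_rvis([GeneCounts(c, 5, 1) for c in "abcd"])


class TestOutlierRemoval:
    def base_counts(self):
        rng = np.random.default_rng(11)
        x = rng.integers(20, 80, 60)
        y = rng.binomial(x, 0.3)
        return [GeneCounts(f"G{i:02d}", int(xi), int(yi))
                for i, (xi, yi) in enumerate(zip(x, y))]

    def test_no_outliers_leaves_table_unchanged(self):
        t = compute_rvis(self.base_counts())
        assert t.table["rvis"].abs().max() < 11
        t2 = remove_outliers(t, threshold=11)
        assert t2 is t

    def test_injected_outlier_excluded_and_refit(self):
        counts = self.base_counts()
        counts[5] = GeneCounts("G05", 80, 80)  # y >> predicted
        t = compute_rvis(counts)
        assert t.scores()["G05"] > 5
        thr = t.scores()["G05"] - 0.1
        t2 = remove_outliers(t, threshold=thr)
        row = t2.table.set_index("gene").loc["G05"]
        assert row["excluded_outlier"]
        assert np.isnan(row["rvis"])
        assert t2.n_genes_fit == len(counts) - 1
        assert abs(t2.scores().mean()) < 1e-6  # re-centered after refit

    def test_one_sided_negative_scores_retained(self):
        counts = self.base_counts()
        counts[7] = GeneCounts("G07", 80, 0)  # far below predicted
        t = compute_rvis(counts)
        neg = t.scores()["G07"]
        assert neg < -2
        t2 = remove_outliers(t, threshold=2)
        assert not t2.table.set_index("gene").loc["G07", "excluded_outlier"]

    def test_bad_threshold(self):
        t = compute_rvis(self.base_counts())
        with pytest.raises(ValueError):
            remove_outliers(t, threshold=0)


def test_constrained_genes_score_lower_on_simulation():
    """Parameter recovery: constraint shows up as negative scores."""
    import scipy.stats as sps

    truth = simulate_truth(rk.SimConfig(n_genes=2000, constraint_factor=0.3, seed=7))
    t = compute_rvis(counts_from_truth(truth))
    s = t.scores()
    con = s[truth.set_index("gene")["constrained"]].to_numpy()
    unc = s[~truth.set_index("gene")["constrained"]].to_numpy()
    assert con.mean() < unc.mean()
    _, p = sps.ttest_ind(con, unc, equal_var=False)
    assert p < 1e-6


def test_truth_score_correlation_negative_across_replicates():
    """Point-biserial corr(constrained, score) < 0 in >=99/100 replicates."""
    negative = 0
    for seed in range(100):
        truth = simulate_truth(
            rk.SimConfig(n_genes=300, constraint_factor=0.3, seed=seed)
        )
        s = compute_rvis(counts_from_truth(truth)).scores()
        flags = truth.set_index("gene")["constrained"].astype(float)
        r = np.corrcoef(flags.loc[s.index], s)[0, 1]
        negative += r < 0
    assert negative >= 99
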