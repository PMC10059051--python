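"""Normalization, NB Wald testing, gene aggregation and overlap analysis."""

import numpy as np
import pandas as pd
import pytest

from isoannot.diffexpr import (
    de_test,
    gene_level,
    normalize,
    overlap_report,
    results_table,
)
from isoannot.simulate import simulate_switch_counts

GROUPS = ["A"] * 5 + ["B"] * 5


def _nb(rng, mu, disp, size):
    r = 1.0 / disp
    return rng.negative_binomial(r, r / (r + mu), size=size)


def _frame(mat):
    return pd.DataFrame(
        mat,
        index=[f"f{i}" for i in range(mat.shape[0])],
        columns=[f"s{j}" for j in range(mat.shape[1])],
    )


def test_size_factors_scaling_identity(rng):
    a = _nb(rng, 100, 0.1, size=(500, 1))
    counts = _frame(np.hstack([a, 2 * a]))
    sf, norm = normalize(counts)
    assert sf.iloc[1] / sf.iloc[0] == pytest.approx(2.0, rel=1e-6)
    assert np.allclose(norm.iloc[:, 0], norm.iloc[:, 1])


def test_identical_samples_unit_factors(rng):
    a = _nb(rng, 50, 0.1, size=(300, 1))
    counts = _frame(np.hstack([a, a, a]))
    sf, _ = normalize(counts)
    assert np.allclose(sf.values, 1.0)


def test_size_factors_recover_simulated_depths(rng):
    depths = np.array([0.5, 0.8, 1.0, 1.3, 2.0])
    base = rng.lognormal(np.log(200), 1, size=2000)
    mat = np.vstack(
        [_nb(rng, base * d, 0.05, size=2000) for d in depths]
    ).T
    sf, _ = normalize(_frame(mat))
    ratio = sf.values / depths
    assert np.all(np.abs(ratio / ratio.mean() - 1) < 0.05)


def test_total_count_fallback_warns():
    counts = _frame(np.array([[0, 5], [3, 0]]))
    with pytest.warns(UserWarning, match="total-count"):
        normalize(counts)


def test_identical_counts_not_called(rng):
    mat = np.tile(_nb(rng, 100, 0.1, size=(50, 1)), (1, 10))
    res = de_test(_frame(mat), GROUPS)
    assert all(r.log2fc == 0 and not r.call for r in res)


def test_all_zero_features_excluded_from_testing_and_bh(rng):
    mat = _nb(rng, 100, 0.1, size=(100, 10))
    mat[:10] = 0
    res = de_test(_frame(mat), GROUPS)
    ids = {r.feature_id for r in res}
    assert len(res) == 90 and not any(f"f{i}" in ids for i in range(10))


def test_insufficient_replicates_rejected(rng):
    counts = _frame(_nb(rng, 100, 0.1, size=(20, 3)))
    with pytest.raises(ValueError):
        de_test(counts, ["A", "A", "B"])
    with pytest.raises(ValueError):
        de_test(counts, ["A", "B", "C"])


def test_planted_fold_change_recovered(rng):
    """log2FC = 3 planted at mean 500, dispersion 0.01, 5v5: every planted
    feature is called and estimated within +/-0.3."""
    null = _nb(rng, 200, 0.1, size=(1960, 10))
    c1 = _nb(rng, 500, 0.01, size=(40, 5))
    c2 = _nb(rng, 500 * 8, 0.01, size=(40, 5))
    counts = _frame(np.vstack([null, np.hstack([c1, c2])]))
    res = de_test(counts, GROUPS)
    planted = res[-40:]
    assert all(r.call for r in planted)
    errors = np.array([r.log2fc - 3.0 for r in planted])
    assert np.all(np.abs(errors) < 0.3)


def test_null_pvalues_uniform_and_few_calls(rng):
    """2000 null features: p-values approximately uniform (KS < 0.1) and the
    called fraction below the nominal level plus Monte-Carlo error."""
    from scipy import stats

    counts = _frame(_nb(rng, 100, 0.1, size=(2000, 10)))
    res = de_test(counts, GROUPS)
    pvals = np.array([r.pvalue for r in res])
    assert stats.kstest(pvals, "uniform").statistic < 0.1
    assert np.mean([r.call for r in res]) <= 0.05 + 0.01


def test_bh_fdr_invariants(rng):
    mat = np.vstack(
        [
            _nb(rng, 100, 0.1, size=(300, 10)),
            np.hstack([_nb(rng, 100, 0.05, size=(30, 5)), _nb(rng, 500, 0.05, size=(30, 5))]),
        ]
    )
    counts = _frame(mat)
    res = de_test(counts, GROUPS)
    p = np.array([r.pvalue for r in res])
    q = np.array([r.fdr for r in res])
    assert q.min() >= p.min()
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-12)
    # permuting the input rows changes no FDR value
    perm = rng.permutation(len(counts))
    res2 = de_test(counts.iloc[perm], GROUPS)
    q2 = {r.feature_id: r.fdr for r in res2}
    assert all(q2[r.feature_id] == pytest.approx(r.fdr) for r in res)


def test_gene_level_sums_and_conserves_totals(rng):
    counts = _frame(_nb(rng, 100, 0.1, size=(30, 10)))
    tx2gene = {f"f{i}": f"g{i // 3}" for i in range(30)}
    genes = gene_level(counts, tx2gene)
    assert np.allclose(genes.sum(axis=0), counts.sum(axis=0))
    assert np.allclose(
        genes.loc["g0"], counts.loc[["f0", "f1", "f2"]].sum(axis=0)
    )
    with pytest.raises(ValueError, match="no gene"):
        gene_level(counts, {"f0": "g0"})


def test_overlap_report_edges():
    from isoannot.diffexpr import DeResult

    def mk(fid, level, call):
        return DeResult(fid, level, 1.0, 2.0, 0.01, 0.01, call)

    tx2gene = {"t1": "g1", "t2": "g2"}
    empty = overlap_report([mk("t1", "transcript", False)], [mk("g1", "gene", True)], tx2gene)
    assert empty.n_det == empty.n_detg == empty.n_overlap == 0
    full = overlap_report(
        [mk("t1", "transcript", True), mk("t2", "transcript", True)],
        [mk("g1", "gene", True)],
        tx2gene,
    )
    assert full.n_detg == 2 and full.n_deg == 1
    assert full.pct_of_deg == 100.0 and full.pct_of_detg == 50.0


def test_isoform_switch_detected_at_transcript_level_only():
    """Genes whose isoforms swap usage between conditions: >= 90% are DETGs
    while <= 10% reach significance as DEGs."""
    counts, tx2gene, switch = simulate_switch_counts(seed=4)
    det = de_test(counts, GROUPS, "transcript")
    deg = de_test(gene_level(counts, tx2gene), GROUPS, "gene")
    detg = {tx2gene[r.feature_id] for r in det if r.call}
    degs = {r.feature_id for r in deg if r.call}
    assert len(switch & detg) / len(switch) >= 0.9
    assert len(switch & degs) / len(switch) <= 0.1


def test_against_independent_deseq2_implementation(rng):
    """Cross-check fold-change estimates and strong calls against pydeseq2
    (independent implementation of the same model family) on a small planted
    matrix."""
    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.ds import DeseqStats

    null = _nb(rng, 300, 0.05, size=(160, 10))
    c1 = _nb(rng, 400, 0.05, size=(40, 5))
    c2 = _nb(rng, 400 * 2 ** np.tile([2.0, -2.0], 20)[:, None], 0.05, size=(40, 5))
    counts = _frame(np.vstack([null, np.hstack([c1, c2])]))
    res = de_test(counts, GROUPS)

    meta = pd.DataFrame({"condition": GROUPS}, index=counts.columns)
    dds = DeseqDataSet(
        counts=counts.T, metadata=meta, design="~condition", quiet=True
    )
    dds.deseq2()
    stats = DeseqStats(dds, contrast=["condition", "B", "A"], quiet=True)
    stats.summary()
    ref = stats.results_df

    ours = {r.feature_id: r for r in res}
    lfc_ours = np.array([ours[f].log2fc for f in ref.index if f in ours])
    lfc_ref = ref.loc[[f for f in ref.index if f in ours], "log2FoldChange"].values
    assert np.corrcoef(lfc_ours, lfc_ref)[0, 1] > 0.95
    # strong planted effects are called by both routes
    strong = [f"f{i}" for i in range(160, 200)]
    ref_called = (ref.loc[strong, "padj"] < 0.05) & (
        ref.loc[strong, "log2FoldChange"].abs() > 1
    )
    ours_called = np.array([ours[f].call for f in strong])
    assert (ref_called.values == ours_called).mean() > 0.9


def test_results_table_shape(rng):
    counts = _frame(_nb(rng, 100, 0.1, size=(20, 10)))
    df = results_table(de_test(counts, GROUPS))
    assert list(df.columns) == [
        "feature_id", "level", "baseMean", "log2FC", "pvalue", "FDR", "call"
    ]
    assert len(df) == 20
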