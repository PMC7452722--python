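import numpy as np
import pandas as pd
import pytest

from nmdscope import reference
from nmdscope.synthetic import gen_study_truth, simulate_bulk
from nmdscope.targets import (
    call_tiers,
    minimal_nb_de,
    overlap_known_targets,
    select_upregulated,
    tier_counts,
)


def _nif_table_from_truth(truth: pd.DataFrame) -> pd.DataFrame:
    cls = truth["nif_class"]
    return pd.DataFrame(
        {
            "gene_id": truth["gene_id"],
            "has_dej": cls == "dej",
            "has_uorf": cls == "uorf",
            "has_long_utr3": cls == "long3utr",
        }
    )


def test_select_upregulated_on_published_rows():
    de = reference.HIGH_CONFIDENCE_TARGETS.rename(
        columns={"symbol": "gene_id", "log2fc": "log2fc"}
    )[["gene_id", "log2fc", "padj"]]
    up = select_upregulated(de, alpha=0.05)
    assert "Sik1" in up
    assert len(up) == 52  # every published row is significant and up


def test_zero_log2fc_never_selected():
    de = pd.DataFrame({"gene_id": ["a"], "log2fc": [0.0], "padj": [1e-9]})
    assert select_upregulated(de) == set()


def test_selection_matches_filter_oracle():
    rng = np.random.default_rng(0)
    de = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(500)],
            "log2fc": rng.normal(0, 1, 500),
            "padj": rng.uniform(0, 1, 500),
        }
    )
    oracle = {
        r.gene_id
        for r in de.itertuples()
        if r.padj < 0.05 and r.log2fc > 0
    }
    assert select_upregulated(de, 0.05) == oracle


def test_missing_padj_dropped(caplog):
    de = pd.DataFrame(
        {"gene_id": ["a", "b"], "log2fc": [1.0, 1.0], "padj": [np.nan, 0.01]}
    )
    with caplog.at_level("WARNING"):
        assert select_upregulated(de) == {"b"}


def test_tier_assignment_matches_planted_truth():
    truth = gen_study_truth(seed=41)
    up = set(truth.loc[truth["is_upregulated"], "gene_id"])
    stab = set(truth.loc[truth["is_stabilized"], "gene_id"])
    tiers = call_tiers(up, stab, _nif_table_from_truth(truth))
    counts = tier_counts(tiers)
    assert counts["n_upregulated"] == 127
    assert counts["n_stabilized_upregulated"] == 82
    assert counts["n_high_confidence"] == 52
    # tier hierarchy: high_confidence => candidate => upregulated
    hc = tiers["tier"] == "high_confidence"
    assert (tiers.loc[hc, "upregulated"] & tiers.loc[hc, "stabilized"]).all()
    assert (tiers.loc[hc, "n_nifs"] >= 1).all()
    assert (
        counts["n_high_confidence"]
        <= counts["n_stabilized_upregulated"]
        <= counts["n_upregulated"]
    )


def test_tiers_monotone_under_alpha_relaxation():
    rng = np.random.default_rng(2)
    de = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(300)],
            "log2fc": rng.normal(0.5, 1, 300),
            "padj": rng.uniform(0, 0.3, 300),
        }
    )
    nif = pd.DataFrame(
        {
            "gene_id": de["gene_id"],
            "has_dej": rng.random(300) < 0.3,
            "has_uorf": False,
            "has_long_utr3": False,
        }
    )
    stab = set(de["gene_id"][rng.random(300) < 0.5])
    strict = tier_counts(call_tiers(select_upregulated(de, 0.01), stab, nif))
    loose = tier_counts(call_tiers(select_upregulated(de, 0.10), stab, nif))
    for key in strict:
        assert loose[key] >= strict[key]


def test_upregulated_only_gene_is_tier_none():
    nif = pd.DataFrame(
        {
            "gene_id": ["g1"],
            "has_dej": [False],
            "has_uorf": [False],
            "has_long_utr3": [False],
        }
    )
    tiers = call_tiers({"g1"}, set(), nif)
    assert tiers.loc[0, "tier"] == "none"


# ---------------------------------------------------------------------------
# minimal NB differential expression
# ---------------------------------------------------------------------------


def _counts(rng, n_genes, mu, lfc=None, disp=0.05, reps=4):
    cols = {}
    genos = []
    for geno in ("WT", "KO"):
        fold = 2.0**lfc if (geno == "KO" and lfc is not None) else 1.0
        for r in range(reps):
            m = mu * fold
            shape = 1.0 / disp
            lam = rng.gamma(shape, m * disp)
            cols[f"{geno}{r}"] = rng.poisson(lam)
            genos.append(geno)
    counts = pd.DataFrame(cols, index=[f"g{i}" for i in range(n_genes)])
    sheet = pd.DataFrame({"sample": counts.columns, "genotype": genos})
    return counts, sheet


def test_nb_de_null_type_one_error():
    rng = np.random.default_rng(3)
    mu = rng.lognormal(5, 1, 2000)
    counts, sheet = _counts(rng, 2000, mu)
    de = minimal_nb_de(counts, sheet)
    assert (de["padj"] < 0.05).mean() <= 0.07


def test_nb_de_recovers_planted_fold_change():
    rng = np.random.default_rng(4)
    n = 500
    mu = np.full(n, 2000.0)
    lfc = np.zeros(n)
    lfc[:50] = 2.0  # 4-fold up
    counts, sheet = _counts(rng, n, mu, lfc=lfc, disp=0.005)
    de = minimal_nb_de(counts, sheet).set_index("gene_id")
    est = de.loc[[f"g{i}" for i in range(50)], "log2fc"]
    assert np.all(np.abs(est - 2.0) < 0.3)


def test_nb_de_label_swap_negates_log2fc():
    rng = np.random.default_rng(5)
    counts, sheet = _counts(rng, 200, rng.lognormal(5, 1, 200))
    de1 = minimal_nb_de(counts, sheet).set_index("gene_id")
    swapped = sheet.assign(
        genotype=sheet["genotype"].map({"WT": "KO", "KO": "WT"})
    )
    de2 = minimal_nb_de(counts, swapped).set_index("gene_id")
    assert np.allclose(de1["log2fc"], -de2["log2fc"])


def test_nb_de_against_independent_reference_implementation():
    """Cross-check the convenience NB test against pydeseq2 on one dataset."""
    pydeseq2 = pytest.importorskip("pydeseq2")
    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.ds import DeseqStats

    rng = np.random.default_rng(6)
    n = 300
    mu = rng.lognormal(5, 1, n)
    lfc = np.zeros(n)
    lfc[:30] = 1.5
    counts, sheet = _counts(rng, n, mu, lfc=lfc)
    de = minimal_nb_de(counts, sheet).set_index("gene_id")

    meta = sheet.set_index("sample")
    dds = DeseqDataSet(
        counts=counts.T, metadata=meta, design="~genotype", quiet=True
    )
    dds.deseq2()
    res = DeseqStats(
        dds, contrast=["genotype", "KO", "WT"], quiet=True
    )
    res.summary()
    ref = res.results_df
    joined = de.join(ref[["log2FoldChange"]], how="inner").dropna()
    r = np.corrcoef(joined["log2fc"], joined["log2FoldChange"])[0, 1]
    assert r > 0.95


# ---------------------------------------------------------------------------
# prior-target overlap
# ---------------------------------------------------------------------------


def test_overlap_with_prior_targets_is_eleven():
    symbols = reference.HIGH_CONFIDENCE_TARGETS["symbol"]
    inter, n = overlap_known_targets(symbols, reference.PRIOR_NMD_TARGETS)
    assert n == 11
    assert inter == set(reference.PRIOR_NMD_TARGETS)


def test_overlap_empty_and_random_sets():
    assert overlap_known_targets(["a", "b"], []) == (set(), 0)
    rng = np.random.default_rng(7)
    a = {f"g{i}" for i in rng.integers(0, 100, 40)}
    b = {f"g{i}" for i in rng.integers(0, 100, 40)}
    inter, n = overlap_known_targets(a, b)
    assert inter == a & b and n == len(a & b)


def test_end_to_end_counts_with_estimated_stability():
    """External DE + stability estimated from counts lands near truth."""
    truth = gen_study_truth(seed=43)
    bulk = simulate_bulk(truth, seed=44)
    from nmdscope.stability import infer_stability
    from nmdscope.synthetic import truth_de_table

    st = infer_stability(
        bulk.exonic, bulk.intronic, bulk.sample_sheet, p_adjust="bh"
    )
    up = select_upregulated(truth_de_table(truth))
    stab = set(st.index[st["stabilized"]])
    tiers = call_tiers(up, stab, _nif_table_from_truth(truth))
    counts = tier_counts(tiers)
    assert counts["n_upregulated"] == 127
    assert abs(counts["n_stabilized_upregulated"] - 82) <= 0.15 * 82
    assert abs(counts["n_high_confidence"] - 52) <= 0.15 * 52
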