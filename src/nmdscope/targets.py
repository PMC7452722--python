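"""Candidate and high-confidence NMD-target tiers.

Combines three gene-level inputs — differential expression (upregulation
in the NMD-deficient genotype), exon/intron stabilization, and NIF
status — into tiers:

- ``candidate_nif``: upregulated and carrying >= 1 NIF;
- ``high_confidence``: upregulated, stabilized, and carrying >= 1 NIF;
- ``none`` otherwise.

Differential expression is normally supplied externally (a table of
gene, log2fc, padj); :func:`minimal_nb_de` provides a self-contained
negative-binomial Wald test as a convenience substitute, not a clone of
any dedicated DE package.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Set

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

TIER_ORDER = {"high_confidence": 0, "candidate_nif": 1, "none": 2}


def select_upregulated(de: pd.DataFrame, alpha: float = 0.05) -> set[str]:
    """Genes significantly upregulated in KO: padj < alpha and log2fc > 0.

    Rows with missing padj are dropped with a warning.
    """
    de = de.set_index("gene_id") if "gene_id" in de.columns else de
    missing = de["padj"].isna()
    if missing.any():
        logger.warning("dropping %d genes with missing padj", int(missing.sum()))
        de = de[~missing]
    sel = de[(de["padj"] < alpha) & (de["log2fc"] > 0)]
    return set(sel.index)


def call_tiers(
    upregulated: Set[str],
    stabilized: Set[str],
    nif_table: pd.DataFrame,
) -> pd.DataFrame:
    """Assign NMD-target tiers over the union of the three gene universes.

    ``nif_table`` is the per-gene NIF table (needs gene_id, has_dej,
    has_uorf, has_long_utr3, any_nif, n_nifs columns).  Genes absent
    from it are treated as NIF-free.  Output is ordered by tier then
    gene_id.
    """
    nif = (
        nif_table.set_index("gene_id")
        if "gene_id" in nif_table.columns
        else nif_table
    )
    universe = sorted(set(upregulated) | set(stabilized) | set(nif.index))
    overlap = set(upregulated) & set(nif.index)
    logger.info(
        "tier universe: %d genes (%d upregulated with NIF annotation)",
        len(universe),
        len(overlap),
    )
    rows = []
    for g in universe:
        up = g in upregulated
        stab = g in stabilized
        if g in nif.index:
            rec = nif.loc[g]
            flags = (
                bool(rec["has_dej"]),
                bool(rec["has_uorf"]),
                bool(rec["has_long_utr3"]),
            )
        else:
            flags = (False, False, False)
        n_nifs = sum(flags)
        if up and stab and n_nifs >= 1:
            tier = "high_confidence"
        elif up and n_nifs >= 1:
            tier = "candidate_nif"
        else:
            tier = "none"
        rows.append(
            {
                "gene_id": g,
                "upregulated": up,
                "stabilized": stab,
                "has_dej": flags[0],
                "has_uorf": flags[1],
                "has_long_utr3": flags[2],
                "n_nifs": n_nifs,
                "tier": tier,
            }
        )
    df = pd.DataFrame(rows)
    df["_tier_rank"] = df["tier"].map(TIER_ORDER)
    df = df.sort_values(["_tier_rank", "gene_id"]).drop(columns="_tier_rank")
    return df.reset_index(drop=True)


def tier_counts(tiers: pd.DataFrame) -> dict[str, int]:
    """Headline cardinalities: upregulated, stabilized+up, tiers."""
    up = tiers["upregulated"]
    return {
        "n_upregulated": int(up.sum()),
        "n_stabilized_upregulated": int((up & tiers["stabilized"]).sum()),
        "n_candidate_nif": int((tiers["tier"] != "none").sum()),
        "n_high_confidence": int((tiers["tier"] == "high_confidence").sum()),
    }


def minimal_nb_de(
    counts: pd.DataFrame, sample_sheet: pd.DataFrame, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Minimal negative-binomial Wald test for KO-vs-WT expression.

    Median-of-ratios size factors, per-gene method-of-moments dispersion,
    a Wald test on log2fc via the delta method, and Benjamini-Hochberg
    adjustment.  A deliberately small convenience: adequate for synthetic
    data and sanity checks, with none of the shrinkage machinery of a
    dedicated DE package.  All-zero genes are dropped.
    """
    geno = sample_sheet.set_index("sample")["genotype"]
    wt_s = [s for s in counts.columns if geno.get(s) == "WT"]
    ko_s = [s for s in counts.columns if geno.get(s) == "KO"]
    if min(len(wt_s), len(ko_s)) < 2:
        raise ValueError("need >=2 replicates per genotype")
    counts = counts[(counts.sum(axis=1) > 0)]

    # median-of-ratios size factors over genes with all-positive counts
    x = counts.to_numpy(float)
    allpos = (x > 0).all(axis=1)
    logg = np.log(x[allpos])
    geo = logg.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logg - geo, axis=0))
    sf = pd.Series(sf, index=counts.columns)
    norm = counts / sf

    wt = norm[wt_s].to_numpy(float)
    ko = norm[ko_s].to_numpy(float)
    mu_w, mu_k = wt.mean(axis=1), ko.mean(axis=1)
    var_w, var_k = wt.var(axis=1, ddof=1), ko.var(axis=1, ddof=1)

    # pooled method-of-moments NB dispersion: var = mu + disp * mu^2
    with np.errstate(divide="ignore", invalid="ignore"):
        disp_w = (var_w - mu_w) / np.square(mu_w)
        disp_k = (var_k - mu_k) / np.square(mu_k)
    disp = np.nanmean(np.vstack([disp_w, disp_k]), axis=0)
    disp = np.clip(np.nan_to_num(disp, nan=0.0), 0.0, None)

    c = pseudocount
    log2fc = np.log2(mu_k + c) - np.log2(mu_w + c)
    ln2 = np.log(2.0)
    se_w = np.sqrt((mu_w + disp * mu_w**2) / len(wt_s)) / ((mu_w + c) * ln2)
    se_k = np.sqrt((mu_k + disp * mu_k**2) / len(ko_s)) / ((mu_k + c) * ln2)
    se = np.sqrt(se_w**2 + se_k**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    padj = multipletests(p, method="fdr_bh")[1]

    return pd.DataFrame(
        {
            "gene_id": counts.index,
            "base_mean_wt": mu_w,
            "base_mean_ko": mu_k,
            "log2fc": log2fc,
            "p": p,
            "padj": padj,
        }
    ).reset_index(drop=True)


def overlap_known_targets(
    call_symbols: Iterable[str], known_list: Iterable[str]
) -> tuple[set[str], int]:
    """Exact case-sensitive intersection with a prior target list."""
    inter = set(call_symbols) & set(known_list)
    return inter, len(inter)
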