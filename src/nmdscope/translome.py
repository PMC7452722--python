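"""RiboTag translation-efficiency analyses.

Translation efficiency (TE) of a gene is the ratio of ribosome-associated
mRNA (RiboTag IP) to steady-state mRNA (input RNA-seq), computed on
length-normalized TPM:

    log2TE = log2((TPM_ip + c) / (TPM_input + c))

Expressed genes (input TPM >= floor) are binned 30/40/30 (low/medium/high)
by TE and, independently, by steady-state level, yielding a 3x3 category
grid (category 1 = high expression & high TE, counting across expression
within each TE stratum, so category 6 = low expression & medium TE).
Additional summaries relate TE to 3'UTR length and to NMD magnitude (the
degree of upregulation after NMD-factor loss).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

BINS = ("low", "medium", "high")


def tpm(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million, length- and depth-normalized."""
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("gene lengths must be positive and cover all genes")
    rate = counts.div(lengths, axis=0)
    return rate.div(rate.sum(axis=0), axis=1) * 1e6


def compute_te(
    input_counts: pd.DataFrame,
    ip_counts: pd.DataFrame,
    gene_lengths: pd.Series,
    expression_floor: float = 1.0,
    pseudocount: float = 0.1,
) -> pd.DataFrame:
    """Per-gene TE records from input and IP count tables.

    TPM is averaged across each table's samples; genes below the
    expression floor (input TPM, default 1) are excluded as unexpressed.
    Returns a table indexed by gene_id with tpm_input, tpm_ip, log2te.
    """
    diff = set(input_counts.index).symmetric_difference(ip_counts.index)
    if diff:
        raise ValueError(f"input/IP gene indices differ: {sorted(diff)[:20]}")
    ip_counts = ip_counts.loc[input_counts.index]
    tpm_input = tpm(input_counts, gene_lengths).mean(axis=1)
    tpm_ip = tpm(ip_counts, gene_lengths).mean(axis=1)
    expressed = tpm_input >= expression_floor
    logger.info(
        "%d/%d genes expressed at floor %.3g TPM",
        int(expressed.sum()),
        len(expressed),
        expression_floor,
    )
    c = pseudocount
    out = pd.DataFrame(
        {
            "tpm_input": tpm_input[expressed],
            "tpm_ip": tpm_ip[expressed],
        }
    )
    out["log2te"] = np.log2((out["tpm_ip"] + c) / (out["tpm_input"] + c))
    out.index.name = "gene_id"
    return out


def _assign_bins(values: pd.Series, fractions=(0.3, 0.4, 0.3)) -> pd.Series:
    """Rank-based low/medium/high bins at the 30th/70th percentiles.

    Values strictly below the lower quantile are low, strictly above the
    upper quantile high, everything else (including boundary ties) medium
    — so a degenerate all-equal input is all medium.
    """
    lo_q, hi_q = fractions[0], fractions[0] + fractions[1]
    lo = values.quantile(lo_q)
    hi = values.quantile(hi_q)
    out = pd.Series("medium", index=values.index)
    out[values < lo] = "low"
    out[values > hi] = "high"
    return out


def bin_translome(records: pd.DataFrame, fractions=(0.3, 0.4, 0.3)) -> pd.DataFrame:
    """Add te_bin, expr_bin and the 1-9 category to TE records.

    Categories cross TE (rows: high, medium, low) with steady-state
    expression (columns: high, medium, low): 1 = high TE & high
    expression, 2 = high TE & medium expression, ..., 9 = low TE & low
    expression.
    """
    if len(records) < 10:
        raise ValueError("need >=10 expressed genes to bin")
    out = records.copy()
    out["te_bin"] = _assign_bins(out["log2te"], fractions)
    out["expr_bin"] = _assign_bins(np.log2(out["tpm_input"]), fractions)
    te_rank = out["te_bin"].map({"high": 0, "medium": 1, "low": 2})
    expr_rank = out["expr_bin"].map({"high": 0, "medium": 1, "low": 2})
    out["category"] = (3 * te_rank + expr_rank + 1).astype(int)
    return out


def category_counts(records: pd.DataFrame) -> pd.Series:
    counts = records["category"].value_counts().reindex(range(1, 10), fill_value=0)
    counts.index.name = "category"
    return counts


@dataclass(frozen=True)
class GroupComparison:
    group_stats: pd.DataFrame
    pairwise_p: dict[tuple[str, str], float]
    global_p: float | None = None  # Kruskal-Wallis across all populated bins


def te_by_utr3(
    records: pd.DataFrame,
    utr3_lens: pd.Series,
    length_edges: tuple[float, ...] = (500, 1000, 2000),
    test: str = "mannwhitney",
) -> GroupComparison:
    """Mean TE of genes binned by 3'UTR length, with pairwise tests.

    Default edges split at 0.5/1/2 kb; with edges (e1..ek) the bins are
    (-inf, e1], (e1, e2], ..., (ek, inf).  Pairwise two-sided
    Mann-Whitney (or Welch t with ``test="welch"``) between bins.
    """
    joined = records.join(utr3_lens.rename("utr3_len"), how="inner")
    edges = [-np.inf, *length_edges, np.inf]
    labels = [
        f"({edges[i]:g},{edges[i + 1]:g}]" for i in range(len(edges) - 1)
    ]
    joined["utr3_bin"] = pd.cut(joined["utr3_len"], bins=edges, labels=labels)
    grp = joined.groupby("utr3_bin", observed=False)["log2te"]
    group_stats = grp.agg(["count", "mean", "median"]).reset_index()
    pairwise = {}
    for a, b in itertools.combinations(labels, 2):
        xa = joined.loc[joined["utr3_bin"] == a, "log2te"]
        xb = joined.loc[joined["utr3_bin"] == b, "log2te"]
        if len(xa) < 2 or len(xb) < 2:
            continue
        if test == "welch":
            p = stats.ttest_ind(xa, xb, equal_var=False).pvalue
        else:
            p = stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue
        pairwise[(a, b)] = float(p)
    groups = [
        joined.loc[joined["utr3_bin"] == lab, "log2te"]
        for lab in labels
        if (joined["utr3_bin"] == lab).sum() >= 2
    ]
    global_p = float(stats.kruskal(*groups).pvalue) if len(groups) >= 2 else None
    return GroupComparison(
        group_stats=group_stats, pairwise_p=pairwise, global_p=global_p
    )


def nmd_magnitude_vs_te(
    de: pd.DataFrame,
    records: pd.DataFrame,
    genes: set[str] | None = None,
    mode: str = "bins",
    high_te_cutoff: float = 1.0,
    test: str = "mannwhitney",
):
    """Relate NMD magnitude (log2fc after NMD-factor loss) to TE.

    ``mode="bins"`` splits the gene set into TE tertiles a/b/c (a the
    most translated) and compares mean log2fc of a vs c.  ``mode=
    "correlation"`` splits at log2TE > ``high_te_cutoff`` and reports the
    least-squares R^2 of log2fc on log2te per group; a group with fewer
    than 3 genes or no TE variance reports R^2 = None (undefined, not
    zero).
    """
    de = de.set_index("gene_id") if "gene_id" in de.columns else de
    joined = records.join(de["log2fc"], how="inner").dropna(subset=["log2fc"])
    if genes is not None:
        joined = joined.loc[joined.index.intersection(sorted(genes))]
    if mode == "bins":
        ranked = joined.sort_values(
            ["log2te", *(["gene_id"] if "gene_id" in joined else [])],
            ascending=False,
            kind="mergesort",
        )
        n = len(ranked)
        thirds = np.array_split(np.arange(n), 3)
        out = {}
        groups = {}
        for name, idx in zip("abc", thirds):
            sub = ranked.iloc[idx]
            groups[name] = sub["log2fc"]
            out[name] = {
                "n": len(sub),
                "mean_log2fc": float(sub["log2fc"].mean()) if len(sub) else np.nan,
            }
        if len(groups["a"]) >= 2 and len(groups["c"]) >= 2:
            if test == "welch":
                p = stats.ttest_ind(groups["a"], groups["c"], equal_var=False).pvalue
            else:
                p = stats.mannwhitneyu(
                    groups["a"], groups["c"], alternative="two-sided"
                ).pvalue
        else:
            p = np.nan
        return {"tertiles": out, "p_a_vs_c": float(p)}
    if mode == "correlation":
        out = {}
        for name, sub in (
            ("high_te", joined[joined["log2te"] > high_te_cutoff]),
            ("low_te", joined[joined["log2te"] <= high_te_cutoff]),
        ):
            if len(sub) < 3 or np.isclose(sub["log2te"].var(ddof=0), 0.0):
                out[name] = {"n": len(sub), "r2": None, "slope": None}
                continue
            fit = stats.linregress(sub["log2te"], sub["log2fc"])
            out[name] = {
                "n": len(sub),
                "r2": float(fit.rvalue**2),
                "slope": float(fit.slope),
            }
        return out
    raise ValueError(f"unknown mode {mode!r}")
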