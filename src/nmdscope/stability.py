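"""Exon/intron-based RNA-stability inference.

Steady-state (exonic) read density reflects transcription divided by
decay; pre-mRNA (intronic) density reflects transcription alone.  Their
log-ratio

    delta_gs = log2((x_gs + c) / N_s) - log2((i_gs + c) / M_s)

is therefore a per-gene, per-sample proxy for relative RNA stability
(N_s, M_s are exonic/intronic library sizes, c a pseudocount).  A
gene-level abundance bias is removed by subtracting a running-median
trend of delta against mean log2 exonic abundance.  Genotype-dependent
stabilization is then called from the replicate delta values: a gene is
stabilized when the knockout-minus-wild-type difference exceeds a
threshold and a Welch t-test across replicates is significant.

The statistic is deliberately simple — it captures relative
stabilization between genotypes, which is all the downstream target
calling consumes; externally computed delta tables can be supplied
instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DeltaResult:
    """Per-gene, per-sample stability proxy plus measurability flags."""

    delta: pd.DataFrame
    measurable: pd.Series  # False where intronic counts are 0 in every sample
    abundance: pd.Series  # mean log2 exonic density, bias-correction covariate


def compute_delta(
    exonic_counts: pd.DataFrame,
    intronic_counts: pd.DataFrame,
    pseudocount: float = 0.5,
) -> DeltaResult:
    """Compute the exon-minus-intron stability proxy per gene and sample.

    Both tables must share identical gene and sample indices; a mismatch
    is a hard error listing the symmetric difference.  Genes with zero
    intronic counts in every sample are flagged unmeasurable (their delta
    is still returned but they are excluded from stabilization calls).
    """
    for axis, a, b in (
        ("gene", exonic_counts.index, intronic_counts.index),
        ("sample", exonic_counts.columns, intronic_counts.columns),
    ):
        diff = set(a).symmetric_difference(set(b))
        if diff:
            raise ValueError(
                f"exonic/intronic {axis} indices differ: {sorted(diff)[:20]}"
            )
    intronic_counts = intronic_counts.loc[exonic_counts.index, exonic_counts.columns]
    n = exonic_counts.sum(axis=0).astype(float)
    m = intronic_counts.sum(axis=0).astype(float)
    if (n <= 0).any() or (m <= 0).any():
        raise ValueError("library sizes must be positive in every sample")
    c = pseudocount
    delta = np.log2((exonic_counts + c).div(n, axis=1)) - np.log2(
        (intronic_counts + c).div(m, axis=1)
    )
    measurable = intronic_counts.sum(axis=1) > 0
    n_un = int((~measurable).sum())
    if n_un:
        logger.info("%d genes unmeasurable (no intronic signal)", n_un)
    abundance = np.log2((exonic_counts + c).div(n, axis=1)).mean(axis=1)
    return DeltaResult(delta=delta, measurable=measurable, abundance=abundance)


def bias_correct(
    delta: pd.DataFrame,
    abundance: pd.Series,
    window_frac: float = 0.1,
    min_genes: int = 50,
) -> pd.DataFrame:
    """Remove the abundance-dependent trend from each sample's delta.

    Per sample, a running median of delta against mean log2 exonic
    abundance (window = ``window_frac`` of the genes) is subtracted, then
    the residual median so that corrected delta is centred at ~0.  A
    window fraction >= 1 degenerates to subtracting the per-sample
    median.  With fewer than ``min_genes`` genes the correction is
    skipped.
    """
    n = len(delta)
    if n < min_genes:
        logger.warning("bias_correct skipped: only %d genes (<%d)", n, min_genes)
        return delta.copy()
    if window_frac >= 1.0:
        return delta - delta.median(axis=0)

    order = abundance.sort_values(kind="mergesort").index
    window = max(int(round(window_frac * n)), 5)
    corrected = pd.DataFrame(index=delta.index, columns=delta.columns, dtype=float)
    for col in delta.columns:
        series = delta.loc[order, col]
        trend = series.rolling(window, center=True, min_periods=1).median()
        corrected[col] = (series - trend).reindex(delta.index)
    return corrected - corrected.median(axis=0)


def call_stabilized(
    delta: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    measurable: pd.Series | None = None,
    stabilization_min_ddelta: float = 0.0,
    alpha: float = 0.05,
    p_adjust: str = "none",
) -> pd.DataFrame:
    """Call genotype-dependent stabilization per gene.

    ``sample_sheet`` needs columns ``sample`` and ``genotype`` (WT/KO).
    A gene is stabilized when ddelta = mean(KO) - mean(WT) exceeds
    ``stabilization_min_ddelta`` and the Welch t-test across replicate
    delta values has p <= ``alpha``.  With ``p_adjust="bh"`` the test is
    Benjamini-Hochberg adjusted across genes first — appropriate for
    genome-wide screens; the raw-p default matches the statistic's usual
    position as a filter inside a small candidate set.  With a single
    replicate per genotype the test is skipped (threshold-only calls,
    with a warning).

    Returns a table with columns delta_wt, delta_ko, ddelta, p,
    stabilized, measurable.
    """
    if p_adjust not in {"none", "bh"}:
        raise ValueError(f"unknown p_adjust {p_adjust!r}")
    geno = sample_sheet.set_index("sample")["genotype"]
    wt_samples = [s for s in delta.columns if geno.get(s) == "WT"]
    ko_samples = [s for s in delta.columns if geno.get(s) == "KO"]
    if not wt_samples or not ko_samples:
        raise ValueError("need samples of both genotypes")
    wt = delta[wt_samples].to_numpy(float)
    ko = delta[ko_samples].to_numpy(float)
    delta_wt = wt.mean(axis=1)
    delta_ko = ko.mean(axis=1)
    ddelta = delta_ko - delta_wt

    if min(len(wt_samples), len(ko_samples)) < 2:
        logger.warning("single replicate in a genotype: threshold-only calls")
        p = np.full(len(delta), np.nan)
        signif = np.ones(len(delta), bool)
    else:
        p = stats.ttest_ind(ko, wt, axis=1, equal_var=False).pvalue
        p_eff = p.copy()
        if p_adjust == "bh":
            ok = np.isfinite(p)
            p_eff = np.full_like(p, np.nan)
            p_eff[ok] = multipletests(p[ok], method="fdr_bh")[1]
        signif = np.nan_to_num(p_eff, nan=1.0) <= alpha

    if measurable is None:
        measurable = pd.Series(True, index=delta.index)
    out = pd.DataFrame(
        {
            "delta_wt": delta_wt,
            "delta_ko": delta_ko,
            "ddelta": ddelta,
            "p": p,
            "measurable": measurable.reindex(delta.index).to_numpy(),
        },
        index=delta.index,
    )
    out["stabilized"] = (
        (out["ddelta"] > stabilization_min_ddelta) & signif & out["measurable"]
    )
    out.index.name = "gene_id"
    return out


def infer_stability(
    exonic_counts: pd.DataFrame,
    intronic_counts: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    pseudocount: float = 0.5,
    window_frac: float = 0.1,
    stabilization_min_ddelta: float = 0.0,
    alpha: float = 0.05,
    p_adjust: str = "none",
) -> pd.DataFrame:
    """Convenience wrapper: delta, bias correction, stabilization calls."""
    res = compute_delta(exonic_counts, intronic_counts, pseudocount)
    corrected = bias_correct(res.delta, res.abundance, window_frac)
    return call_stabilized(
        corrected,
        sample_sheet,
        measurable=res.measurable,
        stabilization_min_ddelta=stabilization_min_ddelta,
        alpha=alpha,
        p_adjust=p_adjust,
    )
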