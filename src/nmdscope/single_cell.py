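"""Single-cell QC, dominant-Olfr calls, and selection-fraction statistics.

Mature olfactory sensory neurons follow a one-neuron-one-receptor rule:
each cell dominantly expresses a single olfactory receptor (Olfr) gene.
Given a QC-filtered cell-by-gene UMI matrix with Olfr genes flagged, the
dominant Olfr of a cell is the Olfr gene with the highest UMI count.
The fraction of cells whose dominant Olfr belongs to a query subset
(e.g. the receptors downregulated after NMD-factor loss) is then
compared between genotypes with a two-proportion test.

The container is :class:`anndata.AnnData`: ``obs`` carries cell_id,
sample_id, genotype and cell_type; ``var`` carries gene_id plus is_olfr
and is_mito flags.  Clustering/embedding is out of scope — cell-type
labels are an input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse, stats
import statsmodels.api as sm

logger = logging.getLogger(__name__)

OSN_LINEAGE = ("HBC", "GBC", "iOSN", "mOSN")


def _to_dense(x) -> np.ndarray:
    return np.asarray(x.todense()) if sparse.issparse(x) else np.asarray(x)


@dataclass(frozen=True)
class QcLog:
    cells_removed: int
    genes_removed: int
    iterations: int


def qc_filter(
    adata: AnnData,
    min_features: int = 500,
    min_counts: int = 1500,
    max_mito_frac: float = 0.002,
    min_cells_per_gene: int = 3,
) -> tuple[AnnData, QcLog]:
    """Filter cells and genes by the standard QC predicates.

    Cells are retained iff detected genes > ``min_features``, total UMIs
    > ``min_counts`` and mitochondrial UMI fraction < ``max_mito_frac``;
    genes iff expressed in >= ``min_cells_per_gene`` cells.  The two
    predicates are iterated to a fixed point so that the filter is
    idempotent.
    """
    ad = adata.copy()
    n_cells0, n_genes0 = ad.shape
    iterations = 0
    while True:
        iterations += 1
        x = ad.X
        detected = np.asarray((x > 0).sum(axis=1)).ravel()
        total = np.asarray(x.sum(axis=1)).ravel()
        mito = np.asarray(
            x[:, ad.var["is_mito"].to_numpy(bool)].sum(axis=1)
        ).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(total > 0, mito / np.maximum(total, 1), 1.0)
        keep_cells = (
            (detected > min_features)
            & (total > min_counts)
            & (mito_frac < max_mito_frac)
        )
        cells_per_gene = np.asarray((x > 0).sum(axis=0)).ravel()
        keep_genes = cells_per_gene >= min_cells_per_gene
        if keep_cells.all() and keep_genes.all():
            break
        ad = ad[keep_cells, :][:, keep_genes].copy()
        if ad.n_obs == 0 or ad.n_vars == 0:
            logger.warning("qc_filter: assay empty after filtering")
            break
    log = QcLog(
        cells_removed=n_cells0 - ad.n_obs,
        genes_removed=n_genes0 - ad.n_vars,
        iterations=iterations,
    )
    logger.info(
        "qc_filter removed %d cells and %d genes in %d pass(es)",
        log.cells_removed,
        log.genes_removed,
        log.iterations,
    )
    return ad, log


def call_dominant_olfr(
    adata: AnnData, cells: pd.Index | np.ndarray | None = None
) -> pd.DataFrame:
    """Call the dominant Olfr gene per cell.

    dominant_gene = argmax UMI over Olfr genes; ties are broken by the
    gene's higher total expression across the considered cells, then by
    lexicographic gene_id, so calls are deterministic.  Cells with zero
    Olfr UMIs get a null call.
    """
    sub = adata[cells, :] if cells is not None else adata
    olfr_mask = sub.var["is_olfr"].to_numpy(bool)
    if not olfr_mask.any():
        raise ValueError("no Olfr genes flagged in var.is_olfr")
    genes = sub.var_names[olfr_mask].to_numpy()
    mat = _to_dense(sub.X[:, olfr_mask])
    totals = mat.sum(axis=0)
    # precedence order: higher subset-wide total first, then gene_id
    order = np.lexsort((genes, -totals))
    mat_ord = mat[:, order]
    genes_ord = genes[order]
    best_idx = mat_ord.argmax(axis=1)  # first occurrence in precedence order
    best_umi = mat_ord.max(axis=1)
    total_olfr = mat_ord.sum(axis=1)
    dominant = np.where(total_olfr > 0, genes_ord[best_idx], None)
    return pd.DataFrame(
        {
            "cell_id": sub.obs_names.to_numpy(),
            "dominant_gene": dominant,
            "dominant_umi": np.where(total_olfr > 0, best_umi, 0).astype(int),
            "total_olfr_umi": total_olfr.astype(int),
        }
    )


@dataclass(frozen=True)
class DominanceFraction:
    k: int
    n: int
    percent: float  # full precision
    percent_display: int  # rounded to the nearest integer for reports

    def as_tuple(self) -> tuple[int, int, int]:
        return self.k, self.n, self.percent_display


def subset_dominance_fraction(
    calls: pd.DataFrame,
    query: set[str],
    n_population: int | None = None,
    denominator: str = "all_cells",
) -> DominanceFraction:
    """Fraction of cells whose dominant Olfr is in ``query``.

    ``denominator="all_cells"`` (default) uses the whole cell population
    (``n_population`` when given, else all rows of ``calls``);
    ``"called_cells"`` uses only cells with a non-null dominant call.
    """
    if denominator not in {"all_cells", "called_cells"}:
        raise ValueError(f"unknown denominator {denominator!r}")
    k = int(calls["dominant_gene"].isin(list(query)).sum())
    if denominator == "called_cells":
        n = int(calls["dominant_gene"].notna().sum())
    else:
        n = int(n_population) if n_population is not None else len(calls)
    pct = 100.0 * k / n if n else 0.0
    return DominanceFraction(
        k=k, n=n, percent=pct, percent_display=int(round(pct))
    )


@dataclass(frozen=True)
class ProportionTest:
    p: float
    odds_ratio: float
    or_ci: tuple[float, float]
    method: str


def compare_fractions(
    wt: tuple[int, int], ko: tuple[int, int]
) -> ProportionTest:
    """Two-proportion test on (k, n) pairs.

    Chi-square without continuity correction; Fisher's exact test when
    any expected cell count is < 5.  Odds ratio and 95% CI from the 2x2
    table.
    """
    (k1, n1), (k2, n2) = wt, ko
    if n1 <= 0 or n2 <= 0:
        raise ValueError("population sizes must be positive")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], float)
    expected = stats.contingency.expected_freq(table)
    if (expected < 5).any():
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        method = "fisher"
    else:
        p = float(stats.chi2_contingency(table, correction=False)[1])
        method = "chi2"
    t22 = sm.stats.Table2x2(table + 0.0)
    return ProportionTest(
        p=p,
        odds_ratio=float(t22.oddsratio),
        or_ci=tuple(float(v) for v in t22.oddsratio_confint()),
        method=method,
    )


def compare_subset_frequencies(
    obs: pd.DataFrame,
    cluster_label: str,
    level: str = "per_all_osn",
) -> dict:
    """Per-sample frequency of a cell cluster, compared between genotypes.

    ``level="per_all_osn"`` divides by OSN-lineage cells (HBC, GBC,
    iOSN, mOSN); ``"per_all_cells"`` by all cells of the sample.  The
    sample (mouse), not the cell, is the replicate unit: genotypes are
    compared with a two-sided Welch t-test on per-sample fractions.
    """
    if level not in {"per_all_osn", "per_all_cells"}:
        raise ValueError(f"unknown level {level!r}")
    df = obs.copy()
    if level == "per_all_osn":
        df = df[df["cell_type"].isin(OSN_LINEAGE)]
    rows = []
    for (sample, genotype), sub in df.groupby(
        ["sample_id", "genotype"], observed=True
    ):
        rows.append(
            {
                "sample_id": sample,
                "genotype": genotype,
                "n_cells": len(sub),
                "fraction": (sub["cell_type"] == cluster_label).mean(),
            }
        )
    per_sample = pd.DataFrame(rows)
    wt = per_sample.loc[per_sample["genotype"] == "WT", "fraction"]
    ko = per_sample.loc[per_sample["genotype"] == "KO", "fraction"]
    if len(wt) < 2 or len(ko) < 2:
        raise ValueError("need >=2 samples per genotype")
    t = stats.ttest_ind(wt, ko, equal_var=False)
    return {
        "per_sample": per_sample,
        "mean_wt": float(wt.mean()),
        "mean_ko": float(ko.mean()),
        "p": float(t.pvalue),
    }
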