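"""End-to-end orchestration of the NMD-target and olfactory analyses.

:func:`run_pipeline` executes the stages in dependency order —
transcript models, NIF profiles, differential expression, stability,
target tiers, translome, and single-cell dominance statistics — and
writes every stage table plus a ``report.json`` capturing tier
cardinalities, dominance fractions, every threshold used, and a
provenance block (version, config hash, seed).

With no input paths configured, the pipeline runs on synthetic data
whose ground truth mirrors the emulated study design; the report then
contains both the truth-input tier counts (which must match the planted
cardinalities exactly) and the counts re-estimated from simulated
counts.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .nif_caller import NifThresholds, profile_transcriptome, profiles_table
from .single_cell import (
    call_dominant_olfr,
    compare_fractions,
    compare_subset_frequencies,
    qc_filter,
    subset_dominance_fraction,
)
from .stability import infer_stability
from .synthetic import (
    gen_study_truth,
    gen_transcriptome,
    simulate_bulk,
    simulate_cells,
    truth_de_table,
)
from .targets import call_tiers, minimal_nb_de, select_upregulated, tier_counts
from .transcript_models import parse_annotation
from .translome import bin_translome, category_counts, compute_te, nmd_magnitude_vs_te

logger = logging.getLogger(__name__)

NA = "."


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, na_rep=NA)


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the report dict (also written as JSON)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        filename=out / "run.log", level=logging.INFO, force=False
    )
    seed = int(config.seed)
    thresholds = NifThresholds(
        dej_min_nt=config.dej_min_nt,
        min_uorf_len=config.min_uorf_len,
        long_utr3_min_nt=config.long_utr3_min_nt,
    )
    synthetic = config.gtf_path is None
    report: dict = {
        "provenance": {
            "version": __version__,
            "config_hash": config.config_hash(),
            "seed": seed,
        },
        "config": config.to_dict(),
        "mode": "synthetic" if synthetic else "external",
    }

    # ---- transcript models & NIF profiles --------------------------------
    if synthetic:
        truth = gen_study_truth(
            n_genes=config.n_genes,
            n_upregulated=config.n_upregulated,
            n_stabilized=config.n_stabilized,
            n_nif=config.n_nif,
            te_coupled_nmd=config.te_coupled_nmd,
            high_te_cutoff=config.high_te_cutoff,
            seed=seed,
        )
        models, t_truth = gen_transcriptome(
            nif_classes=truth["nif_class"],
            long_utr3_min_nt=config.long_utr3_min_nt,
            dej_min_nt=config.dej_min_nt,
            seed=seed + 1,
        )
        truth = truth.merge(
            t_truth[["gene_id", "length", "utr3_len"]], on="gene_id"
        )
        truth["gene_length"] = truth["length"]
    else:
        if config.fasta_path is None:
            raise ValueError("config missing input path: fasta_path")
        models = parse_annotation(config.gtf_path, config.fasta_path)
        truth = None
    profiles = profile_transcriptome(models, thresholds, scope=config.nif_scope)
    nif_table = profiles_table(profiles)
    _write_tsv(nif_table, out / "nif.tsv")

    # ---- counts -----------------------------------------------------------
    if synthetic:
        bulk = simulate_bulk(
            truth,
            depth=config.depth,
            replicates=config.replicates,
            nb_dispersion=config.nb_dispersion,
            seed=seed + 2,
        )
        exonic, intronic, ip = bulk.exonic, bulk.intronic, bulk.ip
        sheet = bulk.sample_sheet
        gene_lengths = bulk.gene_lengths
        de_external = truth_de_table(truth)
    else:
        for key in ("exonic_path", "intronic_path", "sample_sheet_path"):
            if getattr(config, key) is None:
                raise ValueError(f"config missing input path: {key}")
        exonic = pd.read_csv(config.exonic_path, sep="\t", index_col=0)
        intronic = pd.read_csv(config.intronic_path, sep="\t", index_col=0)
        sheet = pd.read_csv(config.sample_sheet_path, sep="\t")
        ip = (
            pd.read_csv(config.ip_path, sep="\t", index_col=0)
            if config.ip_path
            else None
        )
        gene_lengths = pd.Series(2000.0, index=exonic.index)
        de_external = (
            pd.read_csv(config.de_path, sep="\t") if config.de_path else None
        )
    if de_external is not None:
        _write_tsv(de_external, out / "de.tsv")

    # ---- differential expression ------------------------------------------
    de_estimated = minimal_nb_de(exonic, sheet)
    up_external = (
        select_upregulated(de_external, config.alpha)
        if de_external is not None
        else None
    )
    up_estimated = select_upregulated(de_estimated, config.alpha)

    # ---- stability ---------------------------------------------------------
    stability = infer_stability(
        exonic,
        intronic,
        sheet,
        pseudocount=config.stability_pseudocount,
        window_frac=config.stability_window_frac,
        stabilization_min_ddelta=config.stabilization_min_ddelta,
        alpha=config.alpha,
        p_adjust=config.stability_p_adjust,
    )
    _write_tsv(stability.reset_index(), out / "stability.tsv")
    stab_estimated = set(stability.index[stability["stabilized"]])

    # ---- tiers -------------------------------------------------------------
    report["tiers"] = {}
    if synthetic:
        up_true = set(truth.loc[truth["is_upregulated"], "gene_id"])
        stab_true = set(truth.loc[truth["is_stabilized"], "gene_id"])
        tiers_truth = call_tiers(up_true, stab_true, nif_table)
        report["tiers"]["truth_inputs"] = tier_counts(tiers_truth)
        _write_tsv(tiers_truth, out / "targets.tsv")
        up_for_est = up_external if up_external is not None else up_estimated
    else:
        up_for_est = up_external if up_external is not None else up_estimated
    tiers_est = call_tiers(up_for_est, stab_estimated, nif_table)
    report["tiers"]["estimated"] = tier_counts(tiers_est)
    if not synthetic:
        _write_tsv(tiers_est, out / "targets.tsv")

    # ---- translome ---------------------------------------------------------
    if ip is not None:
        wt_samples = sheet.loc[sheet["genotype"] == "WT", "sample"]
        te = compute_te(
            exonic[wt_samples],
            ip[wt_samples] if set(wt_samples) <= set(ip.columns) else ip,
            gene_lengths,
            expression_floor=config.expression_floor,
            pseudocount=config.te_pseudocount,
        )
        binned = bin_translome(te, fractions=config.bin_fractions)
        _write_tsv(binned.reset_index(), out / "translome.tsv")
        report["translome"] = {
            "n_expressed": int(len(binned)),
            "category_counts": {
                str(k): int(v) for k, v in category_counts(binned).items()
            },
        }
        de_for_te = de_external if de_external is not None else de_estimated
        hc_genes = (
            set(tiers_truth.loc[tiers_truth["tier"] == "high_confidence", "gene_id"])
            if synthetic
            else set(tiers_est.loc[tiers_est["tier"] == "high_confidence", "gene_id"])
        )
        if hc_genes:
            report["translome"]["nmd_magnitude_vs_te"] = nmd_magnitude_vs_te(
                de_for_te,
                binned,
                genes=hc_genes,
                mode="correlation",
                high_te_cutoff=config.high_te_cutoff,
            )

    # ---- single cells -------------------------------------------------------
    if synthetic:
        adata, cell_truth = simulate_cells(
            n_cells_per_genotype=config.n_cells_per_genotype,
            subset_mass=config.subset_mass,
            ko_target_prob=config.ko_target_prob,
            seed=seed + 3,
        )
    elif config.cells_dir is not None:
        from .synthetic import read_cells

        adata, cell_truth = read_cells(config.cells_dir), None
    else:
        adata = None
    if adata is not None:
        filtered, qc_log = qc_filter(
            adata,
            min_features=config.qc_min_features,
            min_counts=config.qc_min_counts,
            max_mito_frac=config.qc_max_mito_frac,
        )
        subset = set(
            adata.uns.get("params", {}).get(
                "subset_genes",
                filtered.var_names[filtered.var["is_olfr"]],
            )
        )
        stats = {"qc": {"cells_removed": qc_log.cells_removed,
                        "genes_removed": qc_log.genes_removed}}
        fracs = {}
        for geno in ("WT", "KO"):
            mosn = filtered.obs.index[
                (filtered.obs["genotype"] == geno)
                & (filtered.obs["cell_type"] == "mOSN")
            ]
            calls = call_dominant_olfr(filtered, mosn)
            frac = subset_dominance_fraction(calls, subset)
            fracs[geno] = frac
            stats[geno] = {
                "k": frac.k,
                "n": frac.n,
                "percent": frac.percent,
                "percent_display": frac.percent_display,
            }
        test = compare_fractions(
            (fracs["WT"].k, fracs["WT"].n), (fracs["KO"].k, fracs["KO"].n)
        )
        stats["comparison"] = {
            "p": test.p,
            "odds_ratio": test.odds_ratio,
            "method": test.method,
        }
        hbc = compare_subset_frequencies(filtered.obs, "HBC", level="per_all_osn")
        stats["hbc_frequency"] = {
            "mean_wt": hbc["mean_wt"],
            "mean_ko": hbc["mean_ko"],
            "p": hbc["p"],
        }
        with open(out / "olfr_stats.json", "w") as fh:
            json.dump(stats, fh, indent=2)
        report["olfr"] = stats

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
    logger.info("pipeline complete: %s", out)
    return report


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
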