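"""Run configuration: every tunable threshold with its documented default."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """All thresholds and inputs of an end-to-end run.

    Unknown keys in a YAML config are rejected.  When no input paths are
    given the pipeline runs on synthetic data generated from ``seed``.
    """

    # NIF thresholds (nt)
    dej_min_nt: int = 50
    min_uorf_len: int = 30
    long_utr3_min_nt: int = 1000
    nif_scope: str = "representative"
    # DE / stabilization
    alpha: float = 0.05
    stabilization_min_ddelta: float = 0.0
    stability_pseudocount: float = 0.5
    stability_window_frac: float = 0.1
    stability_p_adjust: str = "bh"  # genome-wide screen; "none" inside candidate sets
    # translome
    expression_floor: float = 1.0
    te_pseudocount: float = 0.1
    bin_fractions: tuple[float, float, float] = (0.3, 0.4, 0.3)
    utr3_length_edges: tuple[float, ...] = (500.0, 1000.0, 2000.0)
    high_te_cutoff: float = 1.0
    # single-cell QC
    qc_min_features: int = 500
    qc_min_counts: int = 1500
    qc_max_mito_frac: float = 0.002
    # synthetic-generation conditions (the emulated study design)
    n_genes: int = 2000
    n_upregulated: int = 127
    n_stabilized: int = 82
    n_nif: int = 52
    depth: float = 1.5e7
    replicates: int = 4
    nb_dispersion: float = 0.1
    te_coupled_nmd: bool = True
    n_cells_per_genotype: int = 4000
    subset_mass: float = 0.13
    ko_target_prob: float = 0.07
    # inputs (optional; synthetic mode when absent)
    gtf_path: str | None = None
    fasta_path: str | None = None
    de_path: str | None = None
    exonic_path: str | None = None
    intronic_path: str | None = None
    ip_path: str | None = None
    sample_sheet_path: str | None = None
    cells_dir: str | None = None
    # run
    seed: int = 1
    output_dir: str = "nmdscope_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("bin_fractions", "utr3_length_edges"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bin_fractions"] = list(self.bin_fractions)
        d["utr3_length_edges"] = list(self.utr3_length_edges)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]
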