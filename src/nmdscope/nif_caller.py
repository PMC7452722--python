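"""NMD-inducing-feature (NIF) calling on transcript models.

Three transcript attributes predict targeting by nonsense-mediated mRNA
decay and are annotated per transcript:

dEJ
    At least one exon-exon junction >= ``dej_min_nt`` (default 50) nt
    downstream of the stop codon terminating the main ORF.  The junction
    is assigned the transcript coordinate of the last base of its
    upstream exon; for a junction at position ``j >= cds_end`` the
    distance is ``j - cds_end + 1`` (number of 3'UTR nt 5' of and
    including the junction's last upstream base).

uORF
    An upstream open reading frame satisfying all of: (i) it lies in the
    5'UTR; (ii) its start codon is in a context known to initiate
    translation — a purine (A/G) at position −3 or a G at position +4
    relative to the A of the AUG (+1); (iii) it is at least
    ``min_uorf_len`` (default 30) nt long, stop codon included; (iv) it
    does not overlap the main ORF (the whole uORF, stop included, ends
    at or before ``cds_start``).

long 3'UTR
    3'UTR length >= ``long_utr3_min_nt`` (default 1000) nt.

Only transcripts with a detectable 5'UTR and 3'UTR are considered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .transcript_models import (
    STOP_CODONS,
    TranscriptModel,
    UtrAnnotation,
    annotate_utrs,
    group_by_gene,
    pick_representative,
)

logger = logging.getLogger(__name__)

PURINES = {"A", "G"}


@dataclass(frozen=True)
class NifThresholds:
    """Thresholds for the three NIF rules, all in nt."""

    dej_min_nt: int = 50
    min_uorf_len: int = 30
    long_utr3_min_nt: int = 1000


@dataclass(frozen=True)
class UorfHit:
    """One qualifying upstream ORF.

    ``start`` is the transcript coordinate of the A of the AUG;
    ``length_nt`` runs from the AUG through the stop codon inclusive.
    """

    start: int
    length_nt: int
    minus3: str
    plus4: str
    context_ok: bool


@dataclass(frozen=True)
class NifProfile:
    transcript_id: str
    gene_id: str
    has_dej: bool
    dej_max_distance: int | None
    uorfs: tuple[UorfHit, ...]
    has_uorf: bool
    utr3_len: int
    has_long_utr3: bool
    any_nif: bool
    thresholds_used: NifThresholds

    @property
    def n_nifs(self) -> int:
        return int(self.has_dej) + int(self.has_uorf) + int(self.has_long_utr3)


def call_dej(
    model: TranscriptModel, utr: UtrAnnotation, dej_min_nt: int = 50
) -> tuple[bool, int | None]:
    """Call a downstream exon junction (dEJ) on one transcript.

    Returns ``(has_dej, dej_max_distance)``; the distance is None when no
    junction lies downstream of the stop codon.
    """
    distances = [
        j - model.cds_end + 1 for j in utr.junction_positions if j >= model.cds_end
    ]
    if not distances:
        return False, None
    dmax = max(distances)
    return dmax >= dej_min_nt, dmax


def call_uorfs(model: TranscriptModel, min_uorf_len: int = 30) -> list[UorfHit]:
    """Scan the 5'UTR (all three frames) for qualifying upstream ORFs.

    An AUG qualifies when an in-frame stop codon ends at or before
    ``cds_start``, the ORF (stop included) is >= ``min_uorf_len`` nt, and
    the initiation context holds (A/G at −3 or G at +4; any other
    character, including lowercase or N, fails the context).  Hits are
    reported 5'->3'.
    """
    seq = model.sequence
    cds_start = model.cds_start
    hits: list[UorfHit] = []
    pos = seq.find("ATG", 0)
    while 0 <= pos < cds_start:
        if pos >= 3:
            hit = _extend_orf(seq, pos, cds_start, min_uorf_len)
            if hit is not None:
                hits.append(hit)
        pos = seq.find("ATG", pos + 1)
    return hits


def _extend_orf(
    seq: str, start: int, cds_start: int, min_uorf_len: int
) -> UorfHit | None:
    for p in range(start + 3, cds_start - 2, 3):
        if seq[p : p + 3] in STOP_CODONS:
            end = p + 3
            if end > cds_start:
                return None
            length = end - start
            if length < min_uorf_len:
                return None
            minus3 = seq[start - 3]
            plus4 = seq[start + 3]
            context_ok = minus3 in PURINES or plus4 == "G"
            if not context_ok:
                return None
            return UorfHit(
                start=start,
                length_nt=length,
                minus3=minus3,
                plus4=plus4,
                context_ok=True,
            )
    return None


def call_long_utr3(utr: UtrAnnotation, long_utr3_min_nt: int = 1000) -> bool:
    """True iff the 3'UTR is at least ``long_utr3_min_nt`` nt long."""
    return utr.utr3_len >= long_utr3_min_nt


def profile_transcript(
    model: TranscriptModel, thresholds: NifThresholds = NifThresholds()
) -> NifProfile:
    """Full NIF profile for one eligible transcript."""
    utr = annotate_utrs(model)
    has_dej, dmax = call_dej(model, utr, thresholds.dej_min_nt)
    uorfs = tuple(call_uorfs(model, thresholds.min_uorf_len))
    has_uorf = len(uorfs) > 0
    has_long = call_long_utr3(utr, thresholds.long_utr3_min_nt)
    return NifProfile(
        transcript_id=model.transcript_id,
        gene_id=model.gene_id,
        has_dej=has_dej,
        dej_max_distance=dmax,
        uorfs=uorfs,
        has_uorf=has_uorf,
        utr3_len=utr.utr3_len,
        has_long_utr3=has_long,
        any_nif=has_dej or has_uorf or has_long,
        thresholds_used=thresholds,
    )


def profile_transcriptome(
    models: Iterable[TranscriptModel],
    thresholds: NifThresholds = NifThresholds(),
    scope: str = "representative",
) -> list[NifProfile]:
    """NIF-profile a transcriptome at gene level.

    ``scope="representative"`` profiles one representative isoform per
    gene (longest CDS); ``scope="any_isoform"`` ORs the three NIF flags
    over every eligible isoform of the gene (dEJ distance and 3'UTR
    length are then reported from the representative).  Ineligible
    transcripts are excluded and counted in the log.
    """
    if scope not in {"representative", "any_isoform"}:
        raise ValueError(f"unknown scope {scope!r}")
    by_gene = group_by_gene(models)
    if not by_gene:
        logger.warning("profile_transcriptome: empty input")
        return []
    n_ineligible = sum(
        1 for ms in by_gene.values() for m in ms if not m.eligible
    )
    if n_ineligible:
        logger.info("excluded %d ineligible transcripts (missing a UTR)", n_ineligible)

    profiles: list[NifProfile] = []
    for gene_id in sorted(by_gene):
        rep = pick_representative(by_gene[gene_id])
        if rep is None:
            logger.info("gene %s unannotatable: no eligible isoform", gene_id)
            continue
        prof = profile_transcript(rep, thresholds)
        if scope == "any_isoform":
            extra = [
                profile_transcript(m, thresholds)
                for m in by_gene[gene_id]
                if m.eligible and m.transcript_id != rep.transcript_id
            ]
            if extra:
                has_dej = prof.has_dej or any(p.has_dej for p in extra)
                has_uorf = prof.has_uorf or any(p.has_uorf for p in extra)
                has_long = prof.has_long_utr3 or any(p.has_long_utr3 for p in extra)
                uorfs = prof.uorfs if prof.has_uorf else next(
                    (p.uorfs for p in extra if p.has_uorf), ()
                )
                prof = NifProfile(
                    transcript_id=prof.transcript_id,
                    gene_id=gene_id,
                    has_dej=has_dej,
                    dej_max_distance=prof.dej_max_distance,
                    uorfs=tuple(uorfs),
                    has_uorf=has_uorf,
                    utr3_len=prof.utr3_len,
                    has_long_utr3=has_long,
                    any_nif=has_dej or has_uorf or has_long,
                    thresholds_used=thresholds,
                )
        profiles.append(prof)
    return profiles


def profiles_table(profiles: Sequence[NifProfile]) -> pd.DataFrame:
    """Tabulate NIF profiles in the published layout plus machine columns.

    Human-readable columns mirror the published target table (gene,
    dEJ YES/NO, uORF YES/NO, 3'UTR length); boolean/machine columns are
    appended for downstream joins.
    """
    rows = []
    for p in profiles:
        rows.append(
            {
                "gene_id": p.gene_id,
                "transcript_id": p.transcript_id,
                "dEJ": "YES" if p.has_dej else "NO",
                "uORF": "YES" if p.has_uorf else "NO",
                "utr3_len": p.utr3_len,
                "has_dej": p.has_dej,
                "has_uorf": p.has_uorf,
                "has_long_utr3": p.has_long_utr3,
                "any_nif": p.any_nif,
                "n_nifs": p.n_nifs,
                "dej_max_distance": p.dej_max_distance,
                "n_uorfs": len(p.uorfs),
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values("gene_id").reset_index(drop=True) if len(df) else df
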