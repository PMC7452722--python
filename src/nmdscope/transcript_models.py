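"""Strand-resolved transcript models with CDS/UTR structure.

A :class:`TranscriptModel` holds the spliced transcript sequence (5'->3'),
the genomic exon intervals ordered in transcript orientation, and the main
ORF as half-open offsets in transcript coordinates.  All internal
coordinates are 0-based half-open; GTF input (1-based inclusive) is
converted on parse.  ``cds_end`` includes the stop codon, so the 3'UTR
begins at the first base after the stop codon — the convention used for
both the 3'UTR-length arithmetic and the downstream-exon-junction (dEJ)
distance.

Parsing of annotation goes through :mod:`gffutils`; sequence access goes
through :mod:`pyfaidx`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

START_CODONS = {"ATG"}
STOP_CODONS = {"TAA", "TAG", "TGA"}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: exon structure, main ORF, and spliced sequence.

    ``exons`` are genomic 0-based half-open intervals ordered 5'->3' in
    transcript orientation (descending genomic order on the minus strand).
    ``cds_start``/``cds_end`` are transcript-coordinate offsets of the
    main ORF including its stop codon.
    """

    transcript_id: str
    gene_id: str
    gene_symbol: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int
    sequence: str
    chrom: str = "."

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        total = sum(e - s for s, e in self.exons)
        if total != len(self.sequence):
            raise ValueError(
                f"{self.transcript_id}: exon lengths sum to {total}, "
                f"sequence is {len(self.sequence)} nt"
            )
        if not (0 <= self.cds_start < self.cds_end <= len(self.sequence)):
            raise ValueError(f"{self.transcript_id}: CDS outside transcript")
        if (self.cds_end - self.cds_start) % 3 != 0:
            raise ValueError(f"{self.transcript_id}: CDS length not a multiple of 3")

    # -- derived quantities -------------------------------------------------

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def utr5_len(self) -> int:
        return self.cds_start

    @property
    def utr3_len(self) -> int:
        return self.length - self.cds_end

    @property
    def cds_len(self) -> int:
        return self.cds_end - self.cds_start

    @property
    def exon_lengths(self) -> tuple[int, ...]:
        return tuple(e - s for s, e in self.exons)

    @property
    def junction_positions(self) -> tuple[int, ...]:
        """Transcript coordinate of the last base of each non-terminal exon."""
        positions = []
        cum = 0
        for length in self.exon_lengths[:-1]:
            cum += length
            positions.append(cum - 1)
        return tuple(positions)

    @property
    def eligible(self) -> bool:
        """True iff the transcript has a detectable 5'UTR and 3'UTR."""
        return self.utr5_len >= 1 and self.utr3_len >= 1

    def codon_check(self) -> bool:
        """True if the ORF starts with a start codon and ends with a stop.

        Ambiguous bases (N) in either codon abolish the check (returns
        True) without invalidating the transcript.
        """
        start = self.sequence[self.cds_start : self.cds_start + 3].upper()
        stop = self.sequence[self.cds_end - 3 : self.cds_end].upper()
        if "N" in start or "N" in stop:
            return True
        return start in START_CODONS and stop in STOP_CODONS

    # -- coordinate mapping -------------------------------------------------

    def genomic_to_transcript(self, gpos: int) -> int:
        """Map a genomic base position (0-based) into transcript coordinates."""
        cum = 0
        for (s, e) in self.exons:
            if s <= gpos < e:
                if self.strand == "+":
                    return cum + (gpos - s)
                return cum + (e - 1 - gpos)
            cum += e - s
        raise ValueError(f"position {gpos} not exonic in {self.transcript_id}")

    def transcript_to_genomic(self, tpos: int) -> int:
        """Map a transcript coordinate back to its genomic base position."""
        if not 0 <= tpos < self.length:
            raise ValueError(f"transcript position {tpos} out of range")
        cum = 0
        for (s, e) in self.exons:
            span = e - s
            if tpos < cum + span:
                off = tpos - cum
                return s + off if self.strand == "+" else e - 1 - off
            cum += span
        raise AssertionError("unreachable")


@dataclass(frozen=True)
class UtrAnnotation:
    """UTR lengths and exon-junction positions in transcript coordinates."""

    transcript_id: str
    utr5_len: int
    utr3_len: int
    junction_positions: tuple[int, ...]
    eligible: bool


def annotate_utrs(model: TranscriptModel) -> UtrAnnotation:
    """Annotate UTR lengths and junction positions for one transcript.

    A transcript is ``eligible`` for NIF calling iff both UTRs are at
    least 1 nt long.
    """
    return UtrAnnotation(
        transcript_id=model.transcript_id,
        utr5_len=model.utr5_len,
        utr3_len=model.utr3_len,
        junction_positions=model.junction_positions,
        eligible=model.eligible,
    )


def pick_representative(models: Sequence[TranscriptModel]) -> TranscriptModel | None:
    """Pick the representative isoform of a gene: longest CDS.

    Ties are broken by longest transcript, then lexicographically smallest
    transcript_id, so the choice is deterministic.  Returns None when the
    gene has no eligible isoform (gene unannotatable for NIF purposes).
    """
    eligible = [m for m in models if m.eligible]
    if not eligible:
        return None
    return min(eligible, key=lambda m: (-m.cds_len, -m.length, m.transcript_id))


def _fetch(fasta: Fasta, chrom: str, start: int, end: int) -> str:
    if chrom not in fasta:
        raise KeyError(f"contig {chrom!r} missing from FASTA")
    return str(fasta[chrom][start:end]).upper()


def parse_annotation(
    gtf_path: str | Path, fasta_path: str | Path
) -> list[TranscriptModel]:
    """Parse a GTF/GFF3 + genome FASTA into transcript models.

    Requires exon and CDS features carrying transcript_id/gene_id
    attributes.  The CDS extent is taken stop-codon-inclusive; separate
    ``stop_codon`` features, when present, are merged into the CDS.
    Minus-strand transcripts are reverse-complemented so sequences read
    5'->3'.  Transcripts whose CDS length is not a multiple of 3 are
    excluded with a warning; a missing FASTA contig is a hard error.
    """
    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=True,
    )
    fasta = Fasta(str(fasta_path), sequence_always_upper=True)

    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    meta: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in {"exon", "CDS", "stop_codon"}:
            continue
        tid = feat.attributes.get("transcript_id", [None])[0]
        if tid is None:
            continue
        rec = meta.setdefault(
            tid,
            {
                "gene_id": feat.attributes.get("gene_id", [tid])[0],
                "gene_symbol": feat.attributes.get(
                    "gene_name", feat.attributes.get("gene_id", [tid])
                )[0],
                "chrom": feat.seqid,
                "strand": feat.strand,
            },
        )
        # GTF 1-based inclusive -> 0-based half-open
        iv = (feat.start - 1, feat.end)
        if feat.featuretype == "exon":
            exons.setdefault(tid, []).append(iv)
        else:
            cds.setdefault(tid, []).append(iv)

    models: list[TranscriptModel] = []
    for tid, ex in exons.items():
        if tid not in cds:
            continue
        info = meta[tid]
        strand = info["strand"]
        ex_sorted = sorted(ex)
        if strand == "-":
            ex_ordered = tuple(ex_sorted[::-1])
        else:
            ex_ordered = tuple(ex_sorted)
        chrom = info["chrom"]
        pieces = []
        for s, e in ex_ordered:
            piece = _fetch(fasta, chrom, s, e)
            pieces.append(reverse_complement(piece) if strand == "-" else piece)
        sequence = "".join(pieces)

        cds_ivs = sorted(cds[tid])
        g_first = cds_ivs[0][0] if strand == "+" else cds_ivs[-1][1] - 1
        g_last = cds_ivs[-1][1] - 1 if strand == "+" else cds_ivs[0][0]

        model_kwargs = dict(
            transcript_id=tid,
            gene_id=info["gene_id"],
            gene_symbol=info["gene_symbol"],
            strand=strand,
            exons=ex_ordered,
            sequence=sequence,
            chrom=chrom,
        )
        probe = TranscriptModel(
            cds_start=0, cds_end=3, **{**model_kwargs, "sequence": sequence}
        )
        t_start = probe.genomic_to_transcript(g_first)
        t_end = probe.genomic_to_transcript(g_last) + 1
        if (t_end - t_start) % 3 != 0:
            logger.warning(
                "transcript %s excluded: CDS length %d not a multiple of 3",
                tid,
                t_end - t_start,
            )
            continue
        model = TranscriptModel(cds_start=t_start, cds_end=t_end, **model_kwargs)
        if not model.codon_check():
            logger.warning(
                "transcript %s: CDS boundaries are not canonical start/stop codons",
                tid,
            )
        models.append(model)
    return models


def group_by_gene(
    models: Iterable[TranscriptModel],
) -> Mapping[str, list[TranscriptModel]]:
    grouped: dict[str, list[TranscriptModel]] = {}
    for m in models:
        grouped.setdefault(m.gene_id, []).append(m)
    return grouped


def annotation_table(models: Iterable[TranscriptModel]) -> pd.DataFrame:
    """Per-transcript summary table (one row per transcript)."""
    rows = []
    for m in models:
        rows.append(
            {
                "transcript_id": m.transcript_id,
                "gene_id": m.gene_id,
                "strand": m.strand,
                "n_exons": len(m.exons),
                "utr5_len": m.utr5_len,
                "cds_len": m.cds_len,
                "utr3_len": m.utr3_len,
                "eligible": m.eligible,
            }
        )
    return pd.DataFrame(rows)
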