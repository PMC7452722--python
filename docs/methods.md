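# Methods

This note documents the models, defaults, and design choices behind
`nmdscope`, and what the synthetic generators do and do not emulate.

## Transcript models and coordinates

Internal coordinates are 0-based half-open and transcript-oriented; GTF
input (1-based inclusive) is converted on parse. `cds_end` *includes*
the stop codon, so the 3′UTR begins at the first base after the stop —
this convention makes 3′UTR-length arithmetic (`utr3_len = length −
cds_end`) and the dEJ distance definition unambiguous. The synthetic GTF
writer emits CDS features stop-codon-inclusive and the parser treats CDS
extent the same way (separate `stop_codon` features, if present, are
merged). Transcripts whose CDS length is not a multiple of 3 are
excluded with a warning; ambiguous bases (N) at the start/stop codons
disable codon validation without excluding the transcript.

Only transcripts with a detectable 5′UTR and 3′UTR (≥ 1 nt each) are
eligible for NIF calling. Genes are reduced to one representative
isoform — longest CDS, ties by longest transcript then lexicographic
id — because downstream tables carry one 3′UTR length per gene; a
`scope="any_isoform"` switch instead ORs the NIF flags over all eligible
isoforms. Which isoform policy the original analyses used is not
documented anywhere we know of, so both are provided and neither is
asserted as canonical.

## NIF calling

- **dEJ.** A junction is assigned the transcript coordinate of the last
  base of its upstream exon; for a junction at position `j ≥ cds_end`
  the distance is `d = j − cds_end + 1`, i.e. the number of 3′UTR nt 5′
  of and including that base. `has_dej` is true iff any `d ≥ dej_min_nt`
  (default 50, inclusive). The inclusive/exclusive boundary and the
  5′-vs-3′ junction-base convention differ by at most 1 nt, which the
  configurable threshold absorbs.
- **uORF.** All AUGs in the 5′UTR are scanned; the ORF runs to the first
  in-frame stop. A hit requires the entire ORF (stop included) to end at
  or before `cds_start` (strict containment: overlap with the main ORF
  could permit re-initiation and escape from NMD), length ≥
  `min_uorf_len` (default 30 nt, i.e. 10 codons *including* the stop —
  whether the stop counts toward the published 30-nt bound is unstated;
  the choice is conventional and configurable), and initiation context:
  A or G at −3, or G at +4. Lowercase or N at those positions fails the
  context test (conservative). Non-AUG starts are out of scope.
- **Long 3′UTR.** `utr3_len ≥ long_utr3_min_nt`. No threshold is printed
  in the source material; 1,000 nt is chosen as an upper-bounding
  default consistent with the bundled published table, whose shortest
  dEJ-free/uORF-free 3′UTR is 1,029 nt (all 52 rows then carry ≥ 1 NIF,
  and a sweep shows this holds iff the threshold is ≤ 1,029). It must
  remain configurable.

## Stability inference

The exon−intron statistic `Δ_gs = log2((x+c)/N_s) − log2((i+c)/M_s)`
(pseudocount c = 0.5) is a deliberate simplification of
gene-specific-bias–corrected stability inference from pre-mRNA vs
mature-mRNA signal: the downstream target calling needs only *relative
stabilization between genotypes*, not absolute decay rates. Bias
correction subtracts a running-median trend of Δ against mean log2
exonic abundance (window = 10% of genes; window ≥ 1 degenerates to
median subtraction; skipped under 50 genes), then re-centres each sample
at median 0. Externally computed Δ tables can be substituted.

Stabilization: ΔΔ = mean Δ(KO) − mean Δ(WT) > `stabilization_min_ddelta`
(default 0) with a two-sided Welch t-test across replicate Δ values at
α = 0.05. Two p-value policies are provided because the statistic is
used in two positions:

- `p_adjust="none"` (default) — the statistic as a *filter inside a
  small, pre-selected candidate set* (e.g. genes already called
  differentially expressed), where per-gene α is the appropriate scale;
- `p_adjust="bh"` — Benjamini–Hochberg across genes for *genome-wide
  screens*, where raw α = 0.05 would admit ~2.5% of null genes as
  false stabilized calls and swamp any realistically sized true set.
  The parameter-recovery analyses use this mode.

Genes with zero intronic counts in every sample are flagged
unmeasurable and never called. With a single replicate per genotype the
test is skipped and calls are threshold-only (with a warning).

## Differential expression

DE tables (gene, log2fc, padj) are expected from a dedicated external
tool; `minimal_nb_de` is a small self-contained substitute
(median-of-ratios size factors, method-of-moments NB dispersion, Wald
test, BH adjustment) adequate for synthetic data and sanity checks. It
has no dispersion shrinkage, so its power at weak fold changes
(log2FC ≲ 0.5 at 4 vs 4 replicates, dispersion 0.1) is limited — by
design it is plumbing, not the analysis.

## Target tiers

Over the union of gene universes: `candidate_nif` = upregulated
(padj < α, log2fc > 0) with ≥ 1 NIF; `high_confidence` = additionally
stabilized. Gene-symbol matching for prior-target overlap is exact and
case-sensitive (no alias resolution, avoiding silent mis-joins).

## Translome

TPM is computed with gene-length normalization for both input and IP
libraries (identical length models — whether the original analysis did
the same is unstated; assumed yes). Defaults: expression floor 1 TPM on
input, TE pseudocount 0.1 TPM, both unstated upstream and therefore
configurable. Binning is rank-based at the 30th/70th percentiles with a
documented tie rule: values strictly below/above the quantiles are
low/high, boundary ties are medium, so a degenerate all-equal input is
all-medium. Categories 1–9 cross TE (rows, high→low) with steady-state
level (columns, high→low); category 1 = high/high. Group comparisons
default to Mann–Whitney (robust; switchable to Welch); TE-by-3′UTR bins
default to 0.5/1/2 kb edges and also report a global Kruskal–Wallis p.
NMD-magnitude analyses split genes either into TE tertiles (a = most
translated) or at log2TE > 1; per-group least-squares R² of log2fc on
log2TE is reported as undefined (not zero) for groups with < 3 genes or
no TE variance.

Note that TPM-based TE is compositional: a global shift in the IP
library composition shifts all log2TE by a constant, so the
log2TE > 1 cutoff is meaningful on a given dataset's scale rather than
absolutely.

## Single cells

QC thresholds: detected genes > 500, UMIs > 1,500, mitochondrial UMI
fraction < 0.2%, genes expressed in ≥ 3 cells. Cell and gene predicates
are iterated to a fixed point so the filter is idempotent. Dominant-Olfr
ties break by the gene's higher total expression across the considered
cells, then lexicographic id (deterministic); cells with zero Olfr UMIs
get a null call, and any cell with ≥ 1 Olfr UMI is callable (no minimum
dominance count — a minimum is not documented upstream). Dominance
fractions default to the *whole* cell population as denominator
(matching reported full-population counts); `called_cells` is the
alternative. The two-proportion test is chi-square without continuity
correction, switching to Fisher's exact test when any expected cell
count is < 5 (the original test is unstated; a permutation oracle backs
the choice in the tests). Cluster-frequency comparisons treat the
sample (mouse), not the cell, as the replicate unit — cells within an
animal are not independent — using Welch's t on per-sample fractions.

## Synthetic data

`gen_study_truth` mirrors the emulated study design: 2,000 genes, 127
upregulated, of which 82 stabilized, of which 52 NIF-bearing; 4 vs 4
bulk replicates; effect sizes uniform in [0.4, 2] log2 units (the range
the bundled published table spans) unless fixed; optional TE-coupled
NMD magnitude (above the log2TE > 1 cutoff, or proportional across the
range) mirroring the high-translation/strong-NMD pattern.

`gen_transcriptome` plants NIF classes *constructively*: a junction
placed ≥ 50 nt into the 3′UTR (dEJ), an AUG with A at −3 and an
in-frame stop inside the 5′UTR (uORF), a 3′UTR drawn ≥ 1,200 nt
(long3utr); non-NIF genes are built to violate every rule (ATG-scrubbed
5′UTRs, junctions confined upstream of the stop or < 50 nt downstream,
3′UTRs ≤ 800 nt). Recovery by the caller is therefore exact, not
probabilistic.

`simulate_bulk` draws one Gamma transcription level per gene and sample
(CV² = `nb_dispersion`, default 0.1) *shared* by the exonic, intronic
and IP means, with Poisson counts given the level. Marginally each
table is NB(mean, dispersion); jointly, the exon−intron Δ cancels
replicate-level transcriptional noise, which is the physically correct
structure — mature mRNA, pre-mRNA and ribosome-associated mRNA all
report the same underlying transcriptional state of that animal.
Stabilized genes gain their fold change on exonic/IP means only
(intronic invariant); transcriptionally upregulated genes gain it
everywhere. Default depth 1.5e7 reads per sample (the emulated
experiments sequenced 15–22M); intronic library 10% of exonic; ~2% of
genes intronless (unmeasurable-path coverage). Counts are generated
directly; no read-level simulation.

`simulate_cells` draws one dominant Olfr per neuron from a categorical
distribution (subset mass 0.13 over 78 of 200 receptors by default; KO
multiplies subset weights by `selection_factor` — or the factor implied
by a target KO probability via the odds ratio — and renormalizes),
Poisson(20) UMIs on the dominant receptor over a Poisson(0.05)
background (keeping dominance calls near-perfect while exercising
tie/absent paths), filler genes to satisfy QC, and a 2% deliberately
shallow cell fraction to exercise the filter. Not emulated: ambient
RNA, doublets, batch effects, per-animal compositional variance beyond
multinomial sampling, and receptor-expression heterogeneity — so
passing tests show the *statistics* behave correctly under the planted
model, not that real data meets the model.

## Problem sizes and determinism

All randomness flows from integer seeds through `numpy.random.default_rng`;
identical seed + parameters give byte-identical outputs. The test suite
and the acceptance script run the oracle-equivalence checks at 1,000
transcripts, stability recovery at 2,000 genes over multiple seeds
(20 in the tests, 5 in the script), single-cell recovery at 4,000 cells
per genotype, and the end-to-end run at the full emulated design —
sizes chosen to make Monte-Carlo checks stable while keeping the whole
suite fast on one CPU.

## Known limitations

- The stability statistic is relative; no half-lives, no isoform-level
  stability, no metabolic-labeling model.
- NIF calling ignores EJC-deposition heterogeneity, non-AUG initiation,
  and translation-efficiency-aware uORF scoring.
- `minimal_nb_de` is not a replacement for a dedicated DE package.
- Clustering, embedding, pseudotime, and enrichment analyses are out of
  scope; cell-type labels are inputs.
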