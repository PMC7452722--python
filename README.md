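# nmdscope

Identification of in-vivo nonsense-mediated mRNA decay (NMD) targets in
mouse mature olfactory sensory neurons (mOSNs), plus the downstream
olfactory analyses that NMD-target calling feeds: RiboTag
translation-efficiency profiling and single-cell dominant
olfactory-receptor (Olfr) selection statistics.

The package is written for transcriptomics researchers who want to call
NMD targets from annotation plus bulk exonic/intronic counts — or to
study the statistical behaviour of that calling pipeline on fully
synthetic data with planted ground truth.

## What it computes

**NMD-inducing features (NIFs).** Per transcript, three features that
predict decay by the UPF3B-dependent NMD branch:

- **dEJ** — an exon–exon junction ≥ 50 nt downstream of the stop codon
  terminating the main ORF (the "−50-nt boundary rule": an exon-junction
  complex left downstream of termination triggers NMD);
- **uORF** — an upstream ORF in the 5′UTR, ≥ 30 nt (stop included), in a
  translation-initiation context (purine at −3 or G at +4 relative to the
  A of the AUG), not overlapping the main ORF;
- **long 3′UTR** — 3′UTR ≥ 1,000 nt (configurable).

**RNA-stability inference.** Steady-state (exonic) read density reflects
transcription/decay; pre-mRNA (intronic) density reflects transcription
alone. Per gene *g* and sample *s*,

    Δ_gs = log2((x_gs + c)/N_s) − log2((i_gs + c)/M_s)

is a relative-stability proxy (library sizes N, M; pseudocount c). After
running-median bias correction against abundance, a gene is *stabilized*
in the knockout when ΔΔ = mean Δ(KO) − mean Δ(WT) > 0 with a Welch test
across replicates (optionally Benjamini–Hochberg adjusted for
genome-wide screens).

**Target tiers.** Genes upregulated in the NMD-deficient genotype
(padj < 0.05, log2FC > 0) that carry ≥ 1 NIF are *candidate* targets;
those additionally stabilized are *high-confidence* targets.

**Translome.** Translation efficiency TE = log2((TPM_IP + c)/(TPM_input
+ c)) from RiboTag IP vs input RNA-seq; 30/40/30 low/medium/high bins by
TE and by steady-state level (a 3×3 category grid), TE vs 3′UTR length,
and NMD magnitude vs TE.

**Single cells.** QC filtering (features > 500, UMIs > 1,500,
mitochondrial fraction < 0.2%, genes in ≥ 3 cells), per-cell dominant
Olfr (argmax UMI; one-neuron-one-receptor), and two-proportion tests on
the fraction of cells dominated by a query receptor subset.

A synthetic-data module generates all inputs — transcript models with
constructively planted NIFs (GTF + FASTA), negative-binomial
exonic/intronic/IP counts with planted decay changes, and cell×gene UMI
matrices with planted dominant receptors — so every stage is testable
without downloads.

## Worked example

Simulate a transcriptome with planted NIF classes and annotate it:

```bash
nmdscope simulate transcriptome --seed 4 --n-genes 200 -o demo/
nmdscope nif --gtf demo/annotation.gtf --fasta demo/genome.fa -o demo/nif.tsv
# wrote 200 gene profiles to demo/nif.tsv
head -3 demo/nif.tsv | cut -f1-5
# gene_id  transcript_id  dEJ  uORF  utr3_len
# g00000   t00000         NO   NO    654
# g00001   t00001         NO   NO    1306
```

Run the full synthetic pipeline (2,000 genes, 127 planted upregulated of
which 82 stabilized of which 52 NIF-bearing; 4,000 cells per genotype
with a 78-receptor subset at 13% selection mass in WT, 7% in KO):

```bash
nmdscope run --seed 1 -o run/
```

`run/report.json` then contains, among others:

```
"tiers": {"truth_inputs": {"n_upregulated": 127,
                           "n_stabilized_upregulated": 82,
                           "n_high_confidence": 52}, ...}
"olfr":  {"WT": {"k": 271, "n": 2023, "percent_display": 13},
          "KO": {"k": 150, "n": 2011, "percent_display": 7},
          "comparison": {"p": 6.97e-10, "odds_ratio": 1.92}}
```

i.e. the tier chain 127 → 82 → 52 is recovered exactly from the planted
truth, and 13% of simulated WT mOSNs vs 7% of KO mOSNs have a
subset receptor as their dominant Olfr (chi-square p ≈ 7e-10).

The library surface mirrors the CLI: `transcript_models.parse_annotation`,
`nif_caller.profile_transcriptome`, `stability.infer_stability`,
`targets.call_tiers`, `translome.compute_te`,
`single_cell.call_dominant_olfr`, `synthetic.gen_transcriptome`, etc.

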