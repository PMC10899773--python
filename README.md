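# chargeseq

Quantify genome-wide tRNA aminoacylation ("charging") from
periodate-oxidation sequencing libraries.

## The problem

Every mature tRNA ends in 3′-CCA, and a charged tRNA carries its amino
acid esterified to the terminal A. Treating total RNA with NaIO₄
oxidizes the free 3′-ribose of *uncharged* tRNAs only (charged ones are
protected by the amino acid); alkaline β-elimination then removes the
oxidized 3′-A from uncharged molecules and deacylates charged ones. The
sequencing library therefore encodes charging state directly in the
read: molecules ending **CCA** were charged, molecules ending **CC**
were uncharged. Each molecule is ligated to a 3′-adapter carrying 5
random nucleotides (UMI) and a 5-nt inline sample barcode, then a
5′-adapter, and PCR-amplified into an ~210 nt product sequenced
paired-end.

`chargeseq` is for bench and computational biologists running this
assay: it takes raw paired-end FASTQ plus a sample sheet and produces
per-isodecoder charged fractions and condition comparisons, with every
step testable against a built-in simulator that knows the ground truth.

## The method

For sample *s* with classified (charged + uncharged) read total *N_s*,
counts are rescaled by the coefficient

&nbsp;&nbsp;&nbsp;&nbsp;*c_s* = mean(*N₁* … *N_S*) / *N_s*

and the charged fraction of group *g* (a tRNA gene, an anticodon-level
isodecoder such as tRNA-Pro-AGG, or all isoacceptors of one amino acid)
in sample *s* is

&nbsp;&nbsp;&nbsp;&nbsp;*f_gs* = Σ charged / (Σ charged + Σ uncharged)

summed over the group's reference entries. Conditions are compared per
group with a two-sided Welch's *t*-test (Welch–Satterthwaite df) and
the family of raw *p*-values is corrected with the Benjamini–Hochberg
step-up FDR procedure; groups are flagged at *q* ≤ 0.05.

The pipeline stages are: inline-barcode demultiplexing (reverse
complement of R2 positions 1–5; unmatched pairs discarded) → adapter /
UMI / barcode trimming with a 20-nt minimum-insert filter → ungapped
semi-global alignment of each insert against a deduplicated,
CCA-appended tRNA reference (deterministic tie-breaking, tie counts
surfaced) → 3′-end charge calling (CCA/CC; anything else is
indeterminate and excluded) → normalization → fractions → statistics.

## Worked example

Simulate the built-in benchmark (10 anticodon groups × 2 genes, two
conditions × 3 replicates, 5,000 pairs/sample here, substitution error
0.002, with Pro-AGG charging 0.85 in control vs 0.45 in treated and all
other groups at 0.80) and run the pipeline:

```python
from chargeseq.presets import benchmark_design, benchmark_reference
from chargeseq import simulate_fastq, sheet_from_design, run_pipeline
from chargeseq.stats import stats_frame

ref = benchmark_reference()
design = benchmark_design(seed=1, n_reads=5000)
r1, r2, truth = simulate_fastq(design, ref)
result = run_pipeline(ref, sheet_from_design(design), zip(r1, r2))
print(result.summaries["anticodon"])
print(stats_frame(result.stats["anticodon"]).sort_values("q").head(3))
```

which prints (abridged):

```
group_id condition   mean     sd  n
 Leu-TAA   control 0.7884 0.0170  3
 Leu-TAA   treated 0.8147 0.0340  3
 Pro-AGG   control 0.8540 0.0027  3
 Pro-AGG   treated 0.4436 0.0230  3

group_id  mean_a  mean_b       t     df      p      q  significant
 Pro-AGG  0.8540  0.4436 30.6727 2.0545 0.0009 0.0091         True
 Asn-GTT  0.7953  0.7812  2.5527 3.8067 0.0662 0.3311        False
 Glu-TTC  0.7778  0.7926 -2.0162 2.9929 0.1374 0.4579        False
```

The estimated condition means sit within binomial sampling error of the
simulated truth (0.85/0.45 for Pro-AGG, 0.80 elsewhere); only the
shifted group survives BH correction. Of 30,000 simulated pairs, 300
(~1%, matching the 0.002 per-base error over the 5-nt barcode) lack an
identifiable barcode and are discarded.

The same workflow is available from the shell:

```bash
chargeseq reference-build genes.fasta --out-prefix ref
chargeseq simulate design.yaml --reference-fasta genes.fasta --outdir sim/
chargeseq run --reference-fasta genes.fasta --sample-sheet sim/sample_sheet.tsv \
    --r1 sim/reads_R1.fastq --r2 sim/reads_R2.fastq --outdir out/
chargeseq stats --fractions out/fractions_anticodon.tsv \
    --sample-sheet sim/sample_sheet.tsv --out stats.tsv
```

`run` writes raw/normalized count TSVs with the per-sample
coefficients, fraction and summary tables per grouping level, the
Welch/BH statistics table, a JSON run log with complete per-stage read
accounting, and heatmap/barplot figures.

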