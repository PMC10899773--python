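# Methods

## Assay model

The package analyses sequencing libraries in which tRNA charging state
is chemically encoded at the 3′ end. Uncharged tRNAs expose a free
2′,3′-diol at the terminal adenosine that NaIO₄ oxidizes; β-elimination
at high pH then removes that adenosine, leaving a 3′-phosphate on the
terminal C (removed by polynucleotide kinase before ligation). Charged
tRNAs are protected during oxidation and are merely deacylated, keeping
their 3′-A-OH. After adapter ligation, reverse transcription and PCR,
a read that runs flush to the end of its reference entry and finishes
**CCA** derives from a charged molecule; one stopping one base short
with **CC** derives from an uncharged molecule.

Molecule architecture, 5′→3′ on the top strand:

```
5'-adapter (26 nt)  tRNA body + CCA|CC  UMI (5 nt)  barcode (5 nt)  3'-constant (24 nt)
GTTCAGAGTTCTACAGTCCGACGATC ........... NNNNN        XXXXX           AGATCGGAAGAGCACACGTCTGAA
```

The PCR primers extend this by 29 nt (forward) and 40 nt (reverse)
beyond their annealing arms, so a 76-nt mature tRNA yields a 208-nt
charged amplicon — rounding to the ~210 nt band excised from the sizing
gel, which is the architecture's built-in consistency check
(`amplicon_length`).

## Pipeline stages and the choices behind them

**Demultiplexing.** The barcode is read as the reverse complement of R2
positions 1–5 (the geometry implied by the adapter layout; the location
convention is configurable). Default `max_mismatch=0`: with a 0.2%
per-base error, ~1% of pairs lose their barcode and are discarded,
which is unbiased with respect to charging state. Mismatch-tolerant
decoding is available but requires all barcode pairs to differ at
> 2·max_mismatch positions, enforced before any read is processed.

**Trimming.** The 26-nt 5′-adapter prefix is stripped from R1
(tolerating a 10% mismatch rate, floor convention). The 24-nt
3′-constant arm is located in R1 — exact match first, then
mismatch-tolerant, then as a 3′-terminal partial of ≥ 10 nt — and
removed together with the 10 preceding nt (UMI + barcode). When the
read is too short to reach the constant arm, the insert is delimited by
overlapping R1 with the reverse complement of R2 (barcode/UMI removed),
whose end coincides exactly with the insert's 3′ end; the best-scoring
overlap (matches − 2·mismatches, ≥ 10 nt) wins. Inserts under 20 nt —
empty-adapter ligation products — are rejected. UMIs are removed but
not used for deduplication (no dedup step is modelled; extension
point).

**Reference.** Gene sequences are uppercased with U→T at parse time so
reference and reads share one alphabet. Deduplication is by exact body
identity *before* CCA appending; the surviving entry takes the
lexicographically smallest member gene name, a deterministic choice
where any would do. Isotype/anticodon disagreements among collapsed
duplicates warn and keep the representative's values. The builder
accepts whatever FASTA it is given (mitochondrial tRNAs included or not
is the caller's decision).

**Alignment.** Inserts are short and, in this library, indel-free, so
the aligner is deliberately exhaustive rather than heuristic: the full
insert is scored ungapped at every feasible offset of every entry
(sense strand only, score = matches − mismatches, N counts as
mismatch), subject to at most ceil(0.1 × length) mismatches. This makes
the contract exactly testable against a brute-force scan. Ties are
broken by smallest entry_id then smallest start, and the number of
tied-best placements is recorded so multi-mapping among near-identical
isodecoders stays auditable rather than silently resolved.

**Charge calling.** Charged requires end_offset 0 *and* a literal
terminal CCA; uncharged requires end_offset 1 and terminal CC. A
sequencing error in the last base therefore demotes the read to
indeterminate rather than miscalling it — a conservative rule that
costs ~0.6% of reads at the benchmark error rate and biases neither
class. Indeterminate reads are excluded from counts but kept in the
accounting.

**Normalization and fractions.** Sample totals are classified
(charged + uncharged) reads, the counts the table actually carries.
The coefficient mean(totals)/total_s makes every sample's total equal
the grand mean and conserves the grand total — an identity the test
suite checks to 1e−9 relative tolerance. Within-sample fractions are
invariant under this uniform rescaling; it matters only when counts
are combined across samples. Group fractions sum counts over member
entries before dividing (at the amino-acid level this weights
isoacceptors by read count; a mean-of-fractions alternative is exposed
as an option but is not the default). Zero-denominator fractions are
missing, never 0, and propagate as such into condition means
(replicates with undefined fractions are excluded; n = 1 gives an
undefined SD, flagged via the reported n).

**Statistics.** Welch's t with Welch–Satterthwaite df (via
`scipy.stats.ttest_ind(equal_var=False)`), two-sided; BH step-up via
`statsmodels`. Both are cross-checked in the tests against hand-written
formula oracles. The BH family is all testable groups at the requested
level in one comparison. Significance is flagged on adjusted q ≤ 0.05,
with raw p reported alongside since published figures sometimes star on
raw p. Groups with fewer than two defined replicate fractions in either
condition, or zero pooled variance, are reported untestable and
excluded from the family.

## The simulator: what it emulates and what it does not

`simulate_fastq` draws, per sample, the reference entry by abundance
weight (uniform by default), the charged state as a Bernoulli with the
(condition, anticodon-group) fraction, and a uniform 5-nt UMI; it
assembles the molecule exactly as the architecture above, reads R1 from
the 5′-adapter's first base and R2 inward from the barcode-adjacent
junction, and applies iid substitutions independently to both mates
(each error replaces a base with a different one). Base quality is the
constant Phred score implied by the error rate. Emission of every
molecule is recorded as ground truth.

Default read length is 150 nt, which covers the longest benchmark
molecule (~141 nt) entirely in R1; 100-nt reads are also exercised in
tests to cover the pair-overlap trimming regime. Error rate defaults to
0 in the dataclass; the benchmark uses 0.002.

Deliberately not modelled: indels, PCR duplicates, position-dependent
quality profiles, ligation bias, tRNA modification-induced RT stops and
misincorporations, and gel size selection (beyond reporting amplicon
lengths). Passing tests therefore demonstrate correctness of the
pipeline's logic and statistics under substitution noise, not
robustness to RT artefacts of real tRNA sequencing — on real data the
alignment mismatch tolerance absorbs some modification signal, but
heavily modified positions remain a known limitation.

## The benchmark

`chargeseq.presets` fixes the validation conditions shared by the test
suite and `scripts/acceptance.py`: a toy reference of 10 anticodon
groups × 2 genes with 72–78-nt bodies and ≥ 20% pairwise divergence
(so toy alignment is unambiguous); two conditions × 3 replicates at
50,000 pairs/sample with barcodes of pairwise Hamming distance ≥ 3;
error rate 0.002; Pro-AGG charging 0.85 → 0.45 with all other groups at
0.80 in both conditions. Recovery is judged per (group, sample) against
the simulator's *emitted* ground-truth fraction, within 3 binomial
standard errors computed from the design fraction at the emitted group
size: this isolates what the pipeline can control (losses from barcode
errors, trimming and indeterminate exclusion) from the irreducible
binomial scatter of the draw itself. Detection requires the shifted
group, and no null group, to be BH-flagged at q ≤ 0.05; with nine null
Welch tests at 3 vs 3 this has an intrinsic few-percent per-run
false-flag probability, which the ≥ 9-of-10-seeds rule absorbs.

Problem sizes in the routine suite (2,000–3,000 pairs/sample for unit
and exactness tests, the full 50,000 for the ten-seed benchmark, 1,000
families for null calibration, 500 inserts for the aligner oracle) were
chosen so the whole suite completes in a few minutes on one CPU while
keeping every statistical check well-powered.

## Numerical conventions

- Mismatch budgets: trimming uses floor(rate × length) (cutadapt-like),
  alignment uses ceil(rate × length); both guard against binary
  floating-point artefacts (e.g. 0.1 × 20 = 2.0000000000000004) with a
  1e−9 slack before rounding.
- All tie-breaks (duplicate representative, alignment placement,
  overlap scoring) are deterministic, so identical inputs give
  byte-identical outputs; the only randomness anywhere is the
  simulator's single seeded generator.
- Degenerate inputs: empty gene lists, zero-total samples, missing
  charging fractions, ambiguous barcode sets and malformed headers all
  raise named errors before any partial output is written; undefined
  fractions and untestable groups are values (NaN / flags), not errors.

## Known limitations

- Ungapped alignment cannot place reads with real indels; such reads
  fall out as unaligned rather than being rescued.
- Reads mapping equally well to divergent duplicate isodecoders are
  assigned deterministically and flagged, not discarded; the tie count
  is the audit trail.
- No UMI deduplication and no abundance-change analysis beyond total
  classified counts per entry.
- The qPCR-based charging measurement used alongside this assay in the
  wet lab is a different protocol and is out of scope.
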