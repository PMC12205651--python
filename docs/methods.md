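# Methods

This note documents the models behind each component, the parameters that
matter, what the synthetic-data generator does and does not emulate, and
the numerical choices made where the design was genuinely open.

## Synthetic data generator

The generator fabricates every input the pipeline consumes, with ground
truth recorded in a JSON manifest so recovery can be tested without
re-derivation.

**Locus.** A three-exon transcript model mirrors the biological geometry of
an alternatively spliced exon that encodes one strand of a regulatory
hairpin: an 18-nt segment (strand A) near the 3′ end of the upstream exon
is reverse-complemented into the 30-nt middle exon (strand B), separated by
a 7-nt loop, so only the middle-exon-containing isoform can fold the
hairpin. Defaults: upstream/downstream exons 100 nt, middle exon 30 nt
(one 40-mer probe then spans both of its junctions), GC content 0.5.
Ground-truth reactivity is an idealized two-level profile — 0.1 on paired,
0.8 on unpaired nucleotides — matching the convention that reactivity
display scales saturate around 0.8.

**Reads.** Single-end reads of length 100 (default depth 20,000 per
sample): isoform chosen Bernoulli(mixture), start uniform over valid
offsets, strand uniform, i.i.d. substitution errors at `error_rate`
(default 10⁻³), constant Q30 qualities. Exactly `depth` reads are emitted.
Not emulated: paired-end fragments, position-dependent quality/error
profiles, PCR duplicates, batch effects. Passing tests therefore show the
scanner and CPM arithmetic are correct under clean mixtures, not that they
are robust to real library artifacts.

**Expression.** Genes × samples matrix of log-normal values: per-gene log2
mean ~ N(5, 2), per-gene log2 dispersion ~ U(0.3, 0.8), two groups of
`n_samples_per_group` (default 20). A target set (default 50 of 1000
genes) is shifted by `delta` log2 units (default −1, i.e. halved) in the
exon-4a-expressing group. Log-normal values were chosen over
negative-binomial counts because every downstream stage consumes
normalized expression, as DESeq2-normalized inputs would be.

**Mutational profiling.** Per-nucleotide two-channel binomial counts at
`shape_depth` reads (default 10,000): the modified channel mutates at
background (0.01) plus 0.005 on paired or 0.04 on unpaired nucleotides;
the untreated channel at background alone. This captures the
paired-low/unpaired-high contrast that makes reactivity informative, not
sequence-dependent adduct chemistry or ambiguous-alignment artifacts.

**Sensorgrams.** Closed-form 1:1 curves (below) plus Gaussian noise
(default sd 2 RU), five analyte doses from 6.25 to 100 nM, three
replicates. The default ground truth (k_a = 2.04×10⁴ 1/(M·s),
k_d = 1.31×10⁻⁵ 1/s, R_max = 100 RU) is a slow-off, sub-nanomolar-K_D
RNA–protein interaction; the long dissociation window (600–4200 s) is what
makes an off-rate of order 10⁻⁵ 1/s identifiable from the decay at this
noise level — a deliberate experimental-design choice of the simulation.

**Seeding.** One master seed; each stage derives a child stream by mixing
the master seed with a fixed offset (and a CRC of the sample id for
reads), so outputs are byte-stable under reruns and uncorrelated across
stages.

## Junction quantification

"Mapping probes to reads" is operationalized as exact full-probe
containment: a read supports a probe when the entire 40-mer occurs
ungapped in the read or its reverse complement with at most
`max_mismatches` substitutions (default 0). This is reproducible,
alignment-free, and appropriate for a 40-mer inside ≥100-nt reads; partial
overlap support is deliberately not the default. Reads shorter than the
probe cannot count and trigger a warning. `total_mapped_reads` is the
number of reads scanned — synthetic data has no separate genome-mapping
step.

Subset calls use a presence threshold of count ≥ 1 (configurable
`min_count`); classification therefore depends only on zero vs nonzero
CPM. Samples expressing both or neither junction are labeled but excluded
from the exclusive A/B analyses.

Matching is a global optimal one-to-one assignment (Hungarian algorithm on
|ΔCPM|), not greedy; ties between equally good assignments are resolved
deterministically by sorting sample ids before solving. Optimality is
verified against exhaustive search over all assignments for up to six
cases.

## Enrichment statistics

The ranking metric is signal-to-noise with each group's sd (ddof = 1)
floored at max(0.2·|μ|, 0.2) — the conventional guard that keeps
near-constant genes from dominating the ranking. The metric is swappable;
nothing downstream depends on its identity.

ES is the signed maximum deviation of the weighted running sum: member
genes add |r|ᵖ (p = 1, normalized over the member total), non-members
subtract 1/(N−|S|). If every member has metric exactly zero the hit
weights fall back to unweighted increments. NES divides ES by the mean
|permutation ES| of the same sign; the nominal p is the same-sign
exceedance fraction, floored at 1/(n_perm+1) so zero is never reported.
Phenotype labels are permuted (1000 by default); permutations are drawn
with replacement, which is declared rather than enforced-distinct because
the default designs have astronomically many label orderings.
Benjamini–Hochberg q-values are provided for multi-set runs alongside
nominal p. Gene sets outside 10–5000 members after intersection with the
matrix are skipped with a reason.

Quartile stratification uses linearly interpolated percentiles: Q1 is
samples ≤ 25th percentile, Q4 ≥ 75th, each listed in sample-id order so
tied values give deterministic membership. Row Z-scores use the n−1 sd;
constant rows map to zero with a warning.

Calibration measured by the acceptance checks: under label
exchangeability the type-I error at α = 0.05 sits near nominal (0.03–0.07
across 500 simulated null datasets), and a −1.5 log2 shift on a 50-gene
set with 20 vs 20 samples is detected (|NES| > 1, p < 0.05) in ≥95% of
replicates.

## SHAPE reactivity and structure

Raw reactivity is the modified-minus-untreated mutation-rate difference.
Positions with fewer than `min_depth` reads (default 1000) in either
channel are no-data; negative differences are retained (they carry
information about the background). Normalization follows the 2%/8% rule:
the top 2% of defined values are excluded as outliers and the mean of the
next 8% is the divisor — so normalization is scale-equivariant, and a
profile of identical values normalizes to 1.

The pseudo-energy ΔG(i) = m·ln(S+1) + b (defaults m = 1.8, b = −0.6
kcal/mol, the values in common use for SHAPE-restrained folding) is added
once per paired nucleotide — simpler than per-stack application, and
switchable in principle because the term enters the recursions only
through the per-pair weight. Negative reactivities are clamped to 0 before
the log; no-data positions contribute zero.

The energy model is deliberately compact: pair energies GC −3, AU −2,
GU −1 kcal/mol, a −1 kcal/mol bonus per directly stacked pair, minimum
hairpin loop 3, no loop-size terms. Full nearest-neighbor parity is a
non-goal; correctness is defined against exhaustive enumeration of the
same model, which the inside–outside implementation matches to better
than 10⁻⁹ relative for all tested sequences up to 20 nt, with and without
restraints. The partition function uses McCaskill-style per-nucleotide
rescaling (scale chosen from a minimum-free-energy pre-pass) to stay
within double-precision range; states far above the ensemble minimum may
underflow, which is harmless at double precision. Sequences longer than
`max_length` (default 2000) are rejected with advice to fold in windows.

Pairing probabilities are classified at strict thresholds
(>0.50, >0.75, >0.8, >0.95): a probability of exactly 0.95 is class
">0.8", matching the strict reading of "greater than". Well-determined
regions are maximal anti-diagonal runs of pairs each above the threshold
(default 0.95) of at least `min_helix` (default 3) pairs. Unprobed
positions simply carry zero pseudo-energy, so folding a window with
missing flanks is the same computation with fewer restraints — output
marks those positions as no-data.

Coordinates are 1-based inclusive transcript positions everywhere,
including CT files, fused-construct intervals and pair-probability
triplets.

## SPR kinetics

Closed-form 1:1 Langmuir solutions are used throughout — no numerical
ODE, no mass-transport limitation. The global fit shares (k_a, k_d,
R_max) across all concentration series, optimizing in log-parameter space
(the parameters are positive and span decades) with
Levenberg–Marquardt from a 3×3 log-uniform grid of (k_a, k_d) starts —
the least-squares surface is multi-modal in log space, and the best of
nine starts is kept. A single-concentration fit is allowed but flagged:
k_a and R_max are then only weakly identifiable. K_D = k_d/k_a exactly as
fitted.

Replicate summaries report the arithmetic mean and n−1 SD of each
parameter. K_D is summarized as the mean of per-replicate ratios rather
than the ratio of mean rates — the convention under which a reported
K_D need not equal mean-k_d/mean-k_a, and the one consistent with
kinetics tables that summarize replicate experiments.

## Pipeline

`run_pipeline` in synthetic mode runs: locus → expression/phenotypes →
probes → per-sample reads and junction counts → subset classification and
optimal matching (cases = subset B, pool = subset A, matched on total
junction CPM) → Q1/Q4 stratification on inclusion-junction CPM →
permutation GSEA of the target set (positive class Q4, so the default
δ = −1 yields negative ES) → mutational-profiling counts, normalization,
restrained folding, well-determined regions, MAP-style dot-bracket and CT
output, fused-construct extraction → sensorgram simulation and per-replicate
global fits with a summary. Every emitted file is checksummed into
`manifest.json`; rerunning with the same configuration reproduces every
hash. FASTQ emission is off by default (quantification consumes reads in
memory); `write_reads=True` or the `simulate` CLI verb writes them.

File-backed mode validates all referenced paths up front (a missing FASTQ
is a configuration error naming the path) and runs whichever stages have
inputs: quantification + classification from FASTQ and a probes FASTA,
enrichment from TSV + CLS + GMT, the reactivity/folding chain from a
mutation-count TSV + FASTA, kinetic fits from a sensorgram CSV.

## Problem sizes used in the shipped checks

The shipped acceptance checks use: 200 random sequences up to 20 nt for
the enumeration equivalence, 500 null datasets at the full default design
(1000 genes, 20 vs 20, 1000 permutations) for calibration and 100
replicates for power, 100 noisy sensorgram replicates for K_D recovery,
and 10⁵ reads for the scanner/oracle comparison. `scripts/acceptance.py`
re-runs the same measurements at moderately reduced replicate counts
(50–200) so a full report completes in about a minute.

## Known limitations

- The scanner requires full-probe containment; isoform evidence from reads
  overlapping a junction by fewer than 40 nt is ignored by design.
- The compact energy model reproduces ensemble behavior of its own
  parameterization; absolute agreement with full nearest-neighbor models
  is out of scope, so predicted probabilities should be read as
  model-relative.
- The permutation p is nominal, not family-wise; multi-set runs should use
  the provided q-values.
- 1:1 kinetics only: bivalent, heterogeneous-ligand and mass-transport
  models are out of scope, as is vendor file-format parsing.
- The generator's idealized two-level reactivity and binary mixtures make
  recovery tests sharp but do not probe robustness to real-data artifacts
  (crosstalk between channels, partial modification, degraded RNA).
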