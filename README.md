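# draictools

Analysis toolkit for studying how alternative splicing controls a small
functional RNA structure, modeled on the DRAIC lncRNA system: DRAIC carries a
36-nt hairpin (called A+B, transcript nts 705–722 paired with 741–758) that
binds IKKα and suppresses NF-κB signaling, and an alternatively spliced exon
(4a) encodes one strand of that hairpin — so whether a tumor's transcripts
include exon 4a determines whether the inhibitory hairpin can form.

The package implements, as reusable and tested components, the four
computational procedures such a study needs, plus a synthetic-data generator
with recorded ground truth so every stage can be validated end to end
without external downloads:

1. **Splice-junction isoform quantification** (`draictools.junctions`).
   Two 40-base probes detect the isoforms alignment-free: the inclusion
   probe is the last 5 bases of exon 3 + 30 bases of exon 4a + the first 5
   bases of exon 4; the skipping probe is the last 20 bases of exon 3 + the
   first 20 of exon 4. A read supports a probe when the full probe occurs
   ungapped in the read or its reverse complement. Abundance is
   CPM = (raw counts / total mapped reads) × 10⁶. Samples are classified
   into exclusive subsets (A: inclusion only, B: skipping only) and matched
   one-to-one across subsets by total transcript CPM with an optimal
   assignment (Hungarian algorithm) minimizing Σ|ΔCPM|.

2. **Gene-set enrichment with a permutation null**
   (`draictools.enrichment`). Genes are ranked by signal-to-noise
   s2n = (μ₁−μ₀)/(σ₁+σ₀) with GSEA-style sd floors; the weighted
   Kolmogorov–Smirnov running sum gives ES; phenotype-label permutations
   give NES = ES / mean|ES_perm, same sign| and a nominal p (floored at
   1/(n_perm+1)). Quartile stratification (Q1 vs Q4) and row Z-scores for
   heatmaps are included.

3. **SHAPE reactivity and restrained structure modeling**
   (`draictools.structure`). Raw reactivity is the modified-channel minus
   untreated-channel mutation rate; normalization uses the 2%/8% rule; a
   pseudo-energy ΔG(i) = m·ln(Sᵢ+1) + b (defaults m = 1.8, b = −0.6
   kcal/mol) is added per paired nucleotide; an inside–outside partition
   function over all pseudoknot-free structures (min hairpin loop 3, compact
   configurable energy model) yields pair probabilities P(i,j), classified
   at the >0.50/0.75/0.8/0.95 display thresholds. "Well-determined" regions
   are helices of ≥3 consecutive pairs each with P > 0.95. Fused constructs
   (e.g. the 36-nt A+B hairpin from intervals 705–722 and 741–758) are
   extracted by coordinate.

4. **1:1 SPR binding kinetics** (`draictools.spr`). Association
   R(t) = R_eq·(1−e^(−(k_a·C+k_d)t)) with R_eq = R_max·C/(C+K_D),
   dissociation R(t) = R₀·e^(−k_d·(t−t₀)), K_D = k_d/k_a. Global nonlinear
   least squares over all analyte concentrations with multi-start
   initialization; replicate summaries report mean ± SD, with K_D averaged
   over per-replicate ratios.

`draictools.synthetic` generates all inputs — a three-exon locus whose
middle exon closes a hairpin with the upstream exon, single-end reads from a
two-isoform mixture, a two-group log-normal expression matrix with a log2
effect `delta` on a target gene set, two-channel mutational-profiling
counts, and noisy sensorgrams — each with its ground truth recorded.
`draictools.pipeline.run_pipeline` ties everything together and emits a
manifest with per-file checksums; reruns with the same seed are
byte-identical.

## Worked example

```python
from draictools import (SimConfig, build_synthetic_locus, design_junction_probes,
                        simulate_reads, count_junction_reads,
                        match_samples_by_expression)

cfg = SimConfig(seed=1, depth=10_000, mixture=0.6)
locus = build_synthetic_locus(cfg)
incl, skip = design_junction_probes(
    locus.exon_upstream, locus.exon_middle, locus.exon_downstream)
print(f"{incl.name}: {incl.sequence}")
print(f"{skip.name}: {skip.sequence}")

reads = simulate_reads(locus, cfg, "sample_1")
res = count_junction_reads(reads, [incl, skip], sample_id="sample_1")
for name in res.counts:
    print(f"{name}: count={res.counts[name]}  CPM={res.cpm[name]:.2f}")

cases = {"B1": 0.38, "B2": 3.92, "B3": 0.83}
pool = {"A1": 0.38, "A2": 3.91, "A3": 0.82, "A4": 10.0}
m = match_samples_by_expression(cases, pool)
for case, ctrl, c_cpm, p_cpm, d in m.pairs:
    print(f"{case} -> {ctrl}  |dCPM| = {d:.2f}")
print(f"objective = {m.objective_value:.2f}")
```

prints

```
exon3-4a-4: GTTCGCACCGGCCTAGGTAAGGGACACGTATCTCCTGGCG
exon3-4: TCCCTTACCTAGGCCGTTCGTGGCGACCATTATCGAGCGG
exon3-4a-4: count=2663  CPM=266300.00
exon3-4: count=2372  CPM=237200.00
B1 -> A1  |dCPM| = 0.00
B2 -> A2  |dCPM| = 0.01
B3 -> A3  |dCPM| = 0.01
objective = 0.02
```

Both probes are 40 nt by construction. At a 0.6 inclusion mixture, about
60% of junction-spanning reads carry the exon3–4a junction (the CPM values
are junction counts per million of the 10,000 scanned reads). The matcher
pairs every skipping-isoform case with the inclusion-isoform control of
nearly identical total expression and ignores the 10.0-CPM distractor.

A full synthetic run (`draictools run-all --outdir out --seed 1`, or
`run_pipeline` from Python) adds quartile stratification, permutation GSEA
of the shifted target set (strongly negative NES, p < 0.05 under the default
`delta = −1`), restrained folding of the locus with well-determined-region
calls, the 36-nt fused hairpin, and 1:1 kinetic fits of three simulated
sensorgram replicates.

The same verbs are available from the shell: `draictools probes | quantify |
classify | match | stratify | gsea | zscore | reactivity | fold | regions |
construct | spr-sim | spr-fit | run-all`.

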