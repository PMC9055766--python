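# Methods

This document records the statistical models, default parameters, and
numerical choices behind each stage of the pipeline, and what the synthetic
data generator does and does not emulate.

## 1. lncRNA screening (`ricecerna.lncrna_screen`)

**Model.** lncRNA candidacy is a conjunction of deterministic rules applied
to assembled transcripts:

| rule | default | rationale |
| --- | --- | --- |
| class code ∈ {i, x, u, o, e} | fixed set | only assembler classes compatible with novel non-coding loci (intronic, antisense, intergenic, sense-overlap) |
| length ≥ `min_length_nt` | 200 | the conventional lncRNA length floor, separating lncRNAs from small RNAs |
| exons ≥ `min_exons` | 2 | single-exon fragments are enriched for assembly artifacts and unspliced noise |
| expression ≥ `min_fpkm` | 0.1 FPKM | removes transcripts too weakly expressed to quantify; the statistic is the maximum over samples, so condition-specific transcripts survive |

Screen results report the first failing rule per transcript so filtering is
auditable. Missing expression can be treated as a failure (`strict`) or a
pass-through (`permissive`); strict is the default because an unquantified
transcript cannot be used downstream anyway.

**Coding potential consensus.** Each of four classifier verdict tables
(CPC-like, CNCI-like, CPAT-like, PFAM-like — any tools emitting a
per-transcript coding/non-coding call) contributes a non-coding set; the
candidate set is their intersection, and a Venn breakdown over the
four-tuple of memberships is reported. Intersection (rather than majority
vote) is used because false-positive lncRNAs contaminate every downstream
stage, while false negatives only cost sensitivity.

**Classification.** u → lincRNA, i → intronic, x → antisense, o/e → sense.
Transcripts on strand "." cannot be oriented relative to the overlapped
gene, so x/o/e with unknown strand classify as "unknown" rather than
guessing.

**ORF finding.** `find_longest_orf` scans all three forward frames for
ATG…stop spans and returns the longest (frame, coordinates, aa length);
ties break to the earliest start. It is cross-checked in the test suite
against an independent all-starts scan.

## 2. Differential expression (`ricecerna.diff_expr`)

**Normalization.** FPKM for length-biased long-RNA libraries; TPM for
miRNA libraries (TPM's within-sample sum of 10⁶ makes composition explicit
and is the norm for small-RNA counts). Both are standard closed-form
transforms of counts, lengths and library sizes.

**Testing.** The default p-value source is a Welch t-test on
log2(normalized + 1): the log stabilizes the variance of abundance data,
the pseudocount of 1 keeps zeros finite while adding negligible bias at
moderate counts, and Welch avoids assuming equal group variances.
Externally computed per-feature p-values (e.g. from a negative-binomial
count model) can be injected via the `p_values` argument, since at 2–3
replicates count models are more powerful than a t-test.

**Screening thresholds** (per RNA class, `CLASS_THRESHOLDS`):

| class | effect | significance |
| --- | --- | --- |
| lncRNA | \|log2FC\| ≥ 2 | P < 0.05 |
| miRNA | \|log2FC\| ≥ 1 | P < 0.05 |
| mRNA | \|log2FC\| ≥ 2 | BH-FDR < 0.05 |

miRNAs use the lower fold-change bar because mature miRNA abundance is
buffered by precursor processing; mRNAs, the largest class, carry the
multiplicity correction. Benjamini–Hochberg q-values come from
`statsmodels` and are re-verified in the tests against a textbook step-up
implementation.

log2FC is computed as log2((mean_trt + c)/(mean_ctrl + c)) with
pseudocount c = 1, making it exactly antisymmetric under swapping the
conditions.

## 3. Target prediction (`ricecerna.target_pred`)

**miRNA target scoring.** A dynamic program aligns the full miRNA against
every window of the candidate site and returns the minimal penalty:
mismatch 1.0, G:U wobble 0.5, gap 1.0, all penalties doubled over miRNA
positions 2–13 (the plant "seed"/central region where pairing is required
for cleavage), at most 2 gaps, hit cutoff `max_penalty` = 4.0. These are
the established plant-miRNA (TargetFinder-style) weights. Site overhangs
outside the aligned region are free; gaps are charged at the weight of the
next miRNA position; site bulges are internal only. The DP is verified in
the tests against explicit enumeration of all gap placements.

The scheme is deliberately asymmetric between the miRNA and the site
(seed weighting, terminal-gap treatment), so no strand-swap symmetry
holds. Two exact invariances do hold and are enforced as properties:
reversing both sequences leaves the score unchanged under uniform
position weights, and complementing both strands leaves it unchanged
whenever wobble and mismatch penalties coincide (complementation maps G:T
wobbles onto C:A mismatches).

**Cis targets.** Gene pairs on the same chromosome within
`window` = 100 000 bp (gap between intervals; 0 for overlap), the common
heuristic radius for cis-regulatory association. Self-pairs are excluded.

**Trans targets.** A documented surrogate for energy-based lncRNA–mRNA
duplex prediction: the best 100-nt window by fraction of complementary
positions (Watson–Crick or G:U), hit threshold 0.8. This stands in for
free-energy methods without shipping a thermodynamics engine; it is a
screening heuristic, not a hybridization model.

## 4. ceRNA screening (`ricecerna.cerna_network`)

For each lncRNA–mRNA pair with k shared targeting miRNAs out of K on the
lncRNA, n on the mRNA and a universe of M, significance is the
hypergeometric upper tail P(X ≥ k) (computed via `scipy.stats.hypergeom`,
cross-checked by exhaustive subset enumeration for M ≤ 12). Pairs pass
with k ≥ 3 (at least three shared sponging channels), p < 0.05, and
BH-FDR < 0.1 computed over all enumerated pairs with k ≥ 1.

Surviving pairs must then (a) have the lncRNA, the mRNA, and at least one
shared miRNA all differentially expressed, and (b) satisfy the ceRNA sign
pattern: each shared DE miRNA anti-correlated with both the lncRNA and the
mRNA, and lncRNA–mRNA correlation positive. Correlation is Pearson on
log2(normalized + 1) when ≥ 3 replicates per condition are available;
with fewer replicates, or for constant series, the check falls back to
comparing DE directions (min |r| default 0.0, i.e. sign only, because at
n = 6 samples the magnitude of r is too unstable to threshold).

The resulting network is a typed `networkx` graph (lncRNA/miRNA/mRNA
nodes; sponge and targeting edges) exported deterministically (sorted
nodes and edges) as SIF, GraphML or node/edge TSV.

## 5. qPCR (`ricecerna.qpcr`)

Relative expression by 2^-ΔΔCt: ΔCt = Ct_target − Ct_reference per
sample, ΔΔCt = mean ΔCt(treatment) − mean ΔCt(control), fold = 2^−ΔΔCt.
The method assumes equal (≈100 %) amplification efficiency for target and
reference. Significance stars compare the per-sample ΔCt values between
conditions with a Welch t-test (\* p < 0.05, \*\* p < 0.01); Ct values
are validated to lie in (0, 45). Identities guaranteed by the algebra —
fold 1 for equal ΔCt, reciprocity under condition swap, invariance under
a common Ct shift — are enforced in the tests.

## 6. Synthetic data generator (`ricecerna.synthetic`)

### Model

- **Counts.** Negative binomial with mean μ and variance μ + φμ²,
  dispersion φ = `nb_dispersion` = 0.1 (a typical RNA-seq value; φ = 0
  degenerates to Poisson). Baseline log2 means uniform on
  `base_mean_log2_range` = (5, 9). Per-sample library sizes jitter by
  `library_jitter` = 0.2.
- **Differential expression.** A fraction `planted_de_fraction` = 0.3 of
  features in each class receives a signed log2 effect of magnitude
  `planted_log2fc` = 3 (comfortably above the screening thresholds so
  recovery failures indicate pipeline errors, not marginal effects).
- **ceRNA modules.** `n_cerna_modules` = 5 modules of 1 lncRNA,
  `module_shared_mirnas` = 4 miRNAs and `module_mrnas_per_lnc` = 4 mRNAs.
  Module miRNAs are up-regulated and module lncRNA/mRNAs down-regulated
  (the drought-sponge sign pattern), with an additional shared latent
  factor (sd = `latent_sd` = 0.5 on the log scale, positive loading on
  lncRNA/mRNA, negative on miRNA) so that within-condition replicates are
  also correlated the way the sign filter expects. Background
  miRNA–target edges occur independently with
  `background_target_prob` = 0.03.
- **Sequences.** Perfect-complement binding sites for each module edge
  are embedded into the target sequences (recorded in
  `GroundTruth.planted_sites`; a later embedding can overwrite an earlier
  one, so consumers should re-check the substring). lncRNA candidate
  sequences are re-drawn/stop-broken until their longest ORF is below
  `novel_min_orf_aa` = 50 aa, with a bounded repair loop (editing one
  reading frame can resurrect an ORF in another, so after 64 repair
  passes the sequence is redrawn).
- **Small-RNA library composition.** The miRNA count matrix includes
  `n_filler_mirna` = 420 non-targeting, non-differential small RNAs.
  Without them the 30 analysed miRNAs would be the entire TPM
  denominator, and planting ~30 % DE would shift every miRNA's TPM
  through the compositional constraint alone. Real small-RNA libraries
  are dominated by non-analysed reads; 420 fillers put the DE mass near
  a realistic few percent of the library.
- **Annotation.** Toy 12-chromosome genome (2 Mb each), multi-exon
  transcripts with valid GTF coordinates, lncRNA categories drawn with
  probabilities `category_fractions` = (0.827, 0.039, 0.08, 0.054)
  (lincRNA, intronic, sense, antisense), four coding-potential verdict
  tables each calling a transcript non-coding with probability
  `consensus_fraction` = 0.9 (independently, so the 4-way intersection is
  a real filter), and `n_trt_specific` = 2 / `n_ctrl_specific` = 1
  condition-specific transcripts with zero counts in the off condition.

### What it does not emulate

Read-level artifacts (mapping ambiguity, positional bias, adapter
contamination), isoform structure and assembly errors, GC/length bias
beyond the FPKM length term, miRNA biogenesis (only mature sequences),
imperfect or bulged planted binding sites (module sites are exact
complements; graded-affinity recovery is not probed), batch effects, and
more than two conditions.

### Determinism

All randomness flows from `SimConfig.seed` through one
`numpy.random.default_rng`; written datasets are byte-identical for a
fixed seed.

## 7. Numerical choices

- Hypergeometric tails use `scipy.stats.hypergeom.sf(k−1, M, K, n)`
  (survival function, stable for small tails) rather than summing PMFs.
- BH q-values use the standard step-up with cumulative minimum from the
  largest p downwards; q is clipped to 1.
- The scoring DP stores penalties as floats; all defaults are multiples
  of 0.5 so comparisons at these settings are exact.
- Variance in `zscore_log_matrix` uses the population convention
  (ddof = 0); rows with zero variance map to zero rather than NaN.
- Derived seeds drawn for sub-simulations are kept below 2³¹.

## 8. Limitations

- At 3 replicates per condition, the Welch t-test plus BH over ~200 mRNAs
  has limited power: a true |log2FC| ≈ 2–4 effect can land at FDR 0.05–0.25
  by sampling noise alone, so occasional simulation seeds lose one or two
  planted modules at the DE-intersection stage. This is a property of the
  design size, not a pipeline defect; injecting count-model p-values
  recovers power.
- The trans-target heuristic and the sign filter at small n are screening
  devices; they rank and gate candidates but do not estimate effect sizes
  or binding energies.
- The hypergeometric null assumes exchangeable miRNA–target edges;
  correlated targeting (miRNA families sharing seeds) would inflate
  significance and is not modelled.
- qPCR assumes equal amplification efficiencies; efficiency-corrected
  models (e.g. Pfaffl) are out of scope.
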