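# Methods

## Scope and model

The package quantifies synonymous codon-usage bias and its relation to
translational selection. The underlying model is the classical one: under
no selection, synonymous codon choice within a family is driven by
mutational/compositional pressure (summarized by positional nucleotide
frequencies, especially GC3); translational selection superimposes a
preference for particular codons that strengthens with expression level,
which lowers the gene's effective number of codons (Nc). The analysis
therefore (i) describes among-genome variation with RSCU +
correspondence analysis, (ii) scores per-gene bias with Nc and its
composition-corrected form Nc′, and (iii) detects preferred codons as
those whose within-family frequency correlates negatively with Nc/Nc′
across genes.

All computations assume the standard nuclear genetic code: 61 sense
codons in 2 one-fold, 9 two-fold, 1 three-fold, 5 four-fold and 3
six-fold families. Six-fold families (Leu, Ser, Arg) are kept whole,
because the class coefficients (9, 1, 5, 3) in Wright's combination
assume exactly that partition. Alternative codes are out of scope.

## Estimators and numerical choices

**Homozygosity and Nc.** F = (nΣp² − 1)/(n − 1) per family with total
n ≥ 2. Families with n < 2 are unusable. F can be exactly 0 when every
observed codon occurs once (e.g. counts (1,1)); such families carry no
bias information and would make 1/F̄ blow up, so they are also treated as
unusable — the standard practice of ENC implementations. If the Ile
class is empty, F̄₃ is imputed as (F̄₂ + F̄₄)/2 (Wright's rule); if all
six-fold families are unusable, F̄₆ is imputed by the four-fold mean.
Both imputations are flagged per gene. Genes with no usable two-fold or
four-fold family are excluded with a reason. Nc is clamped to [20, 61].

**Composition correction (Nc′).** Expected within-family codon
frequencies are products of positional nucleotide frequencies,
renormalized over the family; F′ = (χ² + n − k)/(k(n − 1)) with χ² taken
against those expectations. With a uniform background F′ reduces to F
algebraically (asserted to 1e−12 in tests). The default background is
per-gene (each gene's own positional frequencies); a genome-wide 3×4
frequency matrix can be supplied instead. Note that a gene whose bias is
entirely compositional has Nc′ ≫ Nc — absorbing such bias is the purpose
of the correction, so "maximal bias" forces Nc′ = 20 only under a
uniform background.

**RSCU and the CA matrix.** RSCU is computed on families of size ≥ 2
(59 codons); stops and Met/Trp never enter. A family with zero usage is
reported missing, not 0; at genome scale this is rare, and the CA matrix
builder imputes the no-preference value 1.0 with a logged warning. CA is
run on the RSCU matrix itself (not raw counts), the convention for
codon-usage ordination, making genome rows comparable regardless of gene
content. SVD sign indeterminacy is fixed by orienting each axis so the
codon with the largest |coordinate| is positive.

**Optimal codons.** Gene-level predictors are within-family relative
frequencies (raw counts would confound gene length); the response is Nc′
by default with Nc mirrored in output. Spearman ρ uses average ranks for
ties; P values use the t approximation with n − 2 df (an exact
permutation mode exists for n ≤ 7 and is used in tests; exhaustive
enumeration at n = 5 bounds the approximation error at 0.078 worst-case).
Significance is Bonferroni within family (0.05/k) and the call
additionally requires ρ < 0, making the directional claim explicit. Ties
break by smaller P, then lexicographic codon order. `min_family_count`
defaults to 1: any usage contributes.

**tRNA concordance.** Anticodons are decoded by exact reverse
complementation only; wobble pairing is deliberately excluded, so the
concordance question is literally "does the optimal codon have the most
exact-cognate tRNA gene copies". Records whose stated amino acid
disagrees with the decoded codon are excluded and flagged, never
silently kept. Copy-count ties count as concordant.

**Assembly/annotation statistics.** N50 is the length at which the
descending cumulative sum first reaches half the total. GC excludes
ambiguity codes from numerator and denominator, so N-runs in drafts do
not dilute it. CDS fraction uses the merged interval union per contig so
overlapping isoforms are not double-counted. Coordinates are GFF3
1-based inclusive at every interface.

**Omics filters and correlations.** DEG: P ≤ 0.001 inclusive. DEP:
eligibility FDR < 0.01 and ≥ 2 unique peptides, then the symmetric rule
max(FC, 1/FC) > 1.5 strictly — symmetric because down-regulation is a
fold change below 1, and both directions are reported. Correlations are
Spearman on log2 fold changes (the log is cosmetic for a rank statistic
but keeps the output tables interpretable). Unmatched gene/protein ids
are reported, never silently dropped. Pathways below `min_n = 3` matched
genes are reported as NA with their n.

## Synthetic data: what it emulates and what it does not

`simulate_genome_set` emulates the generative structure the detection
statistic assumes: per gene, expression is log-normal(0, 1); the bias
weight is w = w_max·(rank − 1)/(M − 1), entering through rank only so
recovery is invariant to the expression scale; within each family codon
probabilities are (1 − w)·q + w·δ(planted codon), where q splits the
genome's GC3 target evenly among G/C-ending members and 1 − GC3 among
A/T-ending members — giving every member nonzero baseline probability so
per-gene homozygosities stay estimable in short genes. Defaults are five
genomes on a GC3 gradient from 0.30 to 0.80, 2000 genes per genome,
lengths uniform on 100–600 codons, uniform amino-acid composition over
the 20 standard residues, and w_max = 0.6 — a scale at which the
planted codon is recovered in ≥ 16 of 18 multi-codon families while
leaving visible sampling noise.

`simulate_omics_tables` plants per-pathway Spearman correlations through
a Gaussian copula, converting the Spearman target to the bivariate-normal
Pearson value via ρ_P = 2·sin(πρ_S/6), so targets are population-exact
rather than approximate. Transcript P values are assigned so a
configurable fraction (default 0.3) pass the DEG cutoff.

What the generators do **not** emulate: phylogenetic relatedness among
genomes, amino-acid composition differences between genomes, length–
expression correlation, isochore structure, wobble-driven tRNA pools,
measurement error models of RNA-seq or iTRAQ, and missingness patterns
of real proteomes. Passing recovery tests therefore demonstrates that
the estimators detect the signal they are defined to detect at realistic
sample sizes — not that real genomes satisfy the model.

## Problem sizes

Unit and property tests run on 100–400-gene genomes; the end-to-end
recovery checks use one 2000-gene genome per seed across five seeds, a
5×200-gene GC3 gradient for CA, and 200-gene pathways for correlation
recovery. These sizes put Monte-Carlo noise well below the decision
thresholds being tested while keeping the full suite under a minute of
simulation time.

## Known limitations

- Only the standard genetic code; organisms with reassigned codons need
  a different family table.
- The Nc combination assumes at least one usable two-fold and four-fold
  family; very short or unusual genes are excluded rather than patched.
- The optimal-codon definition is correlation-based; it does not
  distinguish selection from any other covariate that co-varies with
  Nc′ across genes.
- tRNA concordance ignores wobble decoding entirely; isoacceptor
  sharing across synonymous codons is invisible to it.
- GO/KEGG enrichment and differential-expression testing itself are out
  of scope: P values and FDRs are inputs.
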