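# Methods

This note documents the models and procedures implemented in `symtox`, the
parameters that matter, the design choices made where the design was
genuinely open, and what validation on synthetic data does and does not
demonstrate.

## Alignment and BSR partitioning

Local alignments are exact affine-gap Smith–Waterman (Biopython's
`PairwiseAligner`), BLOSUM62, gap existence 11 and extension 1, so a gap of
length *k* costs 11 + *k*. No heuristic seeding is used: at the scale this
package targets (10²–10³ proteins per genome) exact DP is affordable and
removes a source of irreproducibility. E-values use the Karlin–Altschul
formula with the published gapped constants for this scoring system
(λ = 0.267, K = 0.041) and a search space of query length × pooled subject
residues; they are a documented closed-form approximation, adequate for
thresholding at the 1e−5 / 1e−3 ceilings the pipeline uses, not a
replacement for a full finite-size-corrected BLAST statistic.

The BSR uses **raw** scores (the ratio is scale-free, so raw vs bit scores
differ only through the constant offset in the bit transformation; raw is
the original formulation of the statistic). Ties for the best reference
hit break on the lexicographically smallest subject id, which makes
records deterministic. The shared/unique cutoffs are ≥0.4 (genome-wide)
and ≥0.2 (TRG re-screen); cutoff comparisons are inclusive, e-values use
≤, and similarity is strictly > as printed. Coverage ("over at least half
of the length") is enforced on the query side with ≥; the subject-side
coverage is recorded on every hit so the choice remains auditable, and a
strict-inequality variant is available (`HitFilter(coverage_strict=True)`).

## TRG detectors

None of the three toxin classes has a rigid domain signature, so each
detector encodes the weakest sufficient evidence we could defend:

* **YD/Rhs** — tandem `[YFH]D` dipeptides are individually far too common
  (expected ≈1.5 occurrences in a 300-aa background protein), so a call
  requires both a chain of ≥4 copies with consecutive gaps ≤60 aa *and* a
  hit to an Rhs-core PSSM. Both the motif and the copy/spacing parameters
  are configurable (`ClassifierParams`).
* **RTX** — the calcium-binding nonapeptide (consensus `GGxGxDxUx`, U
  hydrophobic) varies in length and in its G/N content, which defeats
  profile methods; the detector is a regex with ±2 residues of per-copy
  length tolerance (`G{1,2}.{1,2}G.{1,2}[DN].{1,2}[LIVF]`) requiring ≥3
  near-tandem copies (gap ≤30 aa). On 2,000 background proteins this
  pattern produced zero false calls while keeping per-protein detection of
  diverged repeat regions above 0.99.
* **MARTX** — log-odds PSSMs for the three characterised effector domains
  (ACD, RID, CPD), background = average amino-acid frequencies. A
  profile's cutoff is the 99.9th percentile of per-sequence maximum window
  scores over 1,000 random background proteins (seeded per profile, hence
  deterministic), floored at 25% of the profile's maximum score: noise
  maxima sit near zero on the log-odds scale while a domain diverged 30%
  still scores about two thirds of the maximum, so the floor rejects
  compositional-bias hits on repeat-rich proteins without costing
  sensitivity. An RTX-repeat protein longer than 1,500 aa is also called
  MARTX, reflecting the giant-ORF architecture of that family.

The shipped seed alignments under `src/symtox/data/profiles/` are
**synthetic stand-ins** built from random consensi — curated toxin seed
alignments are not distributed with this package — and exist so the
machinery is exercisable end to end; users supply real seed alignments (or
pre-built plain-text PSSMs) the same way. Classification priority is
MARTX → repeat classes → annotation-based RTX accessory; a YD/RTX evidence
conflict resolves to the higher copy-count score and is recorded on the
annotation. Truncated ORFs are flagged, never repaired: extension against
curated homologs is a manual step outside this package's scope.

## Similarity network

Edges require similarity >25%, query coverage ≥0.5 and e ≤ 1e−5;
reciprocal hits collapse keeping the better e-value. Clustering is
**connected components** of the thresholded graph — a deliberate,
documented stand-in for transitivity clustering, whose plugin parameters
are unreported; at these thresholds components are the conservative
superset of any transitivity refinement. The two-step joining rule is
applied at the cluster level ("clusters were joined"): clusters are
adjacent when ≥1 inter-cluster hit passes the filter, and the selection is
a breadth-first expansion from all TRG-containing clusters truncated at
`network_max_steps` (default 2). Cluster labels are deterministic
(ordered by smallest member id) and clusters are named by their majority
annotation string.

## Enrichment statistics

Normalized count = class count ÷ genome gene total × 1000. Kruskal–Wallis
(midrank ties, chi-square approximation — matching the df convention of
standard R output) and Mann–Whitney–Wilcoxon (exact by enumeration for
tie-free samples of ≤16 observations, otherwise normal approximation with
tie and continuity correction) come from scipy behind the module surface;
independent enumeration oracles live in the test suite. Strains of one
species are independent rows.

PERMANOVA is implemented in-package: Euclidean distances, sums of squares
from the identity SS = Σᵢ<ⱼ d²ᵢⱼ/n applied to total and within-group
parts, pseudo-F = (SS_A/(k−1))/(SS_W/(n−k)), and
p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm) over seeded unrestricted label
permutations — bit-exact reproducible for a given seed, which the wrapped
library implementations do not guarantee. The statistic is cross-checked
against scikit-bio in the tests. Bonferroni correction is applied across
the family of taxonomic-level tests run in one invocation. Both a
multivariate response (the per-class normalized vector) and single-class
responses are supported.

## SNP density

Depth is normalized into [5, 200]: columns above the cap are downsampled
multinomially (seeded), columns below the floor are excluded. The variant
caller is a **pooled binomial site test**: qual = −10·log₁₀ P(X ≥ alt
count | X ~ Binomial(depth, ε)), ε = 0.01 by default. This replaces a
diploid haplotype caller deliberately — bacterial populations are not
diploid, and a pooled-population tail test is the natural model for
within-host symbiont variation. PASS requires qual ≥ 20, depth within the
normalization window, and distance >5 bp from indel evidence. The
90%-identity and unique-mapping read filters are upstream contracts on the
pileup input; this package does not align reads.

Multi-allelic sites count as one SNP position ("SNPs per gene" is
positional). Density = PASS SNPs ÷ kb of N-corrected length; genes <150 bp
are excluded, and first/last genes of each contig can be dropped by flag
(scaffold-end artefacts). The variability threshold is median + one
**sample** (n−1) standard deviation with a strict > flag; the population
convention is unspecified in the sources this mirrors, and n−1 is the
conservative choice at small gene counts. Densities from multiple
transcriptome replicates are pooled by default (averaging available by
flag).

## Codon-usage HGT screen

The statistic is a length-normalized multinomial log-likelihood ratio of a
gene's codon counts under its own MLE frequencies versus the genome
profile, computed **within synonymous families** so amino-acid composition
cancels and only codon bias is measured. Because the null expectation of
this ratio scales like (degrees of freedom)/(2·length), the cutoff is
calibrated per gene: n_null = 199 replicates resample the gene's own
per-family codon totals from the genome profile, and the gene is flagged
when its score exceeds the m-th largest null score with
m = fpr_target·(n_null+1) — an exact-level order-statistic test under the
null. Genes shorter than 30 codons inherit the genome profile and are
never flagged. This detector is a self-contained stand-in for published
codon-usage HGT methods whose statistics are unspecified; its validation
surface is recovery of planted donor-profile genes, not any particular
genome's published HGT fraction. When a large fraction of a genome is
donor-derived the pooled profile sits between the two sources and the
flagged fraction of *resident* genes rises above the nominal target — an
inherent property of single-genome codon methods, not an implementation
artefact.

## Expression summaries

Per-gene fraction of mRNA = raw count ÷ total × 100 (an
upper-quartile-normalized variant is available by flag; which basis the
original percentages used is not stated, and raw fractions are the
conservative default). Upper-quartile normalization divides by the 75th
percentile of **nonzero** counts. Relative expression divides by a named
reference gene (the planted RuBisCO gene in synthetic data); a zero
reference count is an error, not a silent NaN.

## Synthetic data generator

The generator emulates the statistical structure of the focal study at
desk scale; its defaults are the study conditions for all validation:

| parameter | default | emulates |
|---|---|---|
| focal / reference genomes | 2 / 4 (two reference sets) | focal clade vs two relative clades |
| core genes | 100 at 2% divergence | shared proteome backbone |
| focal-specific genes | 50 | symbiont-specific gene complement |
| planted TRGs per focal genome | 30 YD + 8 RTX + 19 MARTX at 30% divergence | the largest reported per-genome arsenal |
| YD repeat copies / RTX repeat copies | 22 / 40 | Rhs- and CyaA-scale repeat regions |
| mobile-adjacent TRG fraction | 0.25 | ≈¼ of TRGs next to mobile elements |
| HGT fraction (background / TRG) | 0.33 / 0.65 | codon-shifted gene fractions |
| codon shift (per-family TV distance) | 0.3 | donor codon bias |
| hypervariable genes | 5% at 10× substitution rate | fast-evolving toxin loci |
| read coverage / background SNP rate | 50× / 0.003 per bp | transcriptome pileups |
| metadata genomes | 40 per lifestyle | curated multi-genome comparison table |
| planted TRG mRNA share / RuBisCO share | 2% / 0.5% | expression fractions |
| mean protein length | 200 aa | desk-scale proteins |

Planted MARTX templates are ~700 aa carrying all three effector-domain
consensi plus a short RTX-repeat region: domain evidence is the primary
MARTX signal, so the giant->1500-aa architecture is exercised by dedicated
unit tests rather than inflating every synthetic alignment quadratically.
Divergence above 0.6 is rejected because it destroys the planted
signatures by construction. Background proteins are i.i.d. draws from
average Swiss-Prot amino-acid frequencies; substitutions are uniform over
the other 19 residues. Codon-shifted genes sample synonymous codons from a
donor profile at a controlled per-family total-variation distance
(mass moved onto the rarest codon of each family). Pileups are generated
directly (depth ~ Poisson, minor-allele fraction ~ U(0.15, 0.5) at
polymorphic sites, sequencing error 0.002/base, indel evidence 2×10⁻⁴/bp);
no read-level simulation or mapping is performed. All randomness flows
through one seeded generator; identical configs and seeds give
byte-identical output files.

What passing on this generator shows: every stage implements its stated
rule correctly, recovers planted signal at the stated effect sizes, and
holds its nominal error rates. What it does not show: performance on real
proteomes — real toxins diverge under selection rather than uniform
substitution, real repeat counts and spacings vary more than the planted
templates, real codon bias is structured by expression level, and real
pileups carry mapping artefacts the generator omits. Published per-genome
numbers (TRG counts, HGT percentages, expression ranges, enrichment
p-values) depend on the actual genome sets and are out of scope here.

## Problem sizes used in validation

The shipped validation runs use: 200 random pairs (length ≤60) for the
alignment oracle; the six-genome 100-core/50-specific design for
partitioning; 1,000 background + 57 planted genes for the classifier; 100
random cluster graphs for the network rule; 1,000 null replicates for
rank-test calibration; 500 null + 200 powered replicates at 199
permutations for PERMANOVA; a 150-gene genome at 50× coverage for SNP
recovery; 1,000 null + 900/100 mixture genes for the HGT screen; and a
small five-genome pipeline (run twice) for byte-level determinism.
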