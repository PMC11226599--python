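# Methods

This note documents the models, conventions and design choices behind
varlens, in the order the pipeline runs. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Synthetic cohort model

The generator produces the full input ecosystem for the pipeline. It is
deterministic: one global integer seed, with each stage drawing from a
generator derived from a stable hash of `(seed, stage_name)`, so
identical configurations give byte-identical files.

### Gene panel and divergence

Each gene is a random in-frame CDS starting with ATG and containing no
internal stop codons. Codons are sampled with a CpG-depletion penalty
(factor 0.60 per CpG dinucleotide, applied within codons and across
codon junctions), which places the panel's CpG base content near 9% —
the level typical of CpG-depleted mammalian coding sequence and of
targeted panels. Uniform random codons would give ~13% and make the
CpG enrichment fold uninterpretable against real panels.

A second species' sequence is evolved codon by codon: each position
mutates with probability `divergence_per_site` (default 0.06, the
approximate primate–primate coding divergence scale); proposals are
uniform over the three alternative bases; a proposal creating a stop
codon is redirected to another base (nonsense mutations are never
fixed); synonymous proposals always fix and nonsynonymous proposals fix
with probability omega. ND-panel genes use `omega_strong` (default
0.10) and IRD-panel genes `omega_relaxed` (default 0.40), encoding the
stronger purifying selection on neurodevelopmental genes. Setting both
omegas to 1 with uniform transition probabilities yields the neutral
panel used for calibration. Redirection rather than dropping of
stop-bound proposals matters: dropped proposals are all nonsynonymous,
and at a 4–5% proposal rate into stops they bias neutral NG86 dN/dS
down to ~0.91; with redirection the neutral median sits at ~0.95–0.98.

Genes carry a random exon structure (1–8 exons, each ≥ 3 nt of CDS)
laid out with fixed 120-nt introns; the four canonical splice
positions flanking every junction are "sequenced" and can carry
variants. Coordinates are 1-based; each gene maps to a destination
("human") genome through a per-base orthology map with a per-gene
strand flip (probability 0.2) and a 0.5% unmapped fraction.

### Allele-frequency spectrum and genotypes

Every sequenced base becomes a variant site with probability
`snv_rate_per_base` (default 0.085), multiplied by
`cpg_mutation_multiplier` (default 5.0) at CpG-context positions
(position i is CpG-context if ref[i]=C,ref[i+1]=G or ref[i]=G,
ref[i−1]=C on the species-A reference). With the panel's ~9% CpG base
content, a 5-fold mutability multiplier yields a realized variant-level
enrichment of λ/(1+f(λ−1)) ≈ 3.6–3.8-fold. Alternate alleles are
transitions with probability 0.90 at CpG sites (deamination) and 0.67
elsewhere, which produces a cohort Ts/Tv near 3 — the elevated coding
region value.

Allele counts follow a singleton-explicit law: with probability
`singleton_target_fraction` (default 0.26) the variant is a cohort
singleton (AC = 1); otherwise AC = round(AN·q) with q ~ Beta(0.2, 5),
clamped to [2, AN]. The clamp (rather than resampling) puts extra mass
at AC = 2; the realized spectrum is rare-variant dominated with the
singleton fraction recovering the configured target. True-deleterious
variants are capped at AC ≤ floor(0.038·AN), the deleterious AF
ceiling. Truth classes: stop-gains are deleterious; missense variants
are deleterious with probability 0.15 and benign otherwise; synonymous
variants benign; splice/noncoding variants neutral-noncoding.

Genotypes place exactly AC allele copies: a Dirichlet-multinomial
allocation across colonies (concentration set by an Fst-like parameter,
default 0.02 — a guess, since colony-level AF heterogeneity is not
quantified anywhere usable) followed by uniform placement on distinct
chromosomes within each colony. Conditional on the colony allele
count, this is Hardy–Weinberg sampling; real pedigree structure and
inbreeding are deliberately not modelled. Clean per-call values keep a
margin from every QC boundary: DP ~ max(Poisson(70.2), 12), GQ uniform
in [30, 99], het allele balance confined to [0.25, 0.75].

Cross-species structure: a mapped variant whose alternate differs from
the species-B base is shared with the human population with
probability 0.31; shared benign variants get heavy-tailed human AFs
(Beta(0.3, 3)), shared deleterious variants get log-uniform AFs below
the human deleterious ceiling 5.1×10⁻³ with a point mass
(probability 0.35) exactly at the ceiling. The atom reflects that
database AFs are discrete AC/AN ratios, so the maximum over a curated
subset can equal the populationwide maximum — the same mechanism that
makes the macaque cutoff exactly recoverable. Variants absent from the
human table are recorded with human AF 0 (absence from a large human
database is itself informative).

### QC artifact injection

Site artifacts (failing QD/QUAL/FS/MQ values) and a third allele in
one subject are injected at per-site fractions (defaults 0.004 per
rule, 0.002 for the third allele); call artifacts at per-call fractions
(low GQ ≤ 19 and low DP ≤ 9 at 0.01 of calls each) plus allelic
imbalance at 0.01 of *heterozygous* calls (AB corruption is a het-call
phenomenon; defining it against all calls would concentrate ~20% of
het calls and visibly distort the AF spectrum). All injected values
lie strictly beyond their boundaries, and targets are chosen disjointly
across categories and away from artifact sites, so each ledger entry
maps to exactly one downstream masking/dropping reason and ledger
recovery is exact (precision = recall = 1). Consequential drops — a
site going monomorphic because its only carrier was masked — are
attributed to re-qualification, not to the ledger.

### Curated labels and feature scores

A fraction (0.30) of variants is labelled. True-deleterious variants
draw one deleterious string (HGMD `Disease_causing_mutation`, a ClinVar
pathogenic-family string, or SwissVar `LP/P`); true-benign variants a
benign-family string; neutral-noncoding variants occasionally a VUS or
conflicting string. The mislabel rate defaults to 0 (curated labels
are treated as ground truth, as the downstream filtering does), and at
`conflict_rate` (0.02) a labelled row gains a contradicting
second-source string. Under the harmonisation rules a benign string
always blocks deleterious assignment, so conflicted rows harmonise
benign; harmonised-deleterious therefore remains a subset of
true-deleterious at mislabel rate 0.

The 11 in-silico scores are class-conditional normals on familiar
scales (CADD-like 0–50, probabilities 0–1, conservation scores, etc.)
with per-feature effect sizes d = √2·Φ⁻¹(AUC) spanning single-feature
AUCs 0.71–0.95, and an equicorrelated latent factor (ρ = 0.6) modelling
the strong mutual correlation of published predictors. The correlation
is essential realism: with independent features a combined model is
degenerately perfect, while correlated features cap the combined AUC
near the observed 0.98–0.99 range and make the dominance comparison
(combined vs best single feature) meaningful. Missing cells appear at
rate 0.05 in score columns.

## Quality control semantics

All six hard-filter comparisons are strict exactly as stated, so
boundary values (QD = 5.0, QUAL = 30.0, FS = 15.0, MQ = 50.0,
MQRankSum = −12.5, ReadPosRankSum = −8.0) pass. Missing QD/QUAL/FS/MQ
fail conservatively (`missing-annotation`); missing rank sums are
tolerated since callers omit them legitimately. Genotype masking uses
a fixed priority (no-call → low-dp → low-gq → allelic-imbalance) so
reason codes are deterministic; AB is computed from AD, not DP, because
DP may include uninformative reads; AB with zero AD denominator on a
het call is treated as extreme imbalance. Multiallelic-subject
detection runs on raw pre-masking observations, and the rule is
per-subject: two subjects jointly covering three alleles do not trigger
it. The pipeline is idempotent (masked calls become no-calls, which
re-mask as no-calls).

## Population statistics

AN counts only unmasked genotyped individuals at each site, so
denominators are per-base. A singleton is cohort-wide AC = 1. The
CpG enrichment test is an exact two-sided binomial in the
minimum-likelihood convention: p = Σ P(k) over all outcomes with
P(k) ≤ P(observed)·(1+10⁻⁷). Away from underflow the sum is taken
ascending over linear pmf values (relative error ~10⁻¹³ against exact
rational enumeration); in deep tails the log-sum-exp path keeps a
finite log10 p even when the linear value underflows (the cohort-scale
test statistic is of order 10⁻³²⁴ and below). Report display uses
half-up rounding: two decimals for frequencies, one for folds; internal
values keep full precision.

## Selection statistics

NG86 site counting defines the synonymous-site fraction of a codon
position as the number of the three alternative bases preserving the
amino acid over three; mutations to stop codons count as
nonsynonymous, so each codon contributes exactly three sites.
Difference counting averages over all orderings of the differing
positions, excluding paths through stop codons and renormalising; if
every path is blocked, all paths are used with stop steps counted
nonsynonymous. Distances are uncorrected proportions by default
(Jukes–Cantor optional); dN/dS is undefined when sd = 0. This counting
method deliberately replaces maximum-likelihood codon models: it is
self-contained, enumeration-testable, and adequate for ratio-based
downstream statistics; it does not model transition bias or codon
frequencies (F3×4) and underestimates divergence at high saturation.

`polymorphism_pnps` counts missense + stop-gain variants against
synonymous variants (raw counts, per the whitelist; noncoding
consequences are excluded). The free-standing
`neutrality_index(pn, ps, dn, ds)` evaluates (pN/pS)/(dN/dS) verbatim.
For per-gene NI the pipeline passes the divergence pair as raw
difference counts (nd, sd) — the McDonald–Kreitman count form — so the
per-site normalisation factors cancel between numerator and
denominator and neutral evolution gives NI = 1. Mixing a raw-count
polymorphism ratio with a per-site divergence ratio would instead give
a neutral expectation near the nonsynonymous/synonymous site ratio
(~3), which is not a usable neutrality reference. The neutral NI
distribution sits slightly above 1 (median ~1.03–1.12 in calibration)
because segregating stop-gains enter pN while stop fixations are
excluded from divergence — the biologically expected excess of
deleterious polymorphism.

Gene-set comparisons use the Wilcoxon rank-sum (Mann–Whitney) test
with configurable sidedness; one-sided is the default used in the
regime-separation analyses, two-sided available by flag. Genes with
undefined metrics are excluded and counted.

## Curated classification

Deleterious: HGMD disease-causing not benign in ClinVar/SwissVar, or
ClinVar pathogenic-family not benign in SwissVar, or SwissVar LP/P not
benign in ClinVar. Benign: any ClinVar benign-family or SwissVar LB/B
string. "Not annotated as benign" is read literally: only
benign-family strings block; uncertain or conflicting strings do not.
Unknown vocabulary raises rather than guessing.

AF cutoffs are maxima over the curated deleterious set per species,
never hand-set in pipeline mode; the benign filter is strictly
"higher than", so a variant at exactly the cutoff is not flagged, and
a missing AF in a species never triggers that species' clause (a
variant absent from the human database cannot be called benign through
the human clause). Raising the deleterious set can only raise cutoffs,
and therefore can only shrink (never grow) the benign-by-AF set.

Reported-pathogenic selection keeps the ClinVar-pathogenic ∪
HGMD-disease-causing pool with CADD ≥ 25 and a configurable gene
exclusion list (default {RPGR}, a copy-number-unstable region). NMD
calls use the standard 50-nt rule: a premature stop more than 50 nt
upstream of the last exon–exon junction is nmd-likely; last-exon and
single-exon stops escape. Canonical splice-site variants are
nmd-likely by default except at the final intron, whose retention
leaves the last junction unused.

## Integrative score

The 13 features are macaque AF, human AF, and CADD, REVEL,
PolyPhen-2 HVAR, MutationAssessor, MetaSVM, MetaLR, phyloP100,
phastCons100, VEST3, DANN and GERP. Only missense variants with exact
dual-genome amino-acid agreement enter; rows with all features missing
are dropped with a logged reason. Imputation is per-feature training
median, stored in the fitted pipeline. Folds are stratified with a
recorded seed; the per-fold AUC is computed only on held-out rows, and
all families share the same folds so the ensemble (unweighted mean of
the six base families' calibrated probabilities) is evaluated without
refitting. The leaderboard sorts by mean CV AUC with ties broken by
registration order; the winner is refit on all labelled data.
Family hyperparameters are fixed small-scale (150-tree forest, 60-bag
trees, RBF SVM behind sigmoid calibration, one 16-unit hidden layer)
so a full benchmark is deterministic given the seed and runs in
seconds to minutes on one CPU.

Top-percentile thresholding returns the smallest score whose upper
tail proportion is ≤ the requested fraction; ties at the threshold are
all flagged, so the flagged set may exceed the nominal fraction, and
if even the maximum score is too common its ties are flagged. Scores
from tree ensembles saturate at 1.0 on well-separated synthetic
cohorts, so the top-1% threshold can sit at 1.0 there; percentiles are
the empirical CDF of the scored set.

## Problem sizes

The configuration defaults describe the full study conditions (1,845
individuals, 8 colonies, 374 genes at ~500 codons, ~70× depth). The
test suite and the acceptance script run scaled versions chosen to
keep each check well-powered at desk scale: spectrum and benign-filter
recovery use 500 individuals × 25 genes × 300 codons (≈2,500 variants;
500 diploids make the 0.038 ceiling exactly representable as 38/1000
alleles); QC ledger recovery 150 × 20 × 200 (≈4,000 injected
artifacts); neutral calibration 200 genes × 300 codons; regime
separation 30 genes per set; the score benchmark 5,000 labelled
training variants (the curated-set class ratio), 2,000 held-out.

## Known limitations

The generator emulates marginal statistical structure, not biology:
no pedigrees or cryptic relatedness, no indels, no X/Y dosage, no
linkage disequilibrium (sites are independent), no read-level error
model, gene panels are random sequence rather than real orthologs, and
curated-label noise is far simpler than real database heterogeneity.
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated assumptions, not performance on real
cohorts. Orthology mapping consumes a flat per-base map; a chain-file
reader is an extension point, and paralog disambiguation and
multi-nucleotide variants are out of scope. The published AUCs of
integrative scores trained on real ClinVar/dbNSFP data are not
reproducible from synthetic features and are not targeted — the suite
checks structural properties (dominance over single features, chance
level under label shuffling, determinism) instead.
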