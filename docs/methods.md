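# Methods

This note records the models and procedures `ctlkit` implements, the
defaults and why they were chosen, what the simulator does and does not
emulate, and the numerical conventions. It states no result the test suite
or `scripts/acceptance.py` does not itself compute.

## Repertoire classification

Proteomes arrive as `pfam_scan.pl` domain tables plus a gene↔isoform map.
One protein per gene is retained — the longest isoform, ties broken to the
lexicographically smallest protein ID so results are independent of input
row order. The retained protein is classified by domain composition:

* **CTL** — ≥1 lectin domain (`PF00059`) and nothing else;
* **CTLDcp** — ≥1 lectin domain plus ≥1 other domain family;
* **OTHER** — no lectin domain (including proteins with no hits at all).

Accessions are matched on the unversioned prefix (`PF00059` matches
`PF00059.21`): Pfam version suffixes drift between releases and carry no
architectural information. Non-lectin domains are deduplicated by accession —
architectures are described by composition, not copy number — while lectin
domains are *counted*, since multi-CRD lectins are a real feature of these
repertoires. Envelope coordinates are kept 1-based inclusive, exactly as
pfam_scan emits them.

## Conservation levels

For a focal category (CTL or CTLDcp), the orthogroup × species binary
matrix contains a row per orthogroup with ≥1 such protein anywhere; a cell
is 1 iff the species contributes ≥1 such protein. The conservation level of
a row is the broadest taxon whose species coverage reaches θ, evaluated
top-down:

1. **PHYLUM** if some phylum has coverage ≥ θ;
2. **CLASS** if some class does;
3. **MULTI_FAMILY** if ≥2 families *within one class* do (anchored on that
   class) — the mussels+oysters sharing pattern;
4. **FAMILY** if exactly one family does;
5. **RESTRICTED** otherwise.

Ties at equal rank break lexicographically, making calls deterministic.
Families reaching θ in *different* classes do not combine: without
class-level coverage such patterns stay RESTRICTED, because cross-class
sharing without within-class cohesion is more parsimoniously read as
scattered presence than as a conserved subfamily. One consequence worth
noting: the rule is monotone in added presences only within a single class;
on multi-class taxonomies a FAMILY call can, in principle, drop to
RESTRICTED when a second family in another class crosses θ. The property
tests therefore assert monotonicity in the single-class regime the rule is
designed around.

**θ = 0.9, max_exceptions = 1.** Real assemblies lose genes to annotation
and assembly artifacts; subfamily calls in practice tolerate one missing
species in an otherwise universal clade. θ = 0.9 encodes exactly that for
clades of ten species (n·(1−θ) = 1), and `tolerant_class_call` exposes the
count-based variant (absences ≤ max_exceptions, equivalent to
θ = (n−1)/n) for explicit single-exception reasoning. Both are
configurable.

**Ordination and clustering.** Species PCA runs on the centered, unscaled
0/1 matrix (scaling binary columns would inflate rare orthogroups); the
heatmap leaf order uses average-linkage hierarchical clustering on Jaccard
distances, the natural choice for binary profiles. Inputs are sorted by
label before clustering so leaf orders are permutation-invariant; a pair of
all-zero profiles is treated as distance 0.

## CTLDcp retention categories

Per orthogroup, each species is ABSENT, PRESENT_WITH_CTL or
PRESENT_WITHOUT_CTL (≥1 member protein with a lectin hit). With retention
fractions computed over *present* species of each clade:

* **C** if the fraction of non-bivalve species present at all is ≤ ε
  (default ε = 0: "no orthology outside bivalves" read strictly, but the
  knob tolerates spurious cross-phylum hits);
* else **B** if every present chordate lost the lectin domain *and*
  bivalve retention ≥ ρ — the extra bivalve condition anchors B on clades
  that actually kept the domain, preventing universally-lost families from
  qualifying;
* else **A** if chordate retention ≥ ρ;
* else UNCLASSIFIED.

ρ = 0.5 operationalizes "generally found" as a simple majority; the figures
this mirrors show qualitative majorities, not a number, so the threshold is
exposed. A dataset without present chordates cannot distinguish A from B:
such calls are UNCLASSIFIED with a warning flag rather than an error.
An optional list of alternate lectin accessions (e.g. a Gal-lectin fold
standing in for the C-type fold in one ortholog) can be counted as
retention; off by default. Architecture comparisons list unversioned
accessions in envelope-start order for the longest member protein of one
representative species per clade; overlapping hits are both kept.

## Expression

**Tissue profiles.** Following the survey convention, a gene's profile is
its maximum TPM-scale abundance per sample type, summarized by
τ = Σᵢ(1 − xᵢ/max x)/(n − 1): 0 for uniform expression, 1 for single-type
expression, 0 by convention for all-zero genes. Maxima (not means) match
how expression is reported across heterogeneous public samples; abundance
drives profiles while raw counts drive testing.

**NB two-group test.** A deliberately self-contained replacement for a full
shrinkage GLM framework, built to preserve the biological decision rule
(p < 0.05):

* size factors by median-of-ratios against the geometric-mean reference
  over all-positive genes, rescaled to geometric mean 1 (a
  positive-counts fallback handles sparse matrices);
* per-gene NB dispersion α by method of moments on normalized counts,
  estimated within each group, pooled with (n_g−1) weights, floored at
  1e−8;
* log₂FC = log₂((μ̂ₛ+½)/(μ̂_c+½)); the pseudocount bounds fold changes for
  genes silent in one group without dropping them;
* delta-method standard error from the NB variance μs + α(μs)², propagated
  through size factors and the group mean, evaluated at the pseudocounted
  means so it is strictly positive;
* two-sided p from a Student-t reference with n₁+n₂−2 degrees of freedom.
  The t reference is a small-sample correction: with a plug-in
  method-of-moments dispersion at typical replicate numbers (5 vs 5) a
  plain normal reference is anticonservative (empirical type-I error ≈
  0.09 at the nominal 0.05), while the t reference is calibrated (≈ 0.05,
  measured by the Monte Carlo in the acceptance script);
* BH-adjusted q reported alongside; significance is called on raw p by
  default (the decision rule this pipeline inherits), switchable to q.

Swapping group labels negates log₂FC and preserves p exactly.

## The simulator

The generator plants ground truth at every level the pipeline measures and
is itself first-class, tested code. Defaults describe the study conditions:

* **Taxonomy**: a focal phylum with two classes (a bivalve-like and a
  cephalopod-like) of three families × 10 species, plus a 6-species
  chordate outgroup. Ten species per family makes each family, class and
  phylum large enough that θ = 0.9 tolerates exactly one absent species —
  the single-exception regime described above. Each mollusc class has
  three families so that two fully-present families sit at class coverage
  2/3 < θ and a planted MULTI_FAMILY cannot alias to CLASS; configs where
  a planted level would alias structurally are rejected.
* **Orthogroups**: 10 phylum-, 10 class-, 10 multi-family-, 20 family-level
  and 50 restricted CTL orthogroups; restricted rows occupy a random
  minority (≤ half) of one family. Within-species paralog counts are
  geometric with mean 2, so bivalve-like species accumulate repertoires of
  dozens of lectin genes — the expansion signal the census measures.
  CTLDcp categories get 15 orthogroups each: A present everywhere with the
  lectin domain, B lectin-bearing in bivalves but domain-less in chordate
  orthologs, C bivalve-only. 1–3 lectin domains per CTL architecture
  exercise multi-CRD counting.
* **Files**: domains are placed sequentially with 10-residue gaps
  (analyses depend on composition and order only); ~20% of genes get a
  shorter second isoform to exercise the longest-isoform filter;
  class-conserved lectin genes are annotated as secreted single-domain
  proteins (signal peptide, no TM), matching the small-secreted-lectin
  phenotype of class-level subfamilies.
* **Expression**: for one focal bivalve species, a mucosal program
  (class-conserved lectin genes; mean 200 in digestive gland and gill,
  zero elsewhere), a hemocyte program (20 genes high in hemocytes), and
  broad genes with means drawn from {20, 50, 100, 200, 500} uniform across
  five sample types. Counts are NB with dispersion 0.1 (a typical
  moderately overdispersed RNA-seq value); two default experiments
  (digestive-gland toxin, hemocyte bacteria) use 5 control vs 5 stimulated
  samples and a planted log₂FC of 2 on their program's genes. Abundance is
  counts rescaled to a per-sample total of 10⁶ (equal effective lengths).
* **Noise**: presence cells flip independently at a configurable rate
  *after* truth is frozen (1→0 removes the species' members, 0→1 plants a
  fresh lectin-bearing gene); a domain-loss rate can strip the lectin
  domain from CTLDcp members. Truth records pre- and post-noise presence.
* **Determinism**: one seed feeds six named `SeedSequence` streams
  (architecture, orthology, structure, isoforms, expression, noise), and
  all file writes use fixed formatting, so identical configs yield
  byte-identical bundles.

**What the simulator does not emulate** — and hence what passing recovery
tests do and do not show: no real amino-acid sequences (orthology is
planted, not inferred, so OrthoFinder's error modes are out of scope); no
phylogenetic signal within orthogroups; no assembly fragmentation beyond
independent presence flips; no library-size variation, batch effects or
multi-factor designs in expression; no isoform-level expression. Perfect
noise-free recovery demonstrates the bookkeeping and the rules, not
robustness to upstream inference error; the 5%-flip scenario probes
robustness to presence noise only.

## Problem sizes and degenerate inputs

The shipped checks run at the planted-scenario sizes above (100 and 200
conservation orthogroups, 45 CTLDcp orthogroups, 66 species, ~9,000
proteins, 2,000-gene NB Monte Carlos), which keep the full suite and the
acceptance script in the seconds-to-minutes range on one CPU while leaving
every rule exercised at its combinatorial limits (all 2¹⁰ presence
patterns, all 3⁶ retention assignments).

Degenerate inputs are errors, not silent results: empty or malformed input
lines name their line numbers; orthogroup tables reject duplicated
orthogroups and proteins shared between orthogroups (naming the protein);
presence matrices reject species missing from the taxonomy and all-zero
rows; PCA refuses variance-free matrices; the NB test refuses groups with
fewer than two samples or an all-zero library. An all-comment domain file
is a valid empty proteome; a species with zero lectins keeps its census
row.
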