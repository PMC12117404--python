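# Methods

## Substrate prediction

An ORF is a putative MetAP substrate when it begins with methionine and its
second residue is one of Ala, Cys, Gly, Ser, Thr, Val — the small/uncharged
residues accepted by the MetAP catalytic pocket. The rule is binary by
design: MetAP processing efficiency in fact grades with the second residue
(Ala > Ser > Gly), but the scan does not model that gradient. Degenerate
inputs are classified, not rejected: sequences without a leading Met or
shorter than two residues are non-candidates, and an ambiguous second
residue (X) or selenocysteine (U) yields a conservative non-substrate call
with a logged note, keeping counts reproducible across annotation builds.

Proline deserves a comment: observed iMet-retention responders in peptide
data often include Met-Pro N-termini, yet Pro is not in the substrate set
used by the scan. The scan keeps the canonical six-residue set; the
peptidoform composition reports raw second residues without masking, so the
two views can be compared rather than silently reconciled.

Isoform handling: genomes are counted per gene, not per transcript. When a
FASTA carries several isoforms per gene the longest ORF is kept, ties
breaking to the lexicographically smallest protein id, and the rule is
logged. This choice can move genome-wide substrate percentages by roughly a
point relative to other isoform conventions. Gencode-style transcript FASTA
is translated from the `CDS:start-end` range embedded in each transcript
header (1-based inclusive, standard genetic code); this uses the
transcript-coordinate annotation the file itself carries instead of
re-deriving CDS spans from genomic GFF3 coordinates, which would require
exon-structure arithmetic for no gain. Sequences with internal stop codons
are excluded with a warning; a single trailing stop symbol is stripped.

## Overrepresentation and conservation

The overrepresentation statistic is the one-sided hypergeometric upper tail
(Fisher's exact test, greater): with `N` background genes of which `K` are
substrates, and a term annotating `n` background genes of which `k` are
substrates, `p = P(X >= k)` for `X ~ Hypergeom(N, K, n)`. The background is
the set of classified genes present in the annotation table. All terms with
at least one annotated background gene are tested by default
(`min_term_size` is configurable); Benjamini–Hochberg adjustment runs
within species, and conservation is the intersection of per-species
significant terms (FDR < alpha **and** fold enrichment > 1; terms missing
from a species are non-significant there). Significance therefore requires
overrepresentation, never mere depletion. Annotation tables are consumed
pre-propagated up the ontology; no DAG handling is performed.

## Peptide-level quantification

The downstream procedure consumes a search-engine peptide export and makes
the following choices:

* **Confidence filter** — keep peptides with FDR confidence class high
  (q < 0.01) and strictly more than 2 PSMs.
* **Normalisation** — each run is rescaled so its intensity total equals the
  grand mean of raw run totals ("total peptide amount" normalisation).
  Within-run ratios are preserved exactly.
* **Imputation** — "low-abundance resampling" is implemented as uniform
  draws between the 0th and 5th percentile of the run's observed
  intensities, from a generator seeded by `(seed, run_id)`, with imputed
  cells flagged. The method is a seeded, reproducible realisation of the
  low-abundance-resampling idea used by common search platforms, which do
  not document their exact sampler.
* **Modification strings** — peptide tables encode modification events as
  `Name (delta) @ position`, joined by `; ` — e.g.
  `MetLoss (-131.040485) @ protein N-term` or `Oxidation (+15.994915) @ 4`,
  where a numeric position is a 1-based residue index within the peptide.
  Unknown names are rejected with the full offending list.
* **Fold changes** — log₂(MUT/WT) per peptidoform and biological replicate,
  technical runs averaged first. Modification identity (name + mass delta +
  position) is part of the peptidoform key; mass deltas must match the
  canonical monoisotopic values within 1e-6 Da, and Met-loss events are
  only legal at the protein N-terminus.
* **Protein collapse** — peptides are pooled into paralog families via a
  user-supplied map (near-identical paralogs cannot be distinguished at the
  peptide level); peptides with any modification other than
  carbamidomethylation are omitted; families with fewer than 3 distinct
  peptides are excluded; the summary is the median peptide fold change.
  The per-family p-value is a two-sided one-sample t-test of peptide log₂
  fold changes against zero, BH-adjusted across families — a pragmatic
  choice where no canonical per-protein test exists; a zero-variance family
  gets p = 1 at zero mean by convention. Peptides shared between families
  contribute to each and are flagged ambiguous.
* **N-terminal classification** — start position 1 with a leading Met means
  iMet retained; start position 2, or start 1 with a Met-loss event, means
  processed; start > 2 is internal; an N-terminal acetyl (or
  Met-loss+acetyl) event refines retained/processed into the acetylated
  forms. The peptide sequence must match the protein at its reported
  position, else the record is rejected.
* **Retained-vs-all comparison** — a two-sided Wilcoxon rank-sum test of
  iMet-retained fold changes against *all* fold changes, retained included
  (the superset convention of the underlying experimental design). Because
  the groups overlap, the test is conservative: under the null it rejects
  well below its nominal level (the acceptance script typically measures
  ~0.5–2% at nominal 5%). Exact enumeration is used for small untied
  samples (combined n ≤ 20); otherwise the tie-corrected normal
  approximation. Excluding the retained peptides from the reference group
  would make the test nominal; the superset is kept deliberately and the
  sensitivity can be probed by calling `rank_sum_test` on the disjoint
  groups.
* **5-fold partition** — retained peptides at log₂fc ≥ log₂(5) form the
  high group; the boundary belongs to the high group. Second-residue
  composition is reported per group as raw residues.

## Reporter error rates

Per error-construct replicate, the rate is 100 × (signal ratio) / (mean
wild-type signal ratio); dual assays use Fluc/Rluc, single assays the raw
Nluc signal. Normalising to the wild-type *mean* (rather than a matched
replicate) is the default because replicate pairing is usually not
meaningful across transformations; a paired mode is available.
Percentages are never clipped above 100 — wild-type measured against
itself averages exactly 100% but individual replicates scatter around it.
Group comparisons use Welch's unequal-variance t-test (strain variances
routinely differ), with stars at p < 0.05 (*) and p < 0.01 (**), strict
inequalities. A260 conversions are linear: 1 A260 unit = 40 ng/µl RNA =
20 nM 80S, 60 nM 40S, 30 nM 60S.

## Synthetic data: what it emulates, and what it does not

Each artifact draws from its own generator stream derived from
`(seed, role)`, so regenerating one file never perturbs another and equal
seeds give byte-identical files. Ground-truth sidecars carry everything
needed to compute expected downstream quantities without re-simulation.

**Proteome** (defaults: 1000 genes, substrate fraction 0.5, lengths
100–400, 50 terms of 40 genes, planted term drawn with 0.9 substrate
probability, 20 non-coding genes in the GFF3). The planted term's effect
size was chosen so that, at the default background, its hypergeometric
signal survives BH across 50 terms in essentially every draw. Residues are
drawn uniformly, so synthetic proteins carry far more methionines than
real, Met-poor proteomes — methionine-count summaries on synthetic data are
structural checks, not realistic values.

**Peptide tables** (defaults: 30 proteins × 10–16 peptides, 2 conditions ×
2 biological × 3 technical runs, retained fraction 0.3, planted shift
δ = 3 log₂ units on retained N-terminal peptides, log-normal noise
σ = 0.5 log₂ units, 10% missingness, 20 planted filter failures). The
defaults reproduce the scale of a crude-ribosome label-free experiment:
~18 retained and ~760 total peptide-by-replicate fold changes. Three
realism choices matter downstream:

1. *N-terminal peptidoforms are low-abundance* (−3 log₂ offset), so a
   planted shift on them does not distort total-intensity normalisation.
2. *Equal loading*: run totals are equalised before dropout, because equal
   peptide amounts are injected per run. Label-free data are therefore
   compositional, and the sidecar records both the absolute planted family
   shift and the expected **measured** shift (absolute minus the
   compositional closure term) — recovery is judged against the latter.
3. *Left-censored missingness* (default): each run's lowest measurements go
   missing, the dominant mechanism in label-free MS and the regime
   low-abundance resampling is designed for. A `mcar` option drops cells
   completely at random instead. Under censoring, a peptide whose absolute
   signal sits below the detection floor in one condition has its fold
   change squashed toward zero by imputation — visible on the lowest-
   abundance retained peptides, and a faithful reproduction of how real
   pipelines behave at the detection limit.

Passing tests on these tables show the procedure recovers planted effects
under log-normal noise, compositional closure, and left-censoring; they do
not validate behaviour under retention-time drift, shared-peptide protein
inference beyond the supplied paralog map, or intensity-dependent
interference, none of which are simulated.

**Luminescence** (defaults: true rate 1%, wild-type Fluc/Rluc 2.0, CV 0.1,
3 replicates): multiplicative log-normal noise per measured ratio; the
generator supports CV → 0 for exact recovery checks.

## Problem sizes and numerics

The test suite and acceptance script run replicated simulations at the
sizes above: 200 seeded replicates for detection-rate estimates (binomial
s.e. ≈ 1.5% at 5%), 10 replicates for worst-case family-median recovery,
and exhaustive hypergeometric verification for all backgrounds of size
≤ 12 (3184 tables). Hypergeometric tails come from scipy's `hypergeom.sf`,
BH from statsmodels `multipletests`, rank-sum tests from scipy
`mannwhitneyu`, and Welch tests from scipy `ttest_ind(equal_var=False)`;
p-values are clamped into (0, 1]. Reported percentages round half-up at
the printed precision. Known limitations: the scan's binary substrate rule
ignores processing-efficiency gradients; the conserved-term intersection
treats species independently (no phylogenetic weighting); and the
per-family t-test assumes approximately symmetric peptide fold-change
noise within a family.
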