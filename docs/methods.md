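# Methods

## Track-back model

A *clonotype* is a TCRB CDR3 sequence, at nucleotide (nt) or amino-acid (aa)
resolution; the `junction` field of the AIRR rearrangement tables is the CDR3
including the conserved C and F/W anchors, stored verbatim. Matching between
single-cell queries and bulk clones is **CDR3-only**: the search imposes no
V/J condition, because V/J annotations from different platforms are not
reliably comparable and the biological question — has this receptor sequence
been generated and expanded elsewhere — is carried by the junction. A strict
mode requiring V-gene equality is available (`strict_v=True`) for sensitivity
analysis.

Within a bulk repertoire, clone identity is `(cdr3_nt, v_call, j_call)`;
records sharing a nucleotide sequence under different V/J calls have their
frequencies summed before any tracking arithmetic. "Found" means at least
one read; no abundance threshold is applied. At the aa level the convergent
set is keyed by distinct nucleotide sequence and the clonotype frequency is
the unweighted arithmetic mean over variants — so a clonotype carried by two
variants at 2×10⁻⁴ and 4×10⁻⁴ has frequency 3×10⁻⁴ and convergence 2.

Duplicate single cells carrying one clonotype collapse to a single query
before tracking (unique-clonotype semantics); sequence-feature summaries
(CDR3 length, V usage, positional amino-acid frequencies) are likewise
computed on unique clonotypes.

### Publicity

Per (clonotype, subset): pct = 100 · n_found / n_searched, where n_searched
is always taken from the repertoire set actually searched, never a constant.
Bands: extremely public ≥ 75%; public 25.0–74.9%; below 25%, a single hit
confined to the clonotype's own donor is ultraprivate, anything else is
private. With the emulated denominators this puts the ultraprivate line at
3.23% for TN/CM (31 repertoires) and 6.25% for Treg/Tscm (16). (A published
Treg threshold of 5.88 would imply 17 repertoires; since the denominator is
data-driven here, 16 Treg repertoires give 6.25 — the discrepancy is
documented rather than reproduced.) Clonotypes found nowhere get no record.

### Tracking rate and correlations

The tracking rate is per *source donor*: the percentage of that donor's
unique clonotypes found in ≥ 1 repertoire of the full set (any subset, any
donor), summarised as the unweighted mean and sample sd across donors. The
convergence–frequency relation is a two-sided Spearman correlation with one
point per clonotype: x = mean convergence and y = mean frequency across the
subset's repertoires where the clonotype is found (per-repertoire points are
available behind a flag). Identical x ranks leave rho undefined and are
reported as not-available rather than 0.

### Exclusivity and expansion

HD-only clonotypes are found in ≥ 1 HD repertoire and no T1D repertoire of a
subset (T1D-only symmetric); clonotypes in both or neither are excluded.
Clonal expansion is *within donor*: a cross-donor identical sequence is
publicity, not expansion. The group-size threshold defaults to ≥ 2 cells and
is a config knob because published practice varies between counting pairs
and requiring > 2 cells. Motif-based specificity grouping is not
re-implemented; externally produced group assignments can be loaded for
group-level summaries.

## Expression arm

Ct → Et: per (cell, gene), Ct_min is the minimum over the ≤ 2 duplicate
wells; missing readings (and readings above 40 cycles, which are warned
about) are replaced by the ceiling of 32 cycles, and Et = 32 − min(Ct_min,
32) ∈ [0, 32]. Cells with all-zero Et rows are removed. Because Ct is a
log₂-scale quantity, Et differences are log₂ fold changes; `avg_logFC` is
the in-cluster minus out-of-cluster difference of mean Et over all cells.
An optional per-run centering of the housekeeping gene (SRP14) is provided
as a declared stand-in for batch correction and is off by default.

The hurdle test is a plain two-part maximum-likelihood construction (no
shrinkage priors): the discrete part is the 1-df binomial LRT on detection
between the cluster and all other cells; the continuous part is the 1-df
common-variance Gaussian LRT on Et among expressing cells, with deviance
n·log(RSS₀/RSS₁); the overall p-value is chi-square on the summed deviances
(2 df, reducing to the discrete 1 df when either group has no expressing
cells). When the expressing cells fit the two-mean model perfectly
(RSS₁ = 0 with RSS₁ < RSS₀, possible at one expressing cell per group) the
continuous deviance is infinite and the overall p is 0 — a degenerate but
honest limit at tiny n. Markers require Bonferroni-corrected overall
p ≤ α (default 0.05) over all (gene, cluster) tests and |avg_logFC| > 0.25.
Test-side verification maximises the same likelihoods numerically with
scipy.optimize, and a 1000-gene permutation suite checks the null rate at
p < 0.05 stays within 0.05 ± 0.02.

Clustering scales genes to zero mean/unit variance, projects on 10 principal
components, builds a k = 20 shared-nearest-neighbour graph pruned at Jaccard
1/15, and runs seeded Louvain at resolution 1 (all exposed as parameters;
10 PCs and resolution 1 are the study's stated settings, k and the pruning
threshold are common SNN defaults). Labels are 1-based by decreasing size.
Cohort composition per cluster is a two-sided rank-sum test on per-donor
cell fractions, Bonferroni-corrected over clusters; an all-tied cluster is
reported at p = 1 directly since the rank-sum statistic degenerates.

## Assays

SI = mean(antigen triplicate)/mean(diluent triplicate), positive iff
SI ≥ 3 (boundary inclusive). A zero diluent mean leaves the ratio undefined;
the result then uses a pseudocount denominator of 1 and carries an explicit
`zero_background` flag instead of a silent infinity. Phenotype gating:
CD45RO⁺CD27⁺ → CM, CD45RO⁺CD27⁻ → EM, CD45RO⁻CD27⁻ → NTEM, CD45RO⁻CD27⁺
splits on CD95 into Tscm (+) and TN (−); positivity is *strictly above* the
per-sample cutoff, so exact-equal intensities gate negative (ties are
measure-zero for real intensities). Gates are inputs, not inferred. The AIM
responder frequency is n(CD154⁺CD69⁺)/n(CD4⁺) per condition without
background subtraction; phenotype composition is normalised to per-individual
fractions summing to 1.

## Synthetic-data generator

The generator's defaults are the study conditions: 31 bulk donors (17 HD,
14 T1D) each with TN and CM repertoires, 8 + 8 of them with Treg and Tscm
(94 repertoires); single cells from 5 HD + 7 T1D donors, 10 unique
clonotypes per donor with a planted tracking rate of 0.20; clone sizes drawn
from a power law with exponent 2.5 at a read depth of 10⁵ per repertoire
(a desk-scale stand-in for the tens of millions of reads in the emulated
archives) over 1000 background clones; a 48-gene qPCR panel including SRP14.

Background CDR3s are random in-frame, stop-free sequences (36–48 nt, C…F
anchors), globally unique at the nucleotide level and rejected if their
translation collides with any planted amino-acid clonotype — so planted
sharing is the only sharing and publicity/convergence/exclusivity recovery
is exact. Convergence is planted by synonymous-codon substitution,
translation-checked and distinct at the nucleotide level; the cell's own
sequence is always among the seeded variants so nucleotide and amino-acid
tracking rates coincide with the plan. The seeding plan cycles through
templates (extremely public in TN at 24/31, public at 10/31, CM
ultraprivate, CM private, Treg+CM co-seeding for frequency ratios, Tscm
private) after first allocating the configured number of deliberately
HD-only and T1D-only CM clonotypes; a `monotone` plan style instead seeds
clonotypes with convergence 1, 2, …, k at proportionally increasing counts
into a fixed set of TN repertoires, which forces a Spearman rho of exactly 1
between convergence and frequency.

The truth manifest derives all labels (publicity category, exclusivity,
frequencies) from the realised seeding and assembled counts, so recovery
comparisons stay exact even when a template incidentally lands
cohort-exclusive. Expansions are planted on de-novo (untracked) clonotypes
— 10 groups of 3 cells by default, 3 confined to one true expression
cluster — leaving the bulk seeding untouched. Ct values are Gaussian around
per-cluster gene means (marker blocks at Et 10 vs background 1, SRP14 at
12, sd 1), censored at the ceiling, with 15% dropout and 10% missing second
duplicates plus 0.1-cycle replicate noise. ELISPOT triplicates are Poisson
around class-dependent means (positive 50, diluent 10); AIM marker
intensities are lognormal on the planted side of the gates.

What the generator does *not* emulate: V(D)J generation probabilities (no
recombination model — V/J names are labels), sequencing error, cross-donor
background sharing, realistic publicity gradients, PCR amplification bias,
or MAST-style bimodal expression with continuous-component shrinkage.
Passing the recovery suites therefore demonstrates correctness of the
bookkeeping and statistics under the stated model, not robustness to those
real-data features.

## Numerical and design choices

* Sequences are upper-cased on read; clonotype merge order does not matter
  (shuffling input rows yields identical repertoires).
* Cells lacking a productive beta chain (out of frame, internal stop or
  empty) are dropped with a logged count; beta-only cells are retained.
* Bulk "frequency" treats `duplicate_count` as the abundance unit
  (read-count-based), as the table provides no unique-molecule field.
* Bonferroni denominators: the number of (gene, cluster) tests for markers,
  the number of clusters for composition.
* Random state: every stage derives its generator from one root seed via
  `numpy.random.SeedSequence.spawn`; the Louvain pass seeds Python's
  `random` module (used by igraph) and restores it afterwards.
* Desk-scale problem sizes used by the test and acceptance runs: the full
  94-repertoire design at 10⁵ reads/repertoire for recovery suites, a
  20-repertoire layout (~400 clones each, ≥ 50 queries) for brute-force
  oracle equivalence, and 1000 permuted genes at 200 cells for hurdle
  calibration — chosen so an end-to-end run completes in seconds while
  keeping every statistic well away from small-sample degeneracy.

## Known limitations

* The hurdle continuous component relies on chi-square asymptotics; at very
  few expressing cells its p-values are approximate (the discrete component
  is exact-likelihood but also asymptotic in its reference distribution).
* Louvain partitions are seed-stable but can renumber or merge marginal
  communities across library versions; only partition structure (not label
  identity) should be relied on.
* ELISPOT class recovery near the SI = 3 boundary is stochastic by design;
  the generator's positive/negative means are placed away from the boundary
  so flips are rare but not impossible.
* The AIM normalisation for non-gated events is interpreted as per-individual
  phenotype fractions; no alternative formula is offered.
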