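# Methods

`repeatskim` analyses the repetitive fraction of very large plant genomes
from low-pass ("genome skim") single-end read sets.  The guiding scientific
question is whether a genome-size expansion is driven by massive
amplification of a few repeat families (which leaves many near-identical
copies) or by long-term accumulation of many families under weak DNA
removal (which leaves heterogeneous, diverged copies).  The pipeline
implements the analysis chain end to end: read preprocessing, read-overlap
graph construction, graph clustering into repeat families, genome-proportion
quantification, intrafamily heterogeneity statistics, ancestral
monoploid-genome-size reconstruction with expansion accounting, and the
correlation of single/low-copy (S/L) fraction size with genome size.

## Preprocessing

Reads are processed in a fixed order: exact-duplicate removal, organelle
screening, then length standardisation.  Published protocols do not pin the
relative order of the organelle screen and the length filter; screening
before truncation uses the full read for the alignment and is the order
adopted here.

*Duplicates.* Emulsion-PCR artefacts are same-strand verbatim copies, so a
duplicate is a read with identical length and identical (case-insensitive)
sequence; reverse complements are not collapsed.  The first read of each
group, in input order, is retained.

*Organelle screen.* Reads are compared against a plastid/mitochondrial
reference database by seeded (12-mer) gapless x-drop extension with
match +1 / mismatch −1.  Significance uses the Karlin–Altschul form
E = K·m·n·e^(−λS) with K = 0.1, λ = 0.7, m the read length and n the total
database length; reads with E ≤ 10⁻⁶ are organellar.  The operating
contract is that perfect or near-perfect organelle matches are removed and
random sequence is kept — a property insensitive to the exact constants: a
perfect 400 bp read scores ≈400 (E ≈ 10⁻115 against a 100 kb database)
while the score needed to reach E = 10⁻⁶ is ≈42, far above what random
400 bp sequence attains (≈12–20).

*Length.* Reads longer than the target (default 400 bp) are truncated at
the 3′ end; shorter reads are dropped.

## Read-overlap graph

All-vs-all comparison uses Smith–Waterman local alignment (match +1,
mismatch −1, gap −2), both strands.  An edge joins two reads whose best
alignment spans ≥ 220 columns (for 400 bp reads) at ≥ 90% identity;
identity is computed over all alignment columns including gaps.  The edge
weight is `overlap_bp × identity/100`, a score-like quantity bounded by the
read length, so identical 400 bp reads weigh 400.  IUPAC ambiguity codes
match nothing, including themselves.

For scale, candidate pairs are restricted to reads sharing a canonical
16-mer, and the DP is banded (±25 cells) around the most-voted shared-seed
diagonal.  With substitution-only divergence the optimum lies on that
diagonal, so the banded result equals exhaustive DP; the exhaustive mode is
retained and the test suite verifies edge-set equality on small scenes.
The band tolerates ±25 bp of net indel offset; beyond that, overlaps can be
truncated — a deliberate trade against the ~50× speed gain.

The identity floor (90) is a configurable convention rather than a
published constant, matching the similarity regime common in read-clustering
tools for this data type.

## Clustering, merging, assembly, annotation

Repeat families are connected components of the overlap graph — on small
inputs provably identical to brute-force component search.  Reads with no
edges become singleton clusters, so clusters always partition the read set.
The historical failure mode of graph clustering of repeats is
over-splitting of one family across clusters, addressed by a merge step:
two clusters merge when ≥ 5% of the smaller cluster's reads have alignment
evidence to the larger cluster at relaxed, database-hit-like thresholds
(alignment covering ≥ 55% of the read at ≥ 90% identity, rather than the
strict 220 bp clustering overlap) *and* both clusters carry the same
annotation label; "unknown" matches nothing.  Merging runs to a fixpoint.
Checking conserved protein-domain order — the manual third criterion used
when curating such merges — would need a domain HMM library and is out of
scope; the same-annotation requirement stands in for it.

Per-cluster consensus contigs are built by greedy overlap-layout-consensus:
pairwise overlaps ≥ 160 bp at ≥ 90% identity are joined longest-first over
a union-find layout whose offsets come from the alignments (exact under
substitution-only divergence), and the consensus is the per-column base
majority with ties broken alphabetically.  Unjoined reads emit themselves
as contigs.

Top families are clusters holding ≥ 0.05% of the input reads (inclusive).
Automated merging is applied to all clusters, not only those above a manual
inspection cut-off.

Annotation: a reference-library label is assigned when ≥ 20% of member
reads hit one library family best (labels from the `name#Label` FASTA
convention); otherwise a tandem array is called when a contig's
base-identity autocorrelation reaches 0.75 at some lag ≥ 2 (random sequence
sits near 0.25); otherwise "unknown".

## Genome proportion and expansion accounting

Each read gets at most one hit: its best-scoring local alignment against
any contig (ties: longer matched span, then smaller contig id).  Hits are
kept when they cover ≥ 55% of the read at ≥ 90% identity (both inclusive).
A family's genome proportion is

GP = 100 × Σ matched query bp over retained hits to the family's contigs
          / total dataset bp,

and its abundance in Mb is GP/100 × genome size (Mb).  Only the top
high-scoring pair per read contributes bases; overlapping secondary HSPs
are not merged.  The estimator loses read bases at element boundaries
(reads overlapping a copy by less than the coverage threshold contribute
nothing; partial overlaps contribute partially), giving a downward relative
bias of roughly `read_length/element_length`: ≈6% for 2 kb elements, ≈4%
for full-length LTR elements of 4 kb and longer.  Chance hits of random
400 bp reads at the 90%/55% thresholds are negligible (none observed across
simulated backgrounds).

Expansion accounting takes four non-negative Gb inputs — extant monoploid
size, reconstructed ancestral (MRCA) size, the summed abundance of the top
families, and a baseline (the minimum of that summed abundance across the
other sampled species, read as "already present in the ancestor") — and
reports expansion = extant − MRCA, attributable = top − baseline, and the
two percentages attributable/expansion and top/expansion.  Gb values are
rounded to 2 decimals and percentages to integers, the precision at which
such values are conventionally reported; ratios are computed before
rounding.  The summed-then-minimum reading of the baseline (rather than
summing per-family minima) is adopted; it is the conservative
interpretation consistent with the published worked examples.

## Intrafamily heterogeneity

A family's amplification regime is read from the identity distribution of
its member-pair edges: `high_identity_fraction` is the fraction of edges at
or above 98% identity; a family is called "burst" when that fraction is
≥ 0.10, "accumulation" otherwise, and "indeterminate" below 30 edges or 2
members.  The 0.10 cut operationalises "a peak of very-high-similarity
pairs"; published figures show such peaks qualitatively without a numeric
criterion, so the threshold is configurable and sensitivity-tested.

Profiles are computed on a graph built at a lower identity floor (default
70%) and smaller seed (10-mer) than the clustering graph.  At a 90% floor,
copies of a long-accumulated family (pairwise divergence up to tens of
percent) yield almost no edges at all, making every such family
indeterminate; the profiling floor must sit below the divergence range the
statistic is meant to measure.  With 400 bp reads, 0.5% sequencing error
adds ≈1% mismatch between error-free-identical copies, so burst families
(copy divergence U(0, 0.01)) straddle 97–99.5% pair identity and retain a
large ≥ 98% fraction, while accumulation families (U(0.02, 0.30)) have
essentially none — the regimes stay separable at the defaults.

## Ancestral genome-size reconstruction

Monoploid genome size is 1Cx = 2C/ploidy, removing recent-polyploidy
inflation.  Traits (1Cx in Gb) are Box-Cox transformed,
y = (x^λ − 1)/λ with λ = −2 by default (the transform under which such
right-skewed genome-size distributions pass normality checks), then
modelled per tree as Brownian motion, optionally with a directional trend:
E[y_tip] = root + β·(root-to-tip path length), Cov[y_i, y_j] = σ²·(shared
path length).  Each tree is fitted by maximum-likelihood GLS; MRCA states
are best linear unbiased predictions (conditional-normal means given tip
values and the fitted model).  Per-tree model choice uses a likelihood-ratio
test at α = 0.05 (the models are nested; BM is the β = 0 special case).

Uncertainty over phylogeny: node estimates are averaged over the supplied
tree sample, with the 95% CI the t-interval over per-tree estimates; mean
and interval are back-transformed at the end.  With a single tree the CI is
undefined and flagged.  This ML-GLS-plus-tree-averaging estimator replaces
a Bayesian MCMC over trait histories with tree-transform scaling
parameters (δ, κ, λ): the estimand — the mean MRCA state over tree
uncertainty — is approximated by the tree-sample mean of per-tree BLUPs,
which is exactly testable against closed forms and matrix oracles, whereas
MCMC output is not.  Consequences: published point estimates from the MCMC
route are approximate targets only, and whether the tree-scaling parameters
would materially shift MRCA means is untested here.

Numerics: trees are not assumed ultrametric; on an exactly ultrametric tree
the trend is collinear with the intercept and the directional fit
degenerates to BM with β = 0 (preserving the nested-likelihood ordering).
Zero-length branches are jittered by 10⁻⁹ × tree height so the trait
covariance stays invertible.  Back-transformation requires λ·y + 1 > 0; for
λ = −2 the transformed scale is bounded above by 0.5 (x → ∞), and values in
the tens of Gb sit within ~10⁻³ of that bound, so simulation σ² must be
small (the trait simulator raises if a path leaves the domain).

## S/L fraction statistics

From rows of (species, % S/L DNA, 1C Mb, ploidy): exact duplicate rows
(literature re-reports) are dropped, multiple independent estimates per
species are averaged on the percentage scale, then
S/L Mb (1C) = %/100 × 1C and S/L Mb (1Cx) = %/100 × 2·1C/ploidy.
Association with genome size uses Kendall's tau-b with tie corrections,
τ_b = (C − D)/√((n₀ − n₁)(n₀ − n₂)), p-values from the tie-corrected normal
approximation (adequate at the n ≥ 10 of real tables; the test suite checks
the statistic against exhaustive pair enumeration at n ≤ 8).  Per-family
subgroup correlations run only with ≥ 5 species.  The choice of "prime" 1C
value per species is a curation step upstream of this package; 1C is taken
as given.

## Synthetic-data generator

The generator emulates the skim of a repeat-rich genome: family copies are
drawn from a random ancestral element per family and mutated at a per-copy
rate u ~ U(0, 0.01) ("burst") or u ~ U(0.02, 0.30) ("accumulation",
reflecting retention without deletion), then placed at random
non-overlapping genome positions in uniform-random background (GC 0.5 by
default).  Copies are separated by at least one read length of background;
without this, reads spanning the junction of two nearly adjacent copies
from different families chain the families into one component — an artefact
of placement geometry, not of the clustering under test.  Reads have
uniform random start and strand, per-base substitution error (default
0.5%), a planted fraction of verbatim duplicates (default 5%), organelle
contaminants (default 2%) and optionally under-length reads.
Substitutions only by default so identity arithmetic in tests is exact; an
indel mode exists.  Every read carries exactly one provenance record, and
the generator also counts realised exact-duplicate reads (planted plus
coincidental) for exact comparison with deduplication.  What the generator
does *not* model: 454 homopolymer indel error, quality scores, GC bias,
nested/fragmented element insertions and satellite higher-order structure —
so passing tests demonstrate correct recovery of planted structure under
idealised noise, not performance on real 454 data.

## Validation experiments (`repeatskim.experiments`)

* **Clustering/quantification**: a 1 Mb genome with ten 2 kb-element
  families (copy numbers 50…5; per-family copy divergence U(0, u_max),
  u_max 0.005…0.10 so abundant families are the more homogeneous, the
  skewed spectrum genome skims show), 2500 × 400 bp reads at 0.5% error.
  Scored by adjusted Rand index of the partition against planted families
  (over repeat-derived reads) and, over 20 re-skims of the same genome, the
  fraction of per-family GP estimates within 3 binomial SE of truth.
* **Regime classification**: two burst + two accumulation families
  (30 × 1 kb and 100 × 1 kb copies; the accumulation copy number keeps
  same-copy read pairs — which are always near-identical — rare), ~50–180
  reads per family, 20 replicates.
* **Ancestral recovery**: 50 replicates of 100 independent 12-tip
  birth–death trees; Brownian traits (root 35 Gb, σ² = 10⁻⁹ on the
  transformed scale) simulated per tree; coverage of the back-transformed
  95% t-interval checked against the true root.
* **Preprocessing truth**: a 200 kb toy scene with 8% duplicates, 5%
  organelle reads and 5% short reads; filter counts must match the
  generator ledger exactly.

Problem sizes keep the full battery in the tens of minutes on one CPU while
every family retains enough reads (≥ ~25 for clustering, ≥ ~50 for regime
calls) for stable statistics.

## Known limitations

* GP estimates carry the boundary bias described above (≲6% relative for
  ≥ 2 kb elements); abundances of very short elements are underestimated
  more strongly.
* The banded aligner underestimates overlaps with > 25 bp net indel offset.
* Regime calls depend on the profiling identity floor and the 98%/0.10
  operationalisation; they are conventions, not published constants.
* The GLS route ignores tree-transform scaling parameters and reports
  frequentist t-intervals over trees, not posterior credible intervals.
* Kendall p-values are asymptotic; do not trust them below n ≈ 10.
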