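# Methods

## Analysis units and the lineage threshold

All repertoire statistics count *lineages* (clones), not reads: a lineage is
a cluster of rearrangements with an identical grouping key whose pooled
supporting reads reach `min_reads` (default **5 reads**, i.e. the filter is
`read_count >= 5`). When a full V(D)J nucleotide sequence column is present
it is the grouping key; otherwise the exact triple (V gene, J gene, HCDR3
nt) is used. Error-aware read clustering is assumed to have happened
upstream (the input is an annotated rearrangement table, not raw reads), so
the grouping here is exact string identity. Relative frequency is reads per
lineage divided by total reads over retained lineages of the same (donor,
subset, locus); the per-stratum sum is 1 by construction and is asserted to
1e-9.

Gene calls are handled at gene level: allele suffixes (`*01`) are stripped
on read, and families are derived by truncating the V call at the first
hyphen. Nonproductive rearrangements are excluded before every downstream
metric (the alternative — keeping them for counting only — would change
denominators; exclusion is the stricter, more common convention).

## Clonotypes and sharing

A clonotype at the default threshold is the exact key (V gene, J gene,
HCDR3 nt). Below 100%, lineages are merged by single linkage within
(V, J, CDR3-length) blocks whenever Hamming identity ≥ threshold;
sequences of unequal length never merge because identity between unequal
lengths is not defined here. Single linkage makes the clonotype count
non-increasing as the threshold drops (merging monotonicity), which the
test suite checks, and the partition is verified against a brute-force
all-pairs transitive closure.

Sharing is tabulated by *exact* occupancy pattern (the set of subsets a
clonotype appears in); patterns therefore partition the clonotype set.
Per-subset totals count a clonotype once per occupied subset, so the
"total shared" figure is the sum of per-subset shared counts — a clonotype
occupying k subsets contributes k — matching the bookkeeping of the
published sharing table; the distinct-clonotype count is exposed
separately (`n_shared_clonotypes`). Percentages are pattern count ÷ subset
total × 100, **half-up** rounded to 2 decimals (1/2776 → 0.04; banker's
rounding would give 0.03 for some entries). A subset with zero clonotypes
reports NaN percentages, never 0.

Two pooling modes exist because "shared when donors are grouped" is
ambiguous: the default evaluates sharing within each donor and sums
pattern counts across donors (biologically conservative — public
clonotypes between donors are rare and more likely artefactual); a
cross-donor mode pools all lineages first. Clonotype and lineage ids are
assigned by sorted key, so runs are bit-reproducible.

## Usage, mutation and distributional tests

Usage tables give one count per lineage; frequencies are % of lineages per
(donor, subset) stratum and sum to 100. Cross-subset comparison uses, per
gene label, the 2×2 table (label vs all other labels) on donor-pooled
counts with Fisher's exact two-sided test, Benjamini–Hochberg FDR across
labels, and a consistency flag requiring each donor's own (unadjusted)
Fisher test to be significant at alpha with the same direction of the
frequency difference in every donor. One-vs-rest was chosen over
gene-pair-specific contrasts as the standard repertoire convention;
per-donor tests are left unadjusted because the consistency rule is itself
the replication filter.

Mutation load per lineage is `100 − v_identity%` (the complement of
germline identity) unless an explicit mutation % is supplied. Bins are
[0,2), [2,4), [4,6), [6,8), [8,10], >10 percent: left-closed/right-open
except that exactly 10 falls in the fifth bin, because the last interval
is described as "more than 10%". Kruskal–Wallis is the omnibus test;
pairwise comparisons use Dunn's rank z-test with mid-rank tie correction
T = Σ(t³−t)/(12(N−1)) and, by default, Bonferroni adjustment over all
pairs (Holm and no correction are options). When every observation is
identical the omnibus p is defined as 1 rather than erroring.

## HCDR3 features and PCA

The feature matrix has exactly nine numeric descriptors per lineage (CDR3
aa length; relative frequency; N1, N2 lengths; P3'V, P5'D, P3'D, P5'J
lengths; IGHV–IGHJ germline identity %); donor and subset are metadata,
never features. Because units are incommensurate, features are
z-standardised (population SD) — the PCA is on the correlation matrix.
Constant features are dropped with a warning; an all-constant matrix is a
degenerate-input error. Components use a deterministic sign convention
(largest-magnitude loading positive), making embeddings invariant to row
order up to nothing (exactly reproducible). Per-donor embeddings re-run
the PCA on donor-restricted rows rather than projecting onto pooled
components, so each donor's structure is shown on its own axes. Rows are
assumed to be lineages (the natural unit given lineage-level features such
as relative frequency).

CDR3 peptide properties use published scales, shipped as in-code constant
tables: Kyte–Doolittle hydropathy (mean per residue, i.e. GRAVY —
length-normalized), net charge at pH 7 and isoelectric point from the
Lehninger pKa set via Henderson–Hasselbalch (charge is length-extensive;
pI found by bisection on [0,14] to 1e-6), and Ikai's aliphatic index
(mole-percent weighted A + 2.9V + 3.9(I+L), length-normalized).
Non-standard residues flag the sequence and set its properties to missing.

## iMFI

iMFI = percent positive × MFI (units: percent × fluorescence intensity).
Normalization per marker over the five subsets: 5·√iMFI divided by the
subset-mean of √iMFI. Two identities follow algebraically and are enforced
at 1e-9: the per-marker mean of normalized values is 5, and rescaling a
marker's iMFIs by any c > 0 leaves normalized values unchanged. An
all-zero marker is undefined (reported missing). The default normalizes
per-subset *median* iMFI over donors (the legend order of operations); a
per-donor mode is available. Clustering of subsets uses Euclidean distance
with average linkage by default — common defaults for marker heatmaps,
exposed rather than hidden — on the subsets × markers matrix with rows and
columns sorted internally, so the tree is independent of input order;
export is newick. Paired Wilcoxon drops zero differences (Wilcoxon's
original convention; Pratt available) and warns below 5 donor pairs,
where the exact null is too coarse for much power.

## Synthetic data: what it emulates and what it does not

The generator mirrors the study design the pipeline assumes: 3 donors × 5
subsets, with per-subset categorical V/J usage over a bundled toy gene set
(20 IGHV, 4 IGHD, 6 IGHJ names in IMGT nomenclature — names only, since no
alignment is performed), SHM as a per-lineage Beta-distributed per-base
rate applied binomially over a 300 nt V region (defaults: means 0.2, 2, 4,
5, 6 % for naive, IgM_lo, IgM_hi, IgM_only, switched; an alpha of 0 gives
an exactly-zero rate), heavy-tailed lineage read counts (1 + negative
binomial, n = 0.45, p = 0.12, so a realistic majority of clusters fall
below the 5-read threshold), a junction model (CDR3 aa length ≈ N(15,
2.2²) clipped to [5, 32]; N lengths geometric with mean 3; P lengths
truncated geometric ≤ 3; segment lengths clipped to partition the
junction), a 0.9 productive fraction, and planted within-donor sharing at
exact per-pattern counts per donor (default 4 IgM_lo/IgM_hi, 8
IgM_only/IgM_hi, 1 IgM_lo/IgM_only, 1 triple). Planted lineages are drawn
with at least 5 reads so the default filter cannot silently remove the
planted truth. Defaults echo the qualitative biology (SHM ordering, IGHJ6
enrichment in naive/IgM_lo) so demonstration runs are didactic; they are
synthetic choices, not estimates from any dataset.

Not emulated: read-level sequencing error and error-correction artefacts,
intraclonal sequence diversification (one sequence per lineage is
emitted), realistic germline sequence content (junctions are random
codons, so background clonotype collisions occur only at the birthday
rate of a ~45 nt random string — negligible), D-gene alignment ambiguity,
and cross-donor public clonotypes. Passing recovery tests therefore shows
the pipeline's bookkeeping and estimators are correct under the assumed
design, not that the pipeline is robust to upstream annotation error.

## Problem sizes and determinism

The test suite uses a 3 × 5 × 120-lineage repertoire for module tests; the
recovery check runs the full 3 × 5 × 2000-lineage design; calibration uses
200 replicates (Fisher+FDR, 50 genes, 500 lineages per arm) and 500
replicates (Kruskal–Wallis with five groups of 20; paired Wilcoxon with 15
donor pairs — at 15 pairs the discrete exact null has an achievable level
near 0.048, well inside the calibration band, which smaller panels cannot
reach). All simulations are driven by explicit seeds; identical seed and
configuration give byte-identical output.

## Known limitations

* The 97% clonotype mode is O(n²) per (V, J, length) block; adequate for
  per-donor repertoires of ~10⁴ lineages, not for 10⁶.
* Fisher tests treat lineages as exchangeable within pooled subsets; no
  donor random effect is modelled beyond the 3-of-3 consistency rule.
* The kappa locus is supported by the same machinery (IGK gene lists can
  be passed to the generator and all statistics are locus-generic), but
  defaults target the heavy chain.
* Published per-subset mutation medians, PCA variance fractions and other
  data-dependent values require the original sequencing data and are out
  of scope for verification here.
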