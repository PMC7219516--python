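# bcrep — comparative B-cell receptor repertoire analysis of sorted B-cell subsets

`bcrep` is a Python toolkit for contrasting the immunoglobulin heavy/kappa
gene repertoires and surface phenotypes of sorted human B-cell subsets —
naive (IgM+IgD+CD27−), IgM^lo and IgM^hi (the two IgM+IgD+CD27+ subsets
distinguished by reciprocal IgM/IgD density), IgM-only and class-switched
memory B cells. It is aimed at immunologists who have annotated V(D)J
rearrangement tables (AIRR or IMGT/HighV-QUEST dialect) for several donors
and subsets and want lineage-level, statistically controlled comparisons.

## What it computes

**Lineages and relative frequency.** Rearrangements with an identical
grouping key (full V(D)J sequence when available, else exact
(V gene, J gene, HCDR3 nt)) are pooled; clusters with at least
`min_reads` supporting reads (default 5) are the clones ("lineages") all
statistics count. Each lineage *i* of a (donor, subset) stratum gets

> f_i = r_i / Σ_j r_j,  r = reads per retained lineage,

so frequencies sum to 1 per stratum.

**Clonotypes and cross-subset sharing.** A clonotype is the set of lineages
with the same IGHV and IGHJ gene and 100% HCDR3 nucleotide identity (a 97%
single-linkage Hamming mode, restricted to equal lengths, is available).
Clonotypes are tabulated by their exact subset-occupancy pattern; the
sharing matrix reports per-pattern counts and, for every subset in a
pattern, the count as a percentage of that subset's clonotype total
(half-up rounded to 2 decimals). Sharing is evaluated within each donor and
summed across donors by default; a cross-donor pooling mode exists.

**Repertoire statistics.** V/J gene and family usage (% of lineages) with
donor-pooled Fisher exact tests, Benjamini–Hochberg FDR across genes, and a
3-of-3-donor consistency flag (each donor individually significant with the
same direction). Somatic hypermutation as % divergence from germline
(`100 − v_identity`), summarised by medians/IQR and the fraction of clones
in six 2% bins (0–2, …, 8–10, >10). Distributions compared by
Kruskal–Wallis with tie-corrected Dunn pairwise z-tests.

**HCDR3 features.** A nine-descriptor matrix per lineage (HCDR3 aa length,
relative frequency, N1/N2 lengths, P3'V/P5'D/P3'D/P5'J lengths, IGHV–IGHJ
germline identity %), z-standardised and embedded with PCA; plus peptide
properties of the CDR3 (Kyte–Doolittle hydropathy, net charge and pI from
the Lehninger pKa set, Ikai aliphatic index).

**iMFI phenotype.** iMFI = % positive cells × MFI per (donor, subset,
marker); per marker the five-subset normalization
`5·√iMFI / mean_subsets(√iMFI)` (mean exactly 5 by construction), followed
by hierarchical clustering of subsets and Kruskal–Wallis / paired Wilcoxon
marker tests.

**Synthetic repertoires.** A generator emulating the 3-donor × 5-subset
design — subset-specific V/J usage and Beta-distributed SHM rates,
heavy-tailed lineage sizes, an N/P junction model, planted within-donor
clonotype sharing — with a complete ground-truth ledger for recovery tests.

## Worked example

```
$ bcrep simulate --seed 3 --donors 3 --lineages-per-subset 80 --out-dir demo
1287 rearrangements -> demo
$ bcrep clonotypes --input demo/rearrangements.tsv --out demo/sharing.tsv
394 clonotypes (87 shared occurrences) -> demo/sharing.tsv
$ head -5 demo/sharing.tsv
group                   n_clonotypes  pct_naive  pct_IgM_lo  pct_IgM_hi  pct_IgM_only  pct_switched
IgM_lo+IgM_hi           12                       14.46       10.91
IgM_lo+IgM_hi+IgM_only  3                        3.61        2.73        3.7
IgM_hi+IgM_only         24                                   21.82       29.63
IgM_lo+IgM_only         3                        3.61                    3.7
```

The run simulated 80 lineages per donor-subset; after the ≥5-read filter,
394 clonotypes remain. The default generator plants, per donor, 4 clonotypes
shared between IgM^lo and IgM^hi, 8 between IgM-only and IgM^hi, 1 between
IgM^lo and IgM-only and 1 across all three — so the pooled within-donor
pattern counts are exactly 12, 24, 3 and 3 as printed. The percentage
columns read, e.g., "the 12 IgM^lo/IgM^hi clonotypes are 14.46% of all
IgM^lo clonotypes and 10.91% of all IgM^hi clonotypes"; empty cells mark
subsets outside the pattern (undefined, not zero).

```
$ bcrep mutation --input demo/rearrangements.tsv --out demo/mut.tsv
Kruskal-Wallis omnibus p = 1.818e-42
 group_a  group_b          z            p        p_adj
  IgM_hi   IgM_lo   4.782776 1.728911e-06 1.728911e-05
  ...
```

IgM^hi clones carry significantly more V-region mutations than IgM^lo
clones under the generator's SHM ordering (naive < IgM^lo < IgM^hi <
IgM-only < switched), as the Dunn-adjusted p-value shows.

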