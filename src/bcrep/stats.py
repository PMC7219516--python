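"""Gene-usage and mutation statistics across B-cell subsets.

Usage tables count lineages (clones), never reads, per V/J gene or family.
Cross-subset usage comparisons follow a pooled-then-confirm scheme: donors are
pooled into one 2x2 table per gene label (label vs rest, subset A vs subset B),
tested with Fisher's exact two-sided test and Benjamini-Hochberg FDR
correction across labels; a difference is then flagged *consistent* only when
the per-donor Fisher tests are each significant at alpha with the same
direction in all donors (the 3-of-3 rule for a three-donor study).

Somatic hypermutation is summarised per lineage as percent divergence of the
V region from germline (``100 - v_identity_pct`` when an explicit mutation
percentage is absent), with per-subset medians/IQRs and fractions of clones in
six 2%-wide bins: [0,2), [2,4), [4,6), [6,8), [8,10] and >10.  Distributional
comparisons use the Kruskal-Wallis omnibus test with Dunn's rank-based
pairwise z-tests (tie-corrected) and a configurable multiplicity correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import EmptyInputError, ParameterError

__all__ = [
    "usage_table",
    "UsageTable",
    "compare_usage",
    "mutation_profile",
    "MutationProfile",
    "compare_mutation",
    "cdr3_length_compare",
    "dunn_posthoc",
    "MUTATION_BIN_LABELS",
]

#: Left edges of the six mutation bins (percent); last bin is > 10.
MUTATION_BIN_LABELS = ("0-2", "2-4", "4-6", "6-8", "8-10", ">10")


# ---------------------------------------------------------------------------
# usage
# ---------------------------------------------------------------------------

@dataclass
class UsageTable:
    """Lineage counts and percent frequencies per gene/family label.

    ``counts`` is labels x (donor, subset); ``frequencies`` the corresponding
    percent-of-lineages within each (donor, subset) stratum; ``pooled`` the
    per-subset counts summed over donors.
    """

    level: str
    segment: str
    counts: pd.DataFrame
    frequencies: pd.DataFrame
    pooled: pd.DataFrame


def usage_table(lineages: pd.DataFrame, level: str = "gene", segment: str = "V") -> UsageTable:
    """Tabulate V/J gene or family usage; one count per lineage.

    Frequencies are percentages of lineages within each (donor, subset) and
    sum to 100 per stratum.
    """
    if lineages is None or len(lineages) == 0:
        raise EmptyInputError("no lineages")
    if lineages["locus"].nunique() > 1:
        raise ParameterError("lineages must come from a single locus")
    if segment == "V":
        col = "v_family" if level == "family" else "v_call"
    elif segment == "J":
        if level == "family":
            raise ParameterError("family level applies to V segment only")
        col = "j_call"
    else:
        raise ParameterError("segment must be 'V' or 'J'")
    if level not in ("gene", "family"):
        raise ParameterError("level must be 'gene' or 'family'")

    counts = (
        lineages.groupby([col, "donor_id", "subset"], sort=True)
        .size()
        .unstack(["donor_id", "subset"], fill_value=0)
        .sort_index()
    )
    counts.columns.names = ["donor_id", "subset"]
    freq = 100.0 * counts / counts.sum(axis=0)
    pooled = counts.T.groupby(level="subset").sum().T
    return UsageTable(level=level, segment=segment, counts=counts, frequencies=freq, pooled=pooled)


def _fisher_label(count_a, total_a, count_b, total_b):
    table = [[count_a, total_a - count_a], [count_b, total_b - count_b]]
    odds, p = sps.fisher_exact(table, alternative="two-sided")
    return odds, p


def compare_usage(
    usage: UsageTable, subset_a: str, subset_b: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Compare two subsets' usage, label by label.

    Donor-pooled counts give one Fisher exact two-sided test per label
    (label vs all other labels); BH-FDR adjusts across labels.  Per-donor
    Fisher tests (unadjusted, at ``alpha``) and the sign of the frequency
    difference yield ``consistent``: True only when every donor is
    individually significant with the same direction.

    Returns a frame indexed by label with ``odds_ratio``, ``p``, ``p_adj``,
    ``significant`` (BH at alpha), per-donor ``p_<donor>``/``dir_<donor>``
    columns and ``consistent``.
    """
    for s in (subset_a, subset_b):
        if s not in usage.pooled.columns:
            raise ParameterError(f"subset {s!r} not present in usage table")
        if usage.pooled[s].sum() == 0:
            raise EmptyInputError(f"zero lineages in subset {s!r}")

    pooled_a = usage.pooled[subset_a]
    pooled_b = usage.pooled[subset_b]
    tot_a, tot_b = int(pooled_a.sum()), int(pooled_b.sum())

    donors = sorted(usage.counts.columns.get_level_values("donor_id").unique())
    rows = []
    for label in usage.counts.index:
        ca, cb = int(pooled_a[label]), int(pooled_b[label])
        odds, p = _fisher_label(ca, tot_a, cb, tot_b)
        row = {"label": label, "count_a": ca, "count_b": cb, "odds_ratio": odds, "p": p}
        per_donor_sig, per_donor_dir = [], []
        for d in donors:
            da = usage.counts.get((d, subset_a))
            db = usage.counts.get((d, subset_b))
            if da is None or db is None or da.sum() == 0 or db.sum() == 0:
                row[f"p_{d}"] = np.nan
                row[f"dir_{d}"] = 0
                per_donor_sig.append(False)
                continue
            _, pd_ = _fisher_label(int(da[label]), int(da.sum()), int(db[label]), int(db.sum()))
            fa = da[label] / da.sum()
            fb = db[label] / db.sum()
            direction = int(np.sign(fa - fb))
            row[f"p_{d}"] = pd_
            row[f"dir_{d}"] = direction
            per_donor_sig.append(pd_ < alpha and direction != 0)
            per_donor_dir.append(direction)
        row["consistent"] = bool(
            per_donor_sig
            and all(per_donor_sig)
            and len(set(per_donor_dir)) == 1
        )
        rows.append(row)

    out = pd.DataFrame(rows).set_index("label")
    reject, p_adj, _, _ = multipletests(out["p"], alpha=alpha, method="fdr_bh")
    out.insert(out.columns.get_loc("p") + 1, "p_adj", p_adj)
    out.insert(out.columns.get_loc("p_adj") + 1, "significant", reject)
    return out


# ---------------------------------------------------------------------------
# mutation profiling
# ---------------------------------------------------------------------------

def mutation_percent(lineages: pd.DataFrame) -> pd.Series:
    """Per-lineage V-region mutation percent.

    Uses an explicit ``mutation_pct`` column when present, otherwise the
    complement of germline identity, ``100 - v_identity_pct``.
    """
    if "mutation_pct" in lineages.columns:
        return lineages["mutation_pct"].astype(float)
    return 100.0 - lineages["v_identity_pct"].astype(float)


def _bin_fractions(values: np.ndarray) -> np.ndarray:
    """Fractions in [0,2), [2,4), [4,6), [6,8), [8,10], (10, inf)."""
    v = np.asarray(values, dtype=float)
    counts = np.array(
        [
            np.sum((v >= 0) & (v < 2)),
            np.sum((v >= 2) & (v < 4)),
            np.sum((v >= 4) & (v < 6)),
            np.sum((v >= 6) & (v < 8)),
            np.sum((v >= 8) & (v <= 10)),  # exactly 10 falls here; last bin is >10
            np.sum(v > 10),
        ],
        dtype=float,
    )
    return counts / len(v) if len(v) else counts


@dataclass
class MutationProfile:
    """Per-stratum SHM summaries: medians, IQRs and six 2%-bin fractions."""

    per_lineage: pd.DataFrame          # lineage_id, donor_id, subset, mutation_pct
    summary: pd.DataFrame              # (donor, subset) median / iqr / n
    bins: pd.DataFrame                 # (donor, subset) x six bin fractions
    bins_pooled: pd.DataFrame          # subset x six bin fractions (donors pooled)


def mutation_profile(lineages: pd.DataFrame) -> MutationProfile:
    """Summarise V-region mutation load per (donor, subset) and per subset."""
    if lineages is None or len(lineages) == 0:
        raise EmptyInputError("no lineages")
    mut = mutation_percent(lineages)
    per = lineages[["lineage_id", "donor_id", "subset"]].copy()
    per["mutation_pct"] = mut.values

    summ_rows, bin_rows = [], []
    for (donor, subset), grp in per.groupby(["donor_id", "subset"], sort=True):
        v = grp["mutation_pct"].to_numpy()
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        summ_rows.append(
            {"donor_id": donor, "subset": subset, "n": len(v), "median": med,
             "q1": q1, "q3": q3, "iqr": q3 - q1}
        )
        bin_rows.append(
            {"donor_id": donor, "subset": subset,
             **dict(zip(MUTATION_BIN_LABELS, _bin_fractions(v)))}
        )
    pooled_rows = []
    for subset, grp in per.groupby("subset", sort=True):
        pooled_rows.append(
            {"subset": subset,
             **dict(zip(MUTATION_BIN_LABELS, _bin_fractions(grp["mutation_pct"].to_numpy())))}
        )
    return MutationProfile(
        per_lineage=per,
        summary=pd.DataFrame(summ_rows),
        bins=pd.DataFrame(bin_rows),
        bins_pooled=pd.DataFrame(pooled_rows).set_index("subset"),
    )


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn
# ---------------------------------------------------------------------------

def dunn_posthoc(
    groups: dict[str, np.ndarray], correction: str = "bonferroni"
) -> pd.DataFrame:
    """Dunn's pairwise rank z-tests after a Kruskal-Wallis omnibus.

    All observations are ranked jointly (mid-ranks for ties); for groups i, j

        z = (R_i - R_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))

    with tie correction ``T = sum(t^3 - t)`` over tied value multiplicities.
    Two-sided normal p-values are adjusted over all pairs with the chosen
    correction (``"bonferroni"``, ``"holm"`` or ``"none"``).
    """
    names = sorted(groups)
    all_vals = np.concatenate([np.asarray(groups[g], dtype=float) for g in names])
    n = {g: len(groups[g]) for g in names}
    N = len(all_vals)
    ranks = sps.rankdata(all_vals)
    mean_rank, start = {}, 0
    for g in names:
        mean_rank[g] = ranks[start:start + n[g]].mean()
        start += n[g]
    _, t_counts = np.unique(all_vals, return_counts=True)
    tie_term = np.sum(t_counts**3 - t_counts) / (12.0 * (N - 1)) if N > 1 else 0.0
    base_var = N * (N + 1) / 12.0 - tie_term

    rows = []
    for a, b in combinations(names, 2):
        se = np.sqrt(base_var * (1.0 / n[a] + 1.0 / n[b]))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "p": p})
    out = pd.DataFrame(rows)
    if correction == "bonferroni":
        out["p_adj"] = np.minimum(out["p"] * len(out), 1.0)
    elif correction == "holm":
        out["p_adj"] = multipletests(out["p"], method="holm")[1]
    elif correction == "none":
        out["p_adj"] = out["p"]
    else:
        raise ParameterError(f"unknown correction {correction!r}")
    return out


def _kw_dunn(values: pd.Series, labels: pd.Series, correction: str):
    groups = {g: values[labels == g].to_numpy(dtype=float) for g in sorted(labels.unique())}
    groups = {g: v for g, v in groups.items() if len(v) >= 2}
    if len(groups) < 2:
        raise ParameterError("need at least 2 groups with >= 2 observations each")
    arrays = list(groups.values())
    if np.ptp(np.concatenate(arrays)) == 0:
        # every observation identical: no evidence against the null
        omnibus_p = 1.0
    else:
        try:
            _, omnibus_p = sps.kruskal(*arrays)
        except ValueError:  # all values identical within scipy's tie check
            omnibus_p = 1.0
    pairwise = dunn_posthoc(groups, correction=correction)
    return omnibus_p, pairwise


def compare_mutation(
    lineages: pd.DataFrame, correction: str = "bonferroni"
) -> tuple[float, pd.DataFrame]:
    """Kruskal-Wallis across subsets on lineage mutation %, plus Dunn pairs."""
    mut = mutation_percent(lineages)
    return _kw_dunn(mut, lineages["subset"], correction)


def cdr3_length_compare(
    lineages: pd.DataFrame, correction: str = "bonferroni"
) -> tuple[float, pd.DataFrame, pd.DataFrame]:
    """CDR3 amino-acid length distributions per subset with KW/Dunn tests.

    Returns (omnibus p, pairwise Dunn frame, per-subset length summary).
    """
    lengths = lineages["cdr3_aa"].str.len().astype(float)
    omnibus_p, pairwise = _kw_dunn(lengths, lineages["subset"], correction)
    summary = (
        pd.DataFrame({"subset": lineages["subset"], "length": lengths})
        .groupby("subset")["length"]
        .agg(n="size", median="median",
             q1=lambda v: np.percentile(v, 25), q3=lambda v: np.percentile(v, 75))
        .reset_index()
    )
    return omnibus_p, pairwise, summary
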