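"""Lineage construction, clonotype assignment and cross-subset sharing.

A *lineage* is the unit B-cell clone: rearrangements with identical grouping
key (full V(D)J nucleotide sequence when available, else exact
``(v_call, j_call, cdr3_nt)``) are pooled, their supporting reads summed, and
only clusters meeting the read-count threshold (default 5) are retained.  Each
retained lineage gets a relative frequency: its reads divided by the total
reads over retained lineages of the same (donor, subset, locus).

A *clonotype* is an equivalence class of lineages sharing the same IGHV and
IGHJ gene and (near-)identical heavy-chain CDR3 nucleotide sequence.  At the
default 100% identity this is an exact key; below 100% it is single-linkage
clustering by Hamming identity within (V, J, CDR3-length) blocks —
sequences of unequal length are never merged.

The *sharing matrix* tabulates clonotypes by their exact subset-occupancy
pattern (which sorted subsets the clonotype was observed in), with per-subset
totals, unique/shared splits, and percentages of each subset's clonotype
total, reported half-up-rounded to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .errors import EmptyInputError, ParameterError
from .io import SUBSETS

__all__ = [
    "build_lineages",
    "assign_clonotypes",
    "sharing_matrix",
    "sharing_by_donor",
    "SharingMatrix",
]

# Annotation columns copied from the representative rearrangement of a lineage.
_CARRY = [
    "v_call",
    "v_family",
    "d_call",
    "j_call",
    "cdr3_nt",
    "cdr3_aa",
    "v_identity_pct",
    "vj_germline_identity_pct",
    "n1_len",
    "n2_len",
    "p3v_len",
    "p5d_len",
    "p3d_len",
    "p5j_len",
]


def build_lineages(
    records: pd.DataFrame,
    min_reads: int = 5,
    *,
    sequence_column: str | None = None,
) -> pd.DataFrame:
    """Group rearrangements into lineages and apply the read-count threshold.

    Parameters
    ----------
    records
        Canonical rearrangement frame (see :mod:`bcrep.io`).
    min_reads
        Minimum total supporting reads for a cluster to count as a lineage
        (``read_count >= min_reads``).
    sequence_column
        Optional column holding the full V(D)J nucleotide sequence; when
        present (or a ``sequence`` column exists) it is the grouping key,
        otherwise exact ``(v_call, j_call, cdr3_nt)`` is used.

    Returns
    -------
    pandas.DataFrame
        One row per retained lineage with ``lineage_id``, ``read_count`` and
        ``relative_frequency`` plus the representative's annotations.
        Relative frequencies sum to 1 within each (donor, subset, locus).
    """
    if min_reads < 1:
        raise ParameterError("min_reads must be >= 1")
    if sequence_column is None and "sequence" in records.columns:
        sequence_column = "sequence"
    if sequence_column is not None:
        ident = [sequence_column]
    else:
        ident = ["v_call", "j_call", "cdr3_nt"]
    keycols = ["donor_id", "subset", "locus"] + ident

    rows = []
    for key, grp in records.groupby(keycols, sort=True):
        total = int(grp["duplicate_count"].sum())
        if total < min_reads:
            continue
        rep = grp.sort_values(
            ["duplicate_count", "sequence_id"], ascending=[False, True]
        ).iloc[0]
        row = {
            "donor_id": rep["donor_id"],
            "subset": rep["subset"],
            "locus": rep["locus"],
            "read_count": total,
        }
        for c in _CARRY:
            if c in grp.columns:
                row[c] = rep[c]
        rows.append(row)

    lineages = pd.DataFrame(rows)
    if lineages.empty:
        return pd.DataFrame(
            columns=["lineage_id", "donor_id", "subset", "locus", "read_count",
                     "relative_frequency"] + _CARRY
        )
    lineages = lineages.reset_index(drop=True)
    lineages.insert(0, "lineage_id", [f"L{i:06d}" for i in range(len(lineages))])
    totals = lineages.groupby(["donor_id", "subset", "locus"])["read_count"].transform("sum")
    lineages["relative_frequency"] = lineages["read_count"] / totals
    return lineages


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            # keep the smaller root for determinism
            if rj < ri:
                ri, rj = rj, ri
            self.parent[rj] = ri


def _hamming_identity(a: str, b: str) -> float:
    # callers guarantee equal length
    return sum(x == y for x, y in zip(a, b)) / len(a)


def assign_clonotypes(
    lineages: pd.DataFrame, identity_threshold: float = 1.0
) -> pd.DataFrame:
    """Group lineages into clonotypes by V gene, J gene and CDR3 identity.

    At ``identity_threshold == 1.0`` clonotypes are exact
    ``(v_call, j_call, cdr3_nt)`` keys.  Below 1.0, lineages within one
    ``(v_call, j_call, len(cdr3_nt))`` block are merged by single linkage
    whenever their Hamming identity is at least the threshold; unequal CDR3
    lengths never merge.

    Returns
    -------
    pandas.DataFrame
        One row per clonotype: ``clonotype_id``, key fields, ``members``
        (tuple of lineage ids), ``n_lineages``, ``subsets`` and ``donors``
        (frozen occupancy sets).  Ids are deterministic (sorted by key).
    """
    if not (0 < identity_threshold <= 1.0):
        raise ParameterError("identity_threshold must be in (0, 1]")
    if lineages.empty:
        return pd.DataFrame(
            columns=["clonotype_id", "v_call", "j_call", "cdr3_nt", "members",
                     "n_lineages", "subsets", "donors"]
        )
    if lineages["locus"].nunique() > 1:
        raise ParameterError("lineages must come from a single locus")

    df = lineages.sort_values(["v_call", "j_call", "cdr3_nt", "lineage_id"])
    clusters: list[pd.DataFrame] = []
    if identity_threshold == 1.0:
        for _, grp in df.groupby(["v_call", "j_call", "cdr3_nt"], sort=True):
            clusters.append(grp)
    else:
        df = df.assign(_len=df["cdr3_nt"].str.len())
        for _, block in df.groupby(["v_call", "j_call", "_len"], sort=True):
            seqs = block["cdr3_nt"].tolist()
            uf = _UnionFind(len(seqs))
            for i in range(len(seqs)):
                for j in range(i + 1, len(seqs)):
                    if _hamming_identity(seqs[i], seqs[j]) >= identity_threshold:
                        uf.union(i, j)
            roots: dict[int, list[int]] = {}
            for i in range(len(seqs)):
                roots.setdefault(uf.find(i), []).append(i)
            for r in sorted(roots):
                clusters.append(block.iloc[roots[r]])

    rows = []
    for grp in clusters:
        rep = grp.iloc[0]
        rows.append(
            {
                "v_call": rep["v_call"],
                "j_call": rep["j_call"],
                "cdr3_nt": min(grp["cdr3_nt"]),
                "members": tuple(sorted(grp["lineage_id"])),
                "n_lineages": len(grp),
                "subsets": frozenset(grp["subset"]),
                "donors": frozenset(grp["donor_id"]),
            }
        )
    out = pd.DataFrame(rows).sort_values(["v_call", "j_call", "cdr3_nt"]).reset_index(drop=True)
    out.insert(0, "clonotype_id", [f"C{i:06d}" for i in range(len(out))])
    return out


def _round2(x: float) -> float:
    """Half-up rounding to 2 decimals (1/2776*100 -> 0.04)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class SharingMatrix:
    """Clonotype counts by exact subset-occupancy pattern, with totals.

    ``pattern_counts`` maps each multi-subset occupancy pattern (size >= 2) to
    its clonotype count; singleton patterns are accumulated in
    ``unique_counts``.  ``totals[s]`` counts every clonotype observed in
    subset ``s`` (so a clonotype occupying k subsets contributes to k totals).
    ``shared_total`` is the sum of per-subset shared counts — the bookkeeping
    used in the published table, where one clonotype occupying k subsets is
    counted k times; ``n_shared_clonotypes`` counts distinct shared
    clonotypes once.
    """

    subsets: tuple[str, ...]
    pattern_counts: dict[frozenset, int]
    unique_counts: dict[str, int]

    totals: dict[str, int] = field(init=False)
    shared_counts: dict[str, int] = field(init=False)

    def __post_init__(self):
        self.shared_counts = {
            s: sum(c for p, c in self.pattern_counts.items() if s in p) for s in self.subsets
        }
        self.totals = {
            s: self.unique_counts.get(s, 0) + self.shared_counts[s] for s in self.subsets
        }

    @property
    def shared_total(self) -> int:
        return sum(self.shared_counts.values())

    @property
    def n_shared_clonotypes(self) -> int:
        return sum(self.pattern_counts.values())

    @property
    def unique_total(self) -> int:
        return sum(self.unique_counts.values())

    @property
    def grand_total(self) -> int:
        return sum(self.totals.values())

    def percentage(self, pattern, subset: str) -> float:
        """Pattern count as a percent of ``subset``'s clonotype total.

        Undefined (NaN) when the subset's total is zero or the subset is not
        in the pattern.
        """
        pattern = frozenset(pattern)
        if subset not in pattern:
            return float("nan")
        total = self.totals.get(subset, 0)
        if total == 0:
            return float("nan")
        return _round2(100.0 * self.pattern_counts.get(pattern, 0) / total)

    def shared_percentage(self, subset: str) -> float:
        total = self.totals.get(subset, 0)
        if total == 0:
            return float("nan")
        return _round2(100.0 * self.shared_counts[subset] / total)

    def unique_percentage(self, subset: str) -> float:
        total = self.totals.get(subset, 0)
        if total == 0:
            return float("nan")
        return _round2(100.0 * self.unique_counts.get(subset, 0) / total)

    def to_frame(self) -> pd.DataFrame:
        """Published-table layout: one row per pattern plus summary rows."""
        rows = []
        for pattern in sorted(self.pattern_counts, key=lambda p: sorted(p)):
            row = {
                "group": "+".join(s for s in self.subsets if s in pattern),
                "n_clonotypes": self.pattern_counts[pattern],
            }
            for s in self.subsets:
                row[f"pct_{s}"] = self.percentage(pattern, s)
            rows.append(row)
        shared = {"group": "total_shared", "n_clonotypes": self.shared_total}
        unique = {"group": "total_unique", "n_clonotypes": self.unique_total}
        total = {"group": "total", "n_clonotypes": self.grand_total}
        for s in self.subsets:
            shared[f"pct_{s}"] = self.shared_percentage(s)
            unique[f"pct_{s}"] = self.unique_percentage(s)
            total[f"pct_{s}"] = self.totals[s]
        rows += [shared, unique, total]
        return pd.DataFrame(rows)

    @staticmethod
    def sum(matrices: list["SharingMatrix"]) -> "SharingMatrix":
        """Element-wise sum of pattern and unique counts (same subset order)."""
        if not matrices:
            raise EmptyInputError("no matrices to sum")
        subsets = matrices[0].subsets
        patt: dict[frozenset, int] = {}
        uniq: dict[str, int] = {}
        for m in matrices:
            if m.subsets != subsets:
                raise ParameterError("subset orders differ between matrices")
            for p, c in m.pattern_counts.items():
                patt[p] = patt.get(p, 0) + c
            for s, c in m.unique_counts.items():
                uniq[s] = uniq.get(s, 0) + c
        return SharingMatrix(subsets, patt, uniq)


def sharing_matrix(
    clonotypes: pd.DataFrame, subsets: tuple[str, ...] = SUBSETS
) -> SharingMatrix:
    """Tabulate clonotypes by exact subset-occupancy pattern.

    ``clonotypes`` needs a ``subsets`` column of set-like occupancies, each a
    subset of ``subsets``.  Clonotypes occupying exactly one subset are
    counted as unique; patterns of size >= 2 are the shared patterns.
    """
    if clonotypes is None or len(clonotypes) == 0:
        raise EmptyInputError("no clonotypes")
    allowed = set(subsets)
    patt: dict[frozenset, int] = {}
    uniq: dict[str, int] = {}
    for occ in clonotypes["subsets"]:
        occ = frozenset(occ)
        if not occ <= allowed:
            raise ParameterError(f"occupancy {set(occ)} outside subset list")
        if len(occ) == 1:
            (s,) = occ
            uniq[s] = uniq.get(s, 0) + 1
        else:
            patt[occ] = patt.get(occ, 0) + 1
    return SharingMatrix(tuple(subsets), patt, uniq)


def sharing_by_donor(
    lineages: pd.DataFrame,
    subsets: tuple[str, ...] = SUBSETS,
    *,
    identity_threshold: float = 1.0,
    pooling: str = "within",
) -> tuple[dict[str, SharingMatrix], SharingMatrix]:
    """Per-donor sharing matrices plus a pooled matrix.

    ``pooling="within"`` (default) evaluates clonotype sharing inside each
    donor and sums pattern counts across donors — a shared clonotype must
    co-occur in one donor.  ``pooling="cross"`` pools all donors' lineages
    before clonotyping, so clonotypes may bridge donors.
    """
    if pooling not in ("within", "cross"):
        raise ParameterError("pooling must be 'within' or 'cross'")
    per_donor: dict[str, SharingMatrix] = {}
    for donor, grp in lineages.groupby("donor_id", sort=True):
        clons = assign_clonotypes(grp, identity_threshold)
        per_donor[donor] = sharing_matrix(clons, subsets)
    if pooling == "within":
        pooled = SharingMatrix.sum(list(per_donor.values()))
    else:
        pooled = sharing_matrix(assign_clonotypes(lineages, identity_threshold), subsets)
    return per_donor, pooled
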