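"""Integrated MFI phenotype metric, normalization, clustering and tests.

iMFI (integrated mean fluorescence intensity) summarises a flow-cytometry
marker on a cell subset as *percent positive x MFI*, combining how many cells
express the marker with how brightly.  For cross-marker display the metric is
normalized per marker over the five sorted subsets: raw values are square-root
transformed, then each transformed value is multiplied by five and divided by
the mean of the transformed values across the five subsets — so every
marker's normalized values average exactly 5, and the normalization is
invariant to rescaling a marker's iMFIs by any positive constant.

Subset relationships are summarised by agglomerative clustering of per-subset
normalized-iMFI vectors over the discriminating markers (Euclidean distance,
average linkage by default; both configurable), exported as a newick tree.
Marker-wise comparisons use Kruskal-Wallis across subsets and the paired
Wilcoxon signed-rank test across donors.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy

from .errors import EmptyInputError, ParameterError
from .io import SUBSETS

logger = logging.getLogger("bcrep")

__all__ = [
    "compute_imfi",
    "add_imfi",
    "normalize_imfi",
    "cluster_subsets",
    "compare_markers",
]


def compute_imfi(percent_positive, mfi):
    """iMFI = percent positive x MFI (elementwise; scalars or arrays)."""
    pp = np.asarray(percent_positive, dtype=float)
    m = np.asarray(mfi, dtype=float)
    if np.any(pp < 0) or np.any(pp > 100):
        raise ParameterError("percent_positive must lie in [0, 100]")
    if np.any(m < 0):
        raise ParameterError("mfi must be non-negative")
    out = pp * m
    return float(out) if out.ndim == 0 else out


def add_imfi(panel: pd.DataFrame) -> pd.DataFrame:
    """Append an ``imfi`` column to a long panel (donor, subset, marker rows)."""
    out = panel.copy()
    out["imfi"] = compute_imfi(out["percent_positive"], out["mfi"])
    return out


def normalize_imfi(
    panel: pd.DataFrame,
    *,
    subsets: tuple[str, ...] = SUBSETS,
    median_first: bool = True,
) -> pd.DataFrame:
    """Five-subset square-root normalization of iMFI, per marker.

    With ``median_first`` (default), per-(subset, marker) median iMFI over
    donors is normalized; otherwise normalization is applied per donor.  For
    marker m and subset s:

        norm = 5 * sqrt(imfi[m, s]) / mean_over_subsets(sqrt(imfi[m, .]))

    All five subsets must be present per marker.  A marker whose iMFI is zero
    in every subset has an undefined normalization and is reported missing
    (NaN), not zero.

    Returns a frame with columns marker, subset (and donor unless
    ``median_first``), imfi, norm_imfi.
    """
    panel = panel if "imfi" in panel.columns else add_imfi(panel)
    if median_first:
        base = (
            panel.groupby(["marker", "subset"], sort=True)["imfi"].median().reset_index()
        )
        group_cols = ["marker"]
    else:
        base = panel[["donor", "marker", "subset", "imfi"]].copy()
        group_cols = ["donor", "marker"]

    out_rows = []
    for key, grp in base.groupby(group_cols, sort=True):
        present = set(grp["subset"])
        if not set(subsets) <= present:
            missing = set(subsets) - present
            raise ParameterError(f"marker group {key} lacks subset(s) {sorted(missing)}")
        grp = grp[grp["subset"].isin(subsets)].copy()
        root = np.sqrt(grp["imfi"].to_numpy(dtype=float))
        mean_root = root.mean()
        if mean_root == 0:
            logger.warning("marker group %s has all-zero iMFI; normalization undefined", key)
            grp["norm_imfi"] = np.nan
        else:
            grp["norm_imfi"] = 5.0 * root / mean_root
        out_rows.append(grp)
    return pd.concat(out_rows, ignore_index=True)


def _to_newick(node, labels) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _to_newick(node.get_left(), labels)
    right = _to_newick(node.get_right(), labels)
    dl = node.dist - node.get_left().dist
    dr = node.dist - node.get_right().dist
    return f"({left}:{dl:.6g},{right}:{dr:.6g})"


def cluster_subsets(
    norm_panel: pd.DataFrame,
    *,
    subsets: tuple[str, ...] = SUBSETS,
    metric: str = "euclidean",
    linkage: str = "average",
) -> tuple[np.ndarray, str, pd.DataFrame]:
    """Agglomerative clustering of subsets on normalized iMFI vectors.

    ``norm_panel`` must carry marker, subset and norm_imfi columns (medians
    over donors are taken if a donor column is present).  Returns the scipy
    linkage matrix, a newick string over subset labels, and the subsets x
    markers value matrix used.  Output is independent of marker order and of
    subset input order (rows and columns are sorted internally).
    """
    df = norm_panel
    if "donor" in df.columns:
        df = df.groupby(["marker", "subset"], sort=True)["norm_imfi"].median().reset_index()
    mat = df.pivot(index="subset", columns="marker", values="norm_imfi")
    mat = mat.loc[[s for s in subsets if s in mat.index]].sort_index(axis=1)
    if mat.shape[0] < 2:
        raise ParameterError("need at least two subsets to cluster")
    if mat.shape[1] < 2:
        raise ParameterError("need at least two markers to cluster")
    Z = hierarchy.linkage(mat.to_numpy(dtype=float), method=linkage, metric=metric)
    tree = hierarchy.to_tree(Z)
    newick = _to_newick(tree, list(mat.index)) + ";"
    return Z, newick, mat


def compare_markers(
    panel: pd.DataFrame,
    subset_a: str,
    subset_b: str,
    *,
    zero_method: str = "wilcox",
) -> pd.DataFrame:
    """Per-marker Kruskal-Wallis omnibus and paired Wilcoxon signed-rank.

    Kruskal-Wallis runs on iMFI across all subsets present; the Wilcoxon test
    pairs donors between ``subset_a`` and ``subset_b``.  Zero differences are
    dropped by default (Wilcoxon's convention); ``zero_method="pratt"``
    includes them.  Fewer than 5 donor pairs triggers a warning (exact-test
    power is limited) but the test still runs.
    """
    panel = panel if "imfi" in panel.columns else add_imfi(panel)
    rows = []
    for marker, grp in panel.groupby("marker", sort=True):
        groups = [g["imfi"].to_numpy(dtype=float) for _, g in grp.groupby("subset")]
        if len(groups) >= 2 and np.ptp(np.concatenate(groups)) > 0:
            _, kw_p = sps.kruskal(*groups)
        else:
            kw_p = 1.0
        a = grp[grp["subset"] == subset_a].set_index("donor")["imfi"]
        b = grp[grp["subset"] == subset_b].set_index("donor")["imfi"]
        donors = sorted(set(a.index) & set(b.index))
        diffs = a.loc[donors].to_numpy(dtype=float) - b.loc[donors].to_numpy(dtype=float)
        if len(donors) < 5:
            warnings.warn(
                f"marker {marker}: only {len(donors)} donor pairs; exact test power limited",
                stacklevel=2,
            )
        if np.all(diffs == 0):
            wil_p = 1.0
        else:
            _, wil_p = sps.wilcoxon(diffs, zero_method=zero_method, alternative="two-sided")
        rows.append(
            {"marker": marker, "n_pairs": len(donors), "kruskal_p": kw_p, "wilcoxon_p": wil_p}
        )
    return pd.DataFrame(rows)
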