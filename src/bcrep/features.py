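"""HCDR3 property feature matrix, PCA embedding and physicochemical scales.

The feature matrix carries, per lineage, the nine junction descriptors used to
compare subsets: CDR3 amino-acid length, lineage relative frequency, the
non-templated N1/N2 insertion lengths, the four palindromic P-segment lengths
(P3'V, P5'D, P3'D, P5'J) and the percent germline identity of IGHV-IGHJ.
Features are z-standardised (zero mean, unit SD) before embedding because
their units are incommensurate (aa, nt, %, frequency) — i.e. the PCA is run
on the correlation form.

Physicochemical properties of CDR3 peptides are computed from published
scales: Kyte-Doolittle hydropathy (GRAVY), net charge and isoelectric point
from the Lehninger pKa set via Henderson-Hasselbalch, and Ikai's aliphatic
index.  The scale tables are module-level constants and can be swapped by the
caller.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import DegenerateInputError, ParameterError

logger = logging.getLogger("bcrep")

__all__ = [
    "FEATURE_COLUMNS",
    "build_feature_matrix",
    "pca_embed",
    "Embedding",
    "physicochemical",
    "KYTE_DOOLITTLE",
    "LEHNINGER_PKA",
]

#: The nine junction descriptors, in feature-matrix column order.
FEATURE_COLUMNS: tuple[str, ...] = (
    "hcdr3_length",
    "relative_frequency",
    "n1_len",
    "n2_len",
    "p3v_len",
    "p5d_len",
    "p3d_len",
    "p5j_len",
    "vj_germline_identity_pct",
)

_META_COLUMNS = ("lineage_id", "donor_id", "subset")


def build_feature_matrix(lineages: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble and z-standardise the 9-feature matrix, one row per lineage.

    Returns ``(X, meta)``: ``X`` has standardized feature columns (population
    SD, ddof=0); ``meta`` carries lineage/donor/subset labels row-aligned with
    ``X`` (labels are never features).  Constant features are dropped with a
    warning; an all-constant matrix raises :class:`DegenerateInputError`.
    """
    feats = pd.DataFrame(
        {
            "hcdr3_length": lineages["cdr3_aa"].str.len().astype(float),
            "relative_frequency": lineages["relative_frequency"].astype(float),
            "n1_len": lineages["n1_len"].astype(float),
            "n2_len": lineages["n2_len"].astype(float),
            "p3v_len": lineages["p3v_len"].astype(float),
            "p5d_len": lineages["p5d_len"].astype(float),
            "p3d_len": lineages["p3d_len"].astype(float),
            "p5j_len": lineages["p5j_len"].astype(float),
            "vj_germline_identity_pct": lineages["vj_germline_identity_pct"].astype(float),
        }
    )
    if feats.isna().any().any():
        raise ParameterError("feature matrix has missing values; impute or drop first")
    sd = feats.std(ddof=0)
    constant = sd[sd == 0].index.tolist()
    if len(constant) == len(feats.columns):
        raise DegenerateInputError("all features are constant; nothing to embed")
    if constant:
        logger.warning("dropping constant feature(s): %s", ", ".join(constant))
        feats = feats.drop(columns=constant)
        sd = sd.drop(index=constant)
    X = (feats - feats.mean()) / sd
    meta = lineages.loc[:, [c for c in _META_COLUMNS if c in lineages.columns]].reset_index(
        drop=True
    )
    return X.reset_index(drop=True), meta


@dataclass
class Embedding:
    """PCA result: per-row component scores, loadings and variance fractions."""

    scores: pd.DataFrame                 # rows x components (PC1, PC2, ...)
    loadings: pd.DataFrame               # features x components
    explained_variance_ratio: np.ndarray


def pca_embed(X: pd.DataFrame, n_components: int = 2) -> Embedding:
    """Embed a standardized matrix with PCA.

    Components are ordered by decreasing explained variance with a
    deterministic sign convention: each component is flipped, if needed, so
    its largest-magnitude loading is positive.
    """
    if n_components > X.shape[1]:
        raise ParameterError(
            f"n_components={n_components} exceeds feature count {X.shape[1]}"
        )
    if X.shape[0] < n_components:
        raise ParameterError("need at least as many rows as components")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X.to_numpy(dtype=float))
    comps = pca.components_  # components x features
    for k in range(comps.shape[0]):
        j = int(np.argmax(np.abs(comps[k])))
        if comps[k, j] < 0:
            comps[k] *= -1.0
            scores[:, k] *= -1.0
    names = [f"PC{i + 1}" for i in range(n_components)]
    return Embedding(
        scores=pd.DataFrame(scores, columns=names),
        loadings=pd.DataFrame(comps.T, index=X.columns, columns=names),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
    )


# ---------------------------------------------------------------------------
# physicochemical scales
# ---------------------------------------------------------------------------

#: Kyte & Doolittle hydropathy values (per residue; GRAVY = mean over length).
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Lehninger pKa set: side chains plus termini, with charge sign.
LEHNINGER_PKA: dict[str, tuple[float, int]] = {
    # residue/terminus: (pKa, +1 basic / -1 acidic)
    "Nterm": (9.69, +1),
    "Cterm": (2.34, -1),
    "K": (10.53, +1),
    "R": (12.48, +1),
    "H": (6.00, +1),
    "D": (3.65, -1),
    "E": (4.25, -1),
    "C": (8.33, -1),
    "Y": (10.07, -1),
}

# Ikai aliphatic index side-chain weights (mole-percent coefficients).
_ALIPHATIC_WEIGHTS = {"A": 1.0, "V": 2.9, "I": 3.9, "L": 3.9}

_STANDARD_AA = set(KYTE_DOOLITTLE)


def _net_charge(seq: str, ph: float) -> float:
    charge = 0.0
    for site, (pka, sign) in LEHNINGER_PKA.items():
        if site == "Nterm":
            n = 1
        elif site == "Cterm":
            n = 1
        else:
            n = seq.count(site)
        if n == 0:
            continue
        if sign > 0:
            charge += n / (1.0 + 10.0 ** (ph - pka))
        else:
            charge -= n / (1.0 + 10.0 ** (pka - ph))
    return charge


def _isoelectric_point(seq: str, tol: float = 1e-6) -> float:
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _net_charge(seq, mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def physicochemical(sequences) -> pd.DataFrame:
    """Per-sequence CDR3 peptide properties.

    Columns: ``length``, ``charge_ph7`` (Lehninger pKa, Henderson-
    Hasselbalch), ``hydropathy`` (mean Kyte-Doolittle, GRAVY), ``pi``
    (isoelectric point by bisection of the charge curve) and
    ``aliphatic_index`` (Ikai; mole-percent weighted A/V/I/L).  Sequences with
    non-standard residues are flagged ``invalid`` and their properties set to
    missing.
    """
    rows = []
    for seq in sequences:
        s = str(seq).upper()
        if not s or any(ch not in _STANDARD_AA for ch in s):
            rows.append(
                {"sequence": s, "invalid": True, "length": len(s),
                 "charge_ph7": np.nan, "hydropathy": np.nan, "pi": np.nan,
                 "aliphatic_index": np.nan}
            )
            continue
        L = len(s)
        mole_pct = {aa: 100.0 * s.count(aa) / L for aa in _ALIPHATIC_WEIGHTS}
        rows.append(
            {
                "sequence": s,
                "invalid": False,
                "length": L,
                "charge_ph7": _net_charge(s, 7.0),
                "hydropathy": sum(KYTE_DOOLITTLE[ch] for ch in s) / L,
                "pi": _isoelectric_point(s),
                "aliphatic_index": sum(
                    w * mole_pct[aa] for aa, w in _ALIPHATIC_WEIGHTS.items()
                ),
            }
        )
    return pd.DataFrame(rows)
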