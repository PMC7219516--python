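"""Reading, validating, filtering and writing annotated rearrangement tables.

The pipeline's single entry point for sequence data.  Tables are tab-separated
with one row per annotated V(D)J rearrangement and are held in memory as
:class:`pandas.DataFrame` objects with a canonical column set
(:data:`CANONICAL_COLUMNS`).  Two column-name schemas are shipped: ``"airr"``
(AIRR Rearrangement community standard, the native dialect) and ``"imgt"``
(IMGT/HighV-QUEST summary-style headers).  Arbitrary mappings from canonical
names to file column names are also accepted.

Gene calls are normalised on read: allele suffixes (``*01``) are stripped so
calls are gene-level (``IGHV3-7``), and ``v_family`` is derived by truncating
the V call at the first hyphen (``IGHV3``).  When a schema supplies an IMGT
``junction`` (which includes the conserved flanking C-104 and W/F-118 codons)
rather than a CDR3, the flanking codons are trimmed by default;
``junction_inclusive=True`` keeps them.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import EmptyInputError, SchemaError

logger = logging.getLogger("bcrep")

#: Closed vocabulary of sorted B-cell subset labels.
SUBSETS: tuple[str, ...] = ("naive", "IgM_lo", "IgM_hi", "IgM_only", "switched")

#: Supported immunoglobulin loci (heavy chain and kappa light chain).
LOCI: tuple[str, ...] = ("IGH", "IGK")

#: Canonical in-memory column order for rearrangement tables.
CANONICAL_COLUMNS: tuple[str, ...] = (
    "sequence_id",
    "donor_id",
    "subset",
    "locus",
    "v_call",
    "d_call",
    "j_call",
    "v_family",
    "cdr3_nt",
    "cdr3_aa",
    "productive",
    "v_identity_pct",
    "vj_germline_identity_pct",
    "n1_len",
    "n2_len",
    "p3v_len",
    "p5d_len",
    "p3d_len",
    "p5j_len",
    "duplicate_count",
)

# Columns a file must provide (directly or via schema mapping). cdr3_nt may be
# satisfied by a junction column instead.
MANDATORY: tuple[str, ...] = (
    "sequence_id",
    "donor_id",
    "subset",
    "locus",
    "v_call",
    "j_call",
    "cdr3_nt",
    "productive",
    "duplicate_count",
)

_OPTIONAL_DEFAULTS = {
    "d_call": "",
    "cdr3_aa": "",
    "v_identity_pct": np.nan,
    "vj_germline_identity_pct": np.nan,
    "n1_len": 0,
    "n2_len": 0,
    "p3v_len": 0,
    "p5d_len": 0,
    "p3d_len": 0,
    "p5j_len": 0,
}

#: canonical name -> file column name, per named schema preset
SCHEMAS: dict[str, dict[str, str]] = {
    "airr": {
        "sequence_id": "sequence_id",
        "donor_id": "donor_id",
        "subset": "subset",
        "locus": "locus",
        "v_call": "v_call",
        "d_call": "d_call",
        "j_call": "j_call",
        "cdr3_nt": "junction",  # AIRR junction includes conserved codons
        "cdr3_aa": "junction_aa",
        "productive": "productive",
        "v_identity_pct": "v_identity",
        "vj_germline_identity_pct": "vj_identity",
        "n1_len": "n1_length",
        "n2_len": "n2_length",
        "p3v_len": "p3v_length",
        "p5d_len": "p5d_length",
        "p3d_len": "p3d_length",
        "p5j_len": "p5j_length",
        "duplicate_count": "duplicate_count",
    },
    "imgt": {
        "sequence_id": "Sequence ID",
        "donor_id": "donor_id",
        "subset": "subset",
        "locus": "locus",
        "v_call": "V-GENE and allele",
        "d_call": "D-GENE and allele",
        "j_call": "J-GENE and allele",
        "cdr3_nt": "JUNCTION",
        "cdr3_aa": "JUNCTION (AA)",
        "productive": "Functionality",
        "v_identity_pct": "V-REGION identity %",
        "vj_germline_identity_pct": "V-J identity %",
        "n1_len": "N1-REGION-nt nb",
        "n2_len": "N2-REGION-nt nb",
        "p3v_len": "P3'V-nt nb",
        "p5d_len": "P5'D-nt nb",
        "p3d_len": "P3'D-nt nb",
        "p5j_len": "P5'J-nt nb",
        "duplicate_count": "duplicate_count",
    },
}

# Schemas whose cdr3_nt column is an IMGT junction (conserved codons included).
_JUNCTION_SCHEMAS = {"airr", "imgt"}

_TRUE = {"t", "true", "1", "yes", "y", "productive"}
_FALSE = {"f", "false", "0", "no", "n", "unproductive", "non-productive"}


def strip_allele(call: str) -> str:
    """Drop the IMGT allele suffix: ``IGHV3-7*01`` -> ``IGHV3-7``."""
    return str(call).split("*", 1)[0].strip()


def v_family_of(v_call: str) -> str:
    """Family label from a gene-level V call: ``IGHV3-7`` -> ``IGHV3``."""
    return strip_allele(v_call).split("-", 1)[0]


def _coerce_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    # IMGT writes e.g. "productive (see comment)"
    if s.startswith("productive"):
        return True
    if s.startswith("unproductive"):
        return False
    raise ValueError(f"cannot interpret {x!r} as a boolean")


def read_rearrangements(
    path,
    schema: str | Mapping[str, str] = "airr",
    *,
    locus: str | None = None,
    junction_inclusive: bool = False,
) -> pd.DataFrame:
    """Read a tab-separated rearrangement table into canonical form.

    Parameters
    ----------
    path
        TSV file with a header row.
    schema
        Named preset (``"airr"``, ``"imgt"``) or an explicit mapping
        ``{canonical name: file column name}``.
    locus
        If given, keep only rows of this locus (``"IGH"`` or ``"IGK"``).
    junction_inclusive
        Keep the conserved flanking codons when the schema supplies an
        IMGT-style junction.  Default trims 3 nt from each end, yielding
        the CDR3 proper.

    Returns
    -------
    pandas.DataFrame
        One row per sequence, columns :data:`CANONICAL_COLUMNS`.  Rows that
        fail type coercion are dropped and reported (with 1-based data row
        numbers) through the package logger.

    Raises
    ------
    SchemaError
        A mandatory column is missing from the file.
    EmptyInputError
        The file holds no data rows.
    """
    if isinstance(schema, str):
        try:
            mapping = dict(SCHEMAS[schema])
        except KeyError:
            raise SchemaError(f"unknown schema preset {schema!r}") from None
        trim_junction = schema in _JUNCTION_SCHEMAS and not junction_inclusive
    else:
        mapping = dict(schema)
        trim_junction = not junction_inclusive and mapping.get("cdr3_nt", "").lower().startswith(
            "junction"
        )

    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.empty:
        raise EmptyInputError(f"no data rows in {path}")

    for col in MANDATORY:
        file_col = mapping.get(col, col)
        if file_col not in raw.columns:
            raise SchemaError(f"mandatory column {col!r} (file column {file_col!r}) not found")

    out: dict[str, list] = {c: [] for c in CANONICAL_COLUMNS}
    bad_rows: list[tuple[int, str]] = []
    for i, row in enumerate(raw.itertuples(index=False), start=1):
        rowd = dict(zip(raw.columns, row))

        def get(col, default=None):
            file_col = mapping.get(col, col)
            val = rowd.get(file_col, default)
            if val == "" and default is not None:
                return default
            return val

        try:
            cdr3 = str(get("cdr3_nt")).upper().replace(".", "")
            if trim_junction and len(cdr3) > 6:
                cdr3 = cdr3[3:-3]
            cdr3_aa = str(get("cdr3_aa", "")).upper()
            if trim_junction and len(cdr3_aa) > 2:
                cdr3_aa = cdr3_aa[1:-1]
            rec = {
                "sequence_id": str(get("sequence_id")),
                "donor_id": str(get("donor_id")),
                "subset": str(get("subset")),
                "locus": str(get("locus")),
                "v_call": strip_allele(get("v_call")),
                "d_call": strip_allele(get("d_call", "")),
                "j_call": strip_allele(get("j_call")),
                "cdr3_nt": cdr3,
                "cdr3_aa": cdr3_aa,
                "productive": _coerce_bool(get("productive")),
                "v_identity_pct": float(get("v_identity_pct", np.nan)),
                "vj_germline_identity_pct": float(get("vj_germline_identity_pct", np.nan)),
                "n1_len": int(float(get("n1_len", 0))),
                "n2_len": int(float(get("n2_len", 0))),
                "p3v_len": int(float(get("p3v_len", 0))),
                "p5d_len": int(float(get("p5d_len", 0))),
                "p3d_len": int(float(get("p3d_len", 0))),
                "p5j_len": int(float(get("p5j_len", 0))),
                "duplicate_count": int(float(get("duplicate_count"))),
            }
            rec["v_family"] = v_family_of(rec["v_call"])
            if rec["subset"] not in SUBSETS:
                raise ValueError(f"unknown subset {rec['subset']!r}")
            if rec["locus"] not in LOCI:
                raise ValueError(f"unknown locus {rec['locus']!r}")
            if rec["duplicate_count"] < 1:
                raise ValueError("duplicate_count must be >= 1")
        except (ValueError, TypeError) as exc:
            bad_rows.append((i, str(exc)))
            continue
        for c in CANONICAL_COLUMNS:
            out[c].append(rec[c])

    if bad_rows:
        logger.warning(
            "dropped %d malformed row(s): %s",
            len(bad_rows),
            "; ".join(f"row {i}: {msg}" for i, msg in bad_rows[:20]),
        )
    df = pd.DataFrame(out, columns=list(CANONICAL_COLUMNS))
    if df.empty:
        raise EmptyInputError(f"no parseable rows in {path}")
    if locus is not None:
        df = df[df["locus"] == locus].reset_index(drop=True)
    return df


def filter_productive(records: pd.DataFrame) -> pd.DataFrame:
    """Keep productive rearrangements only; log retained/dropped per subset."""
    kept = records[records["productive"].astype(bool)].reset_index(drop=True)
    if "subset" in records.columns:
        for subset, grp in records.groupby("subset"):
            n_keep = int(grp["productive"].astype(bool).sum())
            logger.info(
                "filter_productive %s: retained %d, dropped %d",
                subset,
                n_keep,
                len(grp) - n_keep,
            )
    return kept


def write_report(table: pd.DataFrame, path, *, sep: str = "\t") -> None:
    """Write a tabular result with header; floats at 12 significant digits.

    Re-reading the file reproduces integer values bit-exactly and reals to 12
    significant digits.  Refuses empty tables.
    """
    if table is None or len(table) == 0:
        raise EmptyInputError("refusing to write an empty report")
    table.to_csv(path, sep=sep, index=False, float_format="%.12g")


def read_report(path, *, sep: str = "\t") -> pd.DataFrame:
    """Read back a report written by :func:`write_report`."""
    return pd.read_csv(path, sep=sep)


def records_from_iterable(rows: Iterable[Mapping]) -> pd.DataFrame:
    """Build a canonical rearrangement frame from dict-like records (testing aid)."""
    df = pd.DataFrame(list(rows))
    if "v_family" not in df.columns:
        df["v_family"] = df["v_call"].map(v_family_of)
    for col, default in _OPTIONAL_DEFAULTS.items():
        if col not in df.columns:
            df[col] = default
    return df[list(CANONICAL_COLUMNS)]
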