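"""Readers and writers for the plain-text formats the toolkit exchanges.

Expression matrices are tab-delimited with genes (or probes) on rows and
samples on columns; the first column holds the row identifiers. All tables
round-trip through :class:`pandas.DataFrame`.
"""

from __future__ import annotations

import pandas as pd

RESPONSE_LEVELS = frozenset({"pCR", "RD"})
RECEPTOR_LEVELS = frozenset({"positive", "negative", "unknown"})
STAGE_LEVELS = frozenset({"I", "II", "III", "IV", "unknown"})
GRADE_LEVELS = frozenset({"I", "II", "III", "unknown"})

ANNOTATION_COLUMNS = [
    "sample_id",
    "response",
    "er_status",
    "pr_status",
    "her2_status",
    "stage",
    "grade",
    "age",
    "batch",
]


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


def read_expression_matrix(path, dialect: str = "gene_level") -> pd.DataFrame:
    """Read a gene- or probe-level expression TSV into a genes × samples frame.

    Parameters
    ----------
    path : str or path-like
        TSV whose header row lists sample ids and whose first column holds
        gene ids (``dialect='gene_level'``) or probe ids
        (``dialect='probe_level'``).
    dialect : {'gene_level', 'probe_level'}
        Duplicate row ids are rejected at gene level; probe-level matrices
        may be collapsed later with
        :func:`rpskit.preprocess.collapse_probes`.

    Returns
    -------
    pandas.DataFrame
        Log2 expression values indexed by row id, columns = sample ids.
    """
    if dialect not in ("gene_level", "probe_level"):
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: no data rows") from exc
    if df.shape[0] == 0:
        raise ParseError(f"{path}: no data rows")
    if df.shape[1] == 0:
        raise ParseError(f"{path}: malformed header - no sample columns")
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicated sample ids {dups}")
    non_numeric = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        raise ParseError(
            f"{path}: non-numeric expression values in column(s) {non_numeric}"
        )
    if df.isna().any().any():
        raise ParseError(f"{path}: missing expression values")
    if dialect == "gene_level" and df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicated gene id(s) {dups}")
    df.index = df.index.astype(str)
    df.index.name = "gene_id" if dialect == "gene_level" else "probe_id"
    return df.astype(float)


def read_probe_map(path) -> pd.Series:
    """Read a probe→gene map TSV (columns ``probe_id``, ``gene_id``)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("probe_id", "gene_id"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    if df["probe_id"].duplicated().any():
        dups = df.loc[df["probe_id"].duplicated(), "probe_id"].unique().tolist()
        raise ParseError(f"{path}: probe(s) mapped to more than one gene: {dups}")
    return df.set_index("probe_id")["gene_id"]


def read_annotations(path) -> pd.DataFrame:
    """Read and validate a per-sample clinical annotation TSV.

    Missing categorical values are normalised to the explicit level
    ``'unknown'``; they are never imputed.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing annotation column(s) {missing}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].unique().tolist()
        raise ParseError(f"{path}: duplicated sample id(s) {dups}")
    df = df.set_index("sample_id")
    for col in ("er_status", "pr_status", "her2_status", "stage", "grade"):
        df[col] = df[col].fillna("unknown")
    df["age"] = pd.to_numeric(df["age"], errors="coerce")
    checks = {
        "response": RESPONSE_LEVELS,
        "er_status": RECEPTOR_LEVELS,
        "pr_status": RECEPTOR_LEVELS,
        "her2_status": RECEPTOR_LEVELS,
        "stage": STAGE_LEVELS,
        "grade": GRADE_LEVELS,
    }
    for col, levels in checks.items():
        bad = set(df[col].dropna().unique()) - levels
        if bad:
            raise ParseError(f"{path}: invalid {col} value(s) {sorted(bad)}")
    return df


def read_weight_profiles(path) -> pd.DataFrame:
    """Read a weight-profile TSV (columns ``gene_id,w_plus,w_minus``)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "w_plus", "w_minus"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    df = df.set_index("gene_id")[["w_plus", "w_minus"]].astype(float)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        raise ParseError(f"{path}: duplicated gene ids in weight profile")
    return df


def write_weight_profiles(weights: pd.DataFrame, path) -> None:
    weights.rename_axis("gene_id").reset_index().to_csv(path, sep="\t", index=False)


def write_expression_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.rename_axis(matrix.index.name or "gene_id").to_csv(path, sep="\t")


def read_signature_table(path) -> pd.DataFrame:
    """Read a signature-definition TSV (columns ``name,gene_id,weight``)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("name", "gene_id", "weight"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    df["gene_id"] = df["gene_id"].astype(str)
    df["weight"] = df["weight"].astype(float)
    return df


def read_components_table(path) -> pd.DataFrame:
    """Read a tumor-microenvironment component TSV.

    Expected columns: ``sample_id`` plus one numeric column per component
    (canonically ``immune``, ``stromal``, ``proliferation``). Immune and
    stromal abundances are precomputed upstream (e.g. by ESTIMATE); they are
    consumed, never derived here.
    """
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: missing column 'sample_id'")
    return df.set_index("sample_id").astype(float)
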