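"""Reading, writing and validation of expression tables, labels and models.

Conventions
-----------
Expression files are genes-in-rows (GEO series-matrix orientation): the
first column holds miRNA identifiers, the header row holds sample
identifiers, and cells are log2-scale intensities.  Empty cells and the
tokens ``NA``/``NaN`` (case-insensitive) mark missing values.

Label files are two-column tables (``sample_id``, ``label``) with labels
drawn from the two-class vocabulary ``{"healthy", "sarcoma"}``.

In memory an expression matrix is a :class:`pandas.DataFrame` indexed by
gene identifier with sample identifiers as columns; labels are a
:class:`pandas.Series` indexed by sample identifier.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

HEALTHY = "healthy"
SARCOMA = "sarcoma"
LABEL_VOCABULARY = frozenset({HEALTHY, SARCOMA})

#: Missing-value sentinels accepted in expression files (case-insensitive).
MISSING_TOKENS = ("", "NA", "NaN", "na", "nan", "Na", "nA", "NAN")


class ValidationError(ValueError):
    """An input table violates a structural invariant."""


class ParseError(ValueError):
    """A cell of an input table could not be parsed."""


class ModelFormatError(ValueError):
    """A serialized model file is corrupt or from an incompatible version."""


@dataclass(frozen=True, order=True)
class GenePair:
    """An ordered miRNA pair.

    The pair is a *feature*: its per-sample indicator is 1 when the
    expression of ``gene1`` is strictly smaller than that of ``gene2``,
    so ``(a, b)`` and ``(b, a)`` are different features.
    """

    gene1: str
    gene2: str

    def __post_init__(self) -> None:
        if self.gene1 == self.gene2:
            raise ValidationError(f"gene pair members must differ: {self.gene1!r}")

    @property
    def feature_id(self) -> str:
        return f"{self.gene1}|{self.gene2}"

    @classmethod
    def from_feature_id(cls, feature_id: str) -> "GenePair":
        g1, sep, g2 = feature_id.partition("|")
        if not sep or not g1 or not g2:
            raise ValidationError(f"malformed pair feature id: {feature_id!r}")
        return cls(g1, g2)


#: The six serum miRNA pairs of the published sarcoma classifier panel,
#: in the panel's printed orientation (gene1 is the pair's G1).
PUBLISHED_PANEL: tuple[GenePair, ...] = (
    GenePair("hsa-miR-378c", "hsa-miR-380-5p"),
    GenePair("hsa-miR-378c", "hsa-miR-499b-3p"),
    GenePair("hsa-miR-383-3p", "hsa-miR-571"),
    GenePair("hsa-miR-454-5p", "hsa-miR-571"),
    GenePair("hsa-miR-4740-5p", "hsa-miR-5007-3p"),
    GenePair("hsa-miR-5007-3p", "hsa-miR-518a-3p"),
)

#: Composition of the merged external validation design: three independent
#: sarcoma-subtype serum cohorts pooled with their healthy controls.
EXTERNAL_VALIDATION_DESIGN: dict[str, int] = {
    "synovial_sarcoma": 10,
    "liposarcoma": 6,
    "leiomyosarcoma": 5,
    "healthy": 14,
}


def published_panel() -> tuple[GenePair, ...]:
    """Return the six published classifier pairs (nine distinct miRNAs)."""
    return PUBLISHED_PANEL


def published_panel_genes() -> tuple[str, ...]:
    """Distinct miRNA identifiers of the published panel, in first-seen order."""
    seen: dict[str, None] = {}
    for pair in PUBLISHED_PANEL:
        seen.setdefault(pair.gene1)
        seen.setdefault(pair.gene2)
    return tuple(seen)


def external_design_labels() -> pd.Series:
    """Binary labels of the merged external validation design.

    Sarcoma-subtype counts collapse to ``sarcoma``; sample identifiers are
    synthetic placeholders (``EXT-<group>-<i>``), since only the design —
    not the arrays — is embedded.
    """
    ids: list[str] = []
    labels: list[str] = []
    for group, count in EXTERNAL_VALIDATION_DESIGN.items():
        label = HEALTHY if group == HEALTHY else SARCOMA
        for i in range(1, count + 1):
            ids.append(f"EXT-{group}-{i:02d}")
            labels.append(label)
    return pd.Series(labels, index=pd.Index(ids, name="sample_id"), name="label")


def _infer_sep(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("tsv", "csv"):
            raise ValueError(f"dialect must be 'tsv' or 'csv', got {dialect!r}")
        return "\t" if dialect == "tsv" else ","
    return "," if path.suffix.lower() == ".csv" else "\t"


def _check_unique(values, what: str) -> None:
    seen: set = set()
    for v in values:
        if v in seen:
            raise ValidationError(f"duplicate {what} identifier: {v!r}")
        seen.add(v)


def validate_expression(matrix: pd.DataFrame) -> pd.DataFrame:
    """Validate an in-memory expression matrix and coerce values to float.

    Checks identifier uniqueness and that every non-missing value is finite.
    """
    _check_unique(matrix.index, "gene")
    _check_unique(matrix.columns, "sample")
    values = matrix.to_numpy(dtype=float)
    infinite = np.isinf(values)
    if infinite.any():
        g, s = np.argwhere(infinite)[0]
        raise ValidationError(
            f"non-finite expression value at gene {matrix.index[g]!r}, "
            f"sample {matrix.columns[s]!r}"
        )
    out = pd.DataFrame(values, index=matrix.index.astype(str), columns=matrix.columns.astype(str))
    out.index.name = "miRNA"
    return out


def read_expression(path, dialect: str | None = None, transpose: bool = False) -> pd.DataFrame:
    """Read a genes-by-samples expression table.

    Parameters
    ----------
    path:
        TSV or CSV file; the delimiter is inferred from the suffix unless
        ``dialect`` is given.
    transpose:
        Set when the file is samples-in-rows; the returned frame is always
        genes-by-samples.
    """
    path = Path(path)
    sep = _infer_sep(path, dialect)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    _check_unique(header[1:], "sample")  # pandas would silently mangle duplicates
    numeric = pd.read_csv(
        path, sep=sep, index_col=0,
        na_values=list(MISSING_TOKENS), keep_default_na=False,
        skip_blank_lines=True, float_precision="round_trip",
    )
    if numeric.shape[1] == 0:
        raise ValidationError(f"{path}: no sample columns found")
    for col in numeric.columns:
        if numeric[col].dtype == object:  # at least one unparseable cell
            raw = numeric[col]
            bad = pd.to_numeric(raw, errors="coerce").isna() & raw.notna()
            if bad.any():
                row = bad.idxmax()
                raise ParseError(
                    f"{path}: non-numeric value {raw.loc[row]!r} at "
                    f"row {row!r}, column {col!r}"
                )
            numeric[col] = raw.map(lambda v: np.nan if pd.isna(v) else float(v))
    if transpose:
        numeric = numeric.T
    return validate_expression(numeric)


def write_expression(matrix: pd.DataFrame, path, dialect: str | None = None) -> None:
    """Write a genes-by-samples expression table; missing cells become ``NA``.

    Floats are written with shortest round-trip precision, so
    read ∘ write is bit-exact.
    """
    path = Path(path)
    sep = _infer_sep(path, dialect)
    matrix.to_csv(path, sep=sep, na_rep="NA",
                  float_format=lambda v: repr(float(v)))


def read_labels(path, dialect: str | None = None) -> pd.Series:
    """Read a two-column (sample_id, label) table into a Series."""
    path = Path(path)
    sep = _infer_sep(path, dialect)
    try:
        table = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"{path}: empty label file") from exc
    if table.shape[1] < 2:
        raise ValidationError(f"{path}: expected two columns (sample_id, label)")
    if table.shape[0] == 0:
        raise ValidationError(f"{path}: no samples in label file")
    labels = pd.Series(
        table.iloc[:, 1].to_numpy(),
        index=pd.Index(table.iloc[:, 0].to_numpy(), name="sample_id"),
        name="label",
    )
    return validate_labels(labels)


def validate_labels(labels: pd.Series) -> pd.Series:
    """Validate sample uniqueness and the two-class label vocabulary."""
    _check_unique(labels.index, "sample")
    unknown = sorted(set(labels) - LABEL_VOCABULARY)
    if unknown:
        raise ValidationError(
            f"unknown label token(s) {unknown}; expected one of {sorted(LABEL_VOCABULARY)}"
        )
    if len(labels) == 0:
        raise ValidationError("label table is empty")
    return labels.astype(str)


def write_labels(labels: pd.Series, path, dialect: str | None = None) -> None:
    path = Path(path)
    sep = _infer_sep(path, dialect)
    labels.rename("label").rename_axis("sample_id").to_csv(path, sep=sep)


def save_model(model, path) -> None:
    """Serialize a fitted ensemble to a self-describing JSON document."""
    path = Path(path)
    path.write_text(json.dumps(model.to_dict(), indent=1))


def load_model(path):
    """Load a model saved by :func:`save_model`.

    Raises :class:`ModelFormatError` on truncated, corrupt or
    incompatible files.
    """
    from .rglm import RGLMClassifier  # local import to avoid a cycle

    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ModelFormatError(f"{path}: not a valid model file ({exc})") from exc
    if not isinstance(payload, dict):
        raise ModelFormatError(f"{path}: not a model document")
    return RGLMClassifier.from_dict(payload)
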