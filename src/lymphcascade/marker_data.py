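"""Tri-state immunomarker data model, file I/O, encodings and eligibility filtering.

Immunohistochemistry (IHC) and EBER in-situ-hybridization results are read per
marker as *positive*, *negative* or *unknown* (not stained / not recorded).
This module defines the case-level containers (:class:`CaseRecord`,
:class:`Cohort`), the delimited-text reader/writer, the two numeric encodings
used downstream (paired one-hot for linear/kernel/net models, three-level
categorical codes for tree ensembles), and the availability-based eligibility
filter that restricts each classification task to cases whose minimum required
markers were actually tested.
"""

from __future__ import annotations

import enum
import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MarkerStatus",
    "CaseRecord",
    "Cohort",
    "DesignMatrix",
    "Dialect",
    "DEFAULT_DIALECT",
    "CANONICAL_MARKERS",
    "COHORT_TAGS",
    "normalize_marker",
    "read_cohort",
    "write_cohort",
    "export_vocabulary",
    "encode_onehot",
    "encode_categorical",
    "encode",
    "filter_eligible",
    "MarkerKnown",
    "And",
    "Or",
    "parse_expression",
    "expression_from_dict",
]


class MarkerStatus(enum.Enum):
    """Tri-state marker result."""

    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNKNOWN = "unknown"

    def __repr__(self) -> str:  # compact in error messages
        return f"MarkerStatus.{self.name}"


#: Controlled marker vocabulary: union of the five task candidate panels.
#: EBERs (in situ hybridization) is treated like any IHC marker.
CANONICAL_MARKERS: tuple[str, ...] = (
    "CD15", "CD30", "CD5", "LCA", "CD3", "CD20", "CD79", "EBERs",
    "CD56", "CD4", "CD10", "TIA1", "MUM-1", "GrB", "CD2", "Perf",
    "CD7", "Pax-5", "CD8", "CD21",
    "CyD1", "TdT", "CD23", "Bcl-6", "CD138", "CD38", "CD43", "Ki67",
    "C-myc", "Bcl-2", "ALK",
    "CXCL-13",
)

COHORT_TAGS = ("train", "internal_validation", "temporal_validation",
               "external_validation", "unsplit")

_RESERVED_COLUMNS = ("case_id", "cohort_tag", "subtype_label",
                     "clinical_tested_count")


def _canon_key(name: str) -> str:
    """Folding key: case-insensitive, whitespace and hyphen variants collapse."""
    # U+2010/2011/2212 etc. are frequent in copy-pasted marker names
    name = re.sub(r"[‐‑‒–—−]", "-", name)
    return re.sub(r"[^a-z0-9]", "", name.lower())


_CANON_BY_KEY: dict[str, str] = {_canon_key(m): m for m in CANONICAL_MARKERS}


def normalize_marker(name: str, extra: Iterable[str] = ()) -> str:
    """Map a marker name to its canonical spelling.

    Parameters
    ----------
    name
        Raw marker name (any case, hyphen variant, stray whitespace).
    extra
        User-declared markers beyond the built-in 32-marker vocabulary.

    Raises
    ------
    KeyError
        If the name is not in the vocabulary.
    """
    table = dict(_CANON_BY_KEY)
    for m in extra:
        table.setdefault(_canon_key(m), m)
    key = _canon_key(name)
    if key not in table:
        raise KeyError(
            f"unknown marker {name!r}; known markers: {sorted(table.values())}")
    return table[key]


@dataclass(frozen=True)
class Dialect:
    """Token tables mapping cell text to :class:`MarkerStatus` (case-insensitive)."""

    positive_tokens: tuple[str, ...] = ("+", "pos", "positive", "1")
    negative_tokens: tuple[str, ...] = ("−", "-", "neg", "negative", "0")
    unknown_tokens: tuple[str, ...] = ("", "na", "n/a", "unknown", "?")
    #: tokens used on write (one per status)
    write_positive: str = "positive"
    write_negative: str = "negative"
    write_unknown: str = ""
    delimiter: str = ","

    def parse_status(self, token: str) -> MarkerStatus:
        t = token.strip().lower()
        if t in (s.lower() for s in self.positive_tokens):
            return MarkerStatus.POSITIVE
        if t in (s.lower() for s in self.negative_tokens):
            return MarkerStatus.NEGATIVE
        if t in (s.lower() for s in self.unknown_tokens):
            return MarkerStatus.UNKNOWN
        raise ValueError(f"unrecognized status token {token!r}")

    def format_status(self, status: MarkerStatus) -> str:
        return {MarkerStatus.POSITIVE: self.write_positive,
                MarkerStatus.NEGATIVE: self.write_negative,
                MarkerStatus.UNKNOWN: self.write_unknown}[status]


DEFAULT_DIALECT = Dialect()


@dataclass
class CaseRecord:
    """One patient's tri-state marker map plus labels.

    ``subtype_label`` is the leaf name from the hierarchy vocabulary; it may be
    ``None`` at inference time.  ``clinical_tested_count`` is the number of
    markers actually measured for this case in the clinical setting (used only
    by cost accounting).
    """

    case_id: str
    markers: dict[str, MarkerStatus] = field(default_factory=dict)
    cohort_tag: str = "unsplit"
    subtype_label: str | None = None
    clinical_tested_count: int | None = None

    def __post_init__(self) -> None:
        if self.cohort_tag not in COHORT_TAGS:
            raise ValueError(
                f"cohort_tag {self.cohort_tag!r} not in {COHORT_TAGS}")
        if self.clinical_tested_count is not None and self.clinical_tested_count < 0:
            raise ValueError("clinical_tested_count must be >= 0")

    def status(self, marker: str) -> MarkerStatus:
        return self.markers.get(marker, MarkerStatus.UNKNOWN)

    def known_markers(self) -> set[str]:
        return {m for m, s in self.markers.items() if s is not MarkerStatus.UNKNOWN}


@dataclass
class Cohort:
    """Ordered collection of cases with unique ids."""

    cohort_id: str
    records: list[CaseRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for r in self.records:
            if r.case_id in seen:
                raise ValueError(f"duplicate case_id {r.case_id!r} in cohort "
                                 f"{self.cohort_id!r}")
            seen.add(r.case_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CaseRecord]:
        return iter(self.records)

    def subset(self, records: Sequence[CaseRecord], cohort_id: str | None = None) -> "Cohort":
        return Cohort(cohort_id or self.cohort_id, list(records))

    def labels(self) -> list[str | None]:
        return [r.subtype_label for r in self.records]


@dataclass
class DesignMatrix:
    """Numeric feature matrix aligned to a cohort.

    ``encoding_kind`` is ``"onehot_pair"`` (two columns ``<marker>::pos`` /
    ``<marker>::neg`` per marker; unknown encodes as ``(0, 0)``) or
    ``"categorical3"`` (one column per marker with codes 0=negative,
    1=positive, 2=unknown).
    """

    feature_names: list[str]
    X: np.ndarray
    encoding_kind: str
    case_ids: list[str]

    def __post_init__(self) -> None:
        if self.X.shape != (len(self.case_ids), len(self.feature_names)):
            raise ValueError("matrix shape does not match names/cases")


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _leaf_vocabulary() -> tuple[str, ...]:
    from .task_hierarchy import LEAF_LABELS  # deferred: avoids import cycle
    return LEAF_LABELS


def read_cohort(path: str | Path, dialect: Dialect = DEFAULT_DIALECT, *,
                cohort_id: str | None = None,
                extra_markers: Iterable[str] = (),
                subtype_vocabulary: Iterable[str] | None = None) -> Cohort:
    """Read a delimited-text cohort file.

    The header must declare ``case_id``; ``cohort_tag``, ``subtype_label`` and
    ``clinical_tested_count`` are optional; every other column is a marker.
    Blank or missing marker cells become :attr:`MarkerStatus.UNKNOWN`.

    Raises
    ------
    ValueError
        On a duplicate ``case_id``, an unrecognized status token (the error
        names the row and column), or a subtype label outside the leaf
        vocabulary (the error lists the vocabulary).
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else dialect.delimiter
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if "case_id" not in df.columns:
        raise ValueError(f"{path}: header must declare a case_id column")
    vocab = tuple(subtype_vocabulary) if subtype_vocabulary is not None \
        else _leaf_vocabulary()
    marker_cols = [c for c in df.columns if c not in _RESERVED_COLUMNS]
    canon = {c: normalize_marker(c, extra=extra_markers) for c in marker_cols}

    records: list[CaseRecord] = []
    for i, row in enumerate(df.to_dict(orient="records"), start=2):  # 1 = header
        markers: dict[str, MarkerStatus] = {}
        for col in marker_cols:
            try:
                markers[canon[col]] = dialect.parse_status(str(row[col]))
            except ValueError as exc:
                raise ValueError(f"{path}: line {i}, column {col!r}: {exc}") from exc
        label = str(row.get("subtype_label", "")).strip() or None
        if label is not None and label not in vocab:
            raise ValueError(
                f"{path}: line {i}: unknown subtype label {label!r}; "
                f"vocabulary: {sorted(vocab)}")
        count_raw = str(row.get("clinical_tested_count", "")).strip()
        count = int(float(count_raw)) if count_raw else None
        tag = str(row.get("cohort_tag", "")).strip() or "unsplit"
        records.append(CaseRecord(
            case_id=str(row["case_id"]),
            markers=markers,
            cohort_tag=tag,
            subtype_label=label,
            clinical_tested_count=count,
        ))
    # Cohort.__post_init__ enforces id uniqueness; re-raise with file context
    try:
        return Cohort(cohort_id or path.stem, records)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_cohort(cohort: Cohort, path: str | Path,
                 dialect: Dialect = DEFAULT_DIALECT,
                 markers: Sequence[str] | None = None) -> None:
    """Write a cohort in the same delimited format ``read_cohort`` accepts."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else dialect.delimiter
    if markers is None:
        seen: dict[str, None] = {}
        for r in cohort:
            for m in r.markers:
                seen.setdefault(m, None)
        markers = list(seen)
    rows = []
    for r in cohort:
        row = {
            "case_id": r.case_id,
            "cohort_tag": r.cohort_tag,
            "subtype_label": r.subtype_label or "",
            "clinical_tested_count": "" if r.clinical_tested_count is None
            else str(r.clinical_tested_count),
        }
        for m in markers:
            row[m] = dialect.format_status(r.status(m))
        rows.append(row)
    pd.DataFrame(rows, columns=list(_RESERVED_COLUMNS) + list(markers)) \
        .to_csv(path, sep=sep, index=False)


def export_vocabulary(path: str | Path, extra: Iterable[str] = ()) -> None:
    """Write the controlled marker vocabulary as JSON."""
    vocab = list(CANONICAL_MARKERS) + [m for m in extra
                                       if m not in CANONICAL_MARKERS]
    Path(path).write_text(json.dumps({"markers": vocab}, indent=2) + "\n")


# ---------------------------------------------------------------------------
# encodings
# ---------------------------------------------------------------------------

def _check_panel(panel: Sequence[str], extra: Iterable[str] = ()) -> list[str]:
    if not panel:
        raise ValueError("panel must be non-empty")
    return [normalize_marker(m, extra=extra) for m in panel]


def encode_onehot(cohort: Cohort, panel: Sequence[str], *,
                  extra_markers: Iterable[str] = ()) -> DesignMatrix:
    """Paired one-hot encoding: positive -> (1,0), negative -> (0,1), unknown -> (0,0).

    Missingness therefore carries no weight of its own and is absorbed into
    the model intercept.
    """
    panel = _check_panel(panel, extra_markers)
    X = np.zeros((len(cohort), 2 * len(panel)))
    for i, rec in enumerate(cohort):
        for j, m in enumerate(panel):
            s = rec.status(m)
            if s is MarkerStatus.POSITIVE:
                X[i, 2 * j] = 1.0
            elif s is MarkerStatus.NEGATIVE:
                X[i, 2 * j + 1] = 1.0
    names = [f"{m}::{suffix}" for m in panel for suffix in ("pos", "neg")]
    return DesignMatrix(names, X, "onehot_pair", [r.case_id for r in cohort])


_CATEGORICAL_CODES = {MarkerStatus.NEGATIVE: 0.0,
                      MarkerStatus.POSITIVE: 1.0,
                      MarkerStatus.UNKNOWN: 2.0}


def encode_categorical(cohort: Cohort, panel: Sequence[str], *,
                       extra_markers: Iterable[str] = ()) -> DesignMatrix:
    """Three-level categorical codes: 0=negative, 1=positive, 2=unknown."""
    panel = _check_panel(panel, extra_markers)
    X = np.empty((len(cohort), len(panel)))
    for i, rec in enumerate(cohort):
        for j, m in enumerate(panel):
            X[i, j] = _CATEGORICAL_CODES[rec.status(m)]
    return DesignMatrix(list(panel), X, "categorical3",
                        [r.case_id for r in cohort])


def encode(cohort: Cohort, panel: Sequence[str], kind: str, *,
           extra_markers: Iterable[str] = ()) -> DesignMatrix:
    if kind == "onehot_pair":
        return encode_onehot(cohort, panel, extra_markers=extra_markers)
    if kind == "categorical3":
        return encode_categorical(cohort, panel, extra_markers=extra_markers)
    raise ValueError(f"unknown encoding kind {kind!r}")


# ---------------------------------------------------------------------------
# eligibility expressions
# ---------------------------------------------------------------------------

class Expression:
    """Boolean expression over marker *availability* (status is known)."""

    def evaluate(self, record: CaseRecord) -> bool:  # pragma: no cover - abstract
        raise NotImplementedError

    def markers(self) -> set[str]:  # pragma: no cover - abstract
        raise NotImplementedError

    def to_dict(self):  # pragma: no cover - abstract
        raise NotImplementedError


@dataclass(frozen=True)
class MarkerKnown(Expression):
    """Atom: true when the marker's status is positive or negative (tested)."""

    marker: str

    def evaluate(self, record: CaseRecord) -> bool:
        return record.status(self.marker) is not MarkerStatus.UNKNOWN

    def markers(self) -> set[str]:
        return {self.marker}

    def to_dict(self):
        return self.marker

    def __str__(self) -> str:
        return self.marker


@dataclass(frozen=True)
class And(Expression):
    terms: tuple[Expression, ...]

    def evaluate(self, record: CaseRecord) -> bool:
        return all(t.evaluate(record) for t in self.terms)

    def markers(self) -> set[str]:
        return set().union(*(t.markers() for t in self.terms))

    def to_dict(self):
        return {"and": [t.to_dict() for t in self.terms]}

    def __str__(self) -> str:
        return " AND ".join(
            f"({t})" if isinstance(t, Or) else str(t) for t in self.terms)


@dataclass(frozen=True)
class Or(Expression):
    terms: tuple[Expression, ...]

    def evaluate(self, record: CaseRecord) -> bool:
        return any(t.evaluate(record) for t in self.terms)

    def markers(self) -> set[str]:
        return set().union(*(t.markers() for t in self.terms))

    def to_dict(self):
        return {"or": [t.to_dict() for t in self.terms]}

    def __str__(self) -> str:
        return " OR ".join(
            f"({t})" if isinstance(t, And) else str(t) for t in self.terms)


def expression_from_dict(obj, extra: Iterable[str] = ()) -> Expression:
    """Build an expression from the nested-dict config form."""
    if isinstance(obj, str):
        return MarkerKnown(normalize_marker(obj, extra=extra))
    if isinstance(obj, Mapping) and len(obj) == 1:
        (op, terms), = obj.items()
        parsed = tuple(expression_from_dict(t, extra) for t in terms)
        if op == "and":
            return And(parsed)
        if op == "or":
            return Or(parsed)
    raise ValueError(f"malformed expression {obj!r}")


_TOKEN_RE = re.compile(r"\(|\)|\bAND\b|\bOR\b|,|[^\s(),]+", re.IGNORECASE)


def parse_expression(text: str, extra: Iterable[str] = ()) -> Expression:
    """Parse ``"CD20 AND CD10 AND (CD5 OR Bcl-2)"`` style expressions.

    AND binds tighter than OR; parentheses group.  Marker names are
    normalized against the vocabulary (plus ``extra``).
    """
    tokens = [t for t in _TOKEN_RE.findall(text) if t != ","]
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> Expression:
        terms = [parse_and()]
        while peek() is not None and peek().upper() == "OR":
            take()
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else Or(tuple(terms))

    def parse_and() -> Expression:
        terms = [parse_atom()]
        while peek() is not None and peek().upper() == "AND":
            take()
            terms.append(parse_atom())
        return terms[0] if len(terms) == 1 else And(tuple(terms))

    def parse_atom() -> Expression:
        tok = take()
        if tok == "(":
            inner = parse_or()
            if peek() != ")":
                raise ValueError(f"unbalanced parentheses in {text!r}")
            take()
            return inner
        if tok in (")",) or tok.upper() in ("AND", "OR"):
            raise ValueError(f"unexpected token {tok!r} in {text!r}")
        return MarkerKnown(normalize_marker(tok, extra=extra))

    expr = parse_or()
    if pos != len(tokens):
        raise ValueError(f"trailing tokens in {text!r}")
    return expr


def filter_eligible(cohort: Cohort, task) -> Cohort:
    """Sub-cohort of records whose required markers were tested for *task*.

    ``task`` is a :class:`~lymphcascade.task_hierarchy.TaskSpec` or any object
    with a ``min_required_expr`` attribute; a bare :class:`Expression` is also
    accepted.  Order is preserved; the input cohort is unchanged.
    """
    expr = task if isinstance(task, Expression) else task.min_required_expr
    for m in expr.markers():
        normalize_marker(m)  # raises on out-of-vocabulary reference
    kept = [r for r in cohort if expr.evaluate(r)]
    return Cohort(cohort.cohort_id, kept)
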