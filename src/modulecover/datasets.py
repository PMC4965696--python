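"""Binary indicator matrices, dataset combination logic, and L resolution.

An indicator matrix is a genes × cases table of 0/1 entries where a 1 marks
an "active" case for a gene (e.g. differential expression in that sample).
Multiple datasets can be combined case-wise with a boolean formula over
dataset identifiers (AND binds tighter than OR).  The case-exception
parameter L may be given as an absolute count or as a percentage of the
number of cases.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class IndicatorParseError(ValueError):
    """Raised when an indicator-matrix file cannot be parsed."""


@dataclass(frozen=True)
class IndicatorMatrix:
    """Genes × cases binary table; ``values.loc[g, c] == 1`` means gene *g*
    is active in case *c*."""

    dataset_id: str
    values: pd.DataFrame  # index: gene ids, columns: case ids, dtype int8

    def __post_init__(self):
        df = self.values
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene id(s): {dupes}")
        if df.columns.has_duplicates:
            raise ValueError("duplicate case ids")
        arr = df.to_numpy()
        if arr.size and not np.isin(arr, (0, 1)).all():
            raise ValueError("indicator matrix entries must be 0 or 1")
        object.__setattr__(self, "values", df.astype(np.int8))

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def case_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cases(self) -> int:
        return self.values.shape[1]

    def row(self, gene: str) -> np.ndarray:
        return self.values.loc[gene].to_numpy()


def _open_maybe(source: Union[str, Path, IO[str]], mode: str = "r"):
    if hasattr(source, "read") or hasattr(source, "write"):
        return source, False
    return open(source, mode), True


def read_indicator_matrix(
    source: Union[str, Path, IO[str]], dataset_id: str
) -> IndicatorMatrix:
    """Read a TSV indicator matrix: first column gene id, then 0/1 entries.

    A header row is auto-detected: the first row is treated as a header iff
    any field after the first is not ``0`` or ``1``; otherwise case ids are
    generated as ``c1..cn``.
    """
    fh, close = _open_maybe(source)
    try:
        rows = []
        for raw in fh:
            line = raw.rstrip("\n").rstrip("\r")
            if line.strip():
                rows.append(line.split("\t"))
    finally:
        if close:
            fh.close()
    if not rows:
        raise IndicatorParseError("empty indicator matrix file")

    header = None
    if any(f not in ("0", "1") for f in rows[0][1:]):
        header = rows[0]
        rows = rows[1:]
        if not rows:
            raise IndicatorParseError("indicator matrix has a header but no data rows")

    width = len(rows[0])
    if width < 2:
        raise IndicatorParseError("row 1: expected gene id plus at least one entry")
    genes: list[str] = []
    data = np.empty((len(rows), width - 1), dtype=np.int8)
    for i, fields in enumerate(rows):
        if len(fields) != width:
            raise IndicatorParseError(
                f"row {i + 1}: ragged row ({len(fields)} fields, expected {width})"
            )
        genes.append(fields[0])
        for j, f in enumerate(fields[1:]):
            if f == "0":
                data[i, j] = 0
            elif f == "1":
                data[i, j] = 1
            else:
                raise IndicatorParseError(
                    f"row {i + 1}, column {j + 2}: non-binary entry {f!r}"
                )
    if header is not None:
        cases = [str(c) for c in header[1:]]
        if len(cases) != width - 1:
            raise IndicatorParseError(
                f"header names {len(cases)} cases but rows have {width - 1}"
            )
    else:
        cases = [f"c{j + 1}" for j in range(width - 1)]
    df = pd.DataFrame(data, index=genes, columns=cases)
    return IndicatorMatrix(dataset_id=dataset_id, values=df)


def write_indicator_matrix(
    matrix: IndicatorMatrix, dest: Union[str, Path, IO[str]]
) -> None:
    fh, close = _open_maybe(dest, "w")
    try:
        fh.write("id\t" + "\t".join(matrix.case_ids) + "\n")
        for gene in matrix.gene_ids:
            row = matrix.values.loc[gene]
            fh.write(gene + "\t" + "\t".join(str(int(v)) for v in row) + "\n")
    finally:
        if close:
            fh.close()


def pvalues_to_indicator(
    pmatrix: pd.DataFrame, cutoff: float, dataset_id: str = "pvalues"
) -> IndicatorMatrix:
    """Threshold a gene × case p-value table into an indicator matrix.

    An entry becomes 1 iff p < cutoff (strictly); a p-value exactly at the
    cutoff is *not* significant.
    """
    if not 0 < cutoff < 1:
        raise ValueError(f"cutoff must be in (0, 1), got {cutoff}")
    arr = pmatrix.to_numpy(dtype=float)
    if arr.size and (np.isnan(arr).any() or arr.min() < 0 or arr.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    binary = (arr < cutoff).astype(np.int8)
    df = pd.DataFrame(binary, index=pmatrix.index, columns=pmatrix.columns)
    return IndicatorMatrix(dataset_id=dataset_id, values=df)


# ---------------------------------------------------------------------------
# L specification


@dataclass(frozen=True)
class LSpec:
    """Case-exception allowance: an absolute count or a percentage of cases."""

    kind: str  # "absolute" | "percent"
    value: float

    def __post_init__(self):
        if self.kind not in ("absolute", "percent"):
            raise ValueError(f"LSpec kind must be 'absolute' or 'percent', got {self.kind!r}")
        if self.value < 0:
            raise ValueError(f"L must be non-negative, got {self.value}")
        if self.kind == "percent" and self.value > 100:
            raise ValueError(f"percentage L must be ≤ 100, got {self.value}")
        if self.kind == "absolute" and self.value != int(self.value):
            raise ValueError(f"absolute L must be an integer, got {self.value}")

    @classmethod
    def parse(cls, text: str) -> "LSpec":
        """Parse ``'8'`` → absolute 8, ``'20%'`` → percent 20."""
        text = text.strip()
        if text.endswith("%"):
            return cls("percent", float(text[:-1]))
        return cls("absolute", int(text))


def resolve_l(spec: LSpec, n_cases: int) -> int:
    """Resolve an L specification against a case count.

    Percentages round up (ceiling), so L = 20% of 38 cases allows 8
    exceptions; an absolute value above n_cases is capped with a warning.
    """
    if n_cases < 1:
        raise ValueError(f"n_cases must be ≥ 1, got {n_cases}")
    if spec.kind == "absolute":
        value = int(spec.value)
        if value > n_cases:
            logger.warning("L = %d exceeds the %d cases; capping", value, n_cases)
            return n_cases
        return value
    # round to 9 decimals first so exact fractions (20% of 35 = 7) are not
    # pushed over the ceiling by float noise
    return math.ceil(round(spec.value * n_cases / 100.0, 9))


# ---------------------------------------------------------------------------
# dataset combination formulas


@dataclass(frozen=True)
class LogicFormula:
    """Boolean expression tree over dataset ids; ``op`` is 'AND', 'OR' or
    'ID' (leaf, with ``dataset_id`` set)."""

    op: str
    children: tuple["LogicFormula", ...] = ()
    dataset_id: str | None = None

    def leaves(self) -> frozenset[str]:
        if self.op == "ID":
            return frozenset({self.dataset_id})
        return frozenset().union(*(c.leaves() for c in self.children))

    def evaluate(self, bits: Mapping[str, np.ndarray]) -> np.ndarray:
        """Evaluate element-wise over per-dataset boolean arrays."""
        if self.op == "ID":
            return bits[self.dataset_id]
        parts = [c.evaluate(bits) for c in self.children]
        out = parts[0]
        for p in parts[1:]:
            out = (out & p) if self.op == "AND" else (out | p)
        return out

    def __str__(self) -> str:
        if self.op == "ID":
            return self.dataset_id
        sep = f" {self.op} "
        return "(" + sep.join(str(c) for c in self.children) + ")"


_TOKEN_RE = re.compile(r"\s*(\(|\)|AND\b|OR\b|[A-Za-z0-9_.\-]+)", re.IGNORECASE)


class FormulaParseError(ValueError):
    """Raised for malformed combination formulas."""


def parse_formula(text: str) -> LogicFormula:
    """Parse a dataset-combination formula.

    Grammar: ``expr := term (OR term)*``, ``term := atom (AND atom)*``,
    ``atom := id | '(' expr ')'`` — AND binds tighter than OR; a single
    dataset id is a valid formula.  No negation.
    """
    tokens: list[str] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise FormulaParseError(f"unknown token at position {pos}: {text[pos:]!r}")
        tok = m.group(1)
        upper = tok.upper()
        tokens.append(upper if upper in ("AND", "OR") else tok)
        pos = m.end()
    if not tokens:
        raise FormulaParseError("empty formula")

    idx = 0

    def peek() -> str | None:
        return tokens[idx] if idx < len(tokens) else None

    def take() -> str:
        nonlocal idx
        tok = tokens[idx]
        idx += 1
        return tok

    def atom() -> LogicFormula:
        tok = peek()
        if tok is None:
            raise FormulaParseError("unexpected end of formula")
        if tok == "(":
            take()
            node = expr()
            if peek() != ")":
                raise FormulaParseError("unbalanced parentheses")
            take()
            return node
        if tok in ("AND", "OR", ")"):
            raise FormulaParseError(f"unexpected token {tok!r}")
        return LogicFormula("ID", dataset_id=take())

    def term() -> LogicFormula:
        nodes = [atom()]
        while peek() == "AND":
            take()
            nodes.append(atom())
        return nodes[0] if len(nodes) == 1 else LogicFormula("AND", tuple(nodes))

    def expr() -> LogicFormula:
        nodes = [term()]
        while peek() == "OR":
            take()
            nodes.append(term())
        return nodes[0] if len(nodes) == 1 else LogicFormula("OR", tuple(nodes))

    node = expr()
    if idx != len(tokens):
        raise FormulaParseError(f"trailing tokens: {tokens[idx:]}")
    return node


# ---------------------------------------------------------------------------
# dataset collections


@dataclass
class DatasetCollection:
    """One or more indicator matrices plus the formula combining them.

    ``l_specs`` maps dataset id to its L specification; a single percentage
    spec can be shared across datasets with differing case counts.
    """

    matrices: list[IndicatorMatrix]
    formula: LogicFormula | None = None
    l_specs: dict[str, LSpec] = field(default_factory=dict)

    def __post_init__(self):
        ids = [m.dataset_id for m in self.matrices]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate dataset ids: {ids}")
        if self.formula is None:
            # default: OR over all datasets (active in any dataset)
            leaves = tuple(LogicFormula("ID", dataset_id=i) for i in ids)
            self.formula = leaves[0] if len(leaves) == 1 else LogicFormula("OR", leaves)
        unknown = self.formula.leaves() - set(ids)
        if unknown:
            raise ValueError(f"formula references unknown dataset id(s): {sorted(unknown)}")

    @property
    def dataset_ids(self) -> list[str]:
        return [m.dataset_id for m in self.matrices]


def combine_datasets(collection: DatasetCollection) -> IndicatorMatrix:
    """Combine case-aligned datasets into one indicator matrix.

    All matrices must have the same case count (entries are combined
    position-wise per case).  The gene universe is the union of gene ids;
    a gene missing from a dataset contributes an all-zero row there, so AND
    combinations are conservative.
    """
    used = [m for m in collection.matrices if m.dataset_id in collection.formula.leaves()]
    if not used:
        raise ValueError("formula uses no dataset of the collection")
    n_cases = {m.n_cases for m in used}
    if len(n_cases) != 1:
        raise ValueError(
            "datasets have unequal case counts; case-aligned combination "
            "requires identical counts (per-dataset case semantics are not supported)"
        )
    n = n_cases.pop()
    genes = sorted(set().union(*(set(m.gene_ids) for m in used)))
    bits: dict[str, np.ndarray] = {}
    for m in used:
        arr = np.zeros((len(genes), n), dtype=bool)
        reindexed = m.values.reindex(index=genes, fill_value=0)
        arr[:, :] = reindexed.to_numpy(dtype=bool)
        bits[m.dataset_id] = arr
    combined = collection.formula.evaluate(bits).astype(np.int8)
    case_ids = used[0].case_ids if len(used) == 1 else [f"c{j + 1}" for j in range(n)]
    df = pd.DataFrame(combined, index=genes, columns=case_ids)
    return IndicatorMatrix(dataset_id="combined", values=df)


def resolve_l_for_collection(collection: DatasetCollection, default: LSpec) -> int:
    """Resolve L against the combined case count, preferring a per-dataset
    spec only when a single dataset is used."""
    used_ids = collection.formula.leaves()
    n = max(m.n_cases for m in collection.matrices if m.dataset_id in used_ids)
    if len(used_ids) == 1:
        (only,) = used_ids
        spec = collection.l_specs.get(only, default)
    else:
        spec = default
    return resolve_l(spec, n)
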