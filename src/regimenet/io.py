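"""Reading, validation, alignment and writing of cohort data modalities.

All tabular files are UTF-8, tab-delimited, with ``#``-prefixed comment
lines skipped. Matrices are genes x samples: first column gene symbol,
header row sample ids. Gene symbols are case-preserved and matched
case-sensitively. Floats are written with 6 significant digits, which
defines the round-trip guarantee for expression tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

# CNV alphabets: 5 GISTIC-like levels on input, 3 classes after collapse.
CNV_LEVELS = (-2, -1, 0, 1, 2)
CNV_CLASSES = (-1, 0, 1)  # DEL, NEUT, AMP
DEL, NEUT, AMP = -1, 0, 1

_FLOAT_FMT = "%.6g"


class CohortIOError(ValueError):
    """Raised for malformed or inconsistent cohort input files."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise CohortIOError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """Continuous (log-scale) expression, genes x samples.

    Missing values are stored as NaN and are permitted: downstream
    computations drop affected samples pairwise with N adjusted.
    """

    values: pd.DataFrame  # index = gene ids, columns = sample ids

    def __post_init__(self) -> None:
        _check_unique(list(self.values.index), "gene")
        _check_unique(list(self.values.columns), "sample")
        if self.values.shape[1] < 2:
            raise CohortIOError("expression matrix needs at least 2 samples")
        vals = self.values.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise CohortIOError("expression matrix contains infinite values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class AberrationMatrix:
    """Discrete genomic aberrations, genes x samples.

    kind='mutation': values in {0,1}. kind='cnv': 5-level GISTIC-like
    calls in {-2,...,+2}, or the 3-class {-1,0,+1} alphabet after
    :func:`collapse_cnv`.
    """

    values: pd.DataFrame
    kind: str  # 'mutation' | 'cnv'
    collapsed: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("mutation", "cnv"):
            raise CohortIOError(f"unknown aberration kind {self.kind!r}")
        _check_unique(list(self.values.index), "gene")
        _check_unique(list(self.values.columns), "sample")
        vals = self.values.to_numpy()
        if self.kind == "mutation":
            alphabet = {0, 1}
        elif self.collapsed:
            alphabet = set(CNV_CLASSES)
        else:
            alphabet = set(CNV_LEVELS)
        bad = set(np.unique(vals)) - alphabet
        if bad:
            raise CohortIOError(
                f"{self.kind} matrix contains out-of-alphabet values: {sorted(bad)}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ClinicalTable:
    """Per-sample survival time (months), event indicator and age."""

    table: pd.DataFrame  # index = sample id; columns time, event, age

    def __post_init__(self) -> None:
        required = {"time", "event", "age"}
        missing = required - set(self.table.columns)
        if missing:
            raise CohortIOError(f"clinical table missing columns: {sorted(missing)}")
        _check_unique(list(self.table.index), "sample")
        if (self.table["time"] <= 0).any():
            raise CohortIOError("clinical table: survival times must be > 0")
        ev = set(self.table["event"].unique())
        if not ev <= {0, 1}:
            raise CohortIOError(f"clinical table: event must be 0/1, found {sorted(ev)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)


@dataclass
class InteractionNetwork:
    """Undirected reference interaction network on official gene symbols."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise CohortIOError(f"interaction network contains self-loops: {loops[:3]}")

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def has_edge(self, a: str, b: str) -> bool:
        return self.graph.has_edge(a, b)


@dataclass
class Cohort:
    """Bundle of per-modality matrices sharing (subsets of) samples."""

    expression: Optional[ExpressionMatrix] = None
    mutation: Optional[AberrationMatrix] = None
    cnv: Optional[AberrationMatrix] = None
    clinical: Optional[ClinicalTable] = None

    def modality_samples(self, modality: str) -> list[str]:
        obj = getattr(self, modality, None)
        if obj is None:
            raise CohortIOError(f"modality {modality!r} not present in cohort")
        return obj.sample_ids


# ---------------------------------------------------------------------------
# readers / writers


def _read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, header=0, dtype=str)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    _check_unique(list(df.index), "gene")
    return df


def read_expression(path) -> ExpressionMatrix:
    """Read a genes x samples continuous expression TSV.

    Raises a hard error naming the offending symbol for duplicate gene
    ids, and naming the cell for non-numeric entries. Empty cells are
    missing values (NaN).
    """
    df = _read_matrix(path)
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna() & (df[col].str.strip() != "")
        if bad.any():
            gene = df.index[bad.to_numpy().argmax()]
            raise CohortIOError(
                f"non-numeric expression value at gene {gene!r}, sample {col!r}: "
                f"{df.loc[gene, col]!r}"
            )
        out[col] = converted
    return ExpressionMatrix(out)


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label="gene")


def read_aberrations(path, kind: str) -> AberrationMatrix:
    """Read a genes x samples integer aberration TSV (mutation or cnv)."""
    df = _read_matrix(path)
    try:
        ints = df.astype(float).astype(int)
        if not (df.astype(float).to_numpy() == ints.to_numpy()).all():
            raise ValueError("non-integer values")
    except ValueError as e:
        raise CohortIOError(f"{kind} matrix must be integer-valued: {e}") from e
    return AberrationMatrix(ints, kind=kind)


def write_aberrations(ab: AberrationMatrix, path) -> None:
    ab.values.to_csv(path, sep="\t", index_label="gene")


def collapse_cnv(cnv: AberrationMatrix) -> AberrationMatrix:
    """Collapse 5-level CNV calls to deletion / neutral / amplification.

    {-2,-1} -> DEL, {0} -> NEUT, {+1,+2} -> AMP. Idempotent on data
    already on the 3-class alphabet.
    """
    if cnv.kind != "cnv":
        raise CohortIOError("collapse_cnv requires a cnv matrix")
    collapsed = cnv.values.map(lambda v: int(np.sign(v)))
    return AberrationMatrix(collapsed, kind="cnv", collapsed=True)


def read_clinical(path) -> ClinicalTable:
    """Read a clinical TSV with required headers sample, time, event, age."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    if "sample" not in df.columns:
        raise CohortIOError(
            f"clinical table must have a 'sample' column; found {list(df.columns)}"
        )
    df = df.set_index("sample")
    df.index = df.index.astype(str)
    return ClinicalTable(df[["time", "event", "age"]].astype(float))


def write_clinical(clin: ClinicalTable, path) -> None:
    clin.table.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label="sample")


def read_network(
    path,
    symbol_a_col: str = "Official Symbol Interactor A",
    symbol_b_col: str = "Official Symbol Interactor B",
    type_col: Optional[str] = "Experimental System Type",
) -> InteractionNetwork:
    """Read a BioGRID-style tab-delimited edge list into an undirected network.

    Self-loops and duplicate (undirected) edges are dropped; the number of
    dropped lines is recorded on ``graph.graph['n_dropped']``.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in (symbol_a_col, symbol_b_col):
        if col not in df.columns:
            raise CohortIOError(
                f"network file missing column {col!r}; found headers {list(df.columns)}"
            )
    g = nx.Graph()
    dropped = 0
    for _, row in df.iterrows():
        a, b = row[symbol_a_col], row[symbol_b_col]
        if not isinstance(a, str) or not isinstance(b, str) or not a or not b:
            dropped += 1
            continue
        if a == b:
            dropped += 1
            continue
        if g.has_edge(a, b):
            dropped += 1
            continue
        attrs = {}
        if type_col is not None and type_col in df.columns:
            attrs["interaction_type"] = row[type_col]
        g.add_edge(a, b, **attrs)
    g.graph["n_dropped"] = dropped
    return InteractionNetwork(g)


def write_network_sif(net: InteractionNetwork, path, relation: str = "pp") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(net.graph.edges()):
            fh.write(f"{a}\t{relation}\t{b}\n")


def align_samples(cohort: Cohort, modalities: Iterable[str]) -> list[str]:
    """Ordered intersection of sample ids over the requested modalities.

    Order follows the expression matrix where available; samples absent
    from expression are appended lexicographically. Empty intersections
    are an error: no cross-modality statistic is computable.
    """
    modalities = list(modalities)
    if not modalities:
        raise CohortIOError("align_samples requires at least one modality")
    sets = [set(cohort.modality_samples(m)) for m in modalities]
    common = set.intersection(*sets)
    if not common:
        raise CohortIOError(f"no common samples across modalities {modalities}")
    if cohort.expression is not None:
        expr_order = [s for s in cohort.expression.sample_ids if s in common]
        rest = sorted(common - set(expr_order))
        return expr_order + rest
    return sorted(common)
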