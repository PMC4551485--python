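"""Input/output of expression matrices, phenotype labels, gene-set collections,
probe annotations, and result tables.

All formats are plain text: expression data as a genes x samples delimited
table with a header of sample identifiers and a first column of gene (or
probe) identifiers; phenotype labels as a two-column table or a CLS file;
gene sets in GMT format (one set per line: name, description, genes...);
results as a tab-delimited table sorted by p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "PhenotypeLabels",
    "GeneSetCollection",
    "AnnotationTable",
    "read_expression",
    "read_labels",
    "read_gmt",
    "read_annotation",
    "collapse_probes",
    "write_results",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """A genes x samples real-valued expression matrix.

    Rows are gene (or probe) identifiers, columns are sample identifiers.
    The matrix must be complete (no missing values) and identifiers unique,
    except that duplicate row ids are tolerated transiently before a probe
    collapse (``allow_duplicate_ids=True``).
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __init__(
        self,
        values: np.ndarray,
        gene_ids: Sequence[str],
        sample_ids: Sequence[str],
        *,
        allow_duplicate_ids: bool = False,
    ) -> None:
        self.values = np.asarray(values, dtype=float)
        self.gene_ids = [str(g) for g in gene_ids]
        self.sample_ids = [str(s) for s in sample_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} gene ids x {len(self.sample_ids)} sample ids"
            )
        if np.isnan(self.values).any():
            i, j = np.argwhere(np.isnan(self.values))[0]
            raise ValueError(
                f"missing value at gene {self.gene_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dups = _duplicates(self.sample_ids)
            raise ValueError(f"duplicate sample ids: {dups}")
        if not allow_duplicate_ids and len(set(self.gene_ids)) != len(self.gene_ids):
            dups = _duplicates(self.gene_ids)
            raise ValueError(
                f"duplicate gene ids (collapse probes with an annotation table): {dups}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset(self, genes: Sequence[str] | None = None,
               samples: Sequence[str] | None = None) -> "ExpressionMatrix":
        """Restrict to the given genes and/or samples, in the given order."""
        gidx = (
            [self.gene_ids.index(g) for g in genes] if genes is not None
            else list(range(self.n_genes))
        )
        sidx = (
            [self.sample_ids.index(s) for s in samples] if samples is not None
            else list(range(self.n_samples))
        )
        return ExpressionMatrix(
            self.values[np.ix_(gidx, sidx)],
            [self.gene_ids[i] for i in gidx],
            [self.sample_ids[j] for j in sidx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class PhenotypeLabels:
    """Assignment of every sample to one of exactly two phenotype labels."""

    assignment: dict[str, str]
    labels: tuple[str, str]

    def __init__(self, assignment: Mapping[str, str]) -> None:
        self.assignment = {str(k): str(v) for k, v in assignment.items()}
        distinct = sorted(set(self.assignment.values()))
        if len(distinct) != 2:
            raise ValueError(
                f"exactly two phenotypes required, got {len(distinct)}: {distinct}"
            )
        self.labels = (distinct[0], distinct[1])
        for lab in self.labels:
            n = sum(1 for v in self.assignment.values() if v == lab)
            if n < 2:
                raise ValueError(f"phenotype {lab!r} has {n} sample(s); at least 2 required")

    def counts(self) -> dict[str, int]:
        out = {lab: 0 for lab in self.labels}
        for v in self.assignment.values():
            out[v] += 1
        return out

    def groups(self, sample_ids: Sequence[str]) -> tuple[list[int], list[int]]:
        """Column indices of each phenotype within ``sample_ids``.

        Raises if any sample lacks a label.
        """
        missing = [s for s in sample_ids if s not in self.assignment]
        if missing:
            raise ValueError(f"samples without phenotype label: {missing}")
        g1 = [i for i, s in enumerate(sample_ids) if self.assignment[s] == self.labels[0]]
        g2 = [i for i, s in enumerate(sample_ids) if self.assignment[s] == self.labels[1]]
        return g1, g2


@dataclass
class GeneSetCollection:
    """Ordered collection of named gene sets (GMT-backed)."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def add(self, name: str, description: str, genes: Sequence[str]) -> None:
        if name in self.sets:
            raise ValueError(f"duplicated gene set name: {name!r}")
        deduped: list[str] = []
        seen: set[str] = set()
        for g in genes:
            if g not in seen:
                seen.add(g)
                deduped.append(g)
        if not deduped:
            raise ValueError(f"gene set {name!r} is empty")
        self.sets[name] = (description, deduped)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def genes(self, name: str) -> list[str]:
        return self.sets[name][1]


@dataclass
class AnnotationTable:
    """Probe-to-gene-symbol mapping; probes without a symbol are dropped."""

    rows: dict[str, str]

    def __init__(self, rows: Mapping[str, str]) -> None:
        cleaned: dict[str, str] = {}
        for probe, gene in rows.items():
            probe = str(probe)
            if probe in cleaned:
                raise ValueError(f"duplicate probe id: {probe!r}")
            if gene is None or (isinstance(gene, float) and np.isnan(gene)):
                continue
            gene = str(gene).strip()
            if not gene or gene.upper() in {"NA", "NAN", "---"}:
                continue
            cleaned[probe] = gene
        self.rows = cleaned


def _duplicates(items: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for x in items:
        if x in seen and x not in dups:
            dups.append(x)
        seen.add(x)
    return dups


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_expression(
    path: str | Path,
    delimiter: str = "\t",
    *,
    drop_na_rows: bool = False,
    allow_duplicate_ids: bool = False,
) -> ExpressionMatrix:
    """Read a genes x samples expression table.

    The first column holds gene/probe identifiers and the header row holds
    sample identifiers.  Missing values abort the load unless
    ``drop_na_rows`` removes the incomplete genes instead; non-numeric cells
    always abort.  Duplicate row identifiers are an error unless
    ``allow_duplicate_ids`` is set for a subsequent probe collapse.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(delimiter)[1:]
    if len(set(header)) != len(header):
        raise ValueError(f"{path}: duplicate sample ids: {_duplicates(header)}")
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns found")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric expression cell ({exc})") from exc
    if values.isna().any().any():
        if drop_na_rows:
            values = values.dropna(axis=0, how="any")
        else:
            row = values.index[values.isna().any(axis=1)][0]
            col = values.columns[values.loc[row].isna()][0]
            raise ValueError(
                f"{path}: missing value at gene {row!r}, sample {col!r} "
                "(use drop_na_rows to discard incomplete genes)"
            )
    return ExpressionMatrix(
        values.to_numpy(),
        list(values.index.astype(str)),
        list(values.columns.astype(str)),
        allow_duplicate_ids=allow_duplicate_ids,
    )


def read_labels(path: str | Path, sample_ids: Sequence[str] | None = None) -> PhenotypeLabels:
    """Read phenotype labels from a two-column table or a CLS file.

    The dialect is auto-detected from the first line: a CLS file starts with
    the ``<n_samples> <n_classes> 1`` header.  CLS labels are positional, so
    ``sample_ids`` (the expression matrix column order) must be supplied for
    that dialect.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty label file")
    first = lines[0].split()
    is_cls = len(first) == 3 and all(tok.lstrip("-").isdigit() for tok in first)
    if is_cls:
        return _parse_cls(lines, sample_ids, path)
    assignment: dict[str, str] = {}
    for ln in lines:
        parts = ln.split("\t") if "\t" in ln else ln.split()
        if len(parts) < 2:
            raise ValueError(f"{path}: malformed label line {ln!r}")
        sid, lab = parts[0], parts[1]
        if sid.lower() in {"sample", "sample_id"} and not assignment:
            continue  # optional header
        assignment[sid] = lab
    return PhenotypeLabels(assignment)


def _parse_cls(lines: list[str], sample_ids: Sequence[str] | None, path: Path) -> PhenotypeLabels:
    n_samples, n_classes, _ = (int(x) for x in lines[0].split())
    if n_classes != 2:
        raise ValueError(f"{path}: exactly two phenotypes required, CLS declares {n_classes}")
    if len(lines) < 3:
        raise ValueError(f"{path}: truncated CLS file")
    class_names = lines[1].lstrip("#").split()
    tokens = lines[2].split()
    if len(tokens) != n_samples:
        raise ValueError(
            f"{path}: CLS declares {n_samples} samples but lists {len(tokens)} labels"
        )
    # Tokens may be the class names themselves or 0-based class indices.
    if all(t.isdigit() for t in tokens) and class_names:
        labels = [class_names[int(t)] for t in tokens]
    else:
        labels = tokens
    if sample_ids is None:
        sample_ids = [str(i) for i in range(n_samples)]
    if len(sample_ids) != n_samples:
        raise ValueError(
            f"{path}: CLS lists {n_samples} labels for {len(sample_ids)} samples"
        )
    return PhenotypeLabels(dict(zip(sample_ids, labels)))


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file (name, description, genes..., tab-delimited)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    collection = GeneSetCollection()
    for lineno, ln in enumerate(path.read_text().splitlines(), start=1):
        if not ln.strip():
            continue
        fields = ln.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
        name, description, genes = fields[0], fields[1], [g for g in fields[2:] if g]
        collection.add(name, description, genes)
    return collection


def read_annotation(path: str | Path, delimiter: str = "\t") -> AnnotationTable:
    """Read a two-column probe -> gene-symbol table (header optional)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=delimiter, dtype=str, header=None)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: annotation table needs two columns")
    first = str(df.iloc[0, 0]).lower()
    if first in {"probe", "probe_id", "probeset", "probe set id"}:
        df = df.iloc[1:]
    rows = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    return AnnotationTable(rows)


# ---------------------------------------------------------------------------
# Probe collapse
# ---------------------------------------------------------------------------

def collapse_probes(expr: ExpressionMatrix, ann: AnnotationTable) -> ExpressionMatrix:
    """Collapse probe-level rows to one row per gene symbol.

    The representative probe for a gene is the probe with the highest mean
    expression across all samples; ties break to the lexicographically
    smallest probe id.  Probes absent from the annotation are dropped with a
    warning.
    """
    means = expr.values.mean(axis=1)
    best: dict[str, tuple[float, str, int]] = {}  # gene -> (mean, probe, row)
    unmapped = 0
    for i, probe in enumerate(expr.gene_ids):
        gene = ann.rows.get(probe)
        if gene is None:
            unmapped += 1
            continue
        cur = best.get(gene)
        # Higher mean wins; on an exact tie the smaller probe id wins.
        if cur is None or (means[i], _neg_str(probe)) > (cur[0], _neg_str(cur[1])):
            best[gene] = (means[i], probe, i)
    if not best:
        raise ValueError("no probe maps to any gene in the annotation table")
    if unmapped:
        warnings.warn(f"dropped {unmapped} probe(s) without gene annotation", stacklevel=2)
    genes = sorted(best)
    rows = [best[g][2] for g in genes]
    return ExpressionMatrix(expr.values[rows], genes, expr.sample_ids)


class _neg_str(str):
    """Reverses string comparison so max() prefers the smaller probe id on ties."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


# ---------------------------------------------------------------------------
# Results writer
# ---------------------------------------------------------------------------

RESULT_COLUMNS = ["set_name", "set_size", "statistic_name", "statistic", "p_value", "q_value"]


def write_results(results: Sequence, path: str | Path) -> None:
    """Write test results as a tab-delimited table sorted by p-value.

    ``results`` is a sequence of objects with the fields in
    :data:`RESULT_COLUMNS` (e.g. :class:`coexgraph.testing.TestResult`).
    """
    if not results:
        raise ValueError("no results to write")
    rows = [{c: getattr(r, c) for c in RESULT_COLUMNS} for r in results]
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    df = df.sort_values(["p_value", "set_name"], kind="stable")
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
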