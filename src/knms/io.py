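"""Readers and writers for every file format the pipeline touches.

Component property tables and edge lists are TSV/CSV (delimiter inferred
from the extension, overridable); pathway collections use the standard GMT
format; partitions round-trip through a five-column TSV.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .types import Component, DiseaseGeneList, Partition, PathwayCollection

__all__ = [
    "SchemaError",
    "read_component_table",
    "write_component_table",
    "read_edge_table",
    "write_edge_table",
    "read_gmt",
    "read_disease_genes",
    "filter_disease_genes",
    "write_partition_table",
    "read_partition_table",
]

log = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A required column or field is missing from an input file."""


_REQUIRED = ["id", "name", "formula", "herb", "mw", "logp", "hdon", "hacc", "rbn", "ob", "dl"]
_NUMERIC = {"mw": float, "logp": float, "hdon": int, "hacc": int, "rbn": int, "ob": float, "dl": float}


def _delimiter(path: Path, dialect: Optional[str]) -> str:
    if dialect is not None:
        return dialect
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_component_table(path: str | Path, dialect: Optional[str] = None) -> list[Component]:
    """Read a component property table into :class:`Component` records.

    The header must contain (case-insensitively) the columns
    ``id,name,formula,herb,mw,logp,hdon,hacc,rbn,ob,dl``; ``smiles`` is
    optional.  Row order is preserved.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter(path, dialect), dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in _REQUIRED:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    has_smiles = "smiles" in df.columns
    components: list[Component] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        rec = dict(zip(df.columns, row))
        kwargs: dict = {k: rec[k] for k in ("id", "name", "formula", "herb")}
        for col, cast in _NUMERIC.items():
            raw = rec[col].strip()
            try:
                kwargs[col] = cast(float(raw)) if cast is int else cast(raw)
            except ValueError as exc:
                raise ValueError(f"{path}, row {i}: non-numeric {col!r} value {raw!r}") from exc
            if cast is int and float(raw) != int(float(raw)):
                raise ValueError(f"{path}, row {i}: {col!r} must be an integer, got {raw!r}")
        if has_smiles and rec["smiles"].strip():
            kwargs["smiles"] = rec["smiles"].strip()
        components.append(Component(**kwargs))
    return components


def write_component_table(components: Sequence[Component], path: str | Path,
                          dialect: Optional[str] = None) -> None:
    path = Path(path)
    sep = _delimiter(path, dialect)
    cols = _REQUIRED + ["smiles"]
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=sep, lineterminator="\n")
        writer.writerow(cols)
        for c in components:
            writer.writerow([c.id, c.name, c.formula, c.herb, c.mw, c.logp,
                             c.hdon, c.hacc, c.rbn, c.ob, c.dl, c.smiles or ""])


def read_edge_table(path: str | Path, kind: str = "component-target",
                    dialect: Optional[str] = None) -> list[tuple[str, str, float]]:
    """Read an undirected edge table (``source,target[,weight]``).

    Duplicate rows are collapsed (logged with a count); self-loop rows are
    dropped with a warning.  Returns ``(u, v, weight)`` triples with a
    default weight of 1.
    """
    path = Path(path)
    sep = _delimiter(path, dialect)
    edges: dict[frozenset[str], float] = {}
    order: list[frozenset[str]] = []
    n_dup = 0
    with path.open() as fh:
        reader = csv.reader(fh, delimiter=sep)
        header = next(reader, None)
        if header is None:
            return []
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not f.strip() for f in row):
                continue
            if len(row) < 2:
                raise SchemaError(f"{path}, line {lineno}: expected at least two columns")
            u, v = row[0].strip(), row[1].strip()
            w = float(row[2]) if len(row) > 2 and row[2].strip() else 1.0
            if u == v:
                log.warning("%s, line %d: self-loop %r dropped", path, lineno, u)
                continue
            key = frozenset((u, v))
            if key in edges:
                n_dup += 1
                continue
            edges[key] = w
            order.append(key)
    if n_dup:
        log.info("%s: collapsed %d duplicate edge rows", path, n_dup)
    out = []
    for key in order:
        u, v = sorted(key)
        out.append((u, v, edges[key]))
    return out


def write_edge_table(edges: Iterable[tuple[str, str, float]], path: str | Path,
                     dialect: Optional[str] = None) -> None:
    path = Path(path)
    sep = _delimiter(path, dialect)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=sep, lineterminator="\n")
        writer.writerow(["source", "target", "weight"])
        for u, v, w in edges:
            writer.writerow([u, v, w])


def read_gmt(path: str | Path) -> PathwayCollection:
    """Read a GMT gene-set file (name, description, genes; tab-separated).

    Gene symbols are upper-cased; duplicate genes within a line collapse.
    """
    path = Path(path)
    pathways: dict[str, tuple[str, frozenset[str]]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise SchemaError(f"{path}, line {lineno}: GMT lines need >= 3 tab-separated fields")
            pid, desc = fields[0].strip(), fields[1].strip()
            if pid in pathways:
                raise SchemaError(f"{path}, line {lineno}: duplicate pathway id {pid!r}")
            genes = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
            if not genes:
                raise SchemaError(f"{path}, line {lineno}: pathway {pid!r} has no genes")
            pathways[pid] = (desc, genes)
    return PathwayCollection(pathways)


def write_gmt(collection: PathwayCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for pid in sorted(collection.pathways):
            desc, genes = collection.pathways[pid]
            fh.write("\t".join([pid, desc, *sorted(genes)]) + "\n")


def read_disease_genes(path: str | Path, dialect: Optional[str] = None) -> DiseaseGeneList:
    """Read a disease-gene table (``symbol,evidence_count``)."""
    path = Path(path)
    sep = _delimiter(path, dialect)
    records: list[tuple[str, int]] = []
    with path.open() as fh:
        reader = csv.reader(fh, delimiter=sep)
        header = next(reader, None)
        if header is None:
            return DiseaseGeneList([])
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not f.strip() for f in row):
                continue
            if len(row) < 2:
                raise SchemaError(f"{path}, line {lineno}: expected symbol and evidence_count")
            records.append((row[0], int(row[1])))
    return DiseaseGeneList(records)


def write_disease_genes(genes: DiseaseGeneList, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["symbol", "evidence_count"])
        for sym, count in genes.records:
            writer.writerow([sym, count])


def filter_disease_genes(genes: DiseaseGeneList, min_evidence: int = 5) -> set[str]:
    """Genes supported by strictly more than ``min_evidence`` literature reports.

    The default of 5 retains genes confirmed by more than five independent
    publications; the threshold is strict (a count of exactly 5 is dropped).
    """
    if min_evidence < 0:
        raise ValueError(f"min_evidence must be >= 0, got {min_evidence}")
    return {sym for sym, count in genes.records if count > min_evidence}


def write_partition_table(partition: Partition, path: str | Path,
                          node_types: Optional[Mapping[str, str]] = None,
                          p_values: Optional[Mapping[int, float]] = None,
                          q_values: Optional[Mapping[int, float]] = None) -> None:
    """Write a partition as TSV: node_id, node_type, module_id, module_p, module_q.

    Rows are sorted by module id then node id; modules without a p-value get
    empty fields (never the text "NaN").
    """
    p_values = p_values or {}
    q_values = q_values or {}
    for mapping, label in ((p_values, "p"), (q_values, "q")):
        extra = set(mapping) - set(partition.module_ids)
        if extra:
            raise ValueError(f"significance {label}-values for unknown modules {sorted(extra)}")
    node_types = node_types or {}
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["node_id", "node_type", "module_id", "module_p", "module_q"])
        for mid in partition.module_ids:
            p = p_values.get(mid)
            q = q_values.get(mid)
            for node in sorted(partition.members[mid]):
                writer.writerow([
                    node,
                    node_types.get(node, ""),
                    mid,
                    "" if p is None else repr(p),
                    "" if q is None else repr(q),
                ])


def read_partition_table(path: str | Path) -> tuple[Partition, dict[str, str],
                                                    dict[int, float], dict[int, float]]:
    """Inverse of :func:`write_partition_table`."""
    assignment: dict[str, int] = {}
    node_types: dict[str, str] = {}
    p_values: dict[int, float] = {}
    q_values: dict[int, float] = {}
    with Path(path).open() as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader)
        for row in reader:
            node, ntype, mid, p, q = row
            assignment[node] = int(mid)
            if ntype:
                node_types[node] = ntype
            if p:
                p_values[int(mid)] = float(p)
            if q:
                q_values[int(mid)] = float(q)
    return Partition(assignment), node_types, p_values, q_values
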