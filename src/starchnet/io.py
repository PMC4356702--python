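"""Readers, writers and packaged fixtures for every artifact format.

Formats handled here:

* expression TSV — a self-contained dialect: row 1 is ``gene_id`` followed by
  sample identifiers, row 2 is ``group`` followed by the per-sample condition
  label (``CK`` control / ``RS`` treatment), data rows follow;
* GMT gene-set files (tab-separated: id, description, members...);
* one-symbol-per-line disease gene lists;
* differential-expression tables (TSV, fixed column order);
* graphs (GraphML with node/edge attributes plus a flat edge-list TSV);
* topology reports (flat JSON).

Readers validate and reject structurally broken files rather than repairing
them; the single documented exception is deduplication of repeated members
within one GMT line, which is logged.  Numeric round-trips are exact to the
printing precision of 6 significant digits.

The module also packages small literature-derived fixtures: a 17-gene
diabetes-associated differential-expression table with linear RS/CK ratios,
ordered glucose- (13 genes) and lipid-metabolism (12 genes) module lists, and
the pathway-link neighbourhood of the forkhead class A signaling pathway
(node ``R1``, eight links).  ``load_fixture`` exposes them by name.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .errors import FormatError, InputError

logger = logging.getLogger("starchnet")

GROUP_LABELS = ("CK", "RS")

__all__ = [
    "ExpressionMatrix",
    "PathwayCollection",
    "DiseaseGeneSet",
    "ModuleFixture",
    "norm_symbol",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "write_gene_list",
    "load_fixture",
    "read_deg_table",
    "write_deg_table",
    "read_graph",
    "write_graph",
    "write_topology",
]


def norm_symbol(symbol: str) -> str:
    """Canonical form for gene-symbol comparison: trimmed, lower-cased.

    Matching is case-insensitive throughout the package while the original
    spelling is preserved for output.
    """
    return symbol.strip().lower()


# ---------------------------------------------------------------------------
# core containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Replicate-level linear-scale gene intensities with group labels.

    Parameters
    ----------
    values
        DataFrame of strictly positive intensities, genes as the index and
        samples as columns.
    groups
        Series mapping each sample id to its condition, ``"CK"`` (control)
        or ``"RS"`` (treatment).
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicate gene identifier: {dup!r}")
        if cols.duplicated().any():
            dup = cols[cols.duplicated()][0]
            raise FormatError(f"duplicate sample identifier: {dup!r}")
        if list(self.groups.index) != list(cols):
            raise FormatError("group labels must cover exactly the sample columns")
        bad = set(self.groups.unique()) - set(GROUP_LABELS)
        if bad:
            raise FormatError(f"unknown group label(s): {sorted(bad)}; expected CK/RS")
        for g in GROUP_LABELS:
            if (self.groups == g).sum() == 0:
                raise FormatError(f"group {g!r} has no samples")
        arr = self.values.to_numpy(dtype=float)
        finite = pd.DataFrame(arr, index=idx, columns=cols)
        mask = ~(finite > 0) | ~finite.map(math.isfinite)
        if mask.to_numpy().any():
            r, c = next(zip(*mask.to_numpy().nonzero()))
            raise FormatError(
                f"nonpositive or non-finite intensity at gene {idx[r]!r}, sample {cols[c]!r}"
            )

    # convenience accessors -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_of(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def group_values(self, group: str) -> pd.DataFrame:
        """Sub-matrix of the samples belonging to one condition."""
        return self.values[self.samples_of(group)]


@dataclass
class PathwayCollection:
    """Ordered named gene sets: the knowledge base for network assembly."""

    entries: list[tuple[str, str, list[str]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for pid, _name, members in self.entries:
            if pid in seen:
                raise FormatError(f"duplicate pathway id: {pid!r}")
            seen.add(pid)
            if not members:
                raise FormatError(f"pathway {pid!r} has no members")
            if len({norm_symbol(m) for m in members}) != len(members):
                raise FormatError(f"pathway {pid!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def ids(self) -> list[str]:
        return [pid for pid, _, _ in self.entries]

    def members(self, pathway_id: str) -> list[str]:
        for pid, _, mem in self.entries:
            if pid == pathway_id:
                return list(mem)
        raise InputError(f"unknown pathway id: {pathway_id!r}")

    def name(self, pathway_id: str) -> str:
        for pid, name, _ in self.entries:
            if pid == pathway_id:
                return name
        raise InputError(f"unknown pathway id: {pathway_id!r}")


@dataclass
class DiseaseGeneSet:
    """Set of disease-associated gene symbols (case-preserving)."""

    symbols: list[str]

    def __post_init__(self) -> None:
        keys = [norm_symbol(s) for s in self.symbols]
        if len(set(keys)) != len(keys):
            raise FormatError("duplicate symbols in disease gene set")
        self._keys = set(keys)

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return norm_symbol(symbol) in self._keys


@dataclass(frozen=True)
class ModuleFixture:
    """An ordered metabolism-module gene list with display names and aliases.

    ``aliases`` maps the normalized form of an alternative spelling to the
    normalized canonical symbol (e.g. the lipid list prints ``Cptla`` for the
    gene the differential-expression table calls ``Cpt1a``).
    """

    module_name: str
    symbols: tuple[str, ...]
    gene_names: tuple[str, ...]
    aliases: Mapping[str, str]


# ---------------------------------------------------------------------------
# expression TSV
# ---------------------------------------------------------------------------


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read the expression TSV dialect (header row, group row, data rows)."""
    path = Path(path)
    with path.open() as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) < 3:
        raise FormatError(f"{path}: expected header, group row and ≥1 data row")
    header = lines[0].split("\t")
    if header[0] != "gene_id":
        raise FormatError(f"{path}: first header field must be 'gene_id', got {header[0]!r}")
    samples = header[1:]
    grow = lines[1].split("\t")
    if grow[0] != "group" or len(grow) != len(header):
        raise FormatError(f"{path}: second row must be 'group' + one label per sample")
    groups = pd.Series(grow[1:], index=samples)

    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, ln in enumerate(lines[2:], start=3):
        parts = ln.split("\t")
        if len(parts) != len(header):
            raise FormatError(f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}")
        gene_ids.append(parts[0])
        try:
            rows.append([float(x) for x in parts[1:]])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric intensity ({exc})") from exc
    values = pd.DataFrame(rows, index=gene_ids, columns=samples, dtype=float)
    return ExpressionMatrix(values, groups)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the expression TSV dialect; 6 significant digits."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("gene_id\t" + "\t".join(matrix.sample_ids) + "\n")
        fh.write("group\t" + "\t".join(matrix.groups[s] for s in matrix.sample_ids) + "\n")
        for gid, row in matrix.values.iterrows():
            fh.write(gid + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# GMT / gene lists
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> PathwayCollection:
    """Parse a standard GMT file, preserving file order.

    Repeated members within one line are deduplicated (first occurrence kept)
    with a logged warning; any other structural violation raises.
    """
    path = Path(path)
    entries: list[tuple[str, str, list[str]]] = []
    with path.open() as fh:
        for lineno, ln in enumerate(fh, start=1):
            if not ln.strip():
                continue
            parts = ln.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs ≥3 fields, got {len(parts)}")
            pid, name, raw = parts[0], parts[1], [m for m in parts[2:] if m.strip()]
            members: list[str] = []
            seen: set[str] = set()
            for m in raw:
                key = norm_symbol(m)
                if key in seen:
                    logger.warning("%s:%d: duplicate member %r in pathway %s; deduplicated",
                                   path, lineno, m, pid)
                    continue
                seen.add(key)
                members.append(m.strip())
            entries.append((pid, name, members))
    return PathwayCollection(entries)


def write_gmt(collection: PathwayCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for pid, name, members in collection:
            fh.write("\t".join([pid, name, *members]) + "\n")


def read_gene_list(path: str | Path) -> DiseaseGeneSet:
    """One symbol per line; blank lines and ``#`` comments skipped."""
    symbols = []
    with Path(path).open() as fh:
        for ln in fh:
            s = ln.strip()
            if s and not s.startswith("#"):
                symbols.append(s)
    if not symbols:
        raise FormatError(f"{path}: empty gene list")
    return DiseaseGeneSet(symbols)


def write_gene_list(genes: DiseaseGeneSet | Iterable[str], path: str | Path) -> None:
    symbols = genes.symbols if isinstance(genes, DiseaseGeneSet) else list(genes)
    Path(path).write_text("".join(s + "\n" for s in symbols))


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------


def _data_path(name: str) -> Path:
    return Path(resources.files("starchnet.data") / name)


def load_fixture(name: str):
    """Load a packaged fixture by name.

    ``table2``
        DataFrame of 17 diabetes-associated differentially expressed genes
        (columns ``gene_symbol``, ``gene_name``, ``ratio`` — linear RS/CK).
    ``table3`` / ``table4``
        :class:`ModuleFixture` — glucose- (13 genes) resp. lipid-metabolism
        (12 genes) lists, ordered by position in the metabolic process.
    ``forkhead_links``
        List of 8 ``(source, target)`` pathway-link edges incident to the
        forkhead class A signaling pathway node ``R1``.
    ``demo_pathways`` / ``demo_disease_genes``
        Illustrative knowledge-base fixtures for the demo pipeline.
    """
    if name == "table2":
        return pd.read_csv(_data_path("table2.tsv"), sep="\t")
    if name in ("table3", "table4"):
        df = pd.read_csv(_data_path(f"{name}.tsv"), sep="\t")
        aliases = {"cptla": "cpt1a"} if name == "table4" else {}
        module_name = "glucose metabolism" if name == "table3" else "lipid metabolism"
        return ModuleFixture(
            module_name=module_name,
            symbols=tuple(df["gene_symbol"]),
            gene_names=tuple(df["gene_name"]),
            aliases=aliases,
        )
    if name == "forkhead_links":
        df = pd.read_csv(_data_path("forkhead_links.tsv"), sep="\t")
        return list(zip(df["source"], df["target"]))
    if name == "demo_pathways":
        return read_gmt(_data_path("demo_pathways.gmt"))
    if name == "demo_disease_genes":
        return read_gene_list(_data_path("demo_disease_genes.txt"))
    raise InputError(f"unknown fixture name: {name!r}")


# ---------------------------------------------------------------------------
# DEG tables
# ---------------------------------------------------------------------------

DEG_COLUMNS = ["gene_id", "ratio", "d_stat", "q_value", "call"]


def write_deg_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a differential-expression table as TSV with fixed column order."""
    out = table.reset_index() if table.index.name == "gene_id" else table.copy()
    missing = [c for c in DEG_COLUMNS if c not in out.columns]
    if missing:
        raise InputError(f"DEG table missing column(s): {missing}")
    out[DEG_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_deg_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in DEG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    return df.set_index("gene_id")


# ---------------------------------------------------------------------------
# graphs & topology reports
# ---------------------------------------------------------------------------


def write_graph(graph: nx.Graph, graphml_path: str | Path,
                edgelist_path: str | Path | None = None) -> None:
    """Export a typed graph as GraphML plus a flat edge-list TSV.

    The edge list has columns ``source``, ``target``, ``edge_type``; the
    GraphML carries full node attributes (``node_type``, ``regulation``,
    ``name``).
    """
    graphml_path = Path(graphml_path)
    nx.write_graphml(graph, graphml_path)
    if edgelist_path is None:
        edgelist_path = graphml_path.with_suffix(".edges.tsv")
    with Path(edgelist_path).open("w") as fh:
        fh.write("source\ttarget\tedge_type\n")
        for u, v, data in graph.edges(data=True):
            fh.write(f"{u}\t{v}\t{data.get('edge_type', '')}\n")


def read_graph(graphml_path: str | Path) -> nx.Graph:
    return nx.read_graphml(Path(graphml_path))


def write_topology(report: Mapping, path: str | Path) -> None:
    """Write a topology report (plain dict of documented keys) as JSON."""
    with Path(path).open("w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
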