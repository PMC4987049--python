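"""Readers and writers for PPI edge lists, essentiality lists and complex catalogs.

All inputs are plain text. Identifiers (yeast ORF names such as ``YNL012W``,
or any opaque string) are case-sensitive and stripped of surrounding
whitespace but never remapped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

logger = logging.getLogger(__name__)


class InputError(Exception):
    """A required input file is missing or unreadable."""


class ParseError(Exception):
    """A line of an input file violates its format; message names the line."""


class ContractError(Exception):
    """An operation was called with arguments violating its contract."""


@dataclass(frozen=True)
class PPINetwork:
    """Undirected simple graph over protein identifiers.

    No self-loops, no duplicate edges; every edge endpoint is a node.
    """

    graph: nx.Graph

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset((u, v)) for u, v in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @staticmethod
    def from_edges(edges: Iterable[tuple[str, str]],
                   extra_nodes: Iterable[str] = ()) -> "PPINetwork":
        """Build a network, dropping self-loops and collapsing duplicates."""
        g = nx.Graph()
        n_loops = 0
        n_dups = 0
        for u, v in edges:
            if u == v:
                n_loops += 1
                g.add_node(u)
                continue
            if g.has_edge(u, v):
                n_dups += 1
                continue
            g.add_edge(u, v)
        g.add_nodes_from(extra_nodes)
        if n_loops or n_dups:
            logger.info("dropped %d self-loops, collapsed %d duplicate edges",
                        n_loops, n_dups)
        return PPINetwork(g)


@dataclass(frozen=True)
class EssentialAnnotation:
    """The set of proteins annotated essential.

    May contain identifiers absent from a given network; membership tests are
    plain set lookups and never errors.
    """

    essential_ids: frozenset[str]

    def __contains__(self, pid: str) -> bool:
        return pid in self.essential_ids

    def __len__(self) -> int:
        return len(self.essential_ids)

    def restricted_to(self, net: PPINetwork) -> frozenset[str]:
        """Essential identifiers that are nodes of *net*."""
        return self.essential_ids & frozenset(net.graph.nodes)


@dataclass(frozen=True)
class ComplexCollection:
    """Named protein complexes: ordered (complex_id, member set) pairs."""

    complexes: tuple[tuple[str, frozenset[str]], ...] = field(default=())

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self):
        return iter(self.complexes)

    def membership(self) -> dict[str, list[str]]:
        """Map each protein to the ids of the complexes containing it."""
        out: dict[str, list[str]] = {}
        for cid, members in self.complexes:
            for m in members:
                out.setdefault(m, []).append(cid)
        return out


def _data_lines(path: Path):
    """Yield (line_number, stripped line) for non-blank, non-comment lines."""
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def load_ppi_network(path: str | Path, delimiter: str | None = None) -> PPINetwork:
    """Read a two-or-more-column edge list into a simple undirected graph.

    Parameters
    ----------
    path:
        Text file; each non-comment line holds two protein identifiers
        separated by *delimiter* (default: any run of whitespace). Extra
        columns (e.g. confidence scores) are ignored.
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"edge list not found: {path}")
    edges = []
    for lineno, line in _data_lines(path):
        fields = line.split(delimiter)
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected >=2 columns, got {len(fields)}")
        edges.append((fields[0].strip(), fields[1].strip()))
    return PPINetwork.from_edges(edges)


def load_essentials(path: str | Path) -> EssentialAnnotation:
    """Read an essential-protein list.

    Accepts one identifier per line, or a two-column ``id flag`` table with
    flag in {essential, nonessential}; rows flagged nonessential are ignored.
    Duplicates are deduplicated (count logged).
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"essential-protein list not found: {path}")
    ids: set[str] = set()
    n_rows = 0
    for lineno, line in _data_lines(path):
        fields = line.split()
        pid = fields[0].strip()
        if len(fields) >= 2:
            flag = fields[1].strip().lower()
            if flag == "nonessential":
                continue
            if flag not in ("essential", "1", "true", "yes"):
                raise ParseError(
                    f"{path}:{lineno}: unknown essentiality flag {fields[1]!r}")
        n_rows += 1
        ids.add(pid)
    if n_rows > len(ids):
        logger.info("deduplicated %d duplicate essential ids", n_rows - len(ids))
    return EssentialAnnotation(frozenset(ids))


def load_complexes(path: str | Path, long_format: bool = False) -> ComplexCollection:
    """Read a protein-complex catalog.

    Default layout: one complex per line, first token the complex id, the
    remaining tokens its members. With ``long_format=True``: two columns
    ``complex_id member`` per line, rows of one complex need not be adjacent
    (first appearance fixes complex order).
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"complex catalog not found: {path}")
    order: list[str] = []
    members: dict[str, set[str]] = {}
    for lineno, line in _data_lines(path):
        fields = line.split()
        if long_format:
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 'complex_id member'")
            cid, mem = fields
            if cid not in members:
                order.append(cid)
                members[cid] = set()
            members[cid].add(mem)
        else:
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: complex row has no members")
            cid = fields[0]
            if cid in members:
                raise ParseError(f"{path}:{lineno}: duplicate complex id {cid!r}")
            order.append(cid)
            members[cid] = set(fields[1:])
    return ComplexCollection(tuple((cid, frozenset(members[cid])) for cid in order))


def write_scores(scores, path: str | Path,
                 header_comments: Sequence[str] = ()) -> None:
    """Write one or more score vectors as a TSV table, one row per protein.

    Rows are in ascending identifier order; columns are the measure names in
    the given order. All vectors must cover the same node set.
    """
    from .centrality_baselines import ScoreVector  # local import, avoids cycle

    if isinstance(scores, ScoreVector):
        scores = [scores]
    scores = list(scores)
    if not scores:
        raise ContractError("write_scores: no score vectors given")
    node_set = set(scores[0].values)
    for sv in scores[1:]:
        if set(sv.values) != node_set:
            raise ContractError(
                f"write_scores: node sets differ between {scores[0].measure_name!r} "
                f"and {sv.measure_name!r}")
    path = Path(path)
    with path.open("w") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        fh.write("protein\t" + "\t".join(sv.measure_name for sv in scores) + "\n")
        for pid in sorted(node_set):
            fh.write(pid + "\t" + "\t".join(repr(sv.values[pid]) for sv in scores) + "\n")


def read_scores(path: str | Path) -> dict[str, Mapping[str, float]]:
    """Read a TSV score table back: measure name -> {protein: score}."""
    path = Path(path)
    if not path.is_file():
        raise InputError(f"score table not found: {path}")
    out: dict[str, dict[str, float]] = {}
    names: list[str] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if not names:
            if fields[0] != "protein":
                raise ParseError(f"{path}:{lineno}: missing 'protein' header column")
            names = fields[1:]
            for name in names:
                out[name] = {}
            continue
        if len(fields) != len(names) + 1:
            raise ParseError(f"{path}:{lineno}: expected {len(names) + 1} columns")
        for name, val in zip(names, fields[1:]):
            out[name][fields[0]] = float(val)
    return out


def write_edge_list(net: PPINetwork, path: str | Path) -> None:
    """Write the network as a deterministic two-column edge list."""
    path = Path(path)
    with path.open("w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in net.graph.edges):
            fh.write(f"{u}\t{v}\n")
        # an isolated node is representable only as a self-pair; the loader
        # drops the loop but keeps the node, so the round trip is exact
        for n in sorted(n for n in net.graph.nodes if net.graph.degree(n) == 0):
            fh.write(f"{n}\t{n}\n")


def write_curve(table, path: str | Path, header_comments: Sequence[str] = ()) -> None:
    """Write a rank/TP/precision/recall curve table as TSV."""
    path = Path(path)
    with path.open("w") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        fh.write("rank\tcum_tp\tprecision\trecall\n")
        for row in table.rows:
            fh.write(f"{row.rank}\t{row.cum_tp}\t{row.precision!r}\t{row.recall!r}\n")
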