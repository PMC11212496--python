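"""The complex graph: chains as vertices, contact counts as edge weights.

An undirected, labelled, integer-weighted simple graph G = (V, E, W).
Vertices are chain identifiers; an edge (i, j) exists exactly when chains
i and j share at least one residue–residue contact, and its weight is the
number of such residue pairs.  Graphs are stored in a fixed GML dialect::

    graph [
      node [ id 0 label "A" ]
      node [ id 1 label "B" ]
      edge [ source 0 target 1 weight 7 ]
    ]

Node ids are 0-based in vertex sort order; keys are lowercase; there are no
graphics blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

from .contacts import ChainContactMatrix
from .errors import ParseError
from .structure_io import Structure

__all__ = [
    "ComplexGraph",
    "build_complex_graph",
    "write_gml",
    "read_gml",
    "geometric_centers",
    "write_layout_tsv",
]


@dataclass(frozen=True)
class ComplexGraph:
    """Undirected weighted simple graph over chain labels.

    ``vertices`` is kept in sorted order; ``edges`` maps each unordered pair
    (stored with the lexicographically smaller label first) to a positive
    integer weight.  No self-loops, no parallel edges.
    """

    vertices: tuple[str, ...]
    edges: Mapping[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.vertices)) != len(self.vertices):
            raise ValueError("vertex labels must be unique")
        object.__setattr__(self, "vertices", tuple(sorted(self.vertices)))
        vset = set(self.vertices)
        norm: dict[tuple[str, str], int] = {}
        for (u, v), w in dict(self.edges).items():
            if u == v:
                raise ValueError(f"self-loop on vertex {u!r}")
            if u not in vset or v not in vset:
                raise ValueError(f"edge ({u!r}, {v!r}) references unknown vertex")
            key = (u, v) if u < v else (v, u)
            if key in norm:
                raise ValueError(f"parallel edge {key}")
            w = int(w)
            if w < 1:
                raise ValueError(f"edge {key}: weight must be a positive integer, got {w}")
            norm[key] = w
        object.__setattr__(self, "edges", norm)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def total_weight(self) -> int:
        """Sum of edge weights (the m of the modularity formula)."""
        return sum(self.edges.values())

    def weight(self, u: str, v: str) -> int:
        """Weight of edge (u, v); 0 if absent."""
        return self.edges.get((u, v) if u < v else (v, u), 0)

    def neighbors(self, u: str) -> Iterator[tuple[str, int]]:
        for (a, b), w in self.edges.items():
            if a == u:
                yield b, w
            elif b == u:
                yield a, w

    def strength(self, u: str) -> int:
        return sum(w for _, w in self.neighbors(u))

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ComplexGraph)
            and self.vertices == other.vertices
            and dict(self.edges) == dict(other.edges)
        )


def build_complex_graph(m: ChainContactMatrix) -> ComplexGraph:
    """Graph from a contact matrix: edge iff count ≥ 1, weight = count.

    Chains without any contact remain as isolated (degree-0) vertices.
    """
    counts = np.asarray(m.counts)
    edges: dict[tuple[str, str], int] = {}
    ids = m.chain_ids
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if counts[i, j] >= 1:
                u, v = ids[i], ids[j]
                edges[(u, v) if u < v else (v, u)] = int(counts[i, j])
    return ComplexGraph(vertices=tuple(ids), edges=edges)


def write_gml(g: ComplexGraph, path: str | Path) -> Path:
    path = Path(path)
    index = {v: i for i, v in enumerate(g.vertices)}
    lines = ["graph ["]
    for v in g.vertices:
        lines.append(f'  node [ id {index[v]} label "{v}" ]')
    for (u, v), w in sorted(g.edges.items()):
        lines.append(f"  edge [ source {index[u]} target {index[v]} weight {w} ]")
    lines.append("]")
    path.write_text("\n".join(lines) + "\n")
    return path


def _tokenize_gml(text: str) -> Iterator[tuple[int, str]]:
    for lineno, line in enumerate(text.splitlines(), start=1):
        rest = line
        while rest:
            rest = rest.lstrip()
            if not rest or rest.startswith("#"):
                break
            if rest[0] == '"':
                end = rest.find('"', 1)
                if end < 0:
                    raise ParseError(f"GML line {lineno}: unterminated string")
                yield lineno, rest[: end + 1]
                rest = rest[end + 1 :]
            elif rest[0] in "[]":
                yield lineno, rest[0]
                rest = rest[1:]
            else:
                tok = rest.split(None, 1)[0]
                cut = len(tok)
                for i, ch in enumerate(tok):
                    if ch in "[]":
                        cut = i
                        break
                yield lineno, tok[:cut]
                rest = rest[cut:] if cut < len(tok) else (rest[len(tok):])


def read_gml(path: str | Path) -> ComplexGraph:
    """Parse the package's GML dialect back into a :class:`ComplexGraph`.

    Raises :class:`ParseError` (with the offending line number) on malformed
    files, duplicate node ids, self-loops, parallel edges, or weights < 1.
    """
    path = Path(path)
    if not path.is_file():
        raise ParseError(f"{path}: no such file")
    tokens = list(_tokenize_gml(path.read_text()))
    pos = 0

    def peek() -> tuple[int, str] | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> tuple[int, str]:
        nonlocal pos
        if pos >= len(tokens):
            last = tokens[-1][0] if tokens else 0
            raise ParseError(f"{path}: GML line {last}: unexpected end of file")
        tok = tokens[pos]
        pos += 1
        return tok

    def expect(value: str) -> int:
        lineno, tok = take()
        if tok != value:
            raise ParseError(f"{path}: GML line {lineno}: expected {value!r}, got {tok!r}")
        return lineno

    def read_block() -> dict[str, object]:
        expect("[")
        fields: dict[str, object] = {}
        while True:
            lineno, tok = take()
            if tok == "]":
                return fields
            key = tok
            lineno, val = take()
            if val.startswith('"'):
                fields[key] = val[1:-1]
            else:
                try:
                    fields[key] = int(val)
                except ValueError:
                    raise ParseError(
                        f"{path}: GML line {lineno}: expected integer or string for {key!r}, got {val!r}"
                    ) from None

    expect("graph")
    expect("[")
    nodes: dict[int, str] = {}
    edges: dict[tuple[str, str], int] = {}
    while True:
        nxt = peek()
        if nxt is None:
            raise ParseError(f"{path}: GML: missing closing ']'")
        lineno, tok = take()
        if tok == "]":
            break
        if tok == "node":
            f = read_block()
            if "id" not in f or "label" not in f:
                raise ParseError(f"{path}: GML line {lineno}: node block needs id and label")
            nid = int(f["id"])  # type: ignore[arg-type]
            if nid in nodes:
                raise ParseError(f"{path}: GML line {lineno}: duplicate node id {nid}")
            label = str(f["label"])
            if label in nodes.values():
                raise ParseError(f"{path}: GML line {lineno}: duplicate node label {label!r}")
            nodes[nid] = label
        elif tok == "edge":
            f = read_block()
            for key in ("source", "target", "weight"):
                if key not in f:
                    raise ParseError(f"{path}: GML line {lineno}: edge block needs {key}")
            try:
                u = nodes[int(f["source"])]  # type: ignore[arg-type]
                v = nodes[int(f["target"])]  # type: ignore[arg-type]
            except KeyError as exc:
                raise ParseError(f"{path}: GML line {lineno}: edge references unknown node id {exc}") from None
            if u == v:
                raise ParseError(f"{path}: GML line {lineno}: self-loop on node {u!r}")
            key2 = (u, v) if u < v else (v, u)
            if key2 in edges:
                raise ParseError(f"{path}: GML line {lineno}: parallel edge {key2}")
            w = int(f["weight"])  # type: ignore[arg-type]
            if w < 1:
                raise ParseError(f"{path}: GML line {lineno}: weight must be ≥ 1, got {w}")
            edges[key2] = w
        else:
            raise ParseError(f"{path}: GML line {lineno}: unexpected token {tok!r}")
    return ComplexGraph(vertices=tuple(nodes.values()), edges=edges)


def geometric_centers(s: Structure) -> dict[str, np.ndarray]:
    """Unweighted mean of each chain's atom coordinates (polymer + ligand), Å.

    Used to place graph vertices at the chains' geometrical centres for
    plotting; solvent is excluded like everywhere else.
    """
    centers: dict[str, np.ndarray] = {}
    for chain in s.chains:
        coords = chain.atom_coordinates(include_solvent=False)
        if coords.shape[0]:
            centers[chain.chain_id] = coords.mean(axis=0)
    return centers


def write_layout_tsv(
    layout: Mapping[str, np.ndarray],
    path: str | Path,
    partition: Mapping[str, int] | None = None,
) -> Path:
    """TSV of vertex positions: chain_id, x, y, z [, module_id]."""
    path = Path(path)
    with path.open("w") as fh:
        header = "chain_id\tx\ty\tz"
        if partition is not None:
            header += "\tmodule_id"
        fh.write(header + "\n")
        for cid in sorted(layout):
            x, y, z = (float(c) for c in layout[cid])
            row = f"{cid}\t{x:.3f}\t{y:.3f}\t{z:.3f}"
            if partition is not None:
                row += f"\t{partition.get(cid, -1)}"
            fh.write(row + "\n")
    return path
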