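"""Evaluation of predicted module structure.

Two complementary views: agreement with an external reference assignment
(adjusted Rand index, chance-corrected, computed on the chains both sides
label), and interface statistics of a partition on its graph — intra-module
versus inter-module contact weight, the package's proxy for rigid modules
versus flexible inter-module interfaces.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from math import comb
from pathlib import Path
from typing import Mapping

from .errors import DegenerateInputError, ParseError
from .graph import ComplexGraph
from .leiden import Partition

__all__ = [
    "ModuleReport",
    "adjusted_rand_index",
    "module_report",
    "read_reference_tsv",
    "write_module_report_tsv",
]

logger = logging.getLogger(__name__)


def _as_mapping(p: Partition | Mapping[str, object]) -> Mapping[str, object]:
    return p.membership if isinstance(p, Partition) else p


def adjusted_rand_index(p: Partition | Mapping[str, object], r: Mapping[str, object]) -> float:
    """Adjusted Rand index between a prediction and a reference assignment.

    Restricted to the element labels present in both mappings; module names
    may be arbitrary hashables on either side.  All pair counts use exact
    integer/rational arithmetic, only the final result is a float.

    Raises
    ------
    DegenerateInputError
        If fewer than two elements are shared.
    """
    pm = _as_mapping(p)
    rm = _as_mapping(r)
    shared = sorted(set(pm) & set(rm))
    omitted = (len(pm) - len(shared), len(rm) - len(shared))
    if omitted != (0, 0):
        logger.info(
            "ARI restricted to %d shared elements (%d prediction-only, %d reference-only omitted)",
            len(shared), omitted[0], omitted[1],
        )
    n = len(shared)
    if n < 2:
        raise DegenerateInputError(f"ARI needs at least 2 shared elements, got {n}")
    contingency: Counter[tuple[object, object]] = Counter((pm[x], rm[x]) for x in shared)
    a: Counter[object] = Counter(pm[x] for x in shared)
    b: Counter[object] = Counter(rm[x] for x in shared)
    sum_ij = sum(comb(c, 2) for c in contingency.values())
    sum_a = sum(comb(c, 2) for c in a.values())
    sum_b = sum(comb(c, 2) for c in b.values())
    expected = Fraction(sum_a * sum_b, comb(n, 2))
    denom = Fraction(sum_a + sum_b, 2) - expected
    if denom == 0:
        # both sides all-singletons or both one block: identical clusterings
        return 1.0
    return float(Fraction(sum_ij) - expected) / float(denom)


@dataclass(frozen=True)
class ModuleReport:
    """Interface statistics of a partition on its graph.

    intra-module weights sum with the inter-module pair weights to the total
    graph weight; the intra fraction is their ratio (1.0 for edgeless graphs).
    """

    module_sizes: Mapping[int, int]
    intra_weight: Mapping[int, int]
    inter_weight: Mapping[tuple[int, int], int]
    total_weight: int
    intra_fraction: float


def module_report(g: ComplexGraph, p: Partition) -> ModuleReport:
    """Per-module sizes and intra/inter contact-weight statistics.

    Larger inter-module weight means a stronger (more rigid) connection
    between two modules; small or zero inter-module weight marks interfaces
    expected to be comparatively flexible.
    """
    missing = [v for v in g.vertices if v not in p]
    if missing:
        raise ValueError(f"partition does not cover vertices: {missing[:5]}")
    sizes: dict[int, int] = {c: 0 for c in range(p.k)}
    for v in g.vertices:
        sizes[p[v]] += 1
    intra: dict[int, int] = {c: 0 for c in range(p.k)}
    inter: dict[tuple[int, int], int] = {}
    for (u, v), w in g.edges.items():
        cu, cv = p[u], p[v]
        if cu == cv:
            intra[cu] += w
        else:
            key = (cu, cv) if cu < cv else (cv, cu)
            inter[key] = inter.get(key, 0) + w
    total = g.total_weight
    intra_sum = sum(intra.values())
    frac = 1.0 if total == 0 else intra_sum / total
    return ModuleReport(
        module_sizes=sizes,
        intra_weight=intra,
        inter_weight=inter,
        total_weight=total,
        intra_fraction=frac,
    )


def read_reference_tsv(path: str | Path) -> dict[str, str]:
    """Two-column TSV ``chain_id<TAB>module_name`` (free-form module names)."""
    path = Path(path)
    if not path.is_file():
        raise ParseError(f"{path}: no such file")
    out: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(f"{path}: line {lineno}: expected 2 tab-separated columns")
        if parts[0] in out:
            raise ParseError(f"{path}: line {lineno}: duplicate chain id {parts[0]!r}")
        out[parts[0]] = parts[1]
    return out


def write_module_report_tsv(report: ModuleReport, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# total_weight={report.total_weight} intra_fraction={report.intra_fraction:.4f}\n")
        fh.write("module\tsize\tintra_weight\n")
        for c in sorted(report.module_sizes):
            fh.write(f"{c}\t{report.module_sizes[c]}\t{report.intra_weight.get(c, 0)}\n")
        fh.write("module_a\tmodule_b\tinter_weight\n")
        for (a, b), w in sorted(report.inter_weight.items()):
            fh.write(f"{a}\t{b}\t{w}\n")
    return path
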