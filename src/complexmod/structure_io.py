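"""Parsing of mmCIF / legacy PDB files into a light-weight structure model.

Vertices of a complex graph are the polypeptide chains of one assembly, so
the model kept here is deliberately minimal: chains of residues of atoms
with Cartesian coordinates in ångström.  Author-assigned chain identifiers
are preserved verbatim so that graph vertex labels match the labels used in
depositions and publications.

Conventions applied while reading:

* only the first model of multi-model files is kept;
* alternate locations are resolved per atom name to the conformer with the
  highest occupancy (ties: lexicographically smallest altloc code);
* waters (HOH/DOD/WAT) are flagged as solvent and never take part in any
  contact computation;
* amino-acid residues (standard or modified) are ``polymer``; every other
  non-water residue is a ``ligand`` attached to its author chain.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

from .errors import EmptyStructureError, ParseError

logger = logging.getLogger(__name__)

_SOLVENT_NAMES = frozenset({"HOH", "DOD", "WAT"})


class ResidueKind(enum.Enum):
    POLYMER = "polymer"
    LIGAND = "ligand"
    SOLVENT = "solvent"


@dataclass(frozen=True)
class Atom:
    """One atom: a sphere centre for the contact model."""

    serial: int
    name: str
    element: str
    coords: tuple[float, float, float]
    is_hetero: bool = False
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in self.coords):
            raise ValueError(f"atom {self.serial} ({self.name}): non-finite coordinates")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.serial} ({self.name}): occupancy {self.occupancy} outside [0, 1]")


@dataclass(frozen=True)
class Residue:
    chain_id: str
    seq_id: int
    comp_id: str
    atoms: tuple[Atom, ...]
    kind: ResidueKind
    icode: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"residue {self.comp_id} {self.chain_id}{self.seq_id}: no atoms after filtering")


@dataclass(frozen=True)
class Chain:
    chain_id: str
    residues: tuple[Residue, ...]
    is_polypeptide: bool

    def atom_coordinates(self, include_solvent: bool = False) -> np.ndarray:
        """(N, 3) array of this chain's atom coordinates, Å."""
        coords = [
            a.coords
            for r in self.residues
            if include_solvent or r.kind is not ResidueKind.SOLVENT
            for a in r.atoms
        ]
        return np.asarray(coords, dtype=float).reshape(-1, 3)


@dataclass(frozen=True)
class Structure:
    structure_id: str
    chains: tuple[Chain, ...]
    source_format: str = "mmcif"

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate chain_id in structure")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(chain_id)


def _classify(comp_id: str) -> ResidueKind:
    if comp_id in _SOLVENT_NAMES:
        return ResidueKind.SOLVENT
    info = gemmi.find_tabulated_residue(comp_id)
    if info is not None and info.is_water():
        return ResidueKind.SOLVENT
    if info is not None and info.is_amino_acid():
        return ResidueKind.POLYMER
    return ResidueKind.LIGAND


def _is_standard_aa(comp_id: str) -> bool:
    info = gemmi.find_tabulated_residue(comp_id)
    return info is not None and info.is_amino_acid() and info.is_standard()


def _resolve_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one atom per atom name: highest occupancy, ties by smallest altloc."""
    by_name: dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = by_name.get(atom.name)
        if prev is None:
            by_name[atom.name] = atom
            continue
        alt_new = atom.altloc if atom.altloc != "\0" else ""
        alt_old = prev.altloc if prev.altloc != "\0" else ""
        if atom.occ > prev.occ or (atom.occ == prev.occ and alt_new < alt_old):
            by_name[atom.name] = atom
    return list(by_name.values())


def _convert_chain(ch: gemmi.Chain) -> Chain:
    residues: list[Residue] = []
    n_polymer = 0
    n_standard = 0
    for res in ch:
        kind = _classify(res.name)
        if kind is ResidueKind.POLYMER:
            n_polymer += 1
            if _is_standard_aa(res.name):
                n_standard += 1
        atoms = tuple(
            Atom(
                serial=a.serial,
                name=a.name,
                element=a.element.name,
                coords=(a.pos.x, a.pos.y, a.pos.z),
                is_hetero=(res.het_flag == "H"),
                occupancy=min(max(a.occ, 0.0), 1.0),
                altloc="" if a.altloc == "\0" else a.altloc,
            )
            for a in _resolve_altlocs(res)
        )
        if not atoms:
            continue
        residues.append(
            Residue(
                chain_id=ch.name,
                seq_id=res.seqid.num,
                comp_id=res.name,
                atoms=atoms,
                kind=kind,
                icode=res.seqid.icode.strip(),
            )
        )
    is_polypeptide = n_polymer >= 1 and n_standard > 0.5 * n_polymer
    return Chain(chain_id=ch.name, residues=tuple(residues), is_polypeptide=is_polypeptide)


_FORMATS = {
    "auto": gemmi.CoorFormat.Detect,
    "mmcif": gemmi.CoorFormat.Mmcif,
    "pdb": gemmi.CoorFormat.Pdb,
}


def parse_structure(path: str | Path, format: str = "auto") -> Structure:
    """Parse an mmCIF or legacy PDB file into a :class:`Structure`.

    Parameters
    ----------
    path:
        Path to the structure file.
    format:
        ``"auto"`` (detect from extension/content), ``"mmcif"`` or ``"pdb"``.

    Raises
    ------
    ParseError
        If the file is missing or cannot be parsed (the underlying message
        names the offending line or CIF category).
    EmptyStructureError
        If no polypeptide chain remains after filtering.
    """
    path = Path(path)
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected auto, mmcif or pdb")
    if not path.is_file():
        raise ParseError(f"{path}: no such file")
    try:
        st = gemmi.read_structure(str(path), format=_FORMATS[format])
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: file contains no model")
    if len(st) > 1:
        logger.info("%s: %d models; keeping the first only", path.name, len(st))
    model = st[0]
    chains = tuple(_convert_chain(ch) for ch in model if len(ch) > 0)
    chains = tuple(c for c in chains if c.residues)
    fmt = "pdb" if path.suffix.lower() in {".pdb", ".ent"} or format == "pdb" else "mmcif"
    structure = Structure(structure_id=st.name or path.stem, chains=chains, source_format=fmt)
    if not any(c.is_polypeptide for c in structure.chains):
        raise EmptyStructureError(f"{path}: no polypeptide chain found")
    return structure


def select_vertex_chains(s: Structure) -> list[Chain]:
    """Polypeptide chains in deterministic (chain_id-sorted) order.

    These chains become the vertices of the complex graph.  Detached
    ligand-only chains (an author chain with no amino-acid residues) are
    dropped with a warning; ligand residues sharing a polypeptide chain's id
    stay attached to that chain.
    """
    selected = sorted((c for c in s.chains if c.is_polypeptide), key=lambda c: c.chain_id)
    dropped = [c.chain_id for c in s.chains if not c.is_polypeptide]
    if dropped:
        logger.warning(
            "dropping %d non-polypeptide chain(s) from the vertex set: %s",
            len(dropped),
            ", ".join(sorted(dropped)),
        )
    return selected


def write_mmcif(
    structure_id: str,
    chains: Iterable[tuple[str, Sequence[tuple[str, int, str, Sequence[tuple[str, str, tuple[float, float, float]]]]]]],
    path: str | Path,
) -> Path:
    """Write a minimal, valid mmCIF atom_site loop.

    ``chains`` is an iterable of ``(chain_id, residues)`` where each residue
    is ``(comp_id, seq_id, group ["ATOM"|"HETATM"], atoms)`` and each atom is
    ``(atom_name, element, (x, y, z))``.  Used by the synthetic-fixture
    generator; coordinates are written to 3 decimals, the precision of the
    formats this package reads.
    """
    path = Path(path)
    lines = [
        f"data_{structure_id}",
        f"_entry.id {structure_id}",
        "loop_",
        "_atom_site.group_PDB",
        "_atom_site.id",
        "_atom_site.type_symbol",
        "_atom_site.label_atom_id",
        "_atom_site.label_alt_id",
        "_atom_site.label_comp_id",
        "_atom_site.label_asym_id",
        "_atom_site.label_entity_id",
        "_atom_site.label_seq_id",
        "_atom_site.pdbx_PDB_ins_code",
        "_atom_site.Cartn_x",
        "_atom_site.Cartn_y",
        "_atom_site.Cartn_z",
        "_atom_site.occupancy",
        "_atom_site.B_iso_or_equiv",
        "_atom_site.auth_seq_id",
        "_atom_site.auth_asym_id",
        "_atom_site.pdbx_PDB_model_num",
    ]
    serial = 0
    for entity_id, (chain_id, residues) in enumerate(chains, start=1):
        for comp_id, seq_id, group, atoms in residues:
            for name, element, (x, y, z) in atoms:
                serial += 1
                lines.append(
                    f"{group} {serial} {element} {name} . {comp_id} {chain_id} "
                    f"{entity_id} {seq_id} ? {x:.3f} {y:.3f} {z:.3f} 1.00 0.00 "
                    f"{seq_id} {chain_id} 1"
                )
    path.write_text("\n".join(lines) + "\n")
    return path
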