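"""Reading, writing and slicing of PDB structures.

Coordinates are kept in Ångström with the author residue numbering of the
source file; nothing is renumbered.  Only the first MODEL of a multi-model
file is used and alternate locations other than blank/'A' are dropped, so a
structure always represents a single conformer.

The heavy lifting of the PDB format is delegated to :mod:`gemmi`; this module
only defines the light-weight in-memory containers the rest of the package
works with.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "Structure",
    "DomainRange",
    "CofactorGroup",
    "PDBFormatError",
    "DEFAULT_RESIDUE_CODES",
    "DEFAULT_DOMAIN_RANGES",
    "read_pdb",
    "write_pdb",
    "extract_cofactors",
    "select_domain",
]

#: Residue codes used for the three prosthetic groups of a P450-reductase
#: fusion.  Synonyms (e.g. HEC for a c-type heme) can be supplied per call.
DEFAULT_RESIDUE_CODES: dict[str, str] = {"HEM": "HEM", "FMN": "FMN", "FAD": "FAD"}

#: Author-numbered domain boundaries of CYP102A1 (heme, FMN and FAD domain).
DEFAULT_DOMAIN_RANGES: dict[str, tuple[int, int]] = {
    "HEME": (2, 459),
    "FMN": (460, 650),
    "FAD": (659, 1049),
}


class PDBFormatError(ValueError):
    """Raised when a coordinate file cannot be interpreted."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom as read from an ATOM/HETATM record."""

    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    chain_id: str
    coords: tuple[float, float, float]
    is_hetero: bool = False

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError(f"atom {self.serial} {self.name!r}: empty element")
        if not all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial} {self.name!r}: non-finite coordinates")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Structure:
    """An ordered collection of atoms from one coordinate file."""

    atoms: list[AtomRecord]
    source_label: str = ""

    @property
    def chains(self) -> list[str]:
        """Chain identifiers in order of first appearance."""
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def __len__(self) -> int:
        return len(self.atoms)

    def coords_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)


@dataclass(frozen=True)
class DomainRange:
    """Inclusive author-numbered residue range of one domain on one chain."""

    label: str
    chain_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"domain {self.label}: start {self.start} > end {self.end}")


@dataclass
class CofactorGroup:
    """Heavy atoms of one prosthetic group (HEM, FMN or FAD).

    ``monomer_index`` is the 1-based ordinal of the chain the group sits on,
    in order of first appearance of chains in the file, so that groups can be
    addressed as FMN1, HEME2 etc. in a homodimer.
    """

    label: str
    monomer_index: int
    atoms: list[AtomRecord]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"empty group {self.label}{self.monomer_index}")

    @property
    def key(self) -> str:
        return f"{self.label}{self.monomer_index}"

    def coords_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)


def read_pdb(path: str | Path, source_label: str | None = None) -> Structure:
    """Read ATOM/HETATM records of the first model of a PDB file.

    Alternate locations other than blank or 'A' are skipped.  Raises
    :class:`PDBFormatError` when no atoms can be parsed and ``OSError`` when
    the file cannot be read.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"no such structure file: {path}")
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise PDBFormatError(f"{path}: {exc}") from exc

    atoms: list[AtomRecord] = []
    if len(st) > 0:
        model = st[0]
        for chain in model:
            for res in chain:
                for atom in res:
                    if atom.altloc not in ("\x00", "", "A"):
                        continue
                    atoms.append(
                        AtomRecord(
                            serial=atom.serial,
                            name=atom.name,
                            element=atom.element.name,
                            res_name=res.name,
                            res_seq=res.seqid.num,
                            chain_id=chain.name,
                            coords=(atom.pos.x, atom.pos.y, atom.pos.z),
                            is_hetero=res.het_flag == "H",
                        )
                    )
    if not atoms:
        raise PDBFormatError(f"{path}: no ATOM/HETATM records parsed")
    return Structure(atoms=atoms, source_label=source_label or path.name)


def write_pdb(structure: Structure, path: str | Path) -> Path:
    """Write a structure back to PDB v3.3 fixed columns.

    Round-trips with :func:`read_pdb` on atom identities and coordinates to
    the 3 decimals the format carries.
    """
    path = Path(path)
    # group consecutive atoms into (chain, residue) runs first: gemmi's
    # add_chain/add_residue copy their argument, so containers must be
    # complete before they are added
    chain_order: list[str] = []
    residues: dict[str, list[tuple[tuple[str, int, str], list[AtomRecord]]]] = {}
    for a in structure.atoms:
        if a.chain_id not in residues:
            residues[a.chain_id] = []
            chain_order.append(a.chain_id)
        runs = residues[a.chain_id]
        key = (a.chain_id, a.res_seq, a.res_name)
        if not runs or runs[-1][0] != key:
            runs.append((key, []))
        runs[-1][1].append(a)

    st = gemmi.Structure()
    st.name = structure.source_label or path.stem
    model = gemmi.Model("1")
    for chain_id in chain_order:
        chain = gemmi.Chain(chain_id)
        for (_, res_seq, res_name), atoms in residues[chain_id]:
            res = gemmi.Residue()
            res.name = res_name
            res.seqid = gemmi.SeqId(res_seq, " ")
            res.het_flag = "H" if atoms[0].is_hetero else "A"
            for a in atoms:
                atom = gemmi.Atom()
                atom.name = a.name
                atom.element = gemmi.Element(a.element)
                atom.pos = gemmi.Position(*a.coords)
                atom.occ = 1.0
                atom.b_iso = 0.0
                atom.serial = a.serial
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
    return path


def extract_cofactors(
    structure: Structure,
    residue_codes: Mapping[str, str] | None = None,
) -> list[CofactorGroup]:
    """Collect prosthetic-group heavy atoms as one group per (chain, residue).

    Hydrogens are dropped; a matching residue that contains only hydrogens is
    an error.  Chains are numbered 1, 2, ... in order of first appearance and
    provide the group's monomer index.  Returns an empty list when no residue
    matches.
    """
    codes = dict(residue_codes or DEFAULT_RESIDUE_CODES)
    code_to_label = {v: k for k, v in codes.items()}
    chain_order: dict[str, int] = {}
    for c in structure.chains:
        chain_order[c] = len(chain_order) + 1

    grouped: dict[tuple[str, int, str], list[AtomRecord]] = {}
    order: list[tuple[str, int, str]] = []
    seen_any: dict[tuple[str, int, str], int] = {}
    for a in structure.atoms:
        if a.res_name not in code_to_label:
            continue
        key = (a.chain_id, a.res_seq, a.res_name)
        seen_any[key] = seen_any.get(key, 0) + 1
        if a.is_hydrogen:
            continue
        if key not in grouped:
            grouped[key] = []
            order.append(key)
        grouped[key].append(a)

    for key, n in seen_any.items():
        if key not in grouped:
            chain_id, res_seq, res_name = key
            raise ValueError(
                f"empty group: {res_name} {chain_id}{res_seq} has only hydrogens"
            )

    groups = []
    for chain_id, res_seq, res_name in order:
        groups.append(
            CofactorGroup(
                label=code_to_label[res_name],
                monomer_index=chain_order[chain_id],
                atoms=grouped[(chain_id, res_seq, res_name)],
            )
        )
    return groups


def select_domain(structure: Structure, domain: DomainRange) -> Structure:
    """Atoms of one chain within an inclusive author-numbered residue range."""
    atoms = [
        a
        for a in structure.atoms
        if a.chain_id == domain.chain_id and domain.start <= a.res_seq <= domain.end
    ]
    if not atoms:
        raise ValueError(
            f"empty selection: {domain.label} chain {domain.chain_id} "
            f"residues {domain.start}-{domain.end} of {structure.source_label!r}"
        )
    return Structure(atoms=atoms, source_label=f"{structure.source_label}:{domain.label}")
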