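"""Residue-level protein structure I/O.

Structures are reduced to the representation the neighborhood statistics
operate on: chains of residues, each residue a set of heavy atoms plus the
derived geometric center (unweighted mean of heavy-atom positions).

Reading is backed by gemmi and applies fixed selection rules so that a given
deposit always maps to the same residue set:

* only the first model of multi-model (e.g. NMR) files is used;
* hydrogens and HETATM records are discarded, except selenomethionine (MSE),
  which is mapped to MET and kept;
* for alternate locations, the highest-occupancy altloc wins; ties go to the
  alphabetically first altloc code;
* residues whose type cannot be mapped to one of the 20 standard amino acids
  are dropped with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np

from .errors import (
    DegenerateResidueError,
    EmptyStructureError,
    PDBParseError,
)

logger = logging.getLogger(__name__)

#: The 20 standard amino-acid three-letter codes, in fixed canonical order.
#: This order indexes every 20 x 20 table in the package.
STANDARD_AA3: tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(STANDARD_AA3)}

#: Non-standard residue names mapped onto a standard type instead of dropped.
RESIDUE_ALIASES: dict[str, str] = {"MSE": "MET"}


@dataclass(frozen=True)
class Atom:
    """One heavy atom: PDB name, element symbol, position in Angstrom."""

    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.name!r}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name!r}: occupancy {self.occupancy} not in [0, 1]")


@dataclass
class Residue:
    """One amino acid: standard type, author sequence id, heavy atoms.

    ``seq_id`` is the pair (author residue number, insertion code); insertion
    codes are kept so the author ordering is preserved without renumbering.
    """

    res_type: str
    seq_id: tuple[int, str]
    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.res_type not in AA_INDEX:
            raise ValueError(f"{self.res_type!r} is not a standard amino-acid code")

    @property
    def center(self) -> np.ndarray:
        """Geometric center: unweighted mean of heavy-atom positions (A)."""
        return residue_center(self)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def label(self) -> str:
        num, icode = self.seq_id
        return f"{self.res_type}{num}{icode.strip()}"


def residue_center(residue: Residue) -> np.ndarray:
    """Unweighted arithmetic mean of a residue's heavy-atom positions."""
    if not residue.atoms:
        raise DegenerateResidueError(
            f"residue {residue.res_type}{residue.seq_id}: no heavy atoms, center undefined"
        )
    return residue.coords().mean(axis=0)


@dataclass
class ProteinChain:
    """An ordered single protein chain; the unit of training and scoring."""

    chain_id: str
    residues: list[Residue]
    source: str = ""

    def __post_init__(self) -> None:
        self.residues = sorted(self.residues, key=lambda r: r.seq_id)
        seen = set()
        for r in self.residues:
            if r.seq_id in seen:
                raise ValueError(f"duplicate seq_id {r.seq_id} in chain {self.chain_id!r}")
            seen.add(r.seq_id)

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def centers(self) -> np.ndarray:
        """(n, 3) array of residue geometric centers."""
        return np.array([r.center for r in self.residues], dtype=float)

    def ca_coords(self) -> dict[tuple[int, str], np.ndarray]:
        """CA position per seq_id, for superposition against another chain."""
        out = {}
        for r in self.residues:
            ca = r.atom("CA")
            if ca is not None:
                out[r.seq_id] = ca.position
        return out


def _normalize_altloc(altloc: str) -> str:
    return "" if altloc in ("\x00", " ") else altloc


def _select_altlocs(atoms: Sequence[gemmi.Atom]) -> list[gemmi.Atom]:
    """Keep one atom per name: highest occupancy, ties to first altloc code."""
    by_name: dict[str, gemmi.Atom] = {}
    for at in atoms:
        prev = by_name.get(at.name)
        if prev is None:
            by_name[at.name] = at
            continue
        key_new = (-at.occ, _normalize_altloc(at.altloc))
        key_old = (-prev.occ, _normalize_altloc(prev.altloc))
        if key_new < key_old:
            by_name[at.name] = at
    return list(by_name.values())


def parse_pdb(path: str | Path, chain_selector: str | None = None) -> list[ProteinChain]:
    """Read a PDB file into residue-level chains.

    Parameters
    ----------
    path : str or Path
        PDB file with fixed-column ATOM records.
    chain_selector : str, optional
        If given, only this chain id is returned.

    Returns
    -------
    list of ProteinChain
        One entry per (selected) chain of the first model.

    Raises
    ------
    FileNotFoundError, PDBParseError, EmptyStructureError
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such PDB file: {path}")
    try:
        structure = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:  # gemmi names the offending line
        raise PDBParseError(f"{path}: {exc}") from exc
    if len(structure) == 0:
        raise EmptyStructureError(f"{path}: no models / ATOM records")

    model = structure[0]
    chains: list[ProteinChain] = []
    dropped_types: dict[str, int] = {}
    for gchain in model:
        if chain_selector is not None and gchain.name != chain_selector:
            continue
        residues: list[Residue] = []
        for gres in gchain:
            raw_name = gres.name
            mapped = RESIDUE_ALIASES.get(raw_name, raw_name)
            if gres.het_flag == "H" and raw_name not in RESIDUE_ALIASES:
                continue  # HETATM (waters, ligands) excluded
            if mapped not in AA_INDEX:
                dropped_types[raw_name] = dropped_types.get(raw_name, 0) + 1
                continue
            heavy = [a for a in gres if not a.is_hydrogen()]
            selected = _select_altlocs(heavy)
            if not selected:
                continue
            atoms = [
                Atom(
                    name=a.name,
                    element=a.element.name,
                    position=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    occupancy=min(max(a.occ, 0.0), 1.0),
                    altloc=_normalize_altloc(a.altloc),
                )
                for a in selected
            ]
            residues.append(
                Residue(res_type=mapped, seq_id=(gres.seqid.num, gres.seqid.icode or " "), atoms=atoms)
            )
        if residues:
            chains.append(
                ProteinChain(chain_id=gchain.name, residues=residues, source=f"{path}#model1")
            )
    if dropped_types:
        logger.warning("%s: dropped non-mappable residues: %s", path, dropped_types)
    if not chains:
        raise EmptyStructureError(
            f"{path}: no standard protein residues"
            + (f" in chain {chain_selector!r}" if chain_selector else "")
        )
    return chains


def write_pdb(chain: ProteinChain, path: str | Path) -> None:
    """Write a chain as fixed-column ATOM records (coordinates to 3 decimals)."""
    if not chain.residues:
        raise ValueError("refusing to write an empty chain")
    structure = gemmi.Structure()
    structure.name = "nepre"
    model = gemmi.Model("1")
    gchain = gemmi.Chain(chain.chain_id or "A")
    for res in chain.residues:
        gres = gemmi.Residue()
        gres.name = res.res_type
        num, icode = res.seq_id
        gres.seqid = gemmi.SeqId(num, icode or " ")
        gres.het_flag = "A"
        for atom in res.atoms:
            gat = gemmi.Atom()
            gat.name = atom.name
            gat.element = gemmi.Element(atom.element)
            gat.pos = gemmi.Position(*atom.position)
            gat.occ = atom.occupancy
            gat.altloc = atom.altloc or "\x00"
            gres.add_atom(gat)
        gchain.add_residue(gres)
    model.add_chain(gchain)
    structure.add_model(model)
    structure.write_pdb(str(path))


def parse_corpus(paths: Iterable[str | Path], chain_selector: str | None = None) -> list[ProteinChain]:
    """Parse many PDB files, skipping unreadable ones with a warning."""
    chains: list[ProteinChain] = []
    for p in paths:
        try:
            chains.extend(parse_pdb(p, chain_selector))
        except (PDBParseError, EmptyStructureError) as exc:
            logger.warning("skipping %s: %s", p, exc)
    return chains
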