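"""Reading and writing protein structures in PDB format.

The package works on heavy atoms of protein chains only.  Parsing is done
with :mod:`gemmi`; this module reduces a parsed structure to light-weight,
hashable :class:`AtomRecord`/:class:`Chain` containers that the rest of the
package consumes, applying a fixed set of policies:

* hydrogens are dropped everywhere (crystal structures rarely resolve them,
  and per-atom score decomposition is defined over heavy atoms);
* waters and other HETATM records are dropped;
* of alternate conformers the highest-occupancy one is kept (ties resolved
  in favour of altloc ``A``, then lexicographically);
* by default only the first MODEL is read;
* selected non-standard residues (e.g. selenomethionine) are mapped to their
  parent standard residue; unmapped non-standard residues are kept for
  geometry but flagged so propensity scoring can skip them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import gemmi
import numpy as np

from ._data import load_table

STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: Default mapping of common modified residues to their standard parent.
NONSTANDARD_PARENT: Mapping[str, str] = {
    "MSE": "MET",  # selenomethionine
    "SEC": "CYS",  # selenocysteine (scored as CYS)
    "HYP": "PRO",  # hydroxyproline
}


class RadiiTable:
    """Element -> van der Waals radius (Å) lookup.

    The packaged default uses Bondi (1964) radii.  A user table can be
    supplied as a plain ``element<TAB>radius`` TSV file.
    """

    def __init__(self, radii: Mapping[str, float] | None = None):
        self._radii = dict(radii) if radii is not None else load_table("vdw_radii.tsv")

    @classmethod
    def from_file(cls, path: str | Path) -> "RadiiTable":
        return cls(load_table(path, packaged=False))

    def __contains__(self, element: str) -> bool:
        return element.upper() in self._radii

    def radius(self, element: str) -> float:
        try:
            return self._radii[element.upper()]
        except KeyError:
            raise KeyError(f"no van der Waals radius configured for element {element!r}") from None


_DEFAULT_RADII = RadiiTable()


def vdw_radius(element: str, table: RadiiTable | None = None) -> float:
    """Van der Waals radius of *element* in Å from the configured table."""
    return (table or _DEFAULT_RADII).radius(element)


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom of a protein chain."""

    serial: int
    name: str
    element: str
    residue_type: str
    residue_seq: int
    chain_id: str
    coords: tuple[float, float, float]
    vdw_radius: float
    icode: str = ""
    is_standard: bool = True

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity of the atom within a structure: (chain, seq, icode, name)."""
        return (self.chain_id, self.residue_seq, self.icode, self.name)


@dataclass(frozen=True)
class Residue:
    residue_type: str
    residue_seq: int
    icode: str
    atoms: tuple[AtomRecord, ...]
    is_standard: bool = True


@dataclass
class Chain:
    """An ordered protein chain of residues with heavy atoms."""

    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        for res in self.residues:
            for atom in res.atoms:
                if atom.chain_id != self.chain_id:
                    raise ValueError(
                        f"atom {atom.key} has chain id {atom.chain_id!r}, expected {self.chain_id!r}"
                    )
        keys = [(self.chain_id, r.residue_seq, r.icode) for r in self.residues]
        if len(set(keys)) != len(keys):
            raise ValueError(f"duplicate residue keys in chain {self.chain_id!r}")

    @property
    def atoms(self) -> list[AtomRecord]:
        return [a for r in self.residues for a in r.atoms]

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def coords_array(self) -> np.ndarray:
        """(n_atoms, 3) coordinate matrix in residue/atom order."""
        atoms = self.atoms
        if not atoms:
            return np.zeros((0, 3))
        return np.array([a.coords for a in atoms], dtype=float)

    def radii_array(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)


class PDBParseError(ValueError):
    pass


def _select_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # Highest occupancy wins; ties prefer altloc 'A', then lexicographic.
    def sort_key(a: gemmi.Atom):
        alt = a.altloc if a.altloc not in ("\0", "") else "A"
        return (-a.occ, alt != "A", alt)

    return sorted(atoms, key=sort_key)[0]


def parse_structure(
    pdb_text: str,
    model_policy: str = "first",
    *,
    radii: RadiiTable | None = None,
    on_unknown_element: str = "error",
    nonstandard_map: Mapping[str, str] | None = None,
) -> dict[str, Chain]:
    """Parse PDB text into a dict of chains keyed by chain id.

    Parameters
    ----------
    pdb_text:
        Contents of a PDB file (ATOM records, wwPDB v3.3 columns).
    model_policy:
        ``"first"`` reads only the first MODEL; ``"error-on-multi"`` raises
        if more than one MODEL is present.
    radii:
        Van der Waals radii table; packaged Bondi values by default.
    on_unknown_element:
        ``"error"`` raises on an element with no configured radius;
        ``"skip"`` drops the atom with a warning.
    nonstandard_map:
        Mapping of non-standard residue names to a standard parent used for
        scoring; defaults to :data:`NONSTANDARD_PARENT`.
    """
    if model_policy not in ("first", "error-on-multi"):
        raise ValueError(f"unknown model_policy {model_policy!r}")
    radii = radii or _DEFAULT_RADII
    ns_map = NONSTANDARD_PARENT if nonstandard_map is None else nonstandard_map

    structure = gemmi.read_pdb_string(pdb_text)
    if len(structure) == 0:
        raise PDBParseError("no protein atoms: structure contains no models")
    if model_policy == "error-on-multi" and len(structure) > 1:
        raise PDBParseError(f"structure has {len(structure)} models")
    model = structure[0]

    chains: dict[str, Chain] = {}
    for gchain in model:
        residues: list[Residue] = []
        for gres in gchain:
            if gres.het_flag != "A" and gres.name not in ns_map:
                continue  # HETATM (waters, ligands) unless a mapped residue
            if gres.name == "HOH":
                continue
            mapped = ns_map.get(gres.name, gres.name)
            is_standard = mapped in STANDARD_RESIDUES
            by_name: dict[str, list[gemmi.Atom]] = {}
            for gatom in gres:
                if gatom.element.is_hydrogen:
                    continue
                by_name.setdefault(gatom.name, []).append(gatom)
            atoms: list[AtomRecord] = []
            for name in by_name:
                gatom = _select_altloc(by_name[name])
                element = gatom.element.name.upper()
                if element not in radii:
                    if on_unknown_element == "skip":
                        warnings.warn(
                            f"skipping atom {gchain.name}/{gres.seqid.num}/{name}: "
                            f"no radius for element {element!r}"
                        )
                        continue
                    raise PDBParseError(f"no van der Waals radius for element {element!r}")
                atoms.append(
                    AtomRecord(
                        serial=gatom.serial,
                        name=name,
                        element=element,
                        residue_type=mapped,
                        residue_seq=gres.seqid.num,
                        chain_id=gchain.name,
                        coords=(gatom.pos.x, gatom.pos.y, gatom.pos.z),
                        vdw_radius=radii.radius(element),
                        icode=gres.seqid.icode.strip(),
                        is_standard=is_standard,
                    )
                )
            if atoms:
                residues.append(
                    Residue(
                        residue_type=mapped,
                        residue_seq=gres.seqid.num,
                        icode=gres.seqid.icode.strip(),
                        atoms=tuple(atoms),
                        is_standard=is_standard,
                    )
                )
        if residues:
            chains[gchain.name] = Chain(chain_id=gchain.name, residues=residues)

    if not chains:
        raise PDBParseError("no protein atoms")
    return chains


def load_structure(path: str | Path, **kwargs) -> dict[str, Chain]:
    """Parse a PDB file from disk; see :func:`parse_structure`."""
    return parse_structure(Path(path).read_text(), **kwargs)


def write_pdb(
    chains: Iterable[Chain], bfactors: Mapping[tuple, float] | None = None
) -> str:
    """Serialize chains back to PDB text (coordinates to 3 decimals).

    ``bfactors`` optionally maps atom keys to B-factor column values (used
    to paint predicted site ranks onto a structure for visualisation).
    """
    structure = gemmi.Structure()
    model = gemmi.Model("1")
    for chain in chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain:
            gres = gemmi.Residue()
            gres.name = res.residue_type
            gres.seqid = gemmi.SeqId(res.residue_seq, res.icode or " ")
            for atom in res.atoms:
                gatom = gemmi.Atom()
                gatom.name = atom.name
                gatom.serial = atom.serial
                gatom.element = gemmi.Element(atom.element)
                gatom.pos = gemmi.Position(*atom.coords)
                gatom.occ = 1.0
                gatom.b_iso = float(bfactors.get(atom.key, 0.0)) if bfactors else 0.0
                gres.add_atom(gatom)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    structure.add_model(model)
    return structure.make_pdb_string()
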