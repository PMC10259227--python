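"""Per-residue score scales and their per-atom decomposition.

Three scales characterise an interacting patch:

* **RIP** — residue interface propensity, the enrichment of a residue type
  at interfaces relative to a reference composition (dimensionless, >1 means
  interface-favoured).  No canonical published table exists for this method,
  so :func:`derive_rip` estimates one from any demarcated interface set; a
  user table can also be loaded from file.
* **hydrophobicity (ϕ)** — the biological hydrophobicity scale of Hessa et
  al. (2005), apparent membrane-insertion free energy in kcal/mol.
* **solvation (ΔG)** — the Wimley–White (1996) interfacial solvation
  free-energy scale in kcal/mol.

Each residue score is decomposed uniformly over the residue's heavy atoms,
*excluding the peptide-bond backbone atoms N, C and O* (CA and the side
chain are counted), and a patch's cumulative score is the linear sum of the
per-atom scores of its interacting atoms.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from ._data import load_table
from .interface import Interface, Patch
from .pdb_io import STANDARD_RESIDUES, Chain

SCALE_NAMES = ("rip", "hydrophobicity", "solvation")

_PACKAGED_SCALES = {
    "hydrophobicity": "hessa_hydrophobicity.tsv",
    "solvation": "white_wimley_solvation.tsv",
}

_ATOM_COUNTS: dict[str, int] = {
    k: int(v) for k, v in load_table("residue_atom_counts.tsv").items()
}


def residue_atom_count(residue_type: str, counts: Mapping[str, int] | None = None) -> int:
    """Heavy atoms of a residue excluding backbone N, C, O (GLY -> 1)."""
    table = _ATOM_COUNTS if counts is None else counts
    try:
        return table[residue_type.upper()]
    except KeyError:
        raise KeyError(f"no atom count for residue type {residue_type!r}") from None


@dataclass(frozen=True)
class PropensityTable:
    """A per-residue score scale plus its per-atom decomposition counts."""

    scale_name: str
    per_residue: Mapping[str, float]
    atom_counts: Mapping[str, int]

    def __post_init__(self) -> None:
        missing = STANDARD_RESIDUES - set(self.per_residue)
        if missing:
            raise ValueError(f"scale {self.scale_name!r} missing residues: {sorted(missing)}")
        for res, n in self.atom_counts.items():
            if n < 1:
                raise ValueError(f"atom count for {res} must be >= 1")

    def residue_score(self, residue_type: str) -> float:
        try:
            return self.per_residue[residue_type.upper()]
        except KeyError:
            raise KeyError(
                f"residue type {residue_type!r} not in scale {self.scale_name!r}"
            ) from None

    def per_atom_score(self, residue_type: str) -> float:
        return self.residue_score(residue_type) / residue_atom_count(
            residue_type, self.atom_counts
        )


def load_scale(name: str, path: str | Path | None = None) -> PropensityTable:
    """Load a packaged scale (``hydrophobicity`` or ``solvation``) or any
    user ``residue<TAB>score`` TSV file."""
    if path is not None:
        values = load_table(path, packaged=False)
    elif name in _PACKAGED_SCALES:
        values = load_table(_PACKAGED_SCALES[name])
    else:
        raise KeyError(f"no packaged scale named {name!r}; supply a file path")
    return PropensityTable(name, values, _ATOM_COUNTS)


def per_atom_score(residue_type: str, table: PropensityTable) -> float:
    """Residue score divided by the residue's decomposition atom count."""
    return table.per_atom_score(residue_type)


@dataclass(frozen=True)
class PatchScores:
    """Cumulative per-atom-summed scores of a patch under the three scales."""

    rip: float
    hydrophobicity: float
    solvation: float

    def by_scale(self) -> dict[str, float]:
        return {
            "rip": self.rip,
            "hydrophobicity": self.hydrophobicity,
            "solvation": self.solvation,
        }


def patch_score(patch: Patch, table: PropensityTable) -> float:
    """Sum of per-atom scores over a patch's interacting atoms (0 if empty)."""
    return sum(table.per_atom_score(a.residue_type) for a in patch.interacting_atoms)


def patch_scores(patch: Patch, tables: Mapping[str, PropensityTable]) -> PatchScores:
    """Cumulative scores of a patch under all three scales at once."""
    return PatchScores(
        rip=patch_score(patch, tables["rip"]),
        hydrophobicity=patch_score(patch, tables["hydrophobicity"]),
        solvation=patch_score(patch, tables["solvation"]),
    )


def derive_rip(
    interfaces: Iterable[Interface],
    reference_chains: Iterable[Chain],
    pseudocount: float = 0.5,
) -> PropensityTable:
    """Estimate a residue-interface-propensity table from demarcated
    interfaces.

    The propensity of residue type *r* is the ratio of its relative
    frequency among interface residues to its relative frequency in the
    reference chains, with an additive pseudocount for stability::

        RIP(r) = [(n_r,int + a) / (N_int + 20a)] / [(n_r,ref + a) / (N_ref + 20a)]

    A residue counts once per interface if at least one of its atoms
    interacts, regardless of how many atoms do; the reference counts every
    standard residue instance of the reference chains.
    """
    interfaces = list(interfaces)
    if not interfaces:
        raise ValueError("derive_rip requires at least one interface")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")

    int_counts = {r: 0 for r in STANDARD_RESIDUES}
    for iface in interfaces:
        for patch in (iface.patch_a, iface.patch_b):
            seen: set[tuple] = set()
            for atom in patch.interacting_atoms:
                res_key = (atom.chain_id, atom.residue_seq, atom.icode)
                if res_key in seen:
                    continue
                seen.add(res_key)
                if atom.residue_type in int_counts:
                    int_counts[atom.residue_type] += 1

    ref_counts = {r: 0 for r in STANDARD_RESIDUES}
    for chain in reference_chains:
        for res in chain:
            if res.residue_type in ref_counts:
                ref_counts[res.residue_type] += 1

    if pseudocount == 0 and min(ref_counts.values()) == 0:
        raise ValueError("reference must cover all 20 residue types when pseudocount is 0")

    n_int = sum(int_counts.values())
    n_ref = sum(ref_counts.values())
    denom_int = n_int + 20 * pseudocount
    denom_ref = n_ref + 20 * pseudocount
    rip = {
        r: ((int_counts[r] + pseudocount) / denom_int)
        / ((ref_counts[r] + pseudocount) / denom_ref)
        for r in STANDARD_RESIDUES
    }
    return PropensityTable("rip", rip, _ATOM_COUNTS)


def default_tables(rip: PropensityTable) -> dict[str, PropensityTable]:
    """Bundle a RIP table with the packaged ϕ and ΔG scales."""
    return {
        "rip": rip,
        "hydrophobicity": load_scale("hydrophobicity"),
        "solvation": load_scale("solvation"),
    }
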