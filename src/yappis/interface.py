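"""Demarcation of atomic contact pairs (ACPs) and interaction interfaces.

Two heavy atoms on different chains of a complex form an *atomic contact
pair* when their distance is strictly less than the sum of their van der
Waals radii plus a tolerance factor (1 Å by default).  The collection of
ACPs between one pair of chains is the *protein-protein interaction
interface* (PPII), and the deduplicated interacting atoms contributed by
each chain form that chain's *protein-protein interacting patch* (PPIP).
Interfaces with fewer than a minimum number of ACPs (20 by default) are
discarded as too tenuous to represent a biological interface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .pdb_io import AtomRecord, Chain

DEFAULT_TOLERANCE = 1.0  # Å added to the vdW-radius sum
DEFAULT_MIN_ACPS = 20


@dataclass(frozen=True)
class AtomContactPair:
    """A cross-chain atom pair in van der Waals contact."""

    atom_a: AtomRecord
    atom_b: AtomRecord
    distance: float

    def __post_init__(self) -> None:
        if self.atom_a.chain_id == self.atom_b.chain_id:
            raise ValueError("ACP atoms must belong to different chains")


@dataclass(frozen=True)
class Patch:
    """The deduplicated interacting atoms one chain contributes to a PPII."""

    chain_id: str
    interacting_atoms: tuple[AtomRecord, ...]

    @property
    def residues_touched(self) -> tuple[tuple[int, str], ...]:
        seen: dict[tuple[int, str], None] = {}
        for a in self.interacting_atoms:
            seen.setdefault((a.residue_seq, a.icode), None)
        return tuple(seen)

    @property
    def atom_keys(self) -> frozenset:
        return frozenset(a.key for a in self.interacting_atoms)

    def __len__(self) -> int:
        return len(self.interacting_atoms)


@dataclass(frozen=True)
class Interface:
    """A PPII: all ACPs between one pair of chains, plus the two patches."""

    chain_pair: tuple[str, str]
    acps: tuple[AtomContactPair, ...]
    patch_a: Patch
    patch_b: Patch

    def __len__(self) -> int:
        return len(self.acps)


def _contact_eligible(chain: Chain) -> list[AtomRecord]:
    # Only standard-residue heavy atoms take part in demarcation.
    return [a for a in chain.atoms if a.is_standard]


def find_acps(
    chain_a: Chain, chain_b: Chain, tolerance: float = DEFAULT_TOLERANCE
) -> list[AtomContactPair]:
    """All cross-chain atom pairs with distance < r_a + r_b + tolerance.

    The comparison is strict.  A k-d tree prunes the pair search; the final
    acceptance test is the exact distance comparison, so the result is
    identical to an all-pairs scan.  Pairs are returned sorted by the two
    atom serial numbers, each unordered pair exactly once.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    if chain_a.chain_id == chain_b.chain_id:
        raise ValueError("find_acps requires two distinct chains")
    atoms_a = _contact_eligible(chain_a)
    atoms_b = _contact_eligible(chain_b)
    if not atoms_a or not atoms_b:
        return []
    xyz_a = np.array([a.coords for a in atoms_a], dtype=float)
    xyz_b = np.array([b.coords for b in atoms_b], dtype=float)
    r_a = np.array([a.vdw_radius for a in atoms_a], dtype=float)
    r_b = np.array([b.vdw_radius for b in atoms_b], dtype=float)

    max_cut = r_a.max() + r_b.max() + tolerance
    tree_b = cKDTree(xyz_b)
    neighborhoods = cKDTree(xyz_a).query_ball_tree(tree_b, r=max_cut)

    pairs: list[AtomContactPair] = []
    for i, js in enumerate(neighborhoods):
        if not js:
            continue
        js = np.asarray(js, dtype=int)
        d = np.linalg.norm(xyz_b[js] - xyz_a[i], axis=1)
        hit = d < (r_a[i] + r_b[js] + tolerance)
        for j, dist in zip(js[hit], d[hit]):
            pairs.append(AtomContactPair(atoms_a[i], atoms_b[int(j)], float(dist)))
    pairs.sort(key=lambda p: (p.atom_a.serial, p.atom_b.serial))
    return pairs


def build_interface(
    chain_a: Chain, chain_b: Chain, acps: Sequence[AtomContactPair]
) -> Interface:
    """Assemble a PPII from a list of ACPs between two chains.

    Each interacting atom appears in its patch exactly once, regardless of
    how many ACPs it participates in; patch order follows atom serials.
    """
    seen_a: dict[tuple, AtomRecord] = {}
    seen_b: dict[tuple, AtomRecord] = {}
    for pair in acps:
        seen_a.setdefault(pair.atom_a.key, pair.atom_a)
        seen_b.setdefault(pair.atom_b.key, pair.atom_b)
    atoms_a = tuple(sorted(seen_a.values(), key=lambda a: a.serial))
    atoms_b = tuple(sorted(seen_b.values(), key=lambda a: a.serial))
    return Interface(
        chain_pair=(chain_a.chain_id, chain_b.chain_id),
        acps=tuple(sorted(acps, key=lambda p: (p.atom_a.serial, p.atom_b.serial))),
        patch_a=Patch(chain_a.chain_id, atoms_a),
        patch_b=Patch(chain_b.chain_id, atoms_b),
    )


def demarcate(
    chain_a: Chain,
    chain_b: Chain,
    tolerance: float = DEFAULT_TOLERANCE,
) -> Interface:
    """Convenience: find ACPs between two chains and build the interface."""
    return build_interface(chain_a, chain_b, find_acps(chain_a, chain_b, tolerance))


def filter_interfaces(
    interfaces: Iterable[Interface], min_acps: int = DEFAULT_MIN_ACPS
) -> list[Interface]:
    """Keep interfaces with at least *min_acps* contact pairs (order kept)."""
    if min_acps < 1:
        raise ValueError("min_acps must be >= 1")
    return [iface for iface in interfaces if len(iface.acps) >= min_acps]


def interface_to_tsv(interface: Interface) -> str:
    """Tabular ACP listing: chain_a, serial_a, chain_b, serial_b, distance."""
    lines = ["chain_a\tserial_a\tchain_b\tserial_b\tdistance"]
    for p in interface.acps:
        lines.append(
            f"{p.atom_a.chain_id}\t{p.atom_a.serial}\t"
            f"{p.atom_b.chain_id}\t{p.atom_b.serial}\t{p.distance:.3f}"
        )
    return "\n".join(lines) + "\n"
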