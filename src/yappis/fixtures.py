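"""Deterministic synthetic two-chain complexes with a known interface.

Real interface benchmarks require structure downloads; these fixtures make
every pipeline stage testable offline.  A fixture is two pseudo-chains of
idealised residues: each residue is a column of carbon spheres (one per
heavy atom of its type, excluding the peptide-bond backbone atoms, at
covalent 1.5 Å spacing) standing on a jittered square lattice.  A central
group of residues on each chain points its column tip toward the partner;
chain B stands on a half-cell-offset lattice, so its contact tips descend
*between* chain A's tips and the two contact zones interdigitate within
van der Waals distance, the way knobs pack into holes on real interfaces.
Removing the partner therefore leaves complementary surface pockets whose
lining atoms are exactly the demarcated patch — the concave, occludable
geometry an energy probe recognises on real unbound chains.  Interface residues are drawn from hydrophobic types and the
remainder from polar types, emulating the compositional signal that
interface-propensity and hydrophobicity scales exploit on real interfaces.

The ground truth *is* the demarcated interface of the generated complex
(guaranteed ≥ the requested contact count by construction), so recovery
tests close the loop through the same demarcation used on real complexes.
All randomness flows from an explicit seeded generator; the same spec
yields byte-identical PDB output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .interface import demarcate
from .pdb_io import AtomRecord, Chain, Residue, vdw_radius
from .pipeline import TrainingComplex
from .scales import PropensityTable, patch_score, residue_atom_count

#: Residue types biased toward the constructed contact zone / the rest.
HYDROPHOBIC = ("ILE", "LEU", "VAL", "PHE", "MET", "TRP", "TYR")
POLAR = ("LYS", "GLU", "ASP", "SER", "GLN", "ASN", "THR", "ARG", "ALA", "GLY")

_LATTICE = 5.5  # Å between residue columns
_BOND = 1.5  # Å between stacked atoms of a column
_BODY_DEPTH = 3.6  # Å thickness of a residue's body ball behind its tip
_TIP_SPREAD = 0.5  # Å lateral offset of the two tip atoms
_RECESS = 3.0  # Å the non-contact surface sits behind the contact plane
_MIN_GAP = -0.5  # Å deepest tip-plane interdigitation the generator will try
_SIDE_NAMES = ("CB", "CG", "CD", "CE", "CZ", "CH1", "CH2", "CH3", "CH4", "CH5")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic complex."""

    seed: int
    n_residues: int = 40
    interface_size: int = 30  # minimum ACP count the contact zone must yield
    #: Vertical offset between chain A's tip plane and chain B's
    #: interdigitated tip plane; the effective contact distances are set by
    #: the half-cell lateral offset (≈3.9 Å) and stay inside the vdW-sum
    #: + tolerance cutoff.
    gap: float = 0.2
    hydrophobic_interface: bool = True

    def __post_init__(self) -> None:
        if self.n_residues < 9:
            raise ValueError("need at least 9 residues per chain")
        if self.interface_size < 1:
            raise ValueError("interface_size must be >= 1")
        if self.gap < _MIN_GAP or self.gap > 2.0:
            raise ValueError("gap must keep the tip planes interdigitated")


class FixtureError(ValueError):
    pass


def _lattice_sites(n: int) -> list[tuple[int, int]]:
    ncols = math.ceil(math.sqrt(n))
    return [(i // ncols, i % ncols) for i in range(n)]


def _central_sites(sites: list[tuple[int, int]], k: int) -> set[int]:
    cx = sum(s[0] for s in sites) / len(sites)
    cy = sum(s[1] for s in sites) / len(sites)
    order = sorted(
        range(len(sites)),
        key=lambda i: ((sites[i][0] - cx) ** 2 + (sites[i][1] - cy) ** 2, i),
    )
    return set(order[:k])


def _residue_column(
    rng: np.random.Generator,
    residue_type: str,
    base_xy: tuple[float, float],
    tip_z: float,
    direction: float,
) -> list[tuple[str, tuple[float, float, float]]]:
    """Atom (name, coords) list of one residue column.

    The column grows from the buried CA toward ``tip_z``; the outermost one
    or two atoms sit exactly on the tip plane with a small lateral spread,
    so tips of facing columns interdigitate across the contact gap.
    """
    count = residue_atom_count(residue_type)
    n_tip = 2 if count >= 3 else 1
    names = ("CA",) + _SIDE_NAMES[: count - 1]
    theta = rng.uniform(0, 2 * math.pi)
    atoms: list[tuple[str, tuple[float, float, float]]] = []
    for i in range(count):
        if i >= count - n_tip:  # tip atom(s) on the contact plane
            j = i - (count - n_tip)
            sign = 1.0 if j == 0 else -1.0
            spread = _TIP_SPREAD if count > 1 else 0.0
            x = base_xy[0] + sign * spread * math.cos(theta)
            y = base_xy[1] + sign * spread * math.sin(theta)
            z = tip_z
        else:  # body atoms: a compact disordered ball behind the tip, CA
            # deepest; keeps the slab thin and packed so no straight
            # inter-column channel stays probe-accessible below the surface
            phi = rng.uniform(0, 2 * math.pi)
            rad = rng.uniform(0.4, 1.6)
            x = base_xy[0] + rad * math.cos(phi)
            y = base_xy[1] + rad * math.sin(phi)
            if i == 0:  # CA anchors the bottom of the ball
                z = tip_z - direction * _BODY_DEPTH
            else:
                z = tip_z - direction * rng.uniform(1.2, _BODY_DEPTH)
        atoms.append((names[i], (round(x, 3), round(y, 3), round(z, 3))))
    return atoms


def _compose(
    rng: np.random.Generator, n: int, interface_idx: set[int], hydrophobic_interface: bool
) -> list[str]:
    types = []
    for i in range(n):
        if i in interface_idx and hydrophobic_interface:
            pool = HYDROPHOBIC if rng.uniform() < 0.85 else POLAR
        else:
            pool = POLAR if rng.uniform() < 0.9 else HYDROPHOBIC
        types.append(pool[int(rng.integers(len(pool)))])
    return types


def _build_chain(
    chain_id: str,
    residue_types: list[str],
    interface_idx: set[int],
    rng: np.random.Generator,
    contact_plane: float,
    direction: float,
    serial_start: int,
    site_xy: list[tuple[float, float]],
) -> tuple[Chain, int]:
    residues: list[Residue] = []
    serial = serial_start
    for ridx, rtype in enumerate(residue_types):
        tip_z = contact_plane if ridx in interface_idx else contact_plane - direction * _RECESS
        column = _residue_column(rng, rtype, site_xy[ridx], tip_z, direction)
        atoms = tuple(
            AtomRecord(
                serial=serial + i,
                name=name,
                element="C",
                residue_type=rtype,
                residue_seq=ridx + 1,
                chain_id=chain_id,
                coords=xyz,
                vdw_radius=vdw_radius("C"),
            )
            for i, (name, xyz) in enumerate(column)
        )
        serial += len(atoms)
        residues.append(Residue(rtype, ridx + 1, "", atoms))
    return Chain(chain_id, residues), serial


def _generate(
    spec: FixtureSpec,
    n_iface: int,
    gap: float,
    types_a: list[str] | None = None,
    types_b: list[str] | None = None,
) -> TrainingComplex:
    rng = np.random.default_rng(spec.seed)
    sites = _lattice_sites(spec.n_residues)
    iface_idx = _central_sites(sites, n_iface)
    # The composition draws always happen so that overriding the types (the
    # scored-fixture search does) leaves the downstream geometry unchanged.
    comp_a = _compose(rng, spec.n_residues, iface_idx, spec.hydrophobic_interface)
    comp_b = _compose(rng, spec.n_residues, iface_idx, spec.hydrophobic_interface)
    if types_a is not None:
        comp_a = list(types_a)
    if types_b is not None:
        comp_b = list(types_b)
    xy_a = [
        (sx * _LATTICE + rng.uniform(-0.25, 0.25), sy * _LATTICE + rng.uniform(-0.25, 0.25))
        for sx, sy in sites
    ]
    half = _LATTICE / 2.0  # B's columns stand over A's inter-column holes
    xy_b = [
        (
            sx * _LATTICE + half + rng.uniform(-0.25, 0.25),
            sy * _LATTICE + half + rng.uniform(-0.25, 0.25),
        )
        for sx, sy in sites
    ]
    chain_a, next_serial = _build_chain("A", comp_a, iface_idx, rng, 0.0, 1.0, 1, xy_a)
    chain_b, _ = _build_chain("B", comp_b, iface_idx, rng, gap, -1.0, next_serial, xy_b)
    return TrainingComplex(chain_a, chain_b, demarcate(chain_a, chain_b))


def _solve_geometry(spec: FixtureSpec) -> tuple[int, float, TrainingComplex]:
    """Find (contact-zone size, gap) meeting the requested contact count.

    Deterministic search: deepen the interdigitation in 0.1 Å steps (down
    to a -0.5 Å tip-plane offset), then widen the contact zone by two
    residues, until the demarcated interface has enough ACPs.
    """
    n_iface = 6  # smallest zone; interdigitation yields ~25 ACPs/residue
    n_iface_max = max(n_iface, int(spec.n_residues * 0.75))
    while n_iface <= n_iface_max:
        gap = spec.gap
        while gap >= _MIN_GAP:
            complex_ = _generate(spec, n_iface, gap)
            if len(complex_.interface.acps) >= spec.interface_size:
                return n_iface, gap, complex_
            gap = round(gap - 0.1, 3)
        n_iface += 2
    raise FixtureError(
        f"cannot reach {spec.interface_size} contacts with "
        f"{spec.n_residues} residues and gap {spec.gap}"
    )


def make_synthetic_complex(spec: FixtureSpec) -> TrainingComplex:
    """Generate a two-chain complex whose demarcated interface has at least
    ``spec.interface_size`` atomic contact pairs (deterministic in seed)."""
    return _solve_geometry(spec)[2]


def make_scored_fixture(
    spec: FixtureSpec,
    target_bin: tuple[float, float],
    table: PropensityTable,
    max_attempts: int = 50,
) -> TrainingComplex:
    """A complex whose chain-A patch cumulative score under *table* falls
    inside ``target_bin``.

    A deterministic greedy search mutates the contact-zone composition of
    chain A (one residue per round, taking the substitution whose patch
    score comes closest to the bin centre) until the score lands in the
    bin; raises :class:`FixtureError` if the bin stays unreachable.
    """
    lo, hi = target_bin
    if hi <= lo:
        raise ValueError("target_bin must be a non-empty interval")
    mid = 0.5 * (lo + hi)

    n_iface, gap, current = _solve_geometry(spec)
    types_a = [r.residue_type for r in current.chain_a.residues]
    iface_positions = sorted({a.residue_seq - 1 for a in current.interface.patch_a.interacting_atoms})
    all_types = HYDROPHOBIC + POLAR

    for _ in range(max_attempts):
        score = patch_score(current.interface.patch_a, table)
        if lo <= score <= hi:
            return current
        best: tuple[float, list[str], TrainingComplex] | None = None
        for pos in iface_positions:
            for new_type in all_types:
                if new_type == types_a[pos]:
                    continue
                trial_types = list(types_a)
                trial_types[pos] = new_type
                trial = _generate(spec, n_iface, gap, types_a=trial_types)
                dist = abs(patch_score(trial.interface.patch_a, table) - mid)
                if best is None or dist < best[0]:
                    best = (dist, trial_types, trial)
        if best is None or best[0] >= abs(score - mid) - 1e-12:
            break  # no substitution improves; bin unreachable from here
        _, types_a, current = best
    score = patch_score(current.interface.patch_a, table)
    if lo <= score <= hi:
        return current
    raise FixtureError(f"could not reach target bin [{lo}, {hi}] (best score {score:.3f})")


def make_dataset(
    n_complexes: int,
    seed: int,
    n_residues: int = 40,
    interface_range: tuple[int, int] = (60, 300),
) -> list[TrainingComplex]:
    """A seeded batch of fixtures with varied interface sizes.

    Interface sizes are drawn uniformly from ``interface_range`` so the
    cumulative patch-score distributions span a realistic spread (real
    interfaces vary several-fold in buried-contact count).
    """
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n_complexes)
    sizes = rng.integers(interface_range[0], interface_range[1] + 1, size=n_complexes)
    return [
        make_synthetic_complex(
            FixtureSpec(seed=int(s), n_residues=n_residues, interface_size=int(k))
        )
        for s, k in zip(child_seeds, sizes)
    ]
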