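"""Shared builders and fixtures for the test suite.

Everything is generated programmatically; no structure files on disk.
"""

from __future__ import annotations

import numpy as np
import pytest

from yappis.fixtures import FixtureSpec, make_synthetic_complex
from yappis.pdb_io import AtomRecord, Chain, Residue, vdw_radius
from yappis.scales import PropensityTable, _ATOM_COUNTS, load_scale
from yappis.pdb_io import STANDARD_RESIDUES


def make_atom(
    serial: int,
    xyz,
    chain_id: str = "A",
    residue_seq: int = 1,
    residue_type: str = "GLY",
    name: str | None = None,
    element: str = "C",
) -> AtomRecord:
    return AtomRecord(
        serial=serial,
        name=name or f"X{serial}",
        element=element,
        residue_type=residue_type,
        residue_seq=residue_seq,
        chain_id=chain_id,
        coords=tuple(float(v) for v in xyz),
        vdw_radius=vdw_radius(element),
    )


def point_chain(chain_id: str, coords, elements=None, residue_type: str = "GLY") -> Chain:
    """A chain of single-atom residues at the given coordinates (each atom
    its own residue, convenient for geometric tests)."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    elements = elements or ["C"] * len(coords)
    base = 1 if chain_id == "A" else 100001
    residues = [
        Residue(
            residue_type,
            i + 1,
            "",
            (
                make_atom(
                    base + i, xyz, chain_id=chain_id, residue_seq=i + 1,
                    residue_type=residue_type, name="CA", element=elem,
                ),
            ),
        )
        for i, (xyz, elem) in enumerate(zip(coords, elements))
    ]
    return Chain(chain_id, residues)


def flat_table(scale_name: str = "rip", value: float = 1.0, **overrides) -> PropensityTable:
    """A propensity table assigning `value` to every residue type, with
    optional per-residue overrides."""
    per_residue = {r: value for r in STANDARD_RESIDUES}
    per_residue.update({k.upper(): v for k, v in overrides.items()})
    return PropensityTable(scale_name, per_residue, _ATOM_COUNTS)


@pytest.fixture(scope="session")
def hydro_table() -> PropensityTable:
    return load_scale("hydrophobicity")


@pytest.fixture(scope="session")
def solv_table() -> PropensityTable:
    return load_scale("solvation")


@pytest.fixture(scope="session")
def small_complex():
    """A compact synthetic two-chain complex with a demarcated interface."""
    return make_synthetic_complex(FixtureSpec(seed=11, n_residues=16, interface_size=20))


@pytest.fixture(scope="session")
def default_complex():
    return make_synthetic_complex(FixtureSpec(seed=7))
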