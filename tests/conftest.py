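"""Shared builders for the test suite.

All structural fixtures are generated programmatically; nothing is read
from disk except files the tests themselves write.
"""

from __future__ import annotations

import numpy as np
import pytest

from tcrlike import synthetic_data as sd
from tcrlike.structure_model import (
    AnnotatedComplex,
    Atom,
    Chain,
    ChainRole,
    ImmunoglobulinClass,
    Residue,
    ResidueKey,
    assign_regions,
)


def make_residue(chain_id, num, name, atoms, imgt=None, mhc=None, icode=""):
    """atoms: list of (atom_name, element, (x, y, z))."""
    key = ResidueKey(chain_id, num, icode, imgt, mhc)
    return Residue(key, name, [Atom.create(n, e, p) for n, e, p in atoms])


def make_complex(chain_specs, ig_class=ImmunoglobulinClass.TCRM, mhc_class="I",
                 complex_id="toy"):
    """chain_specs: list of (chain_id, role, residues)."""
    chains = {
        cid: Chain(cid, role, residues) for cid, role, residues in chain_specs
    }
    return AnnotatedComplex(complex_id, chains, ig_class, mhc_class)


def random_rotation(rng) -> np.ndarray:
    """Uniform random rotation matrix from a seeded generator."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


@pytest.fixture(scope="session")
def groove_complex():
    """Canonical 45° groove fixture with three occluded peptide positions."""
    spec = sd.GrooveFixtureSpec(occluded_peptide_positions=frozenset({2, 4, 6}))
    cx, annotation = sd.make_groove_complex(spec)
    return cx, annotation, spec


@pytest.fixture(scope="session")
def groove_regions(groove_complex):
    cx, _, _ = groove_complex
    return assign_regions(cx)
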