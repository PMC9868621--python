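"""Pinned numerical conventions and chemistry tables.

Everything a rerun must hold fixed to reproduce numbers lives here:
van der Waals radii, CDR windows on the IMGT scale, MHC helix windows on
the renumbered MHC scale, and the geometric criteria used to type
interface contacts. All of these are plain module-level constants or
dataclasses that callers may copy and override.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

# ---------------------------------------------------------------------------
# van der Waals radii (Å), heavy atoms only.
#
# Complexes are profiled hydrogen-free, so only the four elements that occur
# in protein heavy atoms are tabulated. An element missing from the table is
# an error, never a silent default.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
}

#: Water probe radius for solvent-accessible surface area (Å).
DEFAULT_PROBE_RADIUS: float = 1.4

#: Default number of quasi-uniform sphere points per atom (golden spiral).
DEFAULT_N_SPHERE_POINTS: int = 960

#: ΔSASA below this (Å²) is treated as lattice noise, not burial.
BURIAL_EPSILON: float = 0.01

# ---------------------------------------------------------------------------
# CDR windows on the IMGT numbering scale (inclusive bounds). Identical for
# heavy/light and beta/alpha chains — that symmetry is the point of IMGT.
CDR_WINDOWS: dict[str, tuple[int, int]] = {
    "CDR1": (27, 38),
    "CDR2": (56, 65),
    "CDR3": (105, 117),
}

# ---------------------------------------------------------------------------
# MHC helix windows on the renumbered (class-I-style) MHC scale.


@dataclass(frozen=True)
class MhcHelixWindows:
    """Residue windows delimiting the groove-flanking helices.

    For class I both helices lie on the α chain. For class II the α1-style
    helix lies on the α chain and the α2-style helix on the β chain; the
    same window container is reused with ``alpha2_on_beta=True``.
    """

    alpha1: tuple[int, int] = (50, 86)
    alpha2: tuple[int, int] = (138, 176)
    alpha2_on_beta: bool = False

    def with_windows(self, alpha1=None, alpha2=None) -> "MhcHelixWindows":
        return replace(
            self,
            alpha1=alpha1 or self.alpha1,
            alpha2=alpha2 or self.alpha2,
        )


CLASS_I_HELIX_WINDOWS = MhcHelixWindows()
CLASS_II_HELIX_WINDOWS = MhcHelixWindows(
    alpha1=(46, 78), alpha2=(54, 91), alpha2_on_beta=True
)

# ---------------------------------------------------------------------------
# Interface contact criteria (heavy-atom geometric definitions).


@dataclass(frozen=True)
class ContactCriteria:
    """Distance/angle cutoffs used to type interface atom contacts.

    The defaults are this package's own documented conventions; users
    aiming to match an external contact-typing tool can override any
    cutoff, or import that tool's output instead of recomputing.
    """

    hydrophobic_cutoff: float = 4.5  # apolar C ... apolar C, Å
    aromatic_centroid_cutoff: float = 5.0  # ring centroid distance, Å
    hbond_cutoff: float = 3.5  # donor heavy atom ... acceptor, Å
    hbond_min_angle: float = 90.0  # antecedent-donor-acceptor, degrees
    salt_bridge_cutoff: float = 4.0  # charged N/O pair, Å
    histidine_positive: bool = True  # treat His as protonatable cation


DEFAULT_CONTACT_CRITERIA = ContactCriteria()

# Side-chain chemistry tables, keyed by residue name then atom name.
# Backbone donors/acceptors (N with antecedent CA; carbonyl O) are handled
# uniformly in code and are not listed here.

#: Side-chain carbons considered polarised (bonded to N/O/S) and therefore
#: excluded from hydrophobic contact detection. Backbone C is always polar.
POLAR_CARBONS: dict[str, frozenset[str]] = {
    "ARG": frozenset({"CZ"}),
    "ASN": frozenset({"CG"}),
    "ASP": frozenset({"CG"}),
    "GLN": frozenset({"CD"}),
    "GLU": frozenset({"CD"}),
    "HIS": frozenset({"CG", "CD2", "CE1"}),  # imidazole carbons
    "LYS": frozenset({"CE"}),
    "MET": frozenset({"CG", "CE"}),
    "SER": frozenset({"CB"}),
    "THR": frozenset({"CB"}),
    "TRP": frozenset({"CD1", "CE2"}),  # pyrrole-adjacent
    "TYR": frozenset({"CZ"}),
    "CYS": frozenset({"CB"}),
}

#: Aromatic ring atoms used for centroid-based aromatic contact detection.
RING_ATOMS: dict[str, tuple[str, ...]] = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}

#: Side-chain hydrogen-bond donors mapped to their antecedent heavy atom.
SIDECHAIN_DONORS: dict[str, dict[str, str]] = {
    "ARG": {"NE": "CD", "NH1": "CZ", "NH2": "CZ"},
    "ASN": {"ND2": "CG"},
    "GLN": {"NE2": "CD"},
    "HIS": {"ND1": "CG", "NE2": "CD2"},
    "LYS": {"NZ": "CE"},
    "SER": {"OG": "CB"},
    "THR": {"OG1": "CB"},
    "TRP": {"NE1": "CD1"},
    "TYR": {"OH": "CZ"},
    "CYS": {"SG": "CB"},
}

#: Side-chain hydrogen-bond acceptors.
SIDECHAIN_ACCEPTORS: dict[str, frozenset[str]] = {
    "ASP": frozenset({"OD1", "OD2"}),
    "GLU": frozenset({"OE1", "OE2"}),
    "ASN": frozenset({"OD1"}),
    "GLN": frozenset({"OE1"}),
    "SER": frozenset({"OG"}),
    "THR": frozenset({"OG1"}),
    "TYR": frozenset({"OH"}),
    "HIS": frozenset({"ND1", "NE2"}),
    "MET": frozenset({"SD"}),
}

#: Negatively charged (carboxylate) side-chain oxygens.
ANION_ATOMS: dict[str, frozenset[str]] = {
    "ASP": frozenset({"OD1", "OD2"}),
    "GLU": frozenset({"OE1", "OE2"}),
}

#: Positively charged side-chain nitrogens (His optional, see criteria).
CATION_ATOMS: dict[str, frozenset[str]] = {
    "LYS": frozenset({"NZ"}),
    "ARG": frozenset({"NE", "NH1", "NH2"}),
    "HIS": frozenset({"ND1", "NE2"}),
}

# ---------------------------------------------------------------------------
# Binding-energy hotspot thresholds (kcal/mol; attractive is negative).
HOTSPOT_THRESHOLD: float = -7.0
SEMI_HOTSPOT_THRESHOLD: float = -4.0

# ---------------------------------------------------------------------------
# Dataset curation defaults.
DEFAULT_MAX_RESOLUTION: float = 2.5  # Å, X-ray only
DEFAULT_IDENTITY_THRESHOLD: float = 0.8
DEFAULT_ANTIGEN_MIN_COVERAGE: float = 0.2
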