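"""Interface interaction typing and residue-level consolidation.

Atom contacts across the immunoglobulin:antigen interface are typed
geometrically (heavy atoms only) into the four attractive classes —
hydrophobic, aromatic, hydrogen bond and salt bridge — using the pinned
criteria in :mod:`tcrlike.config`. Weak (angle-violating) hydrogen
bonds are never emitted. Atom-level contacts are then consolidated into
residue-pair interactions:

1. multiple hydrophobic atom contacts between two residues collapse to
   one hydrophobic interaction;
2. likewise for aromatic contacts;
3. a residue pair may carry both a hydrophobic and an aromatic
   interaction (they have distinct electrostatic origins);
4. among salt-bridge candidates, each charged side chain participates
   in at most one salt bridge — the candidate residue pair with the
   closest atom–atom distance wins it (tie broken by lexicographically
   smaller pair), and all displaced candidates are recorded as
   hydrogen bonds.

Contacts produced by an external typing tool can be imported from a
TSV instead of being recomputed; consolidation is identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from . import config
from .structure_model import (
    ANTIGEN_ROLES,
    IMMUNOGLOBULIN_ROLES,
    AnnotatedComplex,
    RegionLabel,
    ResidueKey,
)

logger = logging.getLogger(__name__)

HYDROPHOBIC = "hydrophobic"
AROMATIC = "aromatic"
HYDROGEN_BOND = "hydrogen_bond"
SALT_BRIDGE = "salt_bridge"
SALT_BRIDGE_CANDIDATE = "salt_bridge_candidate"

INTERACTION_TYPES = (HYDROPHOBIC, AROMATIC, HYDROGEN_BOND, SALT_BRIDGE)


@dataclass(frozen=True)
class AtomContact:
    """One typed atom–atom (or ring–ring) contact across the interface."""

    res_a: ResidueKey  # immunoglobulin side
    atom_a: str
    res_b: ResidueKey  # antigen side
    atom_b: str
    distance: float
    contact_types: frozenset[str]

    def __post_init__(self):
        if self.distance <= 0:
            raise ValueError("contact distance must be positive")
        if not self.contact_types:
            raise ValueError("contact must carry at least one type")


@dataclass
class InteractionProfile:
    """Consolidated residue-pair interactions of one complex."""

    residue_pair_interactions: dict[tuple[ResidueKey, ResidueKey], set[str]] = field(
        default_factory=dict
    )

    def total_interactions(self) -> int:
        """Number of (residue pair, type) entries.

        A pair carrying both a hydrophobic and an aromatic interaction
        contributes two, reflecting their distinct physical origins.
        """
        return sum(len(types) for types in self.residue_pair_interactions.values())

    def pairs_with_type(self, itype: str):
        return [
            pair
            for pair, types in self.residue_pair_interactions.items()
            if itype in types
        ]


# ---------------------------------------------------------------------------
# Geometric contact detection


def _is_apolar_carbon(res_name: str, atom_name: str, element: str) -> bool:
    if element != "C" or atom_name in ("C", "CA"):
        return False  # backbone carbonyl C and CA are polarised
    return atom_name not in config.POLAR_CARBONS.get(res_name, frozenset())


def _donors(residue) -> list[tuple[str, str]]:
    """(donor atom, antecedent atom) pairs present in the residue."""
    out = []
    if residue.atom("N") is not None and residue.atom("CA") is not None:
        out.append(("N", "CA"))
    for donor, antecedent in config.SIDECHAIN_DONORS.get(residue.name, {}).items():
        if residue.atom(donor) is not None and residue.atom(antecedent) is not None:
            out.append((donor, antecedent))
    return out


def _acceptors(residue) -> list[str]:
    out = [n for n in ("O", "OXT") if residue.atom(n) is not None]
    for name in config.SIDECHAIN_ACCEPTORS.get(residue.name, frozenset()):
        if residue.atom(name) is not None:
            out.append(name)
    return out


def _charged_atoms(residue, criteria: config.ContactCriteria):
    anion = [
        n for n in config.ANION_ATOMS.get(residue.name, frozenset()) if residue.atom(n)
    ]
    cations = config.CATION_ATOMS.get(residue.name, frozenset())
    if residue.name == "HIS" and not criteria.histidine_positive:
        cations = frozenset()
    cation = [n for n in cations if residue.atom(n)]
    return anion, cation


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle at vertex b (degrees)."""
    u, v = a - b, c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def detect_atom_contacts(
    cx: AnnotatedComplex,
    criteria: config.ContactCriteria = config.DEFAULT_CONTACT_CRITERIA,
) -> list[AtomContact]:
    """Type all atom contacts between the immunoglobulin and antigen sides."""
    side_a = [
        (res, atom)
        for res in cx.iter_residues(IMMUNOGLOBULIN_ROLES)
        for atom in res.atoms
    ]
    side_b = [
        (res, atom) for res in cx.iter_residues(ANTIGEN_ROLES) for atom in res.atoms
    ]
    if not side_a or not side_b:
        return []

    res_a_by_key = {res.key: res for res, _ in side_a}
    res_b_by_key = {res.key: res for res, _ in side_b}

    pos_a = np.array([a.position for _, a in side_a])
    pos_b = np.array([a.position for _, a in side_b])
    max_cut = max(
        criteria.hydrophobic_cutoff, criteria.hbond_cutoff, criteria.salt_bridge_cutoff
    )
    pairs = cKDTree(pos_a).query_ball_tree(cKDTree(pos_b), max_cut)

    contacts: list[AtomContact] = []
    for i, js in enumerate(pairs):
        res_i, atom_i = side_a[i]
        for j in js:
            res_j, atom_j = side_b[j]
            d = float(np.linalg.norm(atom_i.position - atom_j.position))
            if d <= 0:
                continue
            types = set()
            if (
                d <= criteria.hydrophobic_cutoff
                and _is_apolar_carbon(res_i.name, atom_i.name, atom_i.element)
                and _is_apolar_carbon(res_j.name, atom_j.name, atom_j.element)
            ):
                types.add(HYDROPHOBIC)
            if d <= criteria.hbond_cutoff:
                if _hbond_geometry_ok(res_i, atom_i, res_j, atom_j, criteria):
                    types.add(HYDROGEN_BOND)
            if d <= criteria.salt_bridge_cutoff:
                an_i, cat_i = _charged_atoms(res_i, criteria)
                an_j, cat_j = _charged_atoms(res_j, criteria)
                if (atom_i.name in an_i and atom_j.name in cat_j) or (
                    atom_i.name in cat_i and atom_j.name in an_j
                ):
                    types.add(SALT_BRIDGE_CANDIDATE)
            if types:
                contacts.append(
                    AtomContact(
                        res_i.key, atom_i.name, res_j.key, atom_j.name, d,
                        frozenset(types),
                    )
                )

    contacts.extend(_aromatic_contacts(res_a_by_key, res_b_by_key, criteria))
    return contacts


def _hbond_geometry_ok(res_i, atom_i, res_j, atom_j, criteria) -> bool:
    """Donor→acceptor in either direction, with the antecedent angle check.

    Hydrogen-free criterion: the angle antecedent–donor–acceptor must be
    at least ``hbond_min_angle``; anything tighter would imply the
    (implicit) hydrogen pointing away from the acceptor — those weak
    assignments are discarded.
    """
    for donor_res, donor_atom, acc_res, acc_atom in (
        (res_i, atom_i, res_j, atom_j),
        (res_j, atom_j, res_i, atom_i),
    ):
        for dname, antecedent in _donors(donor_res):
            if dname != donor_atom.name:
                continue
            if acc_atom.name not in _acceptors(acc_res):
                continue
            ang = _angle_deg(
                donor_res.atom(antecedent).position,
                donor_atom.position,
                acc_atom.position,
            )
            if ang >= criteria.hbond_min_angle:
                return True
    return False


def _aromatic_contacts(res_a_by_key, res_b_by_key, criteria) -> list[AtomContact]:
    def centroids(res_by_key):
        out = {}
        for key, res in res_by_key.items():
            names = config.RING_ATOMS.get(res.name)
            if not names:
                continue
            pts = [res.atom(n).position for n in names if res.atom(n)]
            if len(pts) >= 3:
                out[key] = (np.mean(pts, axis=0), names[0])
        return out

    cent_a, cent_b = centroids(res_a_by_key), centroids(res_b_by_key)
    contacts = []
    for key_a, (ca, rep_a) in cent_a.items():
        for key_b, (cb, rep_b) in cent_b.items():
            d = float(np.linalg.norm(ca - cb))
            if 0 < d <= criteria.aromatic_centroid_cutoff:
                contacts.append(
                    AtomContact(key_a, rep_a, key_b, rep_b, d, frozenset({AROMATIC}))
                )
    return contacts


# ---------------------------------------------------------------------------
# External contact import

EXTERNAL_CONTACT_COLUMNS = (
    "chain_a resnum_a icode_a atom_a chain_b resnum_b icode_b atom_b "
    "distance types"
).split()


def read_contacts_tsv(path) -> list[AtomContact]:
    """Import externally produced atom contacts.

    Tab-separated columns: chain_a, resnum_a, icode_a ('.' for none),
    atom_a, chain_b, resnum_b, icode_b, atom_b, distance (Å), types
    (comma-separated subset of hydrophobic, aromatic, hydrogen_bond,
    salt_bridge_candidate). A header row is permitted.
    """
    contacts = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#") or line.startswith("chain_a"):
            continue
        parts = line.split("\t")
        if len(parts) != 10:
            raise ValueError(f"{path}:{lineno}: expected 10 columns")
        ic_a = "" if parts[2] == "." else parts[2]
        ic_b = "" if parts[6] == "." else parts[6]
        contacts.append(
            AtomContact(
                ResidueKey(parts[0], int(parts[1]), ic_a),
                parts[3],
                ResidueKey(parts[4], int(parts[5]), ic_b),
                parts[7],
                float(parts[8]),
                frozenset(parts[9].split(",")),
            )
        )
    return contacts


# ---------------------------------------------------------------------------
# Consolidation


def consolidate(contacts: list[AtomContact]) -> InteractionProfile:
    """Collapse atom contacts into residue-pair interactions (rules 1–4)."""
    pair_types: dict[tuple[ResidueKey, ResidueKey], set[str]] = {}

    def add(pair, itype):
        pair_types.setdefault(pair, set()).add(itype)

    # candidate salt bridges: closest atom pair per residue pair
    sb_best: dict[tuple[ResidueKey, ResidueKey], float] = {}

    for c in contacts:
        pair = (c.res_a, c.res_b)
        for itype in c.contact_types:
            if itype == SALT_BRIDGE_CANDIDATE:
                if pair not in sb_best or c.distance < sb_best[pair]:
                    sb_best[pair] = c.distance
            elif itype == SALT_BRIDGE:
                add(pair, SALT_BRIDGE)  # pre-resolved external input
            elif itype == HYDROGEN_BOND and SALT_BRIDGE_CANDIDATE in c.contact_types:
                # ambiguous charged polar contact: resolved by rule 4 into
                # either the salt bridge or a hydrogen bond, never both
                continue
            else:
                add(pair, itype)

    # rule 4: one salt bridge per charged side chain; closest pair wins
    used: set[ResidueKey] = set()
    ordered = sorted(
        sb_best.items(), key=lambda kv: (kv[1], str(kv[0][0]), str(kv[0][1]))
    )
    for pair, dist in ordered:
        if pair[0] in used or pair[1] in used:
            add(pair, HYDROGEN_BOND)
            logger.debug("salt-bridge candidate %s demoted to hydrogen bond", pair)
        else:
            add(pair, SALT_BRIDGE)
            # the winning pair's candidate contact is the salt bridge itself,
            # not an additional hydrogen bond
            used.update(pair)

    return InteractionProfile(pair_types)


def expand(profile: InteractionProfile) -> list[AtomContact]:
    """Re-expand a profile into one synthetic contact per (pair, type).

    Useful for idempotence checks: consolidating the expansion must
    reproduce the profile.
    """
    out = []
    for (ra, rb), types in profile.residue_pair_interactions.items():
        for itype in types:
            out.append(AtomContact(ra, "X1", rb, "X2", 3.0, frozenset({itype})))
    return out


# ---------------------------------------------------------------------------
# Summaries


@dataclass
class InteractionSummary:
    """Peptide/MHC-resolved interaction counts for one pMHC complex."""

    n_peptide_residues_contacted: int
    n_ig_residues_contacting_peptide: int
    n_ig_peptide_interactions: int
    n_ig_mhc_interactions: int
    n_vdj_cdr3_mhc_interactions: int
    total_interactions: int
    type_counts: dict[str, int]


def interaction_summary(
    profile: InteractionProfile,
    regions: dict[ResidueKey, RegionLabel],
    vdj_chain_id: str | None = None,
) -> InteractionSummary:
    """Count interactions split by peptide vs MHC and by CDR3 of the VDJ chain.

    ``regions`` must cover every residue appearing in the profile; the
    immunoglobulin side is identified as residues whose labels are CDR or
    framework, the antigen side by peptide/MHC labels.
    """
    mhc_labels = {
        RegionLabel.MHC_A1_HELIX,
        RegionLabel.MHC_A2_HELIX,
        RegionLabel.MHC_OTHER,
    }
    pep_residues, ig_to_pep = set(), set()
    n_pep = n_mhc = n_cdr3_mhc = 0
    type_counts = {t: 0 for t in INTERACTION_TYPES}
    for (res_ig, res_ag), types in profile.residue_pair_interactions.items():
        ag_label = regions[res_ag]
        for t in types:
            type_counts[t] += 1
        if ag_label is RegionLabel.PEPTIDE:
            pep_residues.add(res_ag)
            ig_to_pep.add(res_ig)
            n_pep += len(types)
        elif ag_label in mhc_labels:
            n_mhc += len(types)
            if (
                regions[res_ig] is RegionLabel.CDR3
                and (vdj_chain_id is None or res_ig.chain_id == vdj_chain_id)
            ):
                n_cdr3_mhc += len(types)
    return InteractionSummary(
        n_peptide_residues_contacted=len(pep_residues),
        n_ig_residues_contacting_peptide=len(ig_to_pep),
        n_ig_peptide_interactions=n_pep,
        n_ig_mhc_interactions=n_mhc,
        n_vdj_cdr3_mhc_interactions=n_cdr3_mhc,
        total_interactions=profile.total_interactions(),
        type_counts=type_counts,
    )
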