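"""Contact typing criteria and residue-level consolidation rules."""

import numpy as np
import pytest

from conftest import make_complex, make_residue

from tcrlike import config
from tcrlike.interactions import (
    AROMATIC,
    HYDROGEN_BOND,
    HYDROPHOBIC,
    SALT_BRIDGE,
    SALT_BRIDGE_CANDIDATE,
    AtomContact,
    consolidate,
    detect_atom_contacts,
    expand,
    interaction_summary,
    read_contacts_tsv,
)
from tcrlike.structure_model import (
    ChainRole,
    RegionLabel,
    ResidueKey,
    assign_regions,
)


def pairwise_complex(ig_residues, ag_residues, ag_role=ChainRole.PEPTIDE):
    far_l = make_residue("L", 1, "ALA", [("CA", "C", (200, 200, 200))], imgt=1)
    return make_complex(
        [("H", ChainRole.HEAVY, ig_residues),
         ("L", ChainRole.LIGHT, [far_l]),
         ("X", ag_role, ag_residues)]
    )


def contact_types(contacts, atom_a=None, atom_b=None):
    out = set()
    for c in contacts:
        if atom_a and c.atom_a != atom_a:
            continue
        if atom_b and c.atom_b != atom_b:
            continue
        out |= c.contact_types
    return out


class TestDetectAtomContacts:
    def test_apolar_carbons_within_cutoff_are_hydrophobic(self):
        leu = make_residue("H", 30, "LEU", [("CD1", "C", (0, 0, 0))], imgt=30)
        val = make_residue("X", 1, "VAL", [("CG1", "C", (4.0, 0, 0))])
        contacts = detect_atom_contacts(pairwise_complex([leu], [val]))
        assert contact_types(contacts) == {HYDROPHOBIC}

    def test_beyond_all_cutoffs_nothing_recorded(self):
        a = make_residue("H", 30, "ALA",
                         [("N", "N", (0, 0, 0)), ("CA", "C", (1.5, 0, 0))],
                         imgt=30)
        b = make_residue("X", 1, "ALA", [("O", "O", (8.0, 0, 0))])
        assert detect_atom_contacts(pairwise_complex([a], [b])) == []

    def test_charged_pair_is_candidate_and_hydrogen_bond(self):
        arg = make_residue(
            "H", 56, "ARG",
            [("CZ", "C", (0, 0, 0)), ("NE", "N", (-1.3, 0, 0)),
             ("NH1", "N", (0.65, 1.1, 0)), ("NH2", "N", (0.65, -1.1, 0)),
             ("CD", "C", (-2.3, 1.0, 0))],
            imgt=56,
        )
        asp = make_residue(
            "X", 1, "ASP",
            [("CG", "C", (4.0, 2.0, 0)), ("OD1", "O", (3.4, 1.5, 1.0)),
             ("OD2", "O", (3.85, 1.1, 0))],
        )
        contacts = detect_atom_contacts(pairwise_complex([arg], [asp]))
        types = contact_types(contacts, atom_a="NH1")
        assert SALT_BRIDGE_CANDIDATE in types
        assert HYDROGEN_BOND in types

    def test_weak_hydrogen_bond_angle_rejected(self):
        # acceptor behind the donor's antecedent: angle << 90 degrees
        ser = make_residue(
            "H", 30, "SER",
            [("CB", "C", (1.4, 0, 0)), ("OG", "O", (0.0, 0, 0))],
            imgt=30,
        )
        carbonyl = make_residue("X", 1, "GLY", [("O", "O", (2.8, 0.4, 0))])
        contacts = detect_atom_contacts(pairwise_complex([ser], [carbonyl]))
        assert HYDROGEN_BOND not in contact_types(contacts)

    def test_aromatic_ring_centroid_contact(self):
        ring = [("CG", "C", (0, 0, 0)), ("CD1", "C", (1.4, 0, 0)),
                ("CD2", "C", (-0.7, 1.2, 0)), ("CE1", "C", (2.1, 1.2, 0)),
                ("CE2", "C", (0.0, 2.4, 0)), ("CZ", "C", (1.4, 2.4, 0))]
        phe_a = make_residue("H", 107, "PHE", ring, imgt=107)
        phe_b = make_residue(
            "X", 1, "PHE", [(n, e, (x, y, z + 4.0)) for n, e, (x, y, z) in ring]
        )
        contacts = detect_atom_contacts(pairwise_complex([phe_a], [phe_b]))
        assert AROMATIC in contact_types(contacts)

    def test_histidine_cation_configurable(self):
        his = make_residue(
            "H", 56, "HIS",
            [("CG", "C", (0, 0, 0)), ("ND1", "N", (1.3, 0.5, 0)),
             ("CD2", "C", (-0.5, 1.2, 0)), ("CE1", "C", (1.9, 1.7, 0)),
             ("NE2", "N", (0.7, 2.3, 0))],
            imgt=56,
        )
        glu = make_residue(
            "X", 1, "GLU",
            [("CD", "C", (4.6, 0.5, 0)), ("OE1", "O", (4.0, 0.5, 1.0)),
             ("OE2", "O", (4.3, 0.5, -1.0))],
        )
        on = detect_atom_contacts(pairwise_complex([his], [glu]))
        assert SALT_BRIDGE_CANDIDATE in contact_types(on)
        neutral = config.ContactCriteria(histidine_positive=False)
        off = detect_atom_contacts(pairwise_complex([his], [glu]), neutral)
        assert SALT_BRIDGE_CANDIDATE not in contact_types(off)


def rk(chain, num):
    return ResidueKey(chain, num)


class TestConsolidate:
    def test_multiple_hydrophobic_contacts_collapse_to_one(self):
        contacts = [
            AtomContact(rk("H", 1), f"C{i}", rk("P", 1), f"C{i}", 4.0,
                        frozenset({HYDROPHOBIC}))
            for i in range(5)
        ]
        profile = consolidate(contacts)
        assert profile.residue_pair_interactions == {
            (rk("H", 1), rk("P", 1)): {HYDROPHOBIC}
        }
        assert profile.total_interactions() == 1

    def test_pair_may_carry_both_hydrophobic_and_aromatic(self):
        contacts = [
            AtomContact(rk("H", 1), "CD1", rk("P", 1), "CD1", 4.0,
                        frozenset({HYDROPHOBIC})),
            AtomContact(rk("H", 1), "CG", rk("P", 1), "CG", 4.5,
                        frozenset({AROMATIC})),
        ]
        profile = consolidate(contacts)
        assert profile.residue_pair_interactions[(rk("H", 1), rk("P", 1))] == {
            HYDROPHOBIC, AROMATIC
        }
        assert profile.total_interactions() == 2

    def test_salt_bridge_goes_to_closest_pair_others_become_hbonds(self):
        """One Asp courted by two Args: 2.9 Å pair wins the salt bridge."""
        contacts = [
            AtomContact(rk("H", 1), "NH1", rk("P", 5), "OD1", 2.9,
                        frozenset({SALT_BRIDGE_CANDIDATE, HYDROGEN_BOND})),
            AtomContact(rk("H", 9), "NH2", rk("P", 5), "OD2", 3.4,
                        frozenset({SALT_BRIDGE_CANDIDATE, HYDROGEN_BOND})),
        ]
        profile = consolidate(contacts)
        pairs = profile.residue_pair_interactions
        assert pairs[(rk("H", 1), rk("P", 5))] == {SALT_BRIDGE}
        assert pairs[(rk("H", 9), rk("P", 5))] == {HYDROGEN_BOND}

    def test_closest_distance_tie_broken_lexicographically(self):
        contacts = [
            AtomContact(rk("H", 2), "NZ", rk("P", 5), "OD1", 3.0,
                        frozenset({SALT_BRIDGE_CANDIDATE})),
            AtomContact(rk("H", 1), "NZ", rk("P", 5), "OD2", 3.0,
                        frozenset({SALT_BRIDGE_CANDIDATE})),
        ]
        pairs = consolidate(contacts).residue_pair_interactions
        assert pairs[(rk("H", 1), rk("P", 5))] == {SALT_BRIDGE}
        assert pairs[(rk("H", 2), rk("P", 5))] == {HYDROGEN_BOND}

    def test_empty_contact_list_gives_empty_profile(self):
        assert consolidate([]).residue_pair_interactions == {}

    def test_consolidation_idempotent_through_expansion(self):
        contacts = [
            AtomContact(rk("H", 1), "NH1", rk("P", 5), "OD1", 2.9,
                        frozenset({SALT_BRIDGE_CANDIDATE})),
            AtomContact(rk("H", 9), "NH2", rk("P", 5), "OD2", 3.4,
                        frozenset({SALT_BRIDGE_CANDIDATE})),
            AtomContact(rk("H", 1), "CB", rk("P", 2), "CB", 4.1,
                        frozenset({HYDROPHOBIC})),
            AtomContact(rk("H", 1), "CG", rk("P", 2), "CG1", 4.2,
                        frozenset({HYDROPHOBIC})),
        ]
        once = consolidate(contacts)
        twice = consolidate(expand(once))
        assert twice.residue_pair_interactions == once.residue_pair_interactions

    def test_salt_bridge_uniqueness_per_charge_group_random_fixtures(self):
        """However candidates are tangled, each charged residue ends up in
        at most one salt bridge and every candidate pair is resolved."""
        rng = np.random.default_rng(21)
        for _ in range(50):
            n_pos, n_neg = rng.integers(1, 5, size=2)
            contacts = []
            for i in range(n_pos):
                for j in range(n_neg):
                    if rng.random() < 0.6:
                        contacts.append(
                            AtomContact(
                                rk("H", int(i)), "NZ", rk("P", int(j)), "OD1",
                                float(rng.uniform(2.6, 4.0)),
                                frozenset({SALT_BRIDGE_CANDIDATE}),
                            )
                        )
            profile = consolidate(contacts)
            seen = set()
            for (ra, rb), types in profile.residue_pair_interactions.items():
                assert types <= {SALT_BRIDGE, HYDROGEN_BOND}
                if SALT_BRIDGE in types:
                    assert ra not in seen and rb not in seen
                    seen.update((ra, rb))
            n_resolved = sum(
                len(t) for t in profile.residue_pair_interactions.values()
            )
            assert n_resolved == len({(c.res_a, c.res_b) for c in contacts})


class TestInteractionSummary:
    def _regions(self):
        return {
            rk("H", 107): RegionLabel.CDR3,
            rk("H", 30): RegionLabel.CDR1,
            rk("L", 107): RegionLabel.CDR3,
            rk("P", 1): RegionLabel.PEPTIDE,
            rk("P", 2): RegionLabel.PEPTIDE,
            rk("M", 60): RegionLabel.MHC_A1_HELIX,
            rk("M", 150): RegionLabel.MHC_A2_HELIX,
        }

    def test_mhc_only_profile_has_zero_peptide_counts(self):
        contacts = [
            AtomContact(rk("H", 107), "CB", rk("M", 60), "CB", 4.0,
                        frozenset({HYDROPHOBIC})),
            AtomContact(rk("H", 30), "N", rk("M", 150), "O", 3.0,
                        frozenset({HYDROGEN_BOND})),
        ]
        summary = interaction_summary(consolidate(contacts), self._regions(), "H")
        assert summary.n_peptide_residues_contacted == 0
        assert summary.n_ig_peptide_interactions == 0
        assert summary.n_ig_mhc_interactions == summary.total_interactions == 2

    def test_cdr3_and_peptide_bookkeeping(self):
        contacts = [
            AtomContact(rk("H", 107), "CB", rk("P", 1), "CB", 4.0,
                        frozenset({HYDROPHOBIC})),
            AtomContact(rk("H", 30), "N", rk("P", 2), "O", 3.0,
                        frozenset({HYDROGEN_BOND})),
            AtomContact(rk("L", 107), "CB", rk("P", 2), "CB", 4.2,
                        frozenset({HYDROPHOBIC})),
            AtomContact(rk("H", 107), "CB", rk("M", 60), "CB", 4.1,
                        frozenset({HYDROPHOBIC})),
            AtomContact(rk("H", 107), "N", rk("M", 60), "O", 3.1,
                        frozenset({HYDROGEN_BOND})),
        ]
        summary = interaction_summary(consolidate(contacts), self._regions(), "H")
        assert summary.n_peptide_residues_contacted == 2
        assert summary.n_ig_residues_contacting_peptide == 3
        assert summary.n_ig_peptide_interactions == 3
        assert summary.n_ig_mhc_interactions == 2
        assert summary.n_vdj_cdr3_mhc_interactions == 2
        assert summary.total_interactions == 5

    def test_total_equals_pair_type_cardinality(self):
        profile = consolidate([
            AtomContact(rk("H", 107), "CB", rk("P", 1), "CB", 4.0,
                        frozenset({HYDROPHOBIC})),
            AtomContact(rk("H", 107), "CG", rk("P", 1), "CG", 4.5,
                        frozenset({AROMATIC})),
            AtomContact(rk("L", 107), "N", rk("M", 60), "O", 3.2,
                        frozenset({HYDROGEN_BOND})),
        ])
        summary = interaction_summary(profile, self._regions(), "H")
        assert summary.total_interactions == sum(
            len(t) for t in profile.residue_pair_interactions.values()
        ) == 3


class TestExternalContacts:
    def test_round_trip_and_consolidation(self, tmp_path):
        path = tmp_path / "contacts.tsv"
        path.write_text(
            "chain_a\tresnum_a\ticode_a\tatom_a\tchain_b\tresnum_b\ticode_b"
            "\tatom_b\tdistance\ttypes\n"
            "H\t107\t.\tNH1\tP\t5\t.\tOD1\t2.9\tsalt_bridge_candidate,hydrogen_bond\n"
            "H\t107\t.\tCB\tP\t2\t.\tCB\t4.1\thydrophobic\n"
        )
        contacts = read_contacts_tsv(path)
        assert len(contacts) == 2
        profile = consolidate(contacts)
        assert profile.residue_pair_interactions[(rk("H", 107), rk("P", 5))] == {
            SALT_BRIDGE
        }
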