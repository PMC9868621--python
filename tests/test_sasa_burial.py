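"""Shrake–Rupley numerics and interface burial decomposition."""

import numpy as np
import pytest

from conftest import make_complex, make_residue

from tcrlike import synthetic_data as sd
from tcrlike.errors import TcrlikeError
from tcrlike.sasa_burial import (
    BurialProfile,
    burial_profile,
    cdr_fraction,
    complex_sasa,
    shrake_rupley,
    shrake_rupley_atoms,
    sphere_points,
)
from tcrlike.structure_model import (
    ChainRole,
    ResidueKey,
    assign_regions,
)


def dense_sampling_sasa(positions, radii, probe, n_samples=100_000, seed=0):
    """Independent oracle: random-direction sampling + all-pairs occlusion."""
    rng = np.random.default_rng(seed)
    directions = rng.normal(size=(n_samples, 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    expanded = np.asarray(radii, float) + probe
    out = np.zeros(len(positions))
    for i in range(len(positions)):
        pts = positions[i] + expanded[i] * directions
        accessible = np.ones(n_samples, dtype=bool)
        for j in range(len(positions)):
            if j == i:
                continue
            accessible &= (
                np.linalg.norm(pts - positions[j], axis=1) >= expanded[j]
            )
        out[i] = 4 * np.pi * expanded[i] ** 2 * accessible.mean()
    return out


class TestSpherePoints:
    def test_unit_norm_and_count(self):
        pts = sphere_points(960)
        assert pts.shape == (960, 3)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)

    def test_quasi_uniform_centroid_near_origin(self):
        assert np.linalg.norm(sphere_points(960).mean(axis=0)) < 1e-2


class TestShrakeRupley:
    def test_isolated_carbon_matches_analytic_sphere(self):
        area = shrake_rupley_atoms(
            np.array([[0.0, 0.0, 0.0]]), np.array([1.70]), 1.4, 960
        )[0]
        exact = 4 * np.pi * (1.70 + 1.4) ** 2
        assert area == pytest.approx(exact, rel=0.005)

    def test_fully_engulfed_atom_has_zero_area(self):
        # tiny sphere at the centre of a much larger one
        positions = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 0.5]])
        radii = np.array([8.0, 1.52])
        areas = shrake_rupley_atoms(positions, radii, 1.4, 960)
        assert areas[1] == 0.0

    def test_three_atom_triangle_matches_dense_oracle(self):
        positions = np.array(
            [[0.0, 0.0, 0.0], [3.2, 0.0, 0.0], [1.6, 2.6, 0.3]]
        )
        radii = np.array([1.70, 1.55, 1.52])
        ours = shrake_rupley_atoms(positions, radii, 1.4, 960)
        oracle = dense_sampling_sasa(positions, radii, 1.4)
        assert ours == pytest.approx(oracle, rel=0.02)

    def test_sampling_converged_at_default_point_count(self):
        rng = np.random.default_rng(4)
        positions = rng.uniform(0, 8, size=(12, 3))
        radii = np.full(12, 1.70)
        coarse = shrake_rupley_atoms(positions, radii, 1.4, 960).sum()
        fine = shrake_rupley_atoms(positions, radii, 1.4, 3840).sum()
        assert coarse == pytest.approx(fine, rel=0.01)

    def test_neighbor_search_identical_to_all_pairs(self):
        """The tree-pruned occlusion test must equal brute-force all-pairs."""
        rng = np.random.default_rng(9)
        positions = rng.uniform(0, 15, size=(30, 3))
        radii = rng.choice([1.52, 1.55, 1.70, 1.80], size=30)
        ours = shrake_rupley_atoms(positions, radii, 1.4, 240)
        unit = sphere_points(240)
        expanded = radii + 1.4
        brute = np.zeros(30)
        for i in range(30):
            pts = positions[i] + expanded[i] * unit
            blocked = np.zeros(240, dtype=bool)
            for j in range(30):
                if j != i:
                    blocked |= (
                        np.linalg.norm(pts - positions[j], axis=1) < expanded[j]
                    )
            brute[i] = 4 * np.pi * expanded[i] ** 2 * (~blocked).mean()
        assert np.allclose(ours, brute, atol=1e-9)

    def test_unknown_radius_refused_upstream(self):
        with pytest.raises(ValueError):
            shrake_rupley([], n_points=10)

    def test_residue_sums_equal_total(self):
        pairs = [
            (ResidueKey("A", 1), make_residue("A", 1, "ALA",
             [("CA", "C", (0, 0, 0)), ("CB", "C", (1.5, 0, 0))]).atoms),
            (ResidueKey("A", 2), make_residue("A", 2, "GLY",
             [("CA", "C", (3.8, 0, 0))]).atoms),
        ]
        result = shrake_rupley(pairs, n_points=240)
        assert sum(result.per_residue_sasa.values()) == pytest.approx(
            result.per_atom_sasa.sum()
        )


def two_sided_complex(ig_atoms, ag_atoms):
    ig = [make_residue("H", i + 1, "ALA", [a], imgt=i + 1)
          for i, a in enumerate(ig_atoms)]
    ag = [make_residue("P", i + 1, "ALA", [a]) for i, a in enumerate(ag_atoms)]
    return make_complex(
        [("H", ChainRole.HEAVY, ig), ("L", ChainRole.LIGHT,
          [make_residue("L", 1, "ALA", [("CA", "C", (90, 90, 90))], imgt=1)]),
         ("P", ChainRole.PEPTIDE, ag)]
    )


class TestBurialProfile:
    def test_distant_partners_have_zero_bsa(self):
        cx = two_sided_complex(
            [("CA", "C", (0.0, 0.0, 0.0))], [("CA", "C", (100.0, 0.0, 0.0))]
        )
        profile = burial_profile(cx, assign_regions(cx), n_points=240)
        assert profile.interface_bsa == 0.0
        assert all(d == 0.0 for d in profile.per_residue_delta.values())

    def test_symmetric_contact_buries_both_sides_equally(self):
        cx = two_sided_complex(
            [("CA", "C", (0.0, 0.0, 0.0))], [("CA", "C", (4.0, 0.0, 0.0))]
        )
        profile = burial_profile(cx, assign_regions(cx), n_points=960)
        assert profile.immunoglobulin_bsa == pytest.approx(
            profile.antigen_bsa, rel=0.02
        )
        assert profile.interface_bsa == pytest.approx(
            profile.immunoglobulin_bsa + profile.antigen_bsa
        )

    def test_monotonicity_partner_atoms_never_increase_sasa(self, groove_complex):
        cx, _, _ = groove_complex
        holo = complex_sasa(cx, None, n_points=240)
        for roles in (
            {ChainRole.HEAVY, ChainRole.LIGHT},
            {ChainRole.MHC_ALPHA, ChainRole.PEPTIDE},
        ):
            apo = complex_sasa(cx, roles, n_points=240)
            for key, area in apo.per_residue_sasa.items():
                assert area >= holo.per_residue_sasa[key] - 1e-9

    def test_planted_occlusion_count_recovered(self, groove_complex, groove_regions):
        cx, _, spec = groove_complex
        profile = burial_profile(cx, groove_regions, n_points=960)
        buried = sorted(
            k.seq_number
            for k, d in profile.per_residue_delta.items()
            if k.chain_id == "P" and d > profile.burial_epsilon
        )
        assert buried == sorted(spec.occluded_peptide_positions)
        assert profile.buried_peptide_residue_count == len(
            spec.occluded_peptide_positions
        )

    def test_pmhc_split_sums_to_antigen_bsa(self, groove_complex, groove_regions):
        cx, _, _ = groove_complex
        profile = burial_profile(cx, groove_regions, n_points=240)
        assert profile.peptide_bsa + profile.mhc_bsa == pytest.approx(
            profile.antigen_bsa
        )
        assert 0.0 <= profile.peptide_fraction <= 1.0

    def test_missing_partner_rejected(self, groove_complex):
        cx, _, _ = groove_complex
        half = make_complex(
            [("H", ChainRole.HEAVY, cx.chains["H"].residues),
             ("L", ChainRole.LIGHT, cx.chains["L"].residues)]
        )
        with pytest.raises(TcrlikeError):
            burial_profile(half, {}, n_points=60)


class TestCdrFraction:
    def test_loop_with_no_burial_contributes_zero(self, groove_complex, groove_regions):
        cx, _, _ = groove_complex
        profile = burial_profile(cx, groove_regions, n_points=240)
        assert cdr_fraction(profile, cx, groove_regions, "H", "CDR1") == 0.0

    def test_all_interface_on_one_loop_gives_one(self):
        # single buried ig residue sitting in CDR3
        ig = [make_residue("H", 107, "ALA", [("CA", "C", (0.0, 0.0, 0.0))], imgt=107)]
        lg = [make_residue("L", 107, "ALA", [("CA", "C", (90, 0, 0))], imgt=107)]
        ag = [make_residue("P", 1, "ALA", [("CA", "C", (4.0, 0.0, 0.0))])]
        cx = make_complex(
            [("H", ChainRole.HEAVY, ig), ("L", ChainRole.LIGHT, lg),
             ("P", ChainRole.PEPTIDE, ag)]
        )
        regions = assign_regions(cx)
        profile = burial_profile(cx, regions, n_points=240)
        assert cdr_fraction(profile, cx, regions, "H", "CDR3") == pytest.approx(1.0)
        assert cdr_fraction(
            profile, cx, regions, "H", "CDR3", denominator="cdr3_pair"
        ) == pytest.approx(1.0)

    def test_known_split_between_cdr3_loops(self):
        """30/70 ΔSASA split between the two CDR3 loops is reported exactly."""
        delta = {
            ResidueKey("H", 107, "", 107): 30.0,
            ResidueKey("L", 107, "", 107): 70.0,
        }
        profile = BurialProfile(
            per_residue_delta=delta, interface_bsa=200.0,
            immunoglobulin_bsa=100.0, antigen_bsa=100.0,
            peptide_bsa=None, mhc_bsa=None,
            cdr3_pair_fractions={"H": 0.3, "L": 0.7},
        )
        ig = [make_residue("H", 107, "ALA", [("CA", "C", (0, 0, 0))], imgt=107)]
        lg = [make_residue("L", 107, "ALA", [("CA", "C", (9, 0, 0))], imgt=107)]
        ag = [make_residue("P", 1, "ALA", [("CA", "C", (4, 0, 0))])]
        cx = make_complex(
            [("H", ChainRole.HEAVY, ig), ("L", ChainRole.LIGHT, lg),
             ("P", ChainRole.PEPTIDE, ag)]
        )
        regions = assign_regions(cx)
        assert cdr_fraction(
            profile, cx, regions, "H", "CDR3", denominator="cdr3_pair"
        ) == pytest.approx(0.3)
        assert cdr_fraction(profile, cx, regions, "H", "CDR3") == pytest.approx(0.3)

    def test_zero_denominator_flagged(self):
        profile = BurialProfile(
            per_residue_delta={}, interface_bsa=0.0, immunoglobulin_bsa=0.0,
            antigen_bsa=0.0, peptide_bsa=None, mhc_bsa=None,
        )
        ig = [make_residue("H", 107, "ALA", [("CA", "C", (0, 0, 0))], imgt=107)]
        ag = [make_residue("P", 1, "ALA", [("CA", "C", (50, 0, 0))])]
        cx = make_complex(
            [("H", ChainRole.HEAVY, ig), ("L", ChainRole.LIGHT,
              [make_residue("L", 1, "ALA", [("CA", "C", (99, 0, 0))], imgt=1)]),
             ("P", ChainRole.PEPTIDE, ag)]
        )
        with pytest.raises(TcrlikeError, match="denominator"):
            cdr_fraction(profile, cx, assign_regions(cx), "H", "CDR3")
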