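"""Deterministic synthetic fixtures for every pipeline stage.

Three generators emulate the data the pipeline consumes, at the coarse
resolution the geometric code paths require (Cα plus pseudo-side-chain
atoms — deliberately not physically realistic folds):

* :func:`make_groove_complex` — an idealized class-I-style groove (two
  coarse helices flanking an extended peptide) plus a two-domain binder
  placed at a requested docking angle, polarity and elevation, whose
  occluder atoms bury exactly a requested set of peptide positions;
* :func:`make_decomp_table` — per-residue binding-energy tables with a
  truncated-Gaussian attractive background and exactly planted
  hotspots, on the same groove layout;
* :func:`make_sequence_set` — planted-cluster sequence sets with
  controlled within/between pairwise identities for exercising the
  greedy clustering.

Every generator is a pure function of (spec, seed); randomness flows
only through a numpy PCG64 generator seeded from the spec.

Fixture geometry (groove frame: z = 0 plane, groove axis = +x):

* α1-style helix: renumbered residues 50–86, a coarse spiral of Cα/CB
  atoms running N→C along +x at y = +groove_width/2;
* α2-style helix: residues 138–176 running antiparallel (N→C along −x)
  at y = −groove_width/2;
* peptide: extended chain along +x at y = z = 0, Cα spacing 3.8 Å;
* binder: two pseudo-domains at the requested elevation whose conserved
  IMGT-23/104 cysteine Cα midpoints sit exactly at the domain centres,
  so the constructed docking angle is recovered analytically. Occluder
  nitrogen atoms, owned by CDR3 residues of the binder, hover 5 Å above
  each requested peptide Cα — close enough to shadow that residue, far
  enough (by the sphere-overlap margin) to leave its neighbours' solvent
  shells untouched.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.stats import truncnorm

from . import config, energetics
from .errors import FixtureError
from .structure_model import (
    AnnotatedComplex,
    Atom,
    Chain,
    ChainAnnotation,
    ChainRole,
    ImmunoglobulinClass,
    RegionLabel,
    Residue,
    ResidueKey,
    annotation_of,
    write_pdb,
    write_sidecar,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}

#: Default ninemer used for groove fixtures (a well-known tumour antigen).
DEFAULT_PEPTIDE = "RMFPNAPYL"


# ---------------------------------------------------------------------------
# groove fixture


@dataclass(frozen=True)
class GrooveFixtureSpec:
    peptide_length: int = 9
    peptide_sequence: Optional[str] = None  # overrides length when given
    helix_rise: float = 1.5  # Å per residue along the groove axis
    groove_width: float = 18.0  # Å between helix axes
    docking_angle: float = 45.0  # degrees, [0, 180)
    polarity: str = "CANONICAL"  # CANONICAL | REVERSE
    elevation: float = 16.0  # Å of the domain centres above the groove plane
    inter_domain_distance: float = 20.0  # Å between the two domain centres
    occluded_peptide_positions: frozenset[int] = frozenset()  # 1-based
    immunoglobulin_class: ImmunoglobulinClass = ImmunoglobulinClass.TCRM
    arginine_tilt: Optional[float] = None  # plant Arg65 guanidino at this tilt
    seed: int = 0

    def __post_init__(self):
        seq = self.peptide_sequence
        n = len(seq) if seq else self.peptide_length
        if not 8 <= n <= 15:
            raise FixtureError(f"peptide length {n} outside [8, 15]")
        if not 0.0 <= self.docking_angle < 180.0:
            raise FixtureError(f"docking angle {self.docking_angle} outside [0, 180)")
        if self.polarity not in ("CANONICAL", "REVERSE"):
            raise FixtureError(f"unknown polarity {self.polarity!r}")
        bad = [p for p in self.occluded_peptide_positions if not 1 <= p <= n]
        if bad:
            raise FixtureError(f"occluded positions {bad} outside peptide 1..{n}")

    @property
    def resolved_peptide(self) -> str:
        if self.peptide_sequence:
            return self.peptide_sequence
        seq = DEFAULT_PEPTIDE
        return (seq * 2)[: self.peptide_length]


_HELIX_RADIUS = 2.3  # Å, coarse Cα spiral radius
_HELIX_TWIST = np.radians(100.0)  # per residue
_OCCLUDER_HEIGHT = 5.0  # Å above the target peptide Cα (see module docs)


def _helix_chain_residues(
    numbers, start_xyz, direction, rise, phase0=0.0
) -> list[Residue]:
    """Coarse helix: Cα on a spiral about an axis, CB pushed outward."""
    residues = []
    axis = np.asarray(direction, float)
    # local frame perpendicular to the axis (axis is ±x in fixture space)
    perp1, perp2 = np.array([0.0, 1.0, 0.0]), np.array([0.0, 0.0, 1.0])
    for i, num in enumerate(numbers):
        t = phase0 + i * _HELIX_TWIST
        ca = (
            np.asarray(start_xyz, float)
            + axis * (i * rise)
            + _HELIX_RADIUS * (np.cos(t) * perp1 + np.sin(t) * perp2)
        )
        cb = ca + 1.0 * (np.cos(t) * perp1 + np.sin(t) * perp2)
        key = ResidueKey("M", num, "", None, num)
        residues.append(
            Residue(
                key,
                "ALA",
                [Atom.create("CA", "C", ca), Atom.create("CB", "C", cb)],
            )
        )
    return residues


def _domain_residues(
    chain_id: str, centre: np.ndarray, ring_phase: float
) -> list[Residue]:
    """A pseudo variable domain: conserved Cys pair about the centre plus a
    framework ring. The Cys23/Cys104 Cα midpoint is exactly ``centre``."""
    residues = []
    for imgt, offset in ((23, np.array([0.0, 0.0, 2.0])), (104, np.array([0.0, 0.0, -2.0]))):
        key = ResidueKey(chain_id, imgt, "", imgt, None)
        residues.append(
            Residue(key, "CYS", [Atom.create("CA", "C", centre + offset)])
        )
    ring_imgt = (20, 21, 22, 24, 25, 100, 101, 103)
    for j, imgt in enumerate(ring_imgt):
        ang = ring_phase + 2 * np.pi * j / len(ring_imgt)
        pos = centre + 4.0 * np.array([np.cos(ang), np.sin(ang), 0.0])
        key = ResidueKey(chain_id, imgt, "", imgt, None)
        residues.append(Residue(key, "ALA", [Atom.create("CA", "C", pos)]))
    return sorted(residues, key=lambda r: r.key.seq_number)


def make_groove_complex(spec: GrooveFixtureSpec) -> tuple[AnnotatedComplex, ChainAnnotation]:
    """Build the idealized groove complex described in the module docs.

    Returns the in-memory complex together with its sidecar annotation;
    :func:`write_groove_fixture` serialises both to disk.
    """
    rng = np.random.default_rng(spec.seed)
    peptide_seq = spec.resolved_peptide
    n_pep = len(peptide_seq)
    w = spec.groove_width / 2.0
    rise = spec.helix_rise

    a1_numbers = list(range(config.CLASS_I_HELIX_WINDOWS.alpha1[0],
                            config.CLASS_I_HELIX_WINDOWS.alpha1[1] + 1))
    a2_numbers = list(range(config.CLASS_I_HELIX_WINDOWS.alpha2[0],
                            config.CLASS_I_HELIX_WINDOWS.alpha2[1] + 1))
    a1_len = (len(a1_numbers) - 1) * rise
    a2_len = (len(a2_numbers) - 1) * rise
    # α1 runs N→C along +x at +y; α2 antiparallel at −y
    mhc_residues = _helix_chain_residues(
        a1_numbers, (-a1_len / 2.0, +w, 0.0), (1.0, 0.0, 0.0), rise
    ) + _helix_chain_residues(
        a2_numbers, (+a2_len / 2.0, -w, 0.0), (-1.0, 0.0, 0.0), rise,
        phase0=np.pi,
    )

    if spec.arginine_tilt is not None:
        mhc_residues = [r for r in mhc_residues if r.key.seq_number != 65]
        mhc_residues.append(_planted_arginine(65, spec.arginine_tilt, w))
        mhc_residues.sort(key=lambda r: r.key.seq_number)

    pep_spacing = 3.8
    pep_residues = []
    for i, letter in enumerate(peptide_seq, start=1):
        x = (i - (n_pep + 1) / 2.0) * pep_spacing
        key = ResidueKey("P", i, "", None, None)
        pep_residues.append(
            Residue(key, _THREE[letter], [Atom.create("CA", "C", (x, 0.0, 0.0))])
        )

    # binder domains: VJ→VDJ axis at angle φ in the elevated plane, where
    # φ = +angle gives canonical polarity (VDJ over α1 at +y) and −angle
    # gives reverse.
    if spec.immunoglobulin_class is ImmunoglobulinClass.TCR:
        vdj_id, vj_id = "B", "A"
        vdj_role, vj_role = ChainRole.TCR_BETA, ChainRole.TCR_ALPHA
    else:
        vdj_id, vj_id = "H", "L"
        vdj_role, vj_role = ChainRole.HEAVY, ChainRole.LIGHT
    phi = np.radians(
        spec.docking_angle if spec.polarity == "CANONICAL" else -spec.docking_angle
    )
    u = np.array([np.cos(phi), np.sin(phi), 0.0])
    mid = np.array([0.0, 0.0, spec.elevation])
    half = spec.inter_domain_distance / 2.0
    vdj_centre = mid + half * u
    vj_centre = mid - half * u
    vdj_res = _domain_residues(vdj_id, vdj_centre, float(rng.uniform(0, 2 * np.pi)))
    vj_res = _domain_residues(vj_id, vj_centre, float(rng.uniform(0, 2 * np.pi)))

    # occluders: one CDR3 residue per requested peptide position
    occluded = sorted(spec.occluded_peptide_positions)
    cdr3_numbers = list(range(105, 118))
    if len(occluded) > 2 * len(cdr3_numbers):
        raise FixtureError("more occluded positions than available CDR3 residues")
    for j, pos in enumerate(occluded):
        chain_id = vdj_id if j < len(cdr3_numbers) else vj_id
        imgt = cdr3_numbers[j % len(cdr3_numbers)]
        target = pep_residues[pos - 1].atom("CA").position
        site = target + np.array([0.0, 0.0, _OCCLUDER_HEIGHT])
        key = ResidueKey(chain_id, imgt, "", imgt, None)
        res = Residue(key, "ALA", [Atom.create("N", "N", site)])
        (vdj_res if chain_id == vdj_id else vj_res).append(res)
    vdj_res.sort(key=lambda r: r.key.seq_number)
    vj_res.sort(key=lambda r: r.key.seq_number)

    chains = {
        vdj_id: Chain(vdj_id, vdj_role, vdj_res),
        vj_id: Chain(vj_id, vj_role, vj_res),
        "M": Chain("M", ChainRole.MHC_ALPHA, mhc_residues),
        "P": Chain("P", ChainRole.PEPTIDE, pep_residues),
    }
    cx = AnnotatedComplex(
        complex_id=f"groove-{spec.seed}",
        chains=chains,
        immunoglobulin_class=spec.immunoglobulin_class,
        mhc_class="I",
    )
    return cx, annotation_of(cx)


def _planted_arginine(mhc_number: int, tilt_deg: float, y_offset: float) -> Residue:
    """An arginine whose guanidino plane is tilted ``tilt_deg`` degrees
    away from the groove plane (rotation about the groove axis)."""
    tau = np.radians(tilt_deg)
    base = np.array([0.0, y_offset - 4.0, 2.0])  # protrudes into the groove
    # in-plane basis before tilt: e1 along x, e2 along y; tilt rotates e2
    e1 = np.array([1.0, 0.0, 0.0])
    e2 = np.array([0.0, np.cos(tau), np.sin(tau)])
    cz = base
    ne = base - 1.3 * e1
    nh1 = base + 1.3 * np.cos(np.radians(60)) * e1 + 1.3 * np.sin(np.radians(60)) * e2
    nh2 = base + 1.3 * np.cos(np.radians(60)) * e1 - 1.3 * np.sin(np.radians(60)) * e2
    ca = base - 2.0 * e1 - np.array([0.0, -1.5, 0.0])
    key = ResidueKey("M", mhc_number, "", None, mhc_number)
    return Residue(
        key,
        "ARG",
        [
            Atom.create("CA", "C", ca),
            Atom.create("NE", "N", ne),
            Atom.create("CZ", "C", cz),
            Atom.create("NH1", "N", nh1),
            Atom.create("NH2", "N", nh2),
        ],
    )


def write_groove_fixture(spec: GrooveFixtureSpec, out_dir) -> tuple[Path, Path]:
    """Emit PDB + sidecar for a groove fixture; returns their paths."""
    cx, annotation = make_groove_complex(spec)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pdb_path = out / f"{cx.complex_id}.pdb"
    sidecar_path = out / f"{cx.complex_id}.sidecar.tsv"
    write_pdb(cx, pdb_path)
    write_sidecar(annotation, sidecar_path)
    return pdb_path, sidecar_path


# ---------------------------------------------------------------------------
# decomposition-table fixture


@dataclass(frozen=True)
class DecompFixtureSpec:
    """Planted-hotspot energy table on the groove layout.

    ``hotspot_positions`` maps region names ("peptide", "alpha1",
    "alpha2") to residue numbers (1-based peptide position, or the
    renumbered-MHC number for the helices).
    """

    peptide_length: int = 9
    hotspot_positions: tuple[tuple[str, int], ...] = ()
    hotspot_energy: float = -8.0
    background_mean: float = -1.0
    background_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.hotspot_positions and self.hotspot_energy > config.HOTSPOT_THRESHOLD:
            raise FixtureError(
                f"hotspot energy {self.hotspot_energy} weaker than the "
                f"{config.HOTSPOT_THRESHOLD} kcal/mol hotspot threshold"
            )
        if self.background_sd <= 0:
            raise FixtureError("background sd must be positive")


def decomp_layout_regions(peptide_length: int = 9) -> dict[ResidueKey, RegionLabel]:
    """Region map of the pMHC side of the groove layout."""
    regions = {}
    for i in range(1, peptide_length + 1):
        regions[ResidueKey("P", i)] = RegionLabel.PEPTIDE
    lo, hi = config.CLASS_I_HELIX_WINDOWS.alpha1
    for n in range(lo, hi + 1):
        regions[ResidueKey("M", n)] = RegionLabel.MHC_A1_HELIX
    lo, hi = config.CLASS_I_HELIX_WINDOWS.alpha2
    for n in range(lo, hi + 1):
        regions[ResidueKey("M", n)] = RegionLabel.MHC_A2_HELIX
    return regions


def make_decomp_table(
    spec: DecompFixtureSpec,
) -> tuple[energetics.DecompTable, dict[ResidueKey, RegionLabel]]:
    """pMHC-side decomposition table with planted hotspots.

    Background energies are Gaussian truncated above zero (purely
    attractive noise); hotspot entries are exact. Bit-reproducible for a
    given seed.
    """
    rng = np.random.default_rng(spec.seed)
    regions = decomp_layout_regions(spec.peptide_length)
    keys = sorted(regions, key=lambda k: (k.chain_id, k.seq_number))
    a = (0.0 - spec.background_mean) / spec.background_sd  # upper bound at 0
    values = truncnorm.rvs(
        -np.inf, a, loc=spec.background_mean, scale=spec.background_sd,
        size=len(keys), random_state=rng,
    )
    entries = dict(zip(keys, map(float, values)))
    for region, num in spec.hotspot_positions:
        if region == "peptide":
            key = ResidueKey("P", num)
        elif region in ("alpha1", "alpha2"):
            key = ResidueKey("M", num)
        else:
            raise FixtureError(f"unknown hotspot region {region!r}")
        if key not in entries:
            raise FixtureError(f"hotspot position {region}:{num} outside layout")
        expected = {
            "peptide": RegionLabel.PEPTIDE,
            "alpha1": RegionLabel.MHC_A1_HELIX,
            "alpha2": RegionLabel.MHC_A2_HELIX,
        }[region]
        if regions[key] is not expected:
            raise FixtureError(f"position {num} is not in region {region}")
        entries[key] = spec.hotspot_energy
    table = energetics.DecompTable(entries, energetics.PMHC, f"decomp-{spec.seed}")
    return table, regions


def make_ig_decomp_table(
    loop_energies: dict[tuple[str, str], float],
    residues_per_loop: int = 3,
    seed: int = 0,
) -> tuple[energetics.DecompTable, dict[ResidueKey, RegionLabel]]:
    """Immunoglobulin-side table whose per-CDR sums are exactly as given.

    ``loop_energies`` maps (chain_id, CDR label) to the loop's total
    energy; each total is split across ``residues_per_loop`` residues by
    random (seeded) proportions.
    """
    rng = np.random.default_rng(seed)
    entries: dict[ResidueKey, float] = {}
    regions: dict[ResidueKey, RegionLabel] = {}
    for (chain_id, cdr), total in sorted(loop_energies.items()):
        lo, _hi = config.CDR_WINDOWS[cdr]
        weights = rng.dirichlet(np.ones(residues_per_loop))
        running = 0.0
        for j in range(residues_per_loop):
            key = ResidueKey(chain_id, lo + j, "", lo + j, None)
            if j < residues_per_loop - 1:
                value = float(total * weights[j])
                running += value
            else:
                value = total - running  # exact loop sum despite rounding
            entries[key] = value
            regions[key] = RegionLabel(cdr)
    table = energetics.DecompTable(entries, energetics.IMMUNOGLOBULIN, f"igdecomp-{seed}")
    return table, regions


# ---------------------------------------------------------------------------
# planted-cluster sequence sets


@dataclass(frozen=True)
class SequenceSetDesign:
    cluster_sizes: tuple[int, ...] = (1,)
    within_identity: float = 0.95
    between_identity: float = 0.40
    length: int = 100

    def __post_init__(self):
        if not self.cluster_sizes or any(s < 1 for s in self.cluster_sizes):
            raise FixtureError("cluster sizes must be positive")
        if not 0.0 < self.within_identity <= 1.0:
            raise FixtureError("within identity outside (0, 1]")
        if not 0.0 <= self.between_identity < self.within_identity:
            raise FixtureError("between identity must be below within identity")
        if len(self.cluster_sizes) > 19:
            raise FixtureError("at most 19 planted clusters supported")


def make_sequence_set(
    n: int, design: SequenceSetDesign, seed: int = 0
) -> tuple[dict[str, str], dict[str, int]]:
    """Random sequences with planted cluster structure.

    Pairwise identities hit the design targets to within a few
    percentage points: members of the same cluster share
    ``within_identity``, members of different clusters share
    ``between_identity``. Returns (sequences, true cluster labels).
    """
    if n != sum(design.cluster_sizes):
        raise FixtureError(
            f"n={n} does not match cluster sizes {design.cluster_sizes}"
        )
    rng = np.random.default_rng(seed)
    L = design.length
    m_between = round((1.0 - design.between_identity) * L)
    m_within = round((1.0 - design.within_identity) * L / 2.0)
    if m_within * max(design.cluster_sizes) > m_between and m_between > 0:
        raise FixtureError(
            "identity design infeasible: within-cluster mutations exceed the "
            "between-cluster divergent positions"
        )

    alphabet = np.array(list(AMINO_ACIDS))
    base = rng.choice(alphabet, size=L)
    divergent = rng.choice(L, size=m_between, replace=False)

    sequences: dict[str, str] = {}
    labels: dict[str, int] = {}
    for k, size in enumerate(design.cluster_sizes):
        ancestor = base.copy()
        for p in divergent:
            options = [c for c in AMINO_ACIDS if c != base[p]]
            ancestor[p] = options[k % len(options)]  # distinct letter per cluster
        # disjoint mutation blocks inside the divergent set keep
        # between-cluster identity untouched
        block_source = divergent if m_between else np.arange(L)
        perm = rng.permutation(block_source)
        for j in range(size):
            member = ancestor.copy()
            block = perm[j * m_within : (j + 1) * m_within]
            for p in block:
                options = [c for c in AMINO_ACIDS if c != ancestor[p]]
                member[p] = rng.choice(options)
            sid = f"c{k}_{j}"
            sequences[sid] = "".join(member)
            labels[sid] = k
    return sequences, labels
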