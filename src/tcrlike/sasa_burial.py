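"""Shrake–Rupley solvent-accessible surface area and interface burial.

SASA is computed with a deterministic golden-spiral point lattice on
each atom's probe-expanded sphere: a lattice point is accessible iff it
lies outside every other atom's expanded sphere, and the atom's SASA is
the accessible fraction of its expanded-sphere area. No random numbers
are involved, so results are bit-reproducible for a given point count.

Buried surface area (BSA) follows the apo-minus-complex convention:
each binding partner's SASA is recomputed with the other partner's
coordinates deleted, and ΔSASA = SASA(apo) − SASA(complex) per residue.
With a shared lattice this difference is non-negative by construction
(removing atoms can only unblock points). A residue counts as buried
when its ΔSASA exceeds a small epsilon that absorbs floating-point
noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from scipy.spatial import cKDTree

from . import config
from .errors import TcrlikeError
from .structure_model import (
    ANTIGEN_ROLES,
    IMMUNOGLOBULIN_ROLES,
    VDJ_ROLES,
    AnnotatedComplex,
    Atom,
    ChainRole,
    RegionLabel,
    ResidueKey,
)


def sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points on a golden-spiral lattice."""
    if n < 1:
        raise ValueError("need at least one sphere point")
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


@dataclass
class SasaResult:
    """Per-residue and per-atom solvent-accessible surface areas (Å²)."""

    per_residue_sasa: dict[ResidueKey, float]
    per_atom_sasa: np.ndarray
    probe_radius: float
    n_sphere_points: int

    @property
    def total(self) -> float:
        return float(sum(self.per_residue_sasa.values()))


def shrake_rupley_atoms(
    positions: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = config.DEFAULT_PROBE_RADIUS,
    n_points: int = config.DEFAULT_N_SPHERE_POINTS,
) -> np.ndarray:
    """Per-atom SASA for arbitrary spheres; the numerical core.

    Parameters
    ----------
    positions : (n, 3) float array, Å
    radii : (n,) float array of van der Waals radii, Å
    """
    positions = np.asarray(positions, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = len(positions)
    if n == 0:
        return np.zeros(0)
    unit = sphere_points(n_points)
    expanded = radii + probe_radius
    # any occluder's centre lies within r_i + r_j + 2*probe of atom i
    tree = cKDTree(positions)
    max_reach = expanded + expanded.max()
    out = np.zeros(n)
    for i in range(n):
        pts = positions[i] + expanded[i] * unit
        neighbors = [
            j for j in tree.query_ball_point(positions[i], max_reach[i]) if j != i
        ]
        if neighbors:
            nb = np.asarray(neighbors)
            d2 = ((pts[:, None, :] - positions[nb][None, :, :]) ** 2).sum(axis=2)
            blocked = (d2 < (expanded[nb] ** 2)[None, :]).any(axis=1)
            accessible = np.count_nonzero(~blocked)
        else:
            accessible = n_points
        out[i] = 4.0 * np.pi * expanded[i] ** 2 * accessible / n_points
    return out


def shrake_rupley(
    atoms_by_residue: Iterable[tuple[ResidueKey, list[Atom]]],
    probe_radius: float = config.DEFAULT_PROBE_RADIUS,
    n_points: int = config.DEFAULT_N_SPHERE_POINTS,
) -> SasaResult:
    """Shrake–Rupley SASA over residues given as (key, atoms) pairs."""
    if n_points < 60:
        raise ValueError("n_points must be >= 60 for a usable lattice")
    keys: list[ResidueKey] = []
    owner: list[int] = []
    positions: list[np.ndarray] = []
    radii: list[float] = []
    for idx, (key, atoms) in enumerate(atoms_by_residue):
        keys.append(key)
        for atom in atoms:
            owner.append(idx)
            positions.append(atom.position)
            radii.append(atom.vdw_radius)
    per_atom = shrake_rupley_atoms(
        np.array(positions).reshape(-1, 3), np.array(radii), probe_radius, n_points
    )
    per_residue = {k: 0.0 for k in keys}
    for area, idx in zip(per_atom, owner):
        per_residue[keys[idx]] += float(area)
    return SasaResult(per_residue, per_atom, probe_radius, n_points)


def complex_sasa(
    cx: AnnotatedComplex,
    roles=None,
    probe_radius: float = config.DEFAULT_PROBE_RADIUS,
    n_points: int = config.DEFAULT_N_SPHERE_POINTS,
) -> SasaResult:
    """SASA of a complex, optionally restricted to a subset of chain roles."""
    pairs = [(res.key, res.atoms) for res in cx.iter_residues(roles)]
    return shrake_rupley(pairs, probe_radius, n_points)


@dataclass
class BurialProfile:
    """Per-residue ΔSASA (apo − complex) with interface aggregates.

    ``region_fractions`` holds each CDR's share of the immunoglobulin
    BSA; ``cdr3_pair_fractions`` holds each CDR3's share of the combined
    CDR3 BSA of both chains, keyed by chain id.
    """

    per_residue_delta: dict[ResidueKey, float]
    interface_bsa: float
    immunoglobulin_bsa: float
    antigen_bsa: float
    peptide_bsa: Optional[float]
    mhc_bsa: Optional[float]
    region_fractions: dict[str, float] = field(default_factory=dict)
    cdr3_pair_fractions: dict[str, float] = field(default_factory=dict)
    buried_peptide_residue_count: Optional[int] = None
    peptide_fraction: Optional[float] = None
    burial_epsilon: float = config.BURIAL_EPSILON

    def buried_residues(self) -> list[ResidueKey]:
        return [
            k for k, d in self.per_residue_delta.items() if d > self.burial_epsilon
        ]


def burial_profile(
    cx: AnnotatedComplex,
    regions: dict[ResidueKey, RegionLabel],
    probe_radius: float = config.DEFAULT_PROBE_RADIUS,
    n_points: int = config.DEFAULT_N_SPHERE_POINTS,
    epsilon: float = config.BURIAL_EPSILON,
) -> BurialProfile:
    """Interface burial decomposition of one complex.

    Computes holo SASA, then each side's apo SASA with the partner's
    coordinates deleted, and aggregates ΔSASA into the interface totals,
    per-CDR fractions of immunoglobulin BSA, CDR3-pair fractions, the
    peptide/pMHC split, and the buried-peptide-residue count.
    """
    if not cx.immunoglobulin_chains or not cx.antigen_chains:
        raise TcrlikeError(f"{cx.complex_id}: both binding partners required")

    holo = complex_sasa(cx, None, probe_radius, n_points)
    apo_ig = complex_sasa(cx, IMMUNOGLOBULIN_ROLES, probe_radius, n_points)
    apo_ag = complex_sasa(cx, ANTIGEN_ROLES, probe_radius, n_points)

    delta: dict[ResidueKey, float] = {}
    for apo in (apo_ig, apo_ag):
        for key, area in apo.per_residue_sasa.items():
            delta[key] = max(0.0, area - holo.per_residue_sasa[key])

    role_of = {res.key: chain.role for chain in cx.chains.values() for res in chain.residues}
    chain_of = {k: k.chain_id for k in delta}

    ig_bsa = sum(d for k, d in delta.items() if role_of[k] in IMMUNOGLOBULIN_ROLES)
    ag_bsa = sum(d for k, d in delta.items() if role_of[k] in ANTIGEN_ROLES)

    pep_bsa = mhc_bsa = None
    buried_pep = None
    pep_fraction = None
    if cx.is_pmhc:
        pep_bsa = sum(d for k, d in delta.items() if role_of[k] is ChainRole.PEPTIDE)
        mhc_bsa = sum(
            d
            for k, d in delta.items()
            if role_of[k] in {ChainRole.MHC_ALPHA, ChainRole.MHC_BETA, ChainRole.B2M}
        )
        buried_pep = sum(
            1
            for k, d in delta.items()
            if role_of[k] is ChainRole.PEPTIDE and d > epsilon
        )
        denom = pep_bsa + mhc_bsa
        pep_fraction = pep_bsa / denom if denom > 0 else None

    region_fractions: dict[str, float] = {}
    if ig_bsa > 0:
        for cdr in ("CDR1", "CDR2", "CDR3"):
            for chain in cx.immunoglobulin_chains:
                loop_delta = sum(
                    delta.get(res.key, 0.0)
                    for res in chain.residues
                    if regions.get(res.key) is RegionLabel(cdr)
                )
                region_fractions[f"{chain.chain_id}:{cdr}"] = loop_delta / ig_bsa

    cdr3_pair: dict[str, float] = {}
    cdr3_by_chain = {
        chain.chain_id: sum(
            delta.get(res.key, 0.0)
            for res in chain.residues
            if regions.get(res.key) is RegionLabel.CDR3
        )
        for chain in cx.immunoglobulin_chains
    }
    cdr3_total = sum(cdr3_by_chain.values())
    if cdr3_total > 0:
        cdr3_pair = {cid: v / cdr3_total for cid, v in cdr3_by_chain.items()}

    return BurialProfile(
        per_residue_delta=delta,
        interface_bsa=ig_bsa + ag_bsa,
        immunoglobulin_bsa=ig_bsa,
        antigen_bsa=ag_bsa,
        peptide_bsa=pep_bsa,
        mhc_bsa=mhc_bsa,
        region_fractions=region_fractions,
        cdr3_pair_fractions=cdr3_pair,
        buried_peptide_residue_count=buried_pep,
        peptide_fraction=pep_fraction,
        burial_epsilon=epsilon,
    )


def cdr_fraction(
    profile: BurialProfile,
    cx: AnnotatedComplex,
    regions: dict[ResidueKey, RegionLabel],
    chain_id: str,
    cdr: str,
    denominator: str = "immunoglobulin",
) -> float:
    """Fractional contribution of one CDR loop to a burial denominator.

    ``denominator`` is ``"immunoglobulin"`` (loop ΔSASA over total
    immunoglobulin-side BSA) or ``"cdr3_pair"`` (loop ΔSASA over the
    combined CDR3 BSA of both chains; only meaningful for CDR3).
    """
    chain = cx.chains[chain_id]
    loop_delta = sum(
        profile.per_residue_delta.get(res.key, 0.0)
        for res in chain.residues
        if regions.get(res.key) is RegionLabel(cdr)
    )
    if denominator == "immunoglobulin":
        denom = profile.immunoglobulin_bsa
    elif denominator == "cdr3_pair":
        denom = sum(
            profile.per_residue_delta.get(res.key, 0.0)
            for ch in cx.immunoglobulin_chains
            for res in ch.residues
            if regions.get(res.key) is RegionLabel.CDR3
        )
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom <= 0:
        raise TcrlikeError(
            f"{cx.complex_id}: zero burial denominator for {chain_id}:{cdr}"
        )
    return loop_delta / denom


def vdj_cdr3_share(profile: BurialProfile, cx: AnnotatedComplex) -> Optional[float]:
    """CDRH3 (or CDRB3) share of the CDR3-pair BSA, if defined."""
    for chain in cx.immunoglobulin_chains:
        if chain.role in VDJ_ROLES and chain.chain_id in profile.cdr3_pair_fractions:
            return profile.cdr3_pair_fractions[chain.chain_id]
    return None
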