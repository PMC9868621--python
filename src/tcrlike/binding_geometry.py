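"""Docking geometry: groove frame, crossing angle, polarity, guanidino tilt.

The peptide-binding groove defines a natural frame: its long axis
(oriented N→C along the peptide) and the best-fit plane through the
groove-flanking helix Cα atoms. The docking (crossing) angle of a
binder is the in-plane angle between the groove axis and the line
joining the conserved disulfide midpoints of its two variable domains
(Cα of the IMGT-23 and IMGT-104 cysteine positions), measured from the
VJ-recombined domain towards the VDJ-recombined domain. Projection onto
the helix plane makes the angle well-defined for binders approaching at
any elevation.

With this orientation convention, canonically docking TCRs fall in the
diagonal ~45° band and polarity-reversed binders near 180° minus that;
swapping the VDJ/VJ labels of a fixed structure maps θ to 180° − θ.
Polarity itself is classified positionally: a binder is CANONICAL when
its VDJ-chain domain centre sits over the C-terminal half of the MHC α1
helix and the VJ-chain domain over the C-terminal half of the α2 helix,
and REVERSE otherwise.

All quantities derive from inter-atom geometry only, so they are exactly
invariant under rigid-body transformation of the whole complex.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import config
from .errors import DegenerateGeometryError
from .structure_model import (
    VDJ_ROLES,
    VJ_ROLES,
    AnnotatedComplex,
    Chain,
    ChainRole,
    RegionLabel,
    ResidueKey,
)

#: IMGT positions of the conserved intradomain disulfide cysteines.
CONSERVED_CYS_IMGT = (23, 104)


@dataclass(frozen=True)
class GrooveFrame:
    """Groove axis, origin, and helix-plane normal (all unit/Å)."""

    axis: np.ndarray
    origin: np.ndarray
    helix_plane_normal: np.ndarray


@dataclass
class GeometryReport:
    docking_angle: float  # degrees, [0, 180)
    polarity: str  # "CANONICAL" | "REVERSE"
    diagonal: Optional[bool]
    guanidino_tilt: Optional[float] = None  # degrees, [0, 90]


# ---------------------------------------------------------------------------
# helpers


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise DegenerateGeometryError("zero-length vector")
    return v / n


def _principal_axis(points: np.ndarray) -> np.ndarray:
    """Dominant direction of a point cloud (largest-variance eigenvector)."""
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[0]


def _plane_normal(points: np.ndarray) -> np.ndarray:
    """Least-squares plane normal (smallest-variance eigenvector)."""
    if len(points) < 3:
        raise DegenerateGeometryError("plane fit needs >= 3 points")
    centered = points - points.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-6:  # points collinear: plane undefined
        raise DegenerateGeometryError("plane fit degenerate: points collinear")
    return vt[2]


def _helix_ca(cx: AnnotatedComplex, label: RegionLabel, regions) -> list[np.ndarray]:
    pts = []
    for chain in cx.chains_with_role({ChainRole.MHC_ALPHA, ChainRole.MHC_BETA}):
        for res in chain.residues:
            if regions.get(res.key) is label and res.atom("CA"):
                pts.append(res.atom("CA").position)
    return pts


def _peptide_direction(cx: AnnotatedComplex) -> np.ndarray:
    pep = cx.peptide_chain
    if pep is None:
        raise DegenerateGeometryError("no peptide chain: cannot orient groove axis")
    cas = pep.ca_positions()
    if len(cas) < 2:
        raise DegenerateGeometryError("peptide has < 2 Cα atoms")
    return cas[-1] - cas[0]


# ---------------------------------------------------------------------------
# groove frame


def groove_frame(
    cx: AnnotatedComplex,
    regions: dict[ResidueKey, RegionLabel],
    mode: str = "helix_axis",
    anchor_positions: tuple[int, int] = (2, -1),
) -> GrooveFrame:
    """Construct the groove frame from MHC helices or peptide anchors.

    ``helix_axis`` mode takes the principal axis of the Cα atoms of both
    helix windows; ``anchor_ca`` mode takes the vector through the Cα
    atoms of the peptide anchor residues (by default position 2 and the
    C-terminal residue, the class-I anchors). The axis is oriented along
    the peptide N→C direction. The helix-plane normal is the best-fit
    plane through the Cα atoms of both helix windows (configurable to a
    single window by editing the region map).
    """
    a1 = _helix_ca(cx, RegionLabel.MHC_A1_HELIX, regions)
    a2 = _helix_ca(cx, RegionLabel.MHC_A2_HELIX, regions)
    helix_pts = np.array(a1 + a2)
    if len(helix_pts) < 4:
        raise DegenerateGeometryError(
            f"{cx.complex_id}: {len(helix_pts)} helix Cα atoms; need >= 4"
        )

    if mode == "helix_axis":
        axis = _principal_axis(helix_pts)
    elif mode == "anchor_ca":
        pep = cx.peptide_chain
        if pep is None:
            raise DegenerateGeometryError("anchor_ca mode requires a peptide chain")
        cas = pep.ca_positions()
        i, j = anchor_positions
        i = i - 1 if i > 0 else len(cas) + i
        j = j - 1 if j > 0 else len(cas) + j
        if not (0 <= i < len(cas) and 0 <= j < len(cas)) or i == j:
            raise DegenerateGeometryError("peptide anchor positions out of range")
        axis = cas[j] - cas[i]
    else:
        raise ValueError(f"unknown groove mode {mode!r}")

    axis = _unit(axis)
    if np.dot(axis, _peptide_direction(cx)) < 0:
        axis = -axis
    normal = _plane_normal(helix_pts)
    return GrooveFrame(axis=axis, origin=helix_pts.mean(axis=0), helix_plane_normal=normal)


# ---------------------------------------------------------------------------
# docking angle


def _domain_anchor_midpoint(chain: Chain) -> np.ndarray:
    pts = []
    missing = []
    for imgt in CONSERVED_CYS_IMGT:
        hits = [r for r in chain.residues if r.key.imgt_number == imgt and r.atom("CA")]
        if hits:
            pts.append(hits[0].atom("CA").position)
        else:
            missing.append(imgt)
    if missing:
        raise DegenerateGeometryError(
            f"chain {chain.chain_id}: missing Cα at conserved IMGT position(s) "
            f"{missing}"
        )
    return np.mean(pts, axis=0)


def _project(v: np.ndarray, normal: np.ndarray) -> np.ndarray:
    return v - np.dot(v, normal) * normal


def docking_angle(cx: AnnotatedComplex, frame: GrooveFrame) -> float:
    """Crossing angle between the inter-domain line and the groove axis.

    Both the groove axis and the line from the VJ-domain disulfide
    midpoint to the VDJ-domain midpoint are projected onto the helix
    plane; the angle between the projections is reported in [0, 180).
    """
    vdj = cx.chains_with_role(VDJ_ROLES)
    vj = cx.chains_with_role(VJ_ROLES)
    if len(vdj) != 1 or len(vj) != 1:
        raise DegenerateGeometryError(
            f"{cx.complex_id}: need one VDJ and one VJ chain for docking angle"
        )
    inter = _domain_anchor_midpoint(vdj[0]) - _domain_anchor_midpoint(vj[0])
    n = frame.helix_plane_normal
    u = _unit(_project(frame.axis, n))
    w = _unit(_project(inter, n))
    ang = float(np.degrees(np.arccos(np.clip(np.dot(u, w), -1.0, 1.0))))
    return ang % 180.0


def fold_diagonal(angle: float) -> float:
    """Fold a [0,180) docking angle to absolute diagonality in [0,90]."""
    a = angle % 180.0
    return min(a, 180.0 - a)


def classify_diagonal(angle: float, tcr_reference_range: tuple[float, float]) -> bool:
    """Is the (folded) angle within the absolute-diagonality range set by TCRs?"""
    lo, hi = tcr_reference_range
    if not (np.isfinite(lo) and np.isfinite(hi)) or lo > hi:
        raise ValueError(f"invalid reference range {tcr_reference_range!r}")
    return lo <= fold_diagonal(angle) <= hi


def reference_range_from_cohort(angles) -> tuple[float, float]:
    """Absolute-diagonality range spanned by a cohort of docking angles."""
    angles = list(angles)
    if not angles:
        raise ValueError("empty reference cohort")
    folded = [fold_diagonal(a) for a in angles]
    return (min(folded), max(folded))


# ---------------------------------------------------------------------------
# polarity


def classify_polarity(
    cx: AnnotatedComplex,
    frame: GrooveFrame,
    regions: dict[ResidueKey, RegionLabel],
) -> str:
    """CANONICAL iff the VDJ domain sits over the α1 helix and the VJ
    domain over the α2 helix; REVERSE otherwise.

    "Over" is resolved by nearest helix centroid. For a canonically
    docking, diagonal binder this places the VDJ domain over the
    C-terminal half of α1 and the VJ domain over the C-terminal half of
    α2 — the classical description of TCR polarity — but the helix
    assignment itself is what separates canonical from reverse: in a
    reverse binder the VDJ domain sits above α2 while the VJ domain
    occludes α1. Distances to helix ends alone would confuse a change
    of docking angle with a change of polarity.
    """
    a1 = _helix_ca(cx, RegionLabel.MHC_A1_HELIX, regions)
    a2 = _helix_ca(cx, RegionLabel.MHC_A2_HELIX, regions)
    if len(a1) < 2 or len(a2) < 2:
        raise DegenerateGeometryError(f"{cx.complex_id}: helix windows unresolved")
    c1 = np.array(a1).mean(axis=0)
    c2 = np.array(a2).mean(axis=0)
    vdj = cx.chains_with_role(VDJ_ROLES)
    vj = cx.chains_with_role(VJ_ROLES)
    if len(vdj) != 1 or len(vj) != 1:
        raise DegenerateGeometryError(f"{cx.complex_id}: variable-domain pair absent")
    vdj_c = _domain_anchor_midpoint(vdj[0])
    vj_c = _domain_anchor_midpoint(vj[0])
    vdj_over_a1 = np.linalg.norm(vdj_c - c1) <= np.linalg.norm(vdj_c - c2)
    vj_over_a2 = np.linalg.norm(vj_c - c2) <= np.linalg.norm(vj_c - c1)
    return "CANONICAL" if (vdj_over_a1 and vj_over_a2) else "REVERSE"


# ---------------------------------------------------------------------------
# guanidino tilt


def guanidino_tilt(
    cx: AnnotatedComplex, arg_key: ResidueKey, frame: GrooveFrame
) -> float:
    """Tilt of an arginine guanidino plane relative to the helix plane.

    The guanidino plane is the best-fit plane through NE, CZ, NH1, NH2;
    the tilt is the angle between the two plane normals folded to
    [0, 90]: 0° means the guanidino group lies in-plane with the helix,
    90° means it stands perpendicular (extended towards the binder).
    """
    residue = None
    for res in cx.iter_residues():
        if res.key == arg_key:
            residue = res
            break
    if residue is None:
        raise DegenerateGeometryError(f"residue {arg_key} not found")
    if residue.name != "ARG":
        raise DegenerateGeometryError(f"residue {arg_key} is {residue.name}, not ARG")
    atoms = []
    missing = []
    for name in ("NE", "CZ", "NH1", "NH2"):
        a = residue.atom(name)
        (atoms if a else missing).append(a.position if a else name)
    if missing:
        raise DegenerateGeometryError(
            f"residue {arg_key}: missing guanidino atom(s) {missing}"
        )
    gn = _plane_normal(np.array(atoms))
    cosang = abs(float(np.dot(_unit(gn), _unit(frame.helix_plane_normal))))
    return float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))


# ---------------------------------------------------------------------------
# orchestration


def geometry_report(
    cx: AnnotatedComplex,
    regions: dict[ResidueKey, RegionLabel],
    mode: str = "helix_axis",
    tcr_reference_range: Optional[tuple[float, float]] = None,
    guanidino_residue: Optional[ResidueKey] = None,
) -> GeometryReport:
    """Full geometry characterisation of one complex."""
    frame = groove_frame(cx, regions, mode=mode)
    angle = docking_angle(cx, frame)
    polarity = classify_polarity(cx, frame, regions)
    diagonal = (
        classify_diagonal(angle, tcr_reference_range)
        if tcr_reference_range is not None
        else None
    )
    tilt = (
        guanidino_tilt(cx, guanidino_residue, frame)
        if guanidino_residue is not None
        else None
    )
    return GeometryReport(
        docking_angle=angle, polarity=polarity, diagonal=diagonal, guanidino_tilt=tilt
    )
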