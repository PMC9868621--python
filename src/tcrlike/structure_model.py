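"""Annotated complex data model.

Reads immunoglobulin:antigen / immunoglobulin:pMHC coordinate files
(PDB or mmCIF, via gemmi), sanitizes them (no hydrogens, waters or
heteroatoms; one conformer per atom), attaches chain roles and IMGT /
renumbered-MHC annotations from a sidecar file, and assigns region
labels (CDR loops, framework, MHC helices, peptide).

Numbering is consumed, never computed: immunoglobulin chains carry IMGT
numbers supplied by the sidecar (typically produced upstream by ANARCI
or equivalent), and MHC chains carry a user-supplied renumbering onto a
common class-I-style scale. Author numbering is never rewritten — IMGT
and MHC numbers are held as parallel annotations on the residue key.

Sidecar format (tab-separated)::

    # class: TCRM            <- ANTIBODY | TCR | TCRM
    # mhc_class: I           <- optional; I | II
    # chain H HEAVY          <- one line per retained chain
    # chain L LIGHT
    # chain M MHC_ALPHA
    # chain P PEPTIDE
    chain  author_number  icode  imgt  mhc
    H      23             .      23    .
    M      50             .      .     50

Numbering rows are mandatory for immunoglobulin chains and optional for
MHC chains (an MHC chain with no rows falls back to author numbering).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator, Optional

import gemmi
import numpy as np

from . import config
from .errors import AnnotationError, FormatError, NumberingError, PairingError, RadiusError

logger = logging.getLogger(__name__)


class ChainRole(Enum):
    HEAVY = "HEAVY"
    LIGHT = "LIGHT"
    TCR_BETA = "TCR_BETA"
    TCR_ALPHA = "TCR_ALPHA"
    MHC_ALPHA = "MHC_ALPHA"
    MHC_BETA = "MHC_BETA"
    B2M = "B2M"
    PEPTIDE = "PEPTIDE"
    ANTIGEN_OTHER = "ANTIGEN_OTHER"


#: Roles forming the immunoglobulin (binder) side of the interface.
IMMUNOGLOBULIN_ROLES = frozenset(
    {ChainRole.HEAVY, ChainRole.LIGHT, ChainRole.TCR_BETA, ChainRole.TCR_ALPHA}
)
#: Roles forming the antigen side.
ANTIGEN_ROLES = frozenset(
    {
        ChainRole.MHC_ALPHA,
        ChainRole.MHC_BETA,
        ChainRole.B2M,
        ChainRole.PEPTIDE,
        ChainRole.ANTIGEN_OTHER,
    }
)
#: VDJ-recombined roles (heavy / beta); their partners are VJ-recombined.
VDJ_ROLES = frozenset({ChainRole.HEAVY, ChainRole.TCR_BETA})
VJ_ROLES = frozenset({ChainRole.LIGHT, ChainRole.TCR_ALPHA})


class RegionLabel(Enum):
    CDR1 = "CDR1"
    CDR2 = "CDR2"
    CDR3 = "CDR3"
    FRAMEWORK = "FRAMEWORK"
    MHC_A1_HELIX = "MHC_A1_HELIX"
    MHC_A2_HELIX = "MHC_A2_HELIX"
    MHC_OTHER = "MHC_OTHER"
    PEPTIDE = "PEPTIDE"


class ImmunoglobulinClass(Enum):
    ANTIBODY = "ANTIBODY"
    TCR = "TCR"
    TCRM = "TCRM"


@dataclass(frozen=True)
class Atom:
    """A heavy atom with a pinned van der Waals radius."""

    name: str
    element: str
    position: np.ndarray
    vdw_radius: float

    @staticmethod
    def create(name: str, element: str, position, radii=None) -> "Atom":
        radii = config.VDW_RADII if radii is None else radii
        element = element.upper()
        if element not in radii:
            raise RadiusError(
                f"no van der Waals radius for element {element!r} (atom {name!r})"
            )
        pos = np.asarray(position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {name!r} has invalid position {position!r}")
        return Atom(name, element, pos, radii[element])


@dataclass(frozen=True)
class ResidueKey:
    """Identity of a residue: author numbering plus parallel annotations.

    Equality and hashing use only (chain_id, seq_number, insertion_code);
    the IMGT and renumbered-MHC annotations ride along without affecting
    identity.
    """

    chain_id: str
    seq_number: int
    insertion_code: str = ""
    imgt_number: Optional[int] = field(default=None, compare=False)
    mhc_number: Optional[int] = field(default=None, compare=False)

    def __str__(self) -> str:  # e.g. "H100A"
        return f"{self.chain_id}{self.seq_number}{self.insertion_code}"


@dataclass
class Residue:
    key: ResidueKey
    name: str
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Chain:
    chain_id: str
    role: ChainRole
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def ca_positions(self) -> np.ndarray:
        pts = [r.atom("CA").position for r in self.residues if r.atom("CA")]
        return np.array(pts) if pts else np.empty((0, 3))

    def sequence(self) -> str:
        return "".join(
            gemmi.find_tabulated_residue(r.name).one_letter_code.upper()
            if gemmi.find_tabulated_residue(r.name)
            else "X"
            for r in self.residues
        )


@dataclass
class AnnotatedComplex:
    """A sanitized multi-chain complex with roles and numbering attached."""

    complex_id: str
    chains: dict[str, Chain]
    immunoglobulin_class: ImmunoglobulinClass
    mhc_class: Optional[str] = None  # "I" | "II" | None

    def chains_with_role(self, roles) -> list[Chain]:
        if isinstance(roles, ChainRole):
            roles = {roles}
        return [c for c in self.chains.values() if c.role in roles]

    @property
    def immunoglobulin_chains(self) -> list[Chain]:
        return self.chains_with_role(IMMUNOGLOBULIN_ROLES)

    @property
    def antigen_chains(self) -> list[Chain]:
        return self.chains_with_role(ANTIGEN_ROLES)

    @property
    def peptide_chain(self) -> Optional[Chain]:
        hits = self.chains_with_role(ChainRole.PEPTIDE)
        return hits[0] if hits else None

    @property
    def is_pmhc(self) -> bool:
        return self.peptide_chain is not None and bool(
            self.chains_with_role({ChainRole.MHC_ALPHA, ChainRole.MHC_BETA})
        )

    def iter_residues(self, roles=None) -> Iterator[Residue]:
        for chain in self.chains.values():
            if roles is None or chain.role in (
                {roles} if isinstance(roles, ChainRole) else roles
            ):
                yield from chain.residues

    def iter_atoms(self, roles=None) -> Iterator[tuple[ResidueKey, Residue, Atom]]:
        for res in self.iter_residues(roles):
            for atom in res.atoms:
                yield res.key, res, atom


# ---------------------------------------------------------------------------
# Sidecar annotation


@dataclass
class ChainAnnotation:
    """Chain roles plus residue-level numbering maps for one complex."""

    roles: dict[str, ChainRole]
    immunoglobulin_class: ImmunoglobulinClass
    mhc_class: Optional[str] = None
    #: (chain_id, author_number, icode) -> (imgt_number | None, mhc_number | None)
    numbering: dict[tuple[str, int, str], tuple[Optional[int], Optional[int]]] = field(
        default_factory=dict
    )


def read_sidecar(path) -> ChainAnnotation:
    """Parse a tab-separated chain-annotation sidecar (format in module docs)."""
    roles: dict[str, ChainRole] = {}
    ig_class: Optional[ImmunoglobulinClass] = None
    mhc_class: Optional[str] = None
    numbering: dict[tuple[str, int, str], tuple[Optional[int], Optional[int]]] = {}

    def parse_opt(token: str) -> Optional[int]:
        return None if token in (".", "", "NA") else int(token)

    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.lower().startswith("class:"):
                ig_class = ImmunoglobulinClass(body.split(":", 1)[1].strip().upper())
            elif body.lower().startswith("mhc_class:"):
                mhc_class = body.split(":", 1)[1].strip().upper()
            elif body.lower().startswith("chain"):
                parts = body.split()
                if len(parts) != 3:
                    raise AnnotationError(f"{path}:{lineno}: bad chain line {raw!r}")
                try:
                    roles[parts[1]] = ChainRole(parts[2].upper())
                except ValueError as exc:
                    raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if parts[0].lower() == "chain":  # column header row
            continue
        if len(parts) != 5:
            raise AnnotationError(f"{path}:{lineno}: expected 5 columns, got {len(parts)}")
        chain_id, num, icode, imgt, mhc = parts
        icode = "" if icode == "." else icode
        numbering[(chain_id, int(num), icode)] = (parse_opt(imgt), parse_opt(mhc))

    if ig_class is None:
        raise AnnotationError(f"{path}: missing '# class:' header")
    if not roles:
        raise AnnotationError(f"{path}: no '# chain' role lines")
    return ChainAnnotation(roles, ig_class, mhc_class, numbering)


def write_sidecar(annotation: ChainAnnotation, path) -> None:
    lines = [f"# class: {annotation.immunoglobulin_class.value}"]
    if annotation.mhc_class:
        lines.append(f"# mhc_class: {annotation.mhc_class}")
    for chain_id, role in annotation.roles.items():
        lines.append(f"# chain {chain_id} {role.value}")
    lines.append("chain\tauthor_number\ticode\timgt\tmhc")
    for (chain_id, num, icode), (imgt, mhc) in annotation.numbering.items():
        lines.append(
            "\t".join(
                [
                    chain_id,
                    str(num),
                    icode or ".",
                    "." if imgt is None else str(imgt),
                    "." if mhc is None else str(mhc),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Loading and sanitization


def _is_amino_acid(residue_name: str) -> bool:
    info = gemmi.find_tabulated_residue(residue_name)
    return bool(info) and info.is_amino_acid()


def _select_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one conformer per atom name: highest occupancy, tie -> first seen."""
    best: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for atom in residue:
        prev = best.get(atom.name)
        if prev is None:
            best[atom.name] = atom
            order.append(atom.name)
        elif atom.occ > prev.occ:
            best[atom.name] = atom
    return [best[name] for name in order]


def load_complex(
    coordinate_file,
    annotation,
    complex_id: Optional[str] = None,
    radii: Optional[dict[str, float]] = None,
) -> AnnotatedComplex:
    """Read a PDB/mmCIF file and build a sanitized, annotated complex.

    Sanitization drops hydrogens (and deuteriums), waters, and any
    non-amino-acid (HETATM-style) residue; alternate conformers collapse
    to the highest-occupancy atom. Chains absent from the annotation are
    dropped with a logged warning. Annotated antigen chains that are not
    protein are rejected.

    Parameters
    ----------
    coordinate_file : path
        PDB or mmCIF file.
    annotation : ChainAnnotation or path
        Parsed sidecar, or a path to one.
    """
    if not isinstance(annotation, ChainAnnotation):
        annotation = read_sidecar(annotation)

    path = Path(coordinate_file)
    try:
        structure = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError, SystemError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if len(structure) == 0:
        raise FormatError(f"{path}: no models")
    structure.setup_entities()
    model = structure[0]

    present_chain_ids = {chain.name for chain in model}
    missing = set(annotation.roles) - present_chain_ids
    if missing:
        raise AnnotationError(
            f"{path}: annotation references chains absent from file: {sorted(missing)}"
        )

    chains: dict[str, Chain] = {}
    for gchain in model:
        role = annotation.roles.get(gchain.name)
        if role is None:
            logger.warning(
                "%s: dropping unannotated chain %s", path.name, gchain.name
            )
            continue
        residues: list[Residue] = []
        for gres in gchain:
            if gres.is_water():
                continue
            if not _is_amino_acid(gres.name):
                if role in ANTIGEN_ROLES and role is not ChainRole.ANTIGEN_OTHER:
                    # heteroatom ligands inside annotated antigen chains are
                    # stripped silently; whole non-protein chains are caught
                    # below by the empty-chain check
                    pass
                continue
            icode = gres.seqid.icode.strip()
            imgt, mhc = annotation.numbering.get(
                (gchain.name, gres.seqid.num, icode), (None, None)
            )
            if role in {ChainRole.MHC_ALPHA, ChainRole.MHC_BETA} and mhc is None:
                # fall back to author numbering when no renumbering supplied
                mhc = gres.seqid.num
            key = ResidueKey(gchain.name, gres.seqid.num, icode, imgt, mhc)
            atoms = []
            for gatom in _select_altlocs(gres):
                elem = gatom.element.name.upper()
                if elem in ("H", "D"):
                    continue
                atoms.append(Atom.create(gatom.name, elem, gatom.pos.tolist(), radii))
            if atoms:
                residues.append(Residue(key, gres.name, atoms))
        if not residues:
            raise AnnotationError(
                f"{path}: annotated chain {gchain.name} has no protein residues"
            )
        chains[gchain.name] = Chain(gchain.name, role, residues)

    for chain in chains.values():
        if chain.role in IMMUNOGLOBULIN_ROLES and not any(
            r.key.imgt_number is not None for r in chain.residues
        ):
            raise NumberingError(
                f"immunoglobulin chain {chain.chain_id} has no IMGT numbering"
            )

    cx = AnnotatedComplex(
        complex_id or path.stem,
        chains,
        annotation.immunoglobulin_class,
        annotation.mhc_class,
    )
    keys = [r.key for r in cx.iter_residues()]
    if len(keys) != len(set(keys)):
        raise FormatError(f"{path}: duplicate residue identifiers after sanitization")
    if not cx.antigen_chains:
        raise AnnotationError(f"{path}: no antigen-side chains annotated")
    return cx


# ---------------------------------------------------------------------------
# Region assignment and chain pairing


def assign_regions(
    cx: AnnotatedComplex,
    helix_windows: Optional[config.MhcHelixWindows] = None,
) -> dict[ResidueKey, RegionLabel]:
    """Label every residue with exactly one region.

    Immunoglobulin residues map through their IMGT number onto CDR1/2/3
    windows, defaulting to FRAMEWORK outside them (or when unnumbered).
    MHC chains map through the renumbered-MHC scale onto the configured
    helix windows, defaulting to MHC_OTHER. β2-microglobulin and
    non-pMHC antigen chains are labelled MHC_OTHER as generic
    "antigen, not peptide, not helix" surface.
    """
    if helix_windows is None:
        helix_windows = (
            config.CLASS_II_HELIX_WINDOWS
            if cx.mhc_class == "II"
            else config.CLASS_I_HELIX_WINDOWS
        )
    out: dict[ResidueKey, RegionLabel] = {}
    for chain in cx.chains.values():
        for res in chain.residues:
            out[res.key] = _region_of(res.key, chain.role, helix_windows)
    return out


def _region_of(
    key: ResidueKey, role: ChainRole, windows: config.MhcHelixWindows
) -> RegionLabel:
    if role in IMMUNOGLOBULIN_ROLES:
        n = key.imgt_number
        if n is not None:
            for cdr, (lo, hi) in config.CDR_WINDOWS.items():
                if lo <= n <= hi:
                    return RegionLabel(cdr)
        return RegionLabel.FRAMEWORK
    if role is ChainRole.PEPTIDE:
        return RegionLabel.PEPTIDE
    if role in {ChainRole.MHC_ALPHA, ChainRole.MHC_BETA}:
        n = key.mhc_number
        if n is not None:
            a1_here = role is ChainRole.MHC_ALPHA
            a2_here = (
                role is ChainRole.MHC_BETA
                if windows.alpha2_on_beta
                else role is ChainRole.MHC_ALPHA
            )
            if a1_here and windows.alpha1[0] <= n <= windows.alpha1[1]:
                return RegionLabel.MHC_A1_HELIX
            if a2_here and windows.alpha2[0] <= n <= windows.alpha2[1]:
                return RegionLabel.MHC_A2_HELIX
        return RegionLabel.MHC_OTHER
    return RegionLabel.MHC_OTHER  # B2M, ANTIGEN_OTHER


def transform_complex(
    cx: AnnotatedComplex,
    rotation: np.ndarray,
    translation: np.ndarray,
    chain_ids: Optional[set[str]] = None,
) -> AnnotatedComplex:
    """Apply a rigid-body transform x -> R x + t, optionally to a chain subset."""
    rotation = np.asarray(rotation, float)
    translation = np.asarray(translation, float)
    chains = {}
    for cid, chain in cx.chains.items():
        residues = []
        for res in chain.residues:
            if chain_ids is None or cid in chain_ids:
                atoms = [
                    Atom(a.name, a.element, rotation @ a.position + translation,
                         a.vdw_radius)
                    for a in res.atoms
                ]
            else:
                atoms = list(res.atoms)
            residues.append(Residue(res.key, res.name, atoms))
        chains[cid] = Chain(cid, chain.role, residues)
    return AnnotatedComplex(
        cx.complex_id, chains, cx.immunoglobulin_class, cx.mhc_class
    )


def annotation_of(cx: AnnotatedComplex) -> ChainAnnotation:
    """Reconstruct the sidecar annotation carried by a complex."""
    roles = {cid: chain.role for cid, chain in cx.chains.items()}
    numbering = {}
    for chain in cx.chains.values():
        for res in chain.residues:
            k = res.key
            if k.imgt_number is not None or k.mhc_number is not None:
                numbering[(k.chain_id, k.seq_number, k.insertion_code)] = (
                    k.imgt_number,
                    k.mhc_number,
                )
    return ChainAnnotation(roles, cx.immunoglobulin_class, cx.mhc_class, numbering)


def to_structure(cx: AnnotatedComplex) -> gemmi.Structure:
    """Build a gemmi Structure mirroring the in-memory complex."""
    structure = gemmi.Structure()
    structure.name = cx.complex_id
    model = gemmi.Model("1")
    for chain in cx.chains.values():
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.key.seq_number, res.key.insertion_code or " ")
            for atom in res.atoms:
                gatom = gemmi.Atom()
                gatom.name = atom.name
                gatom.element = gemmi.Element(atom.element)
                gatom.pos = gemmi.Position(*atom.position)
                gatom.occ = 1.0
                gres.add_atom(gatom)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    structure.add_model(model)
    structure.setup_entities()
    return structure


def write_pdb(cx: AnnotatedComplex, path) -> None:
    """Write the complex as a PDB file (deterministic for a given complex)."""
    to_structure(cx).write_pdb(str(path))


def chain_pairing_map(cx: AnnotatedComplex) -> dict[str, str]:
    """Map genetic pairing slots to chain ids.

    Heavy and beta chains are VDJ-recombined; light and alpha chains are
    VJ-recombined. The map enables like-for-like comparisons between
    antibody H/L and TCR B/A chains.

    Returns ``{"VDJ_CHAIN": id, "VJ_CHAIN": id}``.
    """
    vdj = cx.chains_with_role(VDJ_ROLES)
    vj = cx.chains_with_role(VJ_ROLES)
    if len(vdj) != 1 or len(vj) != 1:
        raise PairingError(
            f"{cx.complex_id}: need exactly one VDJ and one VJ chain, "
            f"found {len(vdj)} VDJ / {len(vj)} VJ"
        )
    return {"VDJ_CHAIN": vdj[0].chain_id, "VJ_CHAIN": vj[0].chain_id}
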