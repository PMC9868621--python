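"""Binding-energy decomposition statistics: hotspots and regional fractions.

Consumes per-residue binding free-energy contribution tables (kcal/mol,
attractive negative) of the kind produced by MMGBSA per-residue DECOMP
analysis; running the simulations themselves is out of scope. When
several per-frame or per-replica tables are supplied, energies are
averaged per residue before any thresholding, so hotspots are called on
ensemble means.

Hotspot bands (kcal/mol): a residue is a HOTSPOT at −7 or stronger, a
SEMI_HOTSPOT between −4 and −7 (boundaries inclusive on the stronger
side), NONE otherwise.

Regional fractions on the pMHC side split the attractive energy between
the peptide, the MHC α1 helix and the MHC α2 helix:
f_region = |S_region| / (|S_peptide| + |S_α1| + |S_α2|), where S is the
regional energy sum and a repulsive (positive) regional sum is clipped
to zero before normalisation and flagged. CDR fractions on the
immunoglobulin side divide each loop's sum by the total over all six
CDRs, then clip negative (repulsive-loop) fractions to zero — so the
clipped fractions may sum to slightly less than one.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import math

from . import config
from .errors import EnergeticsError
from .structure_model import RegionLabel, ResidueKey

IMMUNOGLOBULIN = "IMMUNOGLOBULIN"
PMHC = "PMHC"

HOTSPOT = "HOTSPOT"
SEMI_HOTSPOT = "SEMI_HOTSPOT"
NONE = "NONE"


@dataclass
class DecompTable:
    """Per-residue binding-energy contributions for one side of one complex."""

    entries: dict[ResidueKey, float]
    side: str  # IMMUNOGLOBULIN | PMHC
    source_id: str = ""

    def __post_init__(self):
        if self.side not in (IMMUNOGLOBULIN, PMHC):
            raise EnergeticsError(f"unknown table side {self.side!r}")
        for key, value in self.entries.items():
            if not math.isfinite(value):
                raise EnergeticsError(f"{self.source_id}: non-finite energy at {key}")


@dataclass(frozen=True)
class HotspotCall:
    residue: ResidueKey
    category: str  # HOTSPOT | SEMI_HOTSPOT | NONE
    energy: float


@dataclass
class RegionalFractions:
    """Peptide/α1/α2 split of the attractive pMHC binding energy."""

    f_peptide: float
    f_alpha1: float
    f_alpha2: float
    clipped_regions: list[str] = field(default_factory=list)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.f_peptide, self.f_alpha1, self.f_alpha2)


def average_tables(tables: Iterable[DecompTable]) -> DecompTable:
    """Per-residue mean over an ensemble of tables (same side)."""
    tables = list(tables)
    if not tables:
        raise EnergeticsError("no tables to average")
    side = tables[0].side
    if any(t.side != side for t in tables):
        raise EnergeticsError("cannot average tables from different sides")
    sums: dict[ResidueKey, float] = defaultdict(float)
    counts: dict[ResidueKey, int] = defaultdict(int)
    for t in tables:
        for key, value in t.entries.items():
            sums[key] += value
            counts[key] += 1
    mean = {key: sums[key] / counts[key] for key in sums}
    return DecompTable(mean, side, tables[0].source_id)


def categorize(energy: float) -> str:
    if energy <= config.HOTSPOT_THRESHOLD:
        return HOTSPOT
    if energy <= config.SEMI_HOTSPOT_THRESHOLD:
        return SEMI_HOTSPOT
    return NONE


def call_hotspots(table: DecompTable) -> list[HotspotCall]:
    """Classify each residue into HOTSPOT / SEMI_HOTSPOT / NONE."""
    return [
        HotspotCall(key, categorize(e), e)
        for key, e in sorted(
            table.entries.items(), key=lambda kv: (kv[0].chain_id, kv[0].seq_number,
                                                   kv[0].insertion_code)
        )
    ]


def regional_fractions(
    table: DecompTable, regions: dict[ResidueKey, RegionLabel]
) -> RegionalFractions:
    """Peptide / α1-helix / α2-helix fractions of the attractive energy."""
    if table.side != PMHC:
        raise EnergeticsError("regional fractions are defined for the pMHC side")
    sums = {"peptide": 0.0, "alpha1": 0.0, "alpha2": 0.0}
    for key, energy in table.entries.items():
        label = regions.get(key)
        if label is RegionLabel.PEPTIDE:
            sums["peptide"] += energy
        elif label is RegionLabel.MHC_A1_HELIX:
            sums["alpha1"] += energy
        elif label is RegionLabel.MHC_A2_HELIX:
            sums["alpha2"] += energy
    clipped = [name for name, s in sums.items() if s > 0]
    magnitudes = {name: max(0.0, -s) for name, s in sums.items()}
    denom = sum(magnitudes.values())
    if denom <= 0:
        raise EnergeticsError(
            f"{table.source_id}: no attractive energy in peptide/α1/α2 regions"
        )
    return RegionalFractions(
        f_peptide=magnitudes["peptide"] / denom,
        f_alpha1=magnitudes["alpha1"] / denom,
        f_alpha2=magnitudes["alpha2"] / denom,
        clipped_regions=clipped,
    )


def cdr_energy_fractions(
    table: DecompTable, regions: dict[ResidueKey, RegionLabel]
) -> dict[tuple[str, str], float]:
    """Each CDR loop's fraction of the total six-CDR energy, clipped at 0.

    Keys are (chain_id, CDR label). The denominator is the signed sum
    over all six loops; repulsive loops therefore yield negative raw
    fractions which are reported as 0.0.
    """
    if table.side != IMMUNOGLOBULIN:
        raise EnergeticsError("CDR fractions are defined for the immunoglobulin side")
    loop_sums: dict[tuple[str, str], float] = defaultdict(float)
    for key, energy in table.entries.items():
        label = regions.get(key)
        if label in (RegionLabel.CDR1, RegionLabel.CDR2, RegionLabel.CDR3):
            loop_sums[(key.chain_id, label.value)] += energy
    total = sum(loop_sums.values())
    if total == 0:
        raise EnergeticsError(f"{table.source_id}: zero total CDR energy")
    return {
        loop: max(0.0, s / total) for loop, s in sorted(loop_sums.items())
    }


@dataclass(frozen=True)
class HotspotSummary:
    source_id: str
    n_peptide: int
    n_alpha1: int
    n_alpha2: int

    def pattern(self) -> str:
        """Compact 'peptide/α1/α2' hotspot-count pattern, e.g. '1/0/0'."""
        return f"{self.n_peptide}/{self.n_alpha1}/{self.n_alpha2}"


def peptide_hotspot_summary(
    tables: Iterable[DecompTable],
    regions: dict[ResidueKey, RegionLabel],
) -> list[HotspotSummary]:
    """Per-complex hotspot counts in the peptide and MHC helix regions."""
    out = []
    for table in tables:
        counts = {"peptide": 0, "alpha1": 0, "alpha2": 0}
        for call in call_hotspots(table):
            if call.category != HOTSPOT:
                continue
            label = regions.get(call.residue)
            if label is RegionLabel.PEPTIDE:
                counts["peptide"] += 1
            elif label is RegionLabel.MHC_A1_HELIX:
                counts["alpha1"] += 1
            elif label is RegionLabel.MHC_A2_HELIX:
                counts["alpha2"] += 1
        out.append(
            HotspotSummary(table.source_id, counts["peptide"], counts["alpha1"],
                           counts["alpha2"])
        )
    return out


# ---------------------------------------------------------------------------
# TSV import


def read_decomp_tsv(path, side: str, source_id: Optional[str] = None) -> DecompTable:
    """Read a per-residue decomposition TSV.

    Tab-separated columns: chain, resnum, icode ('.' for none),
    energy_kcal_mol. Header row optional. Repeated residues are averaged
    (per-frame dumps concatenated into one file are therefore handled).
    """
    sums: dict[ResidueKey, float] = defaultdict(float)
    counts: dict[ResidueKey, int] = defaultdict(int)
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#") or line.lower().startswith("chain"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 4:
            raise EnergeticsError(f"{path}:{lineno}: expected 4 columns")
        icode = "" if parts[2] == "." else parts[2]
        key = ResidueKey(parts[0], int(parts[1]), icode)
        sums[key] += float(parts[3])
        counts[key] += 1
    entries = {k: sums[k] / counts[k] for k in sums}
    return DecompTable(entries, side, source_id or Path(path).stem)


def write_hotspots_tsv(calls: list[HotspotCall], path) -> None:
    lines = ["chain\tresnum\ticode\tenergy_kcal_mol\tcategory"]
    for call in calls:
        lines.append(
            f"{call.residue.chain_id}\t{call.residue.seq_number}\t"
            f"{call.residue.insertion_code or '.'}\t{call.energy:.4f}\t{call.category}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
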