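"""Cohort orchestration: batch-profile complexes and aggregate by class.

Runs burial, interaction and geometry profiling (and energetics when
decomposition tables are supplied) over a cohort of complexes, collects
one row per complex, and summarises each metric per immunoglobulin
class as (mean, sample sd, n) over non-missing values. Per-complex
failures are logged and isolated; they never abort the batch.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import binding_geometry, energetics, interactions, sasa_burial
from .errors import TcrlikeError
from .structure_model import (
    AnnotatedComplex,
    assign_regions,
    chain_pairing_map,
    load_complex,
)

logger = logging.getLogger(__name__)

#: numeric columns eligible for group summaries
_METRIC_COLUMNS = [
    "interface_bsa",
    "immunoglobulin_bsa",
    "antigen_bsa",
    "peptide_bsa",
    "mhc_bsa",
    "peptide_fraction",
    "vdj_cdr3_share",
    "buried_peptide_residues",
    "n_peptide_residues_contacted",
    "n_ig_residues_contacting_peptide",
    "n_ig_peptide_interactions",
    "n_ig_mhc_interactions",
    "n_vdj_cdr3_mhc_interactions",
    "total_interactions",
    "docking_angle",
    "f_peptide",
    "f_alpha1",
    "f_alpha2",
]


@dataclass
class CohortProfile:
    """Per-complex metric table plus per-class (mean, sd, n) summaries."""

    per_complex: pd.DataFrame
    group_summaries: dict[str, dict[str, dict[str, float]]]
    failures: dict[str, str] = field(default_factory=dict)


def profile_complex(
    cx: AnnotatedComplex,
    decomp_table: Optional[energetics.DecompTable] = None,
    n_points: int = 240,
    tcr_reference_range: Optional[tuple[float, float]] = None,
) -> dict:
    """One row of cohort metrics for a single annotated complex."""
    regions = assign_regions(cx)
    row: dict = {
        "complex_id": cx.complex_id,
        "immunoglobulin_class": cx.immunoglobulin_class.value,
        "mhc_class": cx.mhc_class,
    }

    profile = sasa_burial.burial_profile(cx, regions, n_points=n_points)
    row.update(
        interface_bsa=profile.interface_bsa,
        immunoglobulin_bsa=profile.immunoglobulin_bsa,
        antigen_bsa=profile.antigen_bsa,
        peptide_bsa=profile.peptide_bsa,
        mhc_bsa=profile.mhc_bsa,
        peptide_fraction=profile.peptide_fraction,
        vdj_cdr3_share=sasa_burial.vdj_cdr3_share(profile, cx),
        buried_peptide_residues=profile.buried_peptide_residue_count,
    )

    contacts = interactions.detect_atom_contacts(cx)
    iprofile = interactions.consolidate(contacts)
    if cx.is_pmhc:
        vdj_id = chain_pairing_map(cx)["VDJ_CHAIN"]
        summary = interactions.interaction_summary(iprofile, regions, vdj_id)
        row.update(
            n_peptide_residues_contacted=summary.n_peptide_residues_contacted,
            n_ig_residues_contacting_peptide=summary.n_ig_residues_contacting_peptide,
            n_ig_peptide_interactions=summary.n_ig_peptide_interactions,
            n_ig_mhc_interactions=summary.n_ig_mhc_interactions,
            n_vdj_cdr3_mhc_interactions=summary.n_vdj_cdr3_mhc_interactions,
            total_interactions=summary.total_interactions,
        )
        geo = binding_geometry.geometry_report(
            cx, regions, tcr_reference_range=tcr_reference_range
        )
        row.update(
            docking_angle=geo.docking_angle,
            polarity=geo.polarity,
            diagonal=geo.diagonal,
        )
    else:
        row["total_interactions"] = iprofile.total_interactions()

    if decomp_table is not None:
        fractions = energetics.regional_fractions(decomp_table, regions)
        row.update(
            f_peptide=fractions.f_peptide,
            f_alpha1=fractions.f_alpha1,
            f_alpha2=fractions.f_alpha2,
        )
    return row


def profile_cohort(
    complexes,
    decomp_tables: Optional[dict[str, energetics.DecompTable]] = None,
    n_points: int = 240,
    tcr_reference_range: Optional[tuple[float, float]] = None,
    split_mhc_class: bool = False,
) -> CohortProfile:
    """Profile a cohort and aggregate by immunoglobulin class.

    ``complexes`` is an iterable of AnnotatedComplex objects or
    (coordinate_path, sidecar_path) pairs. MHC class I and II are pooled
    within each immunoglobulin class unless ``split_mhc_class`` is set.
    """
    decomp_tables = decomp_tables or {}
    rows, failures = [], {}
    for item in complexes:
        cid = "?"
        try:
            if isinstance(item, AnnotatedComplex):
                cx = item
            else:
                coord, sidecar = item
                cx = load_complex(coord, sidecar)
            cid = cx.complex_id
            rows.append(
                profile_complex(
                    cx,
                    decomp_tables.get(cid),
                    n_points=n_points,
                    tcr_reference_range=tcr_reference_range,
                )
            )
        except (TcrlikeError, OSError, ValueError) as exc:
            if not isinstance(item, AnnotatedComplex) and cid == "?":
                cid = str(item[0])
            logger.warning("cohort: skipping %s: %s", cid, exc)
            failures[cid] = str(exc)
    if not rows:
        raise TcrlikeError("no complex in the cohort could be profiled")

    df = pd.DataFrame(rows)
    group_cols = ["immunoglobulin_class"]
    if split_mhc_class:
        group_cols.append("mhc_class")
    summaries: dict[str, dict[str, dict[str, float]]] = {}
    for group_key, sub in df.groupby(group_cols, dropna=False):
        name = group_key[0] if len(group_cols) == 1 else "/".join(map(str, group_key))
        summaries[name] = {}
        for col in _METRIC_COLUMNS:
            if col not in sub.columns:
                continue
            values = pd.to_numeric(sub[col], errors="coerce").dropna()
            if values.empty:
                continue
            summaries[name][col] = {
                "mean": float(values.mean()),
                "sd": float(values.std(ddof=1)) if len(values) > 1 else 0.0,
                "n": int(len(values)),
                "n_missing": int(len(sub) - len(values)),
            }
    return CohortProfile(df, summaries, failures)


@dataclass
class BurialFractionStat:
    numerator: int
    denominator: int

    @property
    def fraction(self) -> float:
        return self.numerator / self.denominator

    def __str__(self) -> str:  # reporting style "13/29 (44.8%)"
        return f"{self.numerator}/{self.denominator} ({100 * self.fraction:.1f}%)"


def peptide_burial_fraction_stats(
    profile: CohortProfile,
    peptide_length: Optional[int] = None,
    min_buried: int = 7,
    immunoglobulin_class: Optional[str] = None,
    mhc_class: Optional[str] = None,
    exact: bool = False,
) -> BurialFractionStat:
    """Fraction of complexes burying at least (or exactly) k peptide residues.

    The cohort can be restricted by immunoglobulin class, MHC class and
    peptide length before counting; the numerator/denominator pair is
    reported alongside the fraction.
    """
    df = profile.per_complex
    if immunoglobulin_class is not None:
        df = df[df["immunoglobulin_class"] == immunoglobulin_class]
    if mhc_class is not None:
        df = df[df["mhc_class"] == mhc_class]
    counts = pd.to_numeric(df.get("buried_peptide_residues"), errors="coerce").dropna()
    if peptide_length is not None and "peptide_length" in df.columns:
        counts = counts[df.loc[counts.index, "peptide_length"] == peptide_length]
    if counts.empty:
        raise TcrlikeError("empty cohort subset for burial-fraction statistic")
    hits = (counts == min_buried) if exact else (counts >= min_buried)
    return BurialFractionStat(int(hits.sum()), int(len(counts)))


def write_cohort(profile: CohortProfile, out_dir) -> None:
    """Emit the cohort TSV, the group-summary JSON and the failure log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    profile.per_complex.to_csv(out / "cohort.tsv", sep="\t", index=False)
    payload = {"group_summaries": profile.group_summaries, "failures": profile.failures}
    (out / "group_summaries.json").write_text(json.dumps(payload, indent=2) + "\n")
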