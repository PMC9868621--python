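"""Dataset curation: quality filters and two-round greedy clustering.

Non-redundant representative complexes are derived the way large
structural-immunology datasets are curated: keep X-ray structures at or
better than a resolution cutoff with protein antigens, cluster the
concatenated CDR sequences greedily at 80% identity into "paratope
clusters", then, within each paratope cluster, cluster the concatenated
antigen sequences (presented-peptide sequence for TCRs) at 80% identity
with a permissive 20% minimum alignment coverage so that truncated
antigen constructs collapse onto their full-length parent. One
representative — best resolution, ties broken by lexicographic id — is
kept per (paratope, antigen) cluster.

The greedy scheme is cd-hit-style: sequences sorted by descending
length (ties by id), the longest unassigned sequence seeds a cluster,
and each subsequent sequence joins the first seed it matches. Identity
is computed from an exact global alignment scoring match +1, mismatch
0 and gaps 0 (a hair of internal-gap penalty is applied purely as a
tie-break between co-optimal alignments): identity = identical pairs /
alignment columns excluding terminal gaps, and coverage = the shorter
sequence's aligned span / its length. This is a documented substitute
for cd-hit's internal word-filtered identity; at these thresholds the
two agree on all but pathological inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Optional

import pandas as pd
from Bio import Align

from . import config
from .errors import CurationError
from .structure_model import ImmunoglobulinClass


@dataclass
class ComplexRecord:
    """Sequence and quality metadata for one candidate complex."""

    complex_id: str
    method: str  # experimental method, e.g. "X-RAY DIFFRACTION"
    resolution: float  # Å
    cdr_sequences: tuple[str, ...]  # six CDRs in fixed order (H/B 1-3, L/A 1-3)
    antigen_sequences: tuple[str, ...]
    peptide_sequence: Optional[str] = None
    immunoglobulin_class: ImmunoglobulinClass = ImmunoglobulinClass.ANTIBODY
    antigen_is_protein: bool = True

    @property
    def paratope_sequence(self) -> str:
        return "".join(self.cdr_sequences)

    @property
    def antigen_concat(self) -> str:
        """Antigen sequences concatenated in descending length order
        (presented peptide for TCRs)."""
        if (
            self.immunoglobulin_class is ImmunoglobulinClass.TCR
            and self.peptide_sequence
        ):
            return self.peptide_sequence
        return "".join(sorted(self.antigen_sequences, key=lambda s: (-len(s), s)))


@dataclass
class ClusterSet:
    """Greedy clusters: (representative seed id, member ids including seed)."""

    clusters: list[tuple[str, list[str]]]
    identity_threshold: float
    min_alignment_coverage: float

    @property
    def assignment(self) -> dict[str, str]:
        return {m: seed for seed, members in self.clusters for m in members}

    def __len__(self) -> int:
        return len(self.clusters)


# ---------------------------------------------------------------------------
# pairwise identity


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    # gaps contribute nothing to identity; the tiny internal penalty only
    # selects the most compact of the co-optimal max-match alignments
    aligner.open_internal_gap_score = -1e-3
    aligner.extend_internal_gap_score = -1e-4
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


_ALIGNER = _make_aligner()


@lru_cache(maxsize=65536)
def pairwise_identity(seq_a: str, seq_b: str) -> tuple[float, float]:
    """(identity, coverage) of the best global alignment of two sequences.

    identity = identical aligned pairs / alignment columns excluding
    terminal gaps; coverage = shorter sequence's aligned span / its
    length. Symmetric in its arguments.
    """
    if not seq_a or not seq_b:
        raise CurationError("empty sequence in identity computation")
    if len(seq_a) < len(seq_b) or (len(seq_a) == len(seq_b) and seq_a > seq_b):
        seq_a, seq_b = seq_b, seq_a  # canonical order: longer (then smaller) first
    alignment = _ALIGNER.align(seq_a, seq_b)[0]
    blocks = alignment.aligned  # ((t_blocks), (q_blocks))
    t_blocks, q_blocks = blocks[0], blocks[1]
    if len(t_blocks) == 0:
        return 0.0, 0.0
    matches = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        matches += sum(1 for i in range(te - ts) if seq_a[ts + i] == seq_b[qs + i])
    t_span = int(t_blocks[-1][1] - t_blocks[0][0])
    q_span = int(q_blocks[-1][1] - q_blocks[0][0])
    paired = int(sum(te - ts for ts, te in t_blocks))
    columns = t_span + q_span - paired
    identity = matches / columns if columns else 0.0
    shorter_len = len(seq_b)  # seq_b is the shorter after the swap
    coverage = q_span / shorter_len
    return identity, coverage


# ---------------------------------------------------------------------------
# greedy clustering


def greedy_cluster(
    sequences: dict[str, str],
    threshold: float = config.DEFAULT_IDENTITY_THRESHOLD,
    min_coverage: float = 0.0,
) -> ClusterSet:
    """cd-hit-style greedy clustering by pairwise sequence identity.

    Sequences are visited in descending length (ties by id); each joins
    the first existing seed with identity >= threshold and coverage >=
    min_coverage, else seeds a new cluster. Deterministic for a given
    input set regardless of dict ordering.
    """
    if not sequences:
        raise CurationError("no sequences to cluster")
    if not 0.0 < threshold <= 1.0:
        raise CurationError(f"identity threshold {threshold} outside (0, 1]")
    for sid, seq in sequences.items():
        if not seq:
            raise CurationError(f"sequence {sid!r} is empty")

    order = sorted(sequences, key=lambda sid: (-len(sequences[sid]), sid))
    clusters: list[tuple[str, list[str]]] = []
    for sid in order:
        placed = False
        for seed, members in clusters:
            identity, coverage = pairwise_identity(sequences[seed], sequences[sid])
            if identity >= threshold and coverage >= min_coverage:
                members.append(sid)
                placed = True
                break
        if not placed:
            clusters.append((sid, [sid]))
    return ClusterSet(clusters, threshold, min_coverage)


# ---------------------------------------------------------------------------
# filters and representatives


def filter_records(
    records: list[ComplexRecord],
    max_resolution: float = config.DEFAULT_MAX_RESOLUTION,
) -> list[ComplexRecord]:
    """X-ray structures at <= max_resolution Å with protein antigens,
    input order preserved."""
    out = []
    for rec in records:
        if "X-RAY" not in rec.method.upper().replace(" ", "-"):
            continue
        if rec.resolution is None or rec.resolution > max_resolution:
            continue
        if not rec.antigen_is_protein:
            continue
        out.append(rec)
    return out


def tcrm_keyword_prefilter(records: list[ComplexRecord], metadata: dict[str, str]):
    """Crude keyword prefilter for TCR-mimetic candidates.

    ``metadata`` maps complex_id to free text (title/antigen name). Flags
    antibody records whose text mentions HLA or MHC; manual validation of
    the hits remains the caller's responsibility.
    """
    hits = []
    for rec in records:
        text = metadata.get(rec.complex_id, "").upper()
        if rec.immunoglobulin_class is ImmunoglobulinClass.ANTIBODY and (
            "HLA" in text or "MHC" in text
        ):
            hits.append(rec)
    return hits


@dataclass
class TwoRoundResult:
    representatives: list[ComplexRecord]
    paratope_clusters: ClusterSet
    antigen_clusters: dict[str, ClusterSet] = field(default_factory=dict)


def two_round_representatives(
    records: list[ComplexRecord],
    identity_threshold: float = config.DEFAULT_IDENTITY_THRESHOLD,
    antigen_min_coverage: float = config.DEFAULT_ANTIGEN_MIN_COVERAGE,
) -> TwoRoundResult:
    """Two-round redundancy removal: paratope clusters, then antigen split.

    Returns one representative per (paratope cluster, antigen cluster):
    the best-resolution member, ties broken by lexicographic id.
    """
    if not records:
        raise CurationError("no records to curate")
    by_id = {}
    for rec in records:
        if rec.complex_id in by_id:
            raise CurationError(f"duplicate complex id {rec.complex_id!r}")
        if not rec.paratope_sequence:
            raise CurationError(f"{rec.complex_id}: empty concatenated CDR sequence")
        by_id[rec.complex_id] = rec

    paratope = greedy_cluster(
        {cid: rec.paratope_sequence for cid, rec in by_id.items()},
        threshold=identity_threshold,
    )

    representatives = []
    antigen_clusters = {}
    for seed, members in paratope.clusters:
        ag = greedy_cluster(
            {cid: by_id[cid].antigen_concat for cid in members},
            threshold=identity_threshold,
            min_coverage=antigen_min_coverage,
        )
        antigen_clusters[seed] = ag
        for _, ag_members in ag.clusters:
            best = min(
                ag_members, key=lambda cid: (by_id[cid].resolution, cid)
            )
            representatives.append(by_id[best])
    representatives.sort(key=lambda rec: rec.complex_id)
    return TwoRoundResult(representatives, paratope, antigen_clusters)


# ---------------------------------------------------------------------------
# TSV / JSON I/O

_TSV_COLUMNS = [
    "complex_id",
    "method",
    "resolution",
    "cdr1_vdj", "cdr2_vdj", "cdr3_vdj", "cdr1_vj", "cdr2_vj", "cdr3_vj",
    "antigen_sequences",
    "peptide_sequence",
    "immunoglobulin_class",
    "antigen_is_protein",
]


def read_records_tsv(path) -> list[ComplexRecord]:
    """Read ComplexRecords from a TSV (columns as written by
    :func:`write_records_tsv`; antigen sequences ';'-separated)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    records = []
    for _, row in df.iterrows():
        records.append(
            ComplexRecord(
                complex_id=row["complex_id"],
                method=row["method"],
                resolution=float(row["resolution"]),
                cdr_sequences=tuple(
                    row[c] for c in _TSV_COLUMNS[3:9]
                ),
                antigen_sequences=tuple(
                    s for s in row["antigen_sequences"].split(";") if s
                ),
                peptide_sequence=row["peptide_sequence"] or None,
                immunoglobulin_class=ImmunoglobulinClass(
                    row["immunoglobulin_class"]
                ),
                antigen_is_protein=row["antigen_is_protein"].lower() != "false",
            )
        )
    return records


def write_records_tsv(records: list[ComplexRecord], path) -> None:
    rows = []
    for rec in records:
        rows.append(
            dict(
                zip(
                    _TSV_COLUMNS,
                    [
                        rec.complex_id,
                        rec.method,
                        rec.resolution,
                        *rec.cdr_sequences,
                        ";".join(rec.antigen_sequences),
                        rec.peptide_sequence or "",
                        rec.immunoglobulin_class.value,
                        str(rec.antigen_is_protein),
                    ],
                )
            )
        )
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def write_cluster_map(result: TwoRoundResult, path) -> None:
    payload = {
        "identity_threshold": result.paratope_clusters.identity_threshold,
        "paratope_clusters": [
            {"seed": seed, "members": members}
            for seed, members in result.paratope_clusters.clusters
        ],
        "antigen_clusters": {
            seed: [
                {"seed": s, "members": m} for s, m in cs.clusters
            ]
            for seed, cs in result.antigen_clusters.items()
        },
        "representatives": [rec.complex_id for rec in result.representatives],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
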