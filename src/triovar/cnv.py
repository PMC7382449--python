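"""Array CNV calling from probe-level log2 ratios.

States are assigned per probe by fixed thresholds — gain for log2 ratio
strictly above 0.58, loss strictly below −1 — then maximal runs of
same-state probes become segments.  A probe of any other state (including
neutral) breaks a run, as does a genomic gap larger than ``max_gap_bp``
between consecutive probes of the run; runs shorter than ``min_probes``
are discarded.  Segment coordinates are the first and last probe
positions of the run, 1-based inclusive, and the reported size is
``end − start`` (the convention used by array nomenclature strings, where
breakpoints beyond the flanking probes are unknowable).

Copy-number zygosity (het vs hom loss, ×3 vs higher gain) is not
inferred from log2 alone; it is carried as optional input annotation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import FamilyPedigree, normalize_chrom

__all__ = [
    "ProbeState",
    "ProbeTrack",
    "CnvSegment",
    "GeneOverlap",
    "call_probe_state",
    "segment_probes",
    "segment_size_kbp",
    "overlap_genes",
    "compare_family",
    "iscn_string",
]

GAIN_CUTOFF = 0.58
LOSS_CUTOFF = -1.0


class ProbeState(str, enum.Enum):
    GAIN = "gain"
    LOSS = "loss"
    NEUTRAL = "neutral"


@dataclass
class ProbeTrack:
    chrom: str
    positions: np.ndarray  # sorted 1-based ints
    log2_ratio: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = normalize_chrom(self.chrom)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.log2_ratio = np.asarray(self.log2_ratio, dtype=float)
        if self.positions.shape != self.log2_ratio.shape:
            raise ValueError("positions and log2_ratio lengths differ")
        if len(self.positions) > 1 and not (np.diff(self.positions) > 0).all():
            raise ValueError(f"probe positions not strictly increasing on {self.chrom}")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, chrom: str) -> "ProbeTrack":
        sub = df[df["chrom"].map(normalize_chrom) == normalize_chrom(chrom)]
        sub = sub.sort_values("pos")
        return cls(chrom, sub["pos"].to_numpy(), sub["log2"].to_numpy())


@dataclass(frozen=True)
class CnvSegment:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    state: ProbeState
    n_probes: int = 0
    zygosity: Optional[str] = None  # optional annotation ("het"/"hom"), never inferred

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")

    @property
    def size_bp(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneOverlap:
    gene: str
    containment: str  # "entire_gene" | "partial"
    covered_start: int
    covered_end: int


def call_probe_state(
    log2: float, gain_cutoff: float = GAIN_CUTOFF, loss_cutoff: float = LOSS_CUTOFF
) -> ProbeState:
    """Threshold one probe: gain iff log2 > gain_cutoff (strict), loss iff
    log2 < loss_cutoff (strict), otherwise neutral."""
    if np.isnan(log2):
        raise ValueError("NaN log2 ratio")
    if log2 > gain_cutoff:
        return ProbeState.GAIN
    if log2 < loss_cutoff:
        return ProbeState.LOSS
    return ProbeState.NEUTRAL


def segment_probes(
    track: ProbeTrack,
    min_probes: int = 5,
    max_gap_bp: int = 100_000,
    gain_cutoff: float = GAIN_CUTOFF,
    loss_cutoff: float = LOSS_CUTOFF,
) -> list[CnvSegment]:
    """Call gain/loss segments as maximal same-state probe runs.

    A run ends at a probe of a different state or at a genomic gap larger
    than ``max_gap_bp``; only runs of at least ``min_probes`` probes are
    emitted, spanning first to last probe position.
    """
    states = [call_probe_state(v, gain_cutoff, loss_cutoff) for v in track.log2_ratio]
    segments: list[CnvSegment] = []
    run_start: Optional[int] = None  # index of first probe of current run
    prev_state: Optional[ProbeState] = None

    def flush(start_idx: int, end_idx: int, state: ProbeState) -> None:
        n = end_idx - start_idx + 1
        if state != ProbeState.NEUTRAL and n >= min_probes:
            segments.append(
                CnvSegment(
                    chrom=track.chrom,
                    start=int(track.positions[start_idx]),
                    end=int(track.positions[end_idx]),
                    state=state,
                    n_probes=n,
                )
            )

    for i, state in enumerate(states):
        if run_start is None:
            run_start, prev_state = i, state
            continue
        gap = track.positions[i] - track.positions[i - 1]
        if state != prev_state or gap > max_gap_bp:
            flush(run_start, i - 1, prev_state)
            run_start, prev_state = i, state
    if run_start is not None:
        flush(run_start, len(states) - 1, prev_state)
    return segments


def segment_size_kbp(segment: CnvSegment) -> float:
    """Segment size in kbp, (end − start)/1000, to 3 decimals."""
    return round(segment.size_bp / 1000.0, 3)


def overlap_genes(segment: CnvSegment, genes: pd.DataFrame) -> list[GeneOverlap]:
    """Intersect one segment with a gene-interval table (chrom, start, end,
    gene; 1-based inclusive).  ``entire_gene`` when the segment fully
    covers the gene, else ``partial`` with the covered sub-range."""
    sub = genes[genes["chrom"].map(normalize_chrom) == segment.chrom]
    if sub.empty:
        return []
    tree = IntervalTree()
    for _, row in sub.iterrows():
        # interval tree is half-open; +1 to make the end inclusive
        tree.addi(int(row["start"]), int(row["end"]) + 1, row["gene"])
    out: list[GeneOverlap] = []
    for iv in sorted(tree.overlap(segment.start, segment.end + 1)):
        g_start, g_end = iv.begin, iv.end - 1
        entire = segment.start <= g_start and segment.end >= g_end
        out.append(
            GeneOverlap(
                gene=iv.data,
                containment="entire_gene" if entire else "partial",
                covered_start=max(segment.start, g_start),
                covered_end=min(segment.end, g_end),
            )
        )
    return out


def _reciprocal_overlap(a: CnvSegment, b: CnvSegment) -> float:
    """Smaller of the two mutual overlap fractions (0 when disjoint)."""
    inter = min(a.end, b.end) - max(a.start, b.start)
    if inter <= 0 or a.chrom != b.chrom:
        return 0.0
    return min(inter / a.size_bp if a.size_bp else 1.0, inter / b.size_bp if b.size_bp else 1.0)


def compare_family(
    segments_by_member: dict[str, list[CnvSegment]],
    pedigree: FamilyPedigree,
    min_reciprocal_overlap: float = 0.5,
) -> pd.DataFrame:
    """Flag each proband segment as inherited or de novo.

    A proband segment reciprocally overlapping (≥ ``min_reciprocal_overlap``
    both ways) a same-state parental segment is inherited from that parent;
    matches in both parents are flagged ``shared_unknown`` (both-parent
    ambiguity); no parental match means ``de_novo``.
    """
    proband = pedigree.proband
    if proband is None:
        raise ValueError(f"no proband in family {pedigree.family_id}")
    mo, fa = pedigree.parents_of(proband.sample_id)
    rows = []
    for seg in segments_by_member.get(proband.sample_id, []):
        hits = {}
        for label, parent in (("mother", mo), ("father", fa)):
            if parent is None:
                continue
            hits[label] = any(
                p.state == seg.state and _reciprocal_overlap(seg, p) >= min_reciprocal_overlap
                for p in segments_by_member.get(parent, [])
            )
        if hits.get("mother") and hits.get("father"):
            flag = "shared_unknown"
        elif hits.get("mother"):
            flag = "inherited_from_mother"
        elif hits.get("father"):
            flag = "inherited_from_father"
        else:
            flag = "de_novo"
        rows.append(
            {
                "family": pedigree.family_id,
                "chrom": seg.chrom,
                "start": seg.start,
                "end": seg.end,
                "state": seg.state.value,
                "size_kbp": segment_size_kbp(seg),
                "inheritance": flag,
            }
        )
    return pd.DataFrame(rows)


def iscn_string(segment: CnvSegment, band: str = "") -> str:
    """ISCN-style array nomenclature, e.g.
    ``arr[hg19] 22q13.33(51,073,379-51,197,838)x1``."""
    cn = 1 if segment.state == ProbeState.LOSS else 3
    loc = f"{band}" if band else f"{segment.chrom}"
    return f"arr[hg19] {loc}({segment.start:,}-{segment.end:,})x{cn}"
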