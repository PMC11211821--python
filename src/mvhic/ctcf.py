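"""CTCF validation of called loops.

A loop is *peak-associated* when both anchor windows (the 10 kb anchor bin,
symmetrically expanded to at least 15 kb) overlap at least one ChIP-seq peak
from every one of the CTCF, SMC3 and RAD21 tracks (any replicate).  Each
anchor of a peak-associated loop is then assigned the highest-scoring CTCF
motif within a 10 kb search region; the loop is *CTCF validated* when the
left-anchor motif is on the + strand and the right-anchor motif on the -
strand (convergent, inward-facing sites, the cohesin-loop configuration).

All genomic intervals are 0-based half-open (BED semantics).  Motif tables
use a FIMO-style TSV dialect with 1-based inclusive coordinates, converted
on load.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .loops import LoopSet

FACTORS = ("CTCF", "SMC3", "RAD21")

__all__ = [
    "PeakTrack",
    "ValidationReport",
    "read_bed",
    "read_fimo",
    "expand_window",
    "peak_associated",
    "assign_anchor_motif",
    "ctcf_validated",
    "validation_report",
]


@dataclass
class PeakTrack:
    """ChIP-seq peak intervals for one factor and replicate."""

    factor: str
    intervals: pd.DataFrame  # columns: chrom, start, end
    replicate_id: str = "rep1"

    def __post_init__(self) -> None:
        needed = {"chrom", "start", "end"}
        if not needed <= set(self.intervals.columns):
            raise ValueError(f"peak frame needs columns {sorted(needed)}")
        if len(self.intervals) and not (self.intervals.start < self.intervals.end).all():
            raise ValueError("peak intervals require start < end")
        self.intervals = self.intervals.sort_values(["chrom", "start"]).reset_index(drop=True)

    def overlaps(self, chrom: str, start: float, end: float) -> bool:
        sel = self.intervals[self.intervals.chrom == chrom]
        return bool(((sel.start < end) & (sel.end > start)).any())


@dataclass
class ValidationReport:
    total_loops: int
    peak_associated: int
    ctcf_validated: int
    validated_loops: LoopSet | None = None

    @property
    def validation_rate(self) -> float:
        return self.ctcf_validated / self.total_loops if self.total_loops else 0.0


def read_bed(path, factor: str = "CTCF", replicate_id: str = "rep1") -> PeakTrack:
    """Read BED/narrowPeak; only the first three columns are used."""
    frame = pd.read_csv(path, sep="\t", header=None, comment="#")
    frame = frame.iloc[:, :3]
    frame.columns = ["chrom", "start", "end"]
    return PeakTrack(factor=factor, intervals=frame, replicate_id=replicate_id)


def read_fimo(path, p_threshold: float = 1e-4) -> pd.DataFrame:
    """Read a FIMO-style TSV of motif hits, filtered at ``p_threshold``.

    Expected columns (by name): motif_id, chrom (or sequence_name), start,
    stop, strand, score, p-value.  Coordinates are converted to 0-based
    half-open.
    """
    frame = pd.read_csv(path, sep="\t", comment="#")
    cols = {c.lower().replace("-", "_"): c for c in frame.columns}
    chrom_col = cols.get("chrom", cols.get("sequence_name"))
    if chrom_col is None:
        raise ValueError("motif table needs a 'chrom' or 'sequence_name' column")
    out = pd.DataFrame(
        {
            "motif_id": frame[cols.get("motif_id", chrom_col)],
            "chrom": frame[chrom_col],
            "start": frame[cols["start"]].astype(int) - 1,  # 1-based inclusive -> 0-based
            "end": frame[cols["stop"]].astype(int),
            "strand": frame[cols["strand"]],
            "score": frame[cols["score"]].astype(float),
            "pvalue": frame[cols["p_value"]].astype(float),
        }
    )
    return out[out.pvalue <= p_threshold].reset_index(drop=True)


def expand_window(start: float, end: float, min_width: float) -> tuple[float, float]:
    """Symmetrically expand [start, end) to at least ``min_width``."""
    width = end - start
    if width >= min_width:
        return float(start), float(end)
    pad = (min_width - width) / 2.0
    return float(start - pad), float(end + pad)


def _anchor_windows(loops: LoopSet, min_window: float, mode: str) -> list[tuple]:
    res = loops.resolution
    out = []
    for _, row in loops.loops.iterrows():
        i, j = int(row.bin_i), int(row.bin_j)
        if mode == "anchor":
            left = expand_window(i * res, (i + 1) * res, min_window)
            right = expand_window(j * res, (j + 1) * res, min_window)
        elif mode == "span":
            left = right = expand_window(i * res, (j + 1) * res, min_window)
        else:
            raise ValueError("mode must be 'anchor' or 'span'")
        out.append((i, j, left, right))
    return out


def peak_associated(
    loops: LoopSet,
    tracks: list[PeakTrack],
    min_window: float = 15_000.0,
    mode: str = "anchor",
) -> LoopSet:
    """Subset of loops whose anchors are supported by all three factors.

    A factor is satisfied when any of its replicate tracks overlaps the
    window; both anchors must be supported by every factor.  ``mode="span"``
    instead searches the whole [i, j] interval once per factor.
    """
    present = {t.factor for t in tracks}
    missing = [f for f in FACTORS if f not in present]
    if missing:
        raise ValueError(f"missing peak track(s) for factor(s): {', '.join(missing)}")
    by_factor: dict[str, list[PeakTrack]] = {}
    for t in tracks:
        by_factor.setdefault(t.factor, []).append(t)
    keep = []
    for i, j, left, right in _anchor_windows(loops, min_window, mode):
        ok = True
        for factor in FACTORS:
            reps = by_factor[factor]
            left_hit = any(t.overlaps(loops.chrom, *left) for t in reps)
            right_hit = any(t.overlaps(loops.chrom, *right) for t in reps)
            if not (left_hit and right_hit):
                ok = False
                break
        if ok:
            keep.append((i, j))
    frame = loops.loops
    kept = set(keep)
    mask = np.array(
        [(int(r.bin_i), int(r.bin_j)) in kept for _, r in frame.iterrows()], dtype=bool
    )
    return LoopSet(
        chrom=loops.chrom,
        resolution=loops.resolution,
        loops=frame[mask].reset_index(drop=True) if len(frame) else frame.copy(),
    )


def assign_anchor_motif(
    anchor: tuple[float, float],
    hits: pd.DataFrame,
    chrom: str,
    search: float = 10_000.0,
) -> pd.Series | None:
    """Highest-scoring motif overlapping the >= ``search``-wide anchor region.

    Ties on score break to the leftmost start.  Returns None when the region
    holds no hit.
    """
    start, end = expand_window(anchor[0], anchor[1], search)
    sel = hits[(hits.chrom == chrom) & (hits.start < end) & (hits.end > start)]
    if sel.empty:
        return None
    sel = sel.sort_values(["score", "start"], ascending=[False, True], kind="stable")
    return sel.iloc[0]


def ctcf_validated(left_motif, right_motif) -> bool:
    """Convergent orientation: left anchor on +, right anchor on -."""
    if left_motif is None or right_motif is None:
        return False
    return str(left_motif.strand) == "+" and str(right_motif.strand) == "-"


def validation_report(
    loops: LoopSet,
    tracks: list[PeakTrack],
    hits: pd.DataFrame,
    min_window: float = 15_000.0,
    motif_search: float = 10_000.0,
    mode: str = "anchor",
) -> ValidationReport:
    """Full pipeline: peak association, motif assignment, convergence test."""
    associated = peak_associated(loops, tracks, min_window=min_window, mode=mode)
    res = loops.resolution
    validated_rows = []
    for _, row in associated.loops.iterrows():
        i, j = int(row.bin_i), int(row.bin_j)
        left = assign_anchor_motif((i * res, (i + 1) * res), hits, loops.chrom, motif_search)
        right = assign_anchor_motif((j * res, (j + 1) * res), hits, loops.chrom, motif_search)
        if ctcf_validated(left, right):
            validated_rows.append(row)
    validated = LoopSet(
        chrom=loops.chrom,
        resolution=loops.resolution,
        loops=pd.DataFrame(validated_rows, columns=associated.loops.columns).reset_index(
            drop=True
        ),
    )
    return ValidationReport(
        total_loops=len(loops),
        peak_associated=len(associated),
        ctcf_validated=len(validated),
        validated_loops=validated,
    )
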