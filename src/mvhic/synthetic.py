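"""Synthetic paired low/high-coverage Hi-C fixtures with planted truth.

The generator emulates the statistical structure the enhancement task cares
about: a power-law distance decay, block TADs, focal Gaussian loop
enrichments, Poisson count noise, binomial coverage thinning, and matched
ChIP-seq peak / CTCF motif annotations with convergent orientations at loop
anchors.  Every planted feature is returned as ground truth so loop calling,
enhancement and CTCF validation can all be scored without external data.

The Poisson intensity at pixel (i, j), distance d = |i - j| <= band, is

    lambda(i, j) = s * (1 + d)^(-decay_exponent) * tad(i, j)
                     * (1 + sum_loops (fold - 1) * exp(-r^2 / (2 sigma^2))),

with s chosen so the expected upper-triangle total equals ``depth`` reads.
The high-coverage map is a Poisson draw from lambda (mirrored); the
low-coverage map is a binomial thinning of it at ``downsample_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .contacts import BAND_BINS, ContactMap, downsample
from .ctcf import FACTORS, PeakTrack

__all__ = ["SyntheticSpec", "generate_pair", "generate_annotations", "write_annotations", "planted_truth_pixels"]


@dataclass
class SyntheticSpec:
    """Generative parameters for one synthetic chromosome.

    Defaults model a modestly deep 4 Mb locus: 400 bins of 10 kb, 1e6 reads,
    1 Mb TADs, ten 5-fold loops of 1-bin width, and 1/16 coverage thinning.
    """

    n_bins: int = 400
    resolution: int = 10_000
    depth: float = 1e6
    decay_exponent: float = 1.0
    decay_floor: float = 0.0  # relative intensity floor before depth scaling
    band_bins: int = BAND_BINS
    tad_size: int = 100  # bins per domain (1 Mb at 10 kb)
    tad_within: float = 1.2
    tad_between: float = 0.6
    n_loops: int = 10
    loop_fold: float = 5.0
    loop_sigma: float = 1.0
    loop_distance: tuple[int, int] = (15, 100)  # 150 kb - 1 Mb anchor spans
    loop_margin: int = 20  # keep anchors away from matrix edges
    loop_separation: int = 15  # min Chebyshev distance between planted loops
    convergent_fraction: float = 1.0
    downsample_rate: float = 1.0 / 16.0
    decoy_peaks: int = 20
    decoy_motifs: int = 20
    seed: int = 0
    chrom: str = "chrS"

    def __post_init__(self) -> None:
        # YAML scalars like "1e6" arrive as strings; coerce numerics
        for field_ in ("depth", "decay_exponent", "decay_floor", "tad_within",
                       "tad_between", "loop_fold", "loop_sigma", "convergent_fraction",
                       "downsample_rate"):
            setattr(self, field_, float(getattr(self, field_)))
        for field_ in ("n_bins", "resolution", "band_bins", "tad_size", "n_loops",
                       "loop_margin", "loop_separation", "decoy_peaks", "decoy_motifs",
                       "seed"):
            setattr(self, field_, int(getattr(self, field_)))
        if not 0 < self.downsample_rate <= 1:
            raise ValueError("downsample_rate must be in (0, 1]")
        if self.loop_fold <= 1:
            raise ValueError("loop_fold must exceed 1")
        if self.loop_distance[1] > self.band_bins:
            raise ValueError("planted loops must lie inside the band")


def _place_loops(spec: SyntheticSpec, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Rejection-sample well-separated loop anchors inside the band.

    Loops are kept pairwise separated in pixel space and anchor bins are
    kept distinct across loops, so each anchor carries exactly one planted
    motif and the convergence labels stay unambiguous ground truth.
    """
    placed: list[tuple[int, int]] = []
    anchors: list[int] = []
    lo, hi = spec.loop_distance
    attempts = 0
    while len(placed) < spec.n_loops:
        attempts += 1
        if attempts > 10_000:
            raise RuntimeError("could not place loops; spec too crowded")
        d = int(rng.integers(lo, hi + 1))
        if spec.n_bins - spec.loop_margin - d <= spec.loop_margin:
            continue  # distance infeasible for this matrix size
        i = int(rng.integers(spec.loop_margin, spec.n_bins - spec.loop_margin - d))
        j = i + d
        far_in_pixels = all(
            max(abs(i - a), abs(j - b)) >= spec.loop_separation for a, b in placed
        )
        distinct_anchors = all(abs(i - a) >= 2 and abs(j - a) >= 2 for a in anchors)
        if far_in_pixels and distinct_anchors:
            placed.append((i, j))
            anchors.extend((i, j))
    return sorted(placed)


def _tad_multiplier(spec: SyntheticSpec) -> np.ndarray:
    domain = np.arange(spec.n_bins) // spec.tad_size
    same = domain[:, None] == domain[None, :]
    return np.where(same, spec.tad_within, spec.tad_between)


def intensity(spec: SyntheticSpec, loops: list[tuple[int, int]]) -> np.ndarray:
    """Expected-count matrix lambda(i, j), scaled to the target depth."""
    n = spec.n_bins
    idx = np.arange(n)
    d = np.abs(np.subtract.outer(idx, idx))
    lam = np.maximum((1.0 + d) ** (-spec.decay_exponent), spec.decay_floor)
    lam = np.where(d <= spec.band_bins, lam, 0.0)
    lam *= _tad_multiplier(spec)
    if loops:
        bump = np.zeros((n, n))
        ii, jj = np.meshgrid(idx, idx, indexing="ij")
        for a, b in loops:
            for (r, c) in ((a, b), (b, a)):
                bump += np.exp(
                    -((ii - r) ** 2 + (jj - c) ** 2) / (2.0 * spec.loop_sigma**2)
                )
        lam *= 1.0 + (spec.loop_fold - 1.0) * bump
    lam *= spec.depth / np.triu(lam).sum()
    return lam


def planted_truth_pixels(truth: pd.DataFrame) -> set[tuple[int, int]]:
    return set(zip(truth.bin_i.astype(int), truth.bin_j.astype(int)))


def generate_pair(spec: SyntheticSpec) -> tuple[ContactMap, ContactMap, pd.DataFrame]:
    """Draw one (low, high, truth) triple.

    ``truth`` is a frame with columns bin_i, bin_j, convergent.  The same
    spec and seed always reproduce the same pair bit for bit.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xC0FFEE]))
    loops = _place_loops(spec, rng)
    lam = intensity(spec, loops)
    upper = rng.poisson(np.triu(lam))
    counts = (upper + np.triu(upper, 1).T).astype(float)
    high = ContactMap(chrom=spec.chrom, resolution=spec.resolution, counts=counts)
    low = downsample(high, spec.downsample_rate, seed=int(rng.integers(0, 2**31 - 1)))
    n_conv = int(round(spec.convergent_fraction * len(loops)))
    convergent = np.zeros(len(loops), dtype=bool)
    convergent[:n_conv] = True  # loops are sorted; flags attach deterministically
    truth = pd.DataFrame(
        {
            "bin_i": [a for a, _ in loops],
            "bin_j": [b for _, b in loops],
            "convergent": convergent,
        }
    )
    return low, high, truth


def generate_annotations(
    spec: SyntheticSpec, truth: pd.DataFrame
) -> tuple[list[PeakTrack], pd.DataFrame]:
    """Matched ChIP-seq peaks and CTCF motif hits for the planted loops.

    Every anchor gets a peak for each of CTCF/SMC3/RAD21 and one CTCF motif:
    convergent loops get (+, -) strands, the rest the divergent (-, +)
    configuration.  Planted motifs outscore decoys so anchor assignment is
    unambiguous; decoy peaks and motifs are scattered uniformly.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xA110C]))
    res = spec.resolution
    chrom_len = spec.n_bins * res
    anchor_bins = sorted(set(truth.bin_i.astype(int)) | set(truth.bin_j.astype(int)))

    def peak_at(b: int) -> tuple[int, int]:
        center = b * res + res // 2
        return center - 250, center + 250

    tracks = []
    for factor in FACTORS:
        rows = [peak_at(b) for b in anchor_bins]
        rows += [
            (p, p + 500)
            for p in rng.integers(0, chrom_len - 500, size=spec.decoy_peaks)
        ]
        frame = pd.DataFrame(rows, columns=["start", "end"])
        frame.insert(0, "chrom", spec.chrom)
        tracks.append(PeakTrack(factor=factor, intervals=frame, replicate_id="rep1"))

    motif_rows = []
    for _, row in truth.iterrows():
        strands = ("+", "-") if row.convergent else ("-", "+")
        for b, strand in zip((int(row.bin_i), int(row.bin_j)), strands):
            center = b * res + res // 2
            motif_rows.append(
                {
                    "motif_id": "CTCF",
                    "chrom": spec.chrom,
                    "start": center - 9,
                    "end": center + 10,
                    "strand": strand,
                    "score": 20.0 + rng.uniform(0, 1),
                    "pvalue": 1e-6,
                }
            )
    for _ in range(spec.decoy_motifs):
        p = int(rng.integers(0, chrom_len - 19))
        motif_rows.append(
            {
                "motif_id": "CTCF",
                "chrom": spec.chrom,
                "start": p,
                "end": p + 19,
                "strand": rng.choice(["+", "-"]),
                "score": float(rng.uniform(5, 10)),
                "pvalue": 5e-5,
            }
        )
    motifs = pd.DataFrame(
        motif_rows, columns=["motif_id", "chrom", "start", "end", "strand", "score", "pvalue"]
    )
    return tracks, motifs


def write_annotations(outdir, tracks: list[PeakTrack], motifs: pd.DataFrame) -> dict[str, str]:
    """Write peaks as BED and motifs as FIMO-style TSV; returns file paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for track in tracks:
        path = outdir / f"{track.factor.lower()}_{track.replicate_id}.bed"
        track.intervals.to_csv(path, sep="\t", header=False, index=False)
        paths[track.factor] = str(path)
    fimo = pd.DataFrame(
        {
            "motif_id": motifs.motif_id,
            "chrom": motifs.chrom,
            "start": motifs.start + 1,  # FIMO dialect: 1-based inclusive
            "stop": motifs.end,
            "strand": motifs.strand,
            "score": motifs.score,
            "p-value": motifs.pvalue,
        }
    )
    fimo_path = outdir / "motifs_fimo.tsv"
    fimo.to_csv(fimo_path, sep="\t", index=False)
    paths["motifs"] = str(fimo_path)
    return paths
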