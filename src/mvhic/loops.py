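"""HiCCUPS-style chromatin-loop statistics and loop calling.

Each banded pixel (i, j) is tested for focal enrichment against four local
background estimates (donut, lower-left quadrant, horizontal and vertical
stripes).  For kernel k the local expected value is

    lambda_k(i, j) = E[|i - j|] * sum_footprint(O) / sum_footprint(E),

where E is the per-distance expected matrix; the enrichment ratio is
O(i, j) / lambda_k and the p-value is the upper Poisson tail
P(K >= O(i, j)) with mean lambda_k.

Calling requires every kernel's enrichment ratio to clear its threshold
(donut and lower-left > 1.75, stripes > 1.5) and its p-value to be
significant.  Significance defaults to a Benjamini-Hochberg correction at
q = 0.1 applied within lambda chunks (geometric bins of width 2^(1/3)), the
correction used by the original HiCCUPS; a raw per-pixel p < 0.1 mode is
available via ``LoopCallConfig(fdr_q=None)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal, stats
from statsmodels.stats.multitest import multipletests

from .contacts import BAND_BINS, ContactMap

KERNEL_KINDS = ("donut", "lower_left", "horizontal", "vertical")

__all__ = [
    "KernelSpec",
    "PixelStats",
    "LoopStatistics",
    "LoopSet",
    "LoopCallConfig",
    "default_kernels",
    "expected_by_distance",
    "kernel_lambda",
    "loop_statistics",
    "call_loops",
    "counts_for_statistics",
    "read_bedpe",
]


@dataclass(frozen=True)
class KernelSpec:
    """Geometry of one local-background kernel.

    ``peak_radius`` (p) is the half-width of the excluded central square and
    ``donut_radius`` (w) the outer half-width; defaults p=2, w=5 are the
    HiCCUPS values for 10 kb resolution.
    """

    kind: str
    peak_radius: int = 2
    donut_radius: int = 5

    def __post_init__(self) -> None:
        if self.kind not in KERNEL_KINDS:
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if not self.donut_radius > self.peak_radius >= 1:
            raise ValueError("require donut_radius > peak_radius >= 1")

    def mask(self) -> np.ndarray:
        """(2w+1, 2w+1) boolean footprint centred on the tested pixel."""
        p, w = self.peak_radius, self.donut_radius
        di, dj = np.mgrid[-w : w + 1, -w : w + 1]
        cheb = np.maximum(np.abs(di), np.abs(dj))
        if self.kind == "donut":
            m = (cheb <= w) & (cheb > p) & (di != 0) & (dj != 0)
        elif self.kind == "lower_left":
            m = (1 <= di) & (di <= w) & (-w <= dj) & (dj <= -1)
            m &= ~((di <= p) & (dj >= -p))
        elif self.kind == "horizontal":
            m = (np.abs(di) <= 1) & (np.abs(dj) > p) & (np.abs(dj) <= w)
        else:  # vertical
            m = (np.abs(dj) <= 1) & (np.abs(di) > p) & (np.abs(di) <= w)
        return m

    def offsets(self) -> list[tuple[int, int]]:
        """Footprint as a list of (di, dj) offsets."""
        w = self.donut_radius
        return [(di - w, dj - w) for di, dj in np.argwhere(self.mask())]


def default_kernels(peak_radius: int = 2, donut_radius: int = 5) -> tuple[KernelSpec, ...]:
    return tuple(KernelSpec(k, peak_radius, donut_radius) for k in KERNEL_KINDS)


@dataclass
class PixelStats:
    """Per-pixel loop statistics across the four kernels."""

    bin_i: int
    bin_j: int
    observed: float
    ratio_by_kernel: dict[str, float]
    pvalue_by_kernel: dict[str, float]


@dataclass
class LoopStatistics:
    """Dense per-pixel statistics for one chromosome.

    Arrays are (n, n); only ``valid`` pixels (upper triangle, inside the
    band, full kernel footprint inside the matrix, nonzero-marginal bins)
    carry meaningful values.
    """

    chrom: str
    resolution: int
    observed: np.ndarray
    expected: np.ndarray  # per-distance expected vector
    lam: dict[str, np.ndarray]
    ratio: dict[str, np.ndarray]
    pvalue: dict[str, np.ndarray]
    valid: np.ndarray

    def pixel(self, i: int, j: int) -> PixelStats:
        return PixelStats(
            bin_i=i,
            bin_j=j,
            observed=float(self.observed[i, j]),
            ratio_by_kernel={k: float(self.ratio[k][i, j]) for k in self.ratio},
            pvalue_by_kernel={k: float(self.pvalue[k][i, j]) for k in self.pvalue},
        )


@dataclass
class LoopSet:
    """Called loop pixels with attached statistics."""

    chrom: str
    resolution: int
    loops: pd.DataFrame  # columns: bin_i, bin_j, observed, ratio_*, pvalue_*

    REQUIRED = ("bin_i", "bin_j")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.loops.columns:
                raise ValueError(f"LoopSet frame missing column {col!r}")
        if len(self.loops):
            if not (self.loops.bin_i < self.loops.bin_j).all():
                raise ValueError("loops require bin_i < bin_j")
            if self.loops.duplicated(["bin_i", "bin_j"]).any():
                raise ValueError("duplicate loop pixels")

    def __len__(self) -> int:
        return len(self.loops)

    def pixels(self) -> set[tuple[int, int]]:
        return set(zip(self.loops.bin_i.astype(int), self.loops.bin_j.astype(int)))

    @classmethod
    def from_pixels(cls, pixels, chrom: str = "chr?", resolution: int = 10_000) -> "LoopSet":
        arr = sorted(set((int(i), int(j)) for i, j in pixels))
        frame = pd.DataFrame(arr, columns=["bin_i", "bin_j"])
        return cls(chrom=chrom, resolution=resolution, loops=frame)

    def to_bedpe(self, path) -> None:
        """Write loops as BEDPE with ratio/p-value score columns."""
        res = self.resolution
        frame = self.loops
        out = pd.DataFrame(
            {
                "chrom1": self.chrom,
                "start1": frame.bin_i * res,
                "end1": (frame.bin_i + 1) * res,
                "chrom2": self.chrom,
                "start2": frame.bin_j * res,
                "end2": (frame.bin_j + 1) * res,
            }
        )
        for col in frame.columns:
            if col not in ("bin_i", "bin_j"):
                out[col] = frame[col].to_numpy()
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_bedpe(cls, path, resolution: int | None = None) -> "LoopSet":
        """Read a BEDPE loop list (own dialect or external caller output).

        Headerless 6+ column BEDPE is accepted; anchors are collapsed to the
        bin of their midpoint.
        """
        head = pd.read_csv(path, sep="\t", nrows=1, header=None)
        has_header = str(head.iloc[0, 0]).startswith("chrom")
        frame = pd.read_csv(path, sep="\t", header=0 if has_header else None)
        if not has_header:
            frame.columns = ["chrom1", "start1", "end1", "chrom2", "start2", "end2", *[
                f"score{k}" for k in range(frame.shape[1] - 6)
            ]]
        if resolution is None:
            resolution = int((frame.end1 - frame.start1).mode().iloc[0])
        mid1 = (frame.start1 + frame.end1) // 2
        mid2 = (frame.start2 + frame.end2) // 2
        out = pd.DataFrame(
            {"bin_i": mid1 // resolution, "bin_j": mid2 // resolution}
        ).astype(int)
        for col in frame.columns:
            if col.startswith(("ratio_", "pvalue_", "observed", "score")):
                out[col] = frame[col].to_numpy()
        chrom = str(frame.chrom1.iloc[0]) if len(frame) else "chr?"
        swap = out.bin_i > out.bin_j
        out.loc[swap, ["bin_i", "bin_j"]] = out.loc[swap, ["bin_j", "bin_i"]].to_numpy()
        out = out.drop_duplicates(["bin_i", "bin_j"]).reset_index(drop=True)
        return cls(chrom=chrom, resolution=resolution, loops=out)


def read_bedpe(path, resolution: int | None = None) -> LoopSet:
    """Convenience wrapper around :meth:`LoopSet.from_bedpe`."""
    return LoopSet.from_bedpe(path, resolution=resolution)


def expected_by_distance(cmap: ContactMap | np.ndarray, band_bins: int | None = None) -> np.ndarray:
    """Mean contact count per genomic distance, over nonzero-marginal bins.

    Returns a length-n vector; entry d is the mean of pixels (i, i+d) whose
    two bins both have a nonzero marginal, or 0 where no valid pixel exists.
    """
    counts = cmap.counts if isinstance(cmap, ContactMap) else np.asarray(counts_like(cmap))
    n = counts.shape[0]
    valid = counts.sum(axis=0) > 0
    out = np.zeros(n)
    dmax = n if band_bins is None else min(n, band_bins + 1)
    for d in range(dmax):
        diag = np.diagonal(counts, d)
        ok = valid[: n - d] & valid[d:]
        if ok.any():
            out[d] = diag[ok].mean()
    return out


def counts_like(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("expected a square matrix")
    return arr


def counts_for_statistics(cmap: ContactMap, cap: float = 255.0) -> ContactMap:
    """Bring a map to the count scale required by the Poisson tests.

    Generated (normalized) matrices are rescaled by the clamp cap and rounded
    to integers; raw maps pass through unchanged.
    """
    if not cmap.normalized:
        return cmap
    counts = np.rint(cmap.counts * cap)
    return ContactMap(chrom=cmap.chrom, resolution=cmap.resolution, counts=counts)


def kernel_lambda(
    cmap: ContactMap | np.ndarray,
    expected: np.ndarray,
    i: int,
    j: int,
    kernel: KernelSpec,
) -> float:
    """Local expected value at one pixel; NaN when the footprint leaves the matrix."""
    counts = cmap.counts if isinstance(cmap, ContactMap) else counts_like(cmap)
    n = counts.shape[0]
    w = kernel.donut_radius
    if i - w < 0 or j - w < 0 or i + w >= n or j + w >= n:
        return float("nan")
    mask = kernel.mask()
    obs_win = counts[i - w : i + w + 1, j - w : j + w + 1]
    dist = np.abs(np.add.outer(np.arange(i - w, i + w + 1), -np.arange(j - w, j + w + 1)))
    exp_win = expected[np.minimum(dist, len(expected) - 1)]
    exp_sum = exp_win[mask].sum()
    if exp_sum <= 0:
        return 0.0
    return float(expected[abs(i - j)] * obs_win[mask].sum() / exp_sum)


def loop_statistics(
    cmap: ContactMap,
    kernels: tuple[KernelSpec, ...] | None = None,
    band_bins: int = BAND_BINS,
) -> LoopStatistics:
    """Compute observed counts, lambdas, enrichment ratios and Poisson p-values.

    Requires count-scale input (use :func:`counts_for_statistics` for
    normalized matrices).  Candidate pixels are the strict upper triangle
    with ``w < j - i <= band_bins`` whose kernel footprints fit inside the
    matrix and whose bins have nonzero marginals.
    """
    if cmap.normalized:
        raise ValueError(
            "loop_statistics needs count-scale input; rescale normalized maps "
            "with counts_for_statistics first"
        )
    kernels = default_kernels() if kernels is None else kernels
    counts = cmap.counts
    n = cmap.n_bins
    obs = np.rint(counts)
    expected = expected_by_distance(cmap)
    idx = np.arange(n)
    dist = np.abs(np.subtract.outer(idx, idx))
    exp2d = expected[dist]

    w = max(k.donut_radius for k in kernels)
    valid = (dist > w) & (dist <= band_bins) & (idx[:, None] < idx[None, :])
    interior = (idx >= w) & (idx < n - w)
    valid &= interior[:, None] & interior[None, :]
    nonzero = counts.sum(axis=0) > 0
    valid &= nonzero[:, None] & nonzero[None, :]

    lam: dict[str, np.ndarray] = {}
    ratio: dict[str, np.ndarray] = {}
    pvalue: dict[str, np.ndarray] = {}
    for k in kernels:
        mask = k.mask().astype(float)[::-1, ::-1]  # correlate == convolve with flipped kernel
        obs_sum = signal.fftconvolve(counts, mask, mode="same")
        exp_sum = signal.fftconvolve(exp2d, mask, mode="same")
        with np.errstate(divide="ignore", invalid="ignore"):
            lk = np.where(exp_sum > 0, exp2d * obs_sum / np.maximum(exp_sum, 1e-300), 0.0)
        lk = np.maximum(lk, 0.0)  # fft round-off can go slightly negative
        rk = np.where(lk > 0, obs / np.maximum(lk, 1e-300), 0.0)
        pk = np.where(lk > 0, stats.poisson.sf(obs - 1, np.maximum(lk, 1e-300)),
                      np.where(obs > 0, 0.0, 1.0))
        # degenerate all-zero neighborhoods: no evidence, never significant
        pk = np.where((lk == 0) & (obs == 0), 1.0, pk)
        lam[k.kind], ratio[k.kind], pvalue[k.kind] = lk, rk, pk
    return LoopStatistics(
        chrom=cmap.chrom,
        resolution=cmap.resolution,
        observed=obs,
        expected=expected,
        lam=lam,
        ratio=ratio,
        pvalue=pvalue,
        valid=valid,
    )


@dataclass
class LoopCallConfig:
    """Thresholds for :func:`call_loops`.

    ``fdr_q`` selects lambda-chunked Benjamini-Hochberg significance at the
    given level (HiCCUPS practice); set it to ``None`` for raw per-pixel
    ``pvalue < p_threshold`` tests.  ``combine`` chooses whether every kernel
    ("all") or any kernel ("any") must pass.
    """

    p_threshold: float = 0.1
    ratio_thresholds: dict[str, float] = field(
        default_factory=lambda: {
            "donut": 1.75,
            "lower_left": 1.75,
            "horizontal": 1.5,
            "vertical": 1.5,
        }
    )
    combine: str = "all"
    fdr_q: float | None = 0.1
    lambda_chunk_base: float = 2.0 ** (1.0 / 3.0)
    cluster: bool = False


def _significant(stats_: LoopStatistics, kind: str, cfg: LoopCallConfig) -> np.ndarray:
    """Boolean p-value significance map for one kernel."""
    pv = stats_.pvalue[kind]
    if cfg.fdr_q is None:
        return pv < cfg.p_threshold
    lam = stats_.lam[kind]
    sig = np.zeros_like(pv, dtype=bool)
    sel = stats_.valid & (lam > 0)
    if not sel.any():
        return sig
    chunk = np.floor(np.log(lam[sel]) / np.log(cfg.lambda_chunk_base)).astype(int)
    pvals = pv[sel]
    rej = np.zeros(pvals.shape, dtype=bool)
    for c in np.unique(chunk):
        in_chunk = chunk == c
        rej[in_chunk] = multipletests(pvals[in_chunk], alpha=cfg.fdr_q, method="fdr_bh")[0]
    sig[sel] = rej
    return sig


def call_loops(stats_: LoopStatistics, config: LoopCallConfig | None = None) -> LoopSet:
    """Threshold per-pixel statistics into a loop set."""
    cfg = LoopCallConfig() if config is None else config
    passes = []
    for kind in stats_.ratio:
        thr = cfg.ratio_thresholds.get(kind, 1.75)
        passes.append((stats_.ratio[kind] > thr) & _significant(stats_, kind, cfg))
    if cfg.combine == "all":
        keep = np.logical_and.reduce(passes)
    elif cfg.combine == "any":
        keep = np.logical_or.reduce(passes)
    else:
        raise ValueError(f"combine must be 'all' or 'any', got {cfg.combine!r}")
    keep &= stats_.valid
    if cfg.cluster and keep.any():
        labels, nlab = ndimage.label(keep, structure=np.ones((3, 3), dtype=int))
        best = np.zeros_like(keep)
        score = stats_.ratio["donut"]
        for lab in range(1, nlab + 1):
            members = np.argwhere(labels == lab)
            i, j = max(map(tuple, members), key=lambda px: (score[px], -px[0], -px[1]))
            best[i, j] = True
        keep = best
    ii, jj = np.nonzero(keep)
    frame = pd.DataFrame({"bin_i": ii, "bin_j": jj, "observed": stats_.observed[ii, jj]})
    for kind in stats_.ratio:
        frame[f"ratio_{kind}"] = stats_.ratio[kind][ii, jj]
        frame[f"pvalue_{kind}"] = stats_.pvalue[kind][ii, jj]
    frame = frame.sort_values(["bin_i", "bin_j"]).reset_index(drop=True)
    return LoopSet(chrom=stats_.chrom, resolution=stats_.resolution, loops=frame)


def call_loops_matrix(
    cmap: ContactMap,
    config: LoopCallConfig | None = None,
    kernels: tuple[KernelSpec, ...] | None = None,
    band_bins: int = BAND_BINS,
    cap: float = 255.0,
) -> LoopSet:
    """Statistics + thresholding in one step; accepts normalized matrices."""
    return call_loops(
        loop_statistics(counts_for_statistics(cmap, cap=cap), kernels=kernels, band_bins=band_bins),
        config,
    )
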