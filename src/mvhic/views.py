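"""Five-channel multiview stacks: [primary, O/E, TAD insulation, loop-p, loop-r].

All derived channels are computed from the same coverage level as the primary
channel, so the stack built from a low-coverage matrix never sees the
high-coverage target.  Views are computed on the whole chromosome before
tiling so insulation windows and loop kernels see context beyond one tile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contacts import BAND_BINS, ContactMap, clamp_normalize
from .loops import (
    LoopStatistics,
    counts_for_statistics,
    default_kernels,
    expected_by_distance,
    loop_statistics,
)

CHANNEL_NAMES = ("primary", "oe", "tad", "loop_p", "loop_r")

__all__ = [
    "MultiviewStack",
    "ViewConfig",
    "oe_view",
    "tad_view",
    "loop_views",
    "build_stack",
    "CHANNEL_NAMES",
]


@dataclass
class ViewConfig:
    """Constants governing view computation.

    oe_ceiling:
        O/E values are clipped to this ceiling (ratios are unbounded above).
    tad_window:
        Insulation-window half-width in bins; 50 bins = 500 kb at 10 kb.
    loop_p_cap:
        Cap on -log10(p) before rescaling the loop-p channel to [0, 1].
    loop_r_cap:
        Cap on the donut enrichment ratio before rescaling to [0, 1].
    count_cap:
        Clamp cap used to bring normalized matrices back to count scale for
        the Poisson loop statistics.
    """

    oe_ceiling: float = 4.0
    tad_window: int = 50
    loop_p_cap: float = 10.0
    loop_r_cap: float = 4.0
    count_cap: float = 255.0
    band_bins: int = BAND_BINS
    peak_radius: int = 2
    donut_radius: int = 5


@dataclass
class MultiviewStack:
    """Channel-stacked views of one contact map.

    ``channels`` has shape (C, n, n) with C = 5 for the full stack; channel 0
    is always the (normalized) primary matrix.
    """

    channels: np.ndarray
    channel_names: tuple[str, ...] = CHANNEL_NAMES
    chrom: str = "chr?"
    resolution: int = 10_000

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 3:
            raise ValueError("channels must be (C, n, n)")
        if self.channels.shape[0] != len(self.channel_names):
            raise ValueError("channel count does not match channel_names")
        if not np.isfinite(self.channels).all():
            raise ValueError("stack contains non-finite values")

    @property
    def n_bins(self) -> int:
        return self.channels.shape[-1]

    def channel(self, name: str) -> np.ndarray:
        return self.channels[self.channel_names.index(name)]


def oe_view(cmap: ContactMap, ceiling: float = 4.0, band_bins: int = BAND_BINS) -> np.ndarray:
    """Observed-over-expected matrix, clipped to ``ceiling``, 0 where E = 0."""
    expected = expected_by_distance(cmap)
    n = cmap.n_bins
    idx = np.arange(n)
    exp2d = expected[np.abs(np.subtract.outer(idx, idx))]
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(exp2d > 0, cmap.counts / np.maximum(exp2d, 1e-300), 0.0)
    return np.clip(oe, 0.0, ceiling)


def insulation_score(cmap: ContactMap, window: int = 50) -> np.ndarray:
    """Per-bin insulation: mean contact in the square [i-w, i) x (i, i+w].

    Bins without a full window on both sides get NaN.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    counts = cmap.counts
    n = cmap.n_bins
    # summed-area table for O(1) rectangle sums
    sat = np.zeros((n + 1, n + 1))
    sat[1:, 1:] = counts.cumsum(0).cumsum(1)

    def rect(r0, r1, c0, c1):  # sum over [r0, r1) x [c0, c1)
        return sat[r1, c1] - sat[r0, c1] - sat[r1, c0] + sat[r0, c0]

    out = np.full(n, np.nan)
    for i in range(window, n - window):
        out[i] = rect(i - window, i, i + 1, i + window + 1) / window**2
    return out


def tad_view(cmap: ContactMap, window: int = 50) -> np.ndarray:
    """Insulation-score view broadcast to 2-D.

    IS(i) is log2-normalized by the chromosome-mean insulation; pixel (i, j)
    is the anchor mean (ISnorm(i) + ISnorm(j)) / 2.  Bins lacking a full
    window, and bins with zero insulation, contribute 0.
    """
    raw = insulation_score(cmap, window=window)
    ok = np.isfinite(raw) & (raw > 0)
    norm = np.zeros(cmap.n_bins)
    if ok.any():
        mean = raw[ok].mean()
        if mean > 0:
            norm[ok] = np.log2(raw[ok] / mean)
    return 0.5 * (norm[:, None] + norm[None, :])


def loop_views(
    stats_or_map: LoopStatistics | ContactMap,
    p_cap: float = 10.0,
    r_cap: float = 4.0,
    count_cap: float = 255.0,
    band_bins: int = BAND_BINS,
) -> tuple[np.ndarray, np.ndarray]:
    """Loop significance and enrichment channels from the donut kernel.

    loop_p = min(-log10 p, p_cap) / p_cap and loop_r = min(ratio, r_cap) /
    r_cap on valid pixels, mirrored to a symmetric matrix; pixels skipped by
    the edge policy are 0.
    """
    if isinstance(stats_or_map, ContactMap):
        stats_ = loop_statistics(
            counts_for_statistics(stats_or_map, cap=count_cap), band_bins=band_bins
        )
    else:
        stats_ = stats_or_map
    valid = stats_.valid
    pv = np.clip(stats_.pvalue["donut"], 1e-300, 1.0)
    loop_p = np.where(valid, np.minimum(-np.log10(pv), p_cap) / p_cap, 0.0)
    loop_r = np.where(valid, np.minimum(stats_.ratio["donut"], r_cap) / r_cap, 0.0)
    loop_p = loop_p + loop_p.T
    loop_r = loop_r + loop_r.T
    return loop_p, loop_r


def build_stack(
    cmap: ContactMap,
    cap: float = 255.0,
    config: ViewConfig | None = None,
    channels: tuple[str, ...] = CHANNEL_NAMES,
) -> MultiviewStack:
    """Assemble the multiview stack for one contact map.

    ``cmap`` may be raw (counts are clamp-normalized by ``cap`` for the
    primary channel) or already normalized (rescaled by ``config.count_cap``
    for the count-based statistics).  ``channels`` selects a subset for
    ablations; channel order follows ``CHANNEL_NAMES``.
    """
    cfg = ViewConfig() if config is None else config
    if cmap.normalized:
        primary = cmap.counts
        count_map = counts_for_statistics(cmap, cap=cfg.count_cap)
    else:
        primary = clamp_normalize(cmap, cap).counts
        count_map = cmap
    out: dict[str, np.ndarray] = {"primary": primary}
    if "oe" in channels:
        out["oe"] = oe_view(count_map, ceiling=cfg.oe_ceiling, band_bins=cfg.band_bins)
    if "tad" in channels:
        out["tad"] = tad_view(count_map, window=cfg.tad_window)
    if "loop_p" in channels or "loop_r" in channels:
        stats_ = loop_statistics(
            count_map,
            kernels=default_kernels(cfg.peak_radius, cfg.donut_radius),
            band_bins=cfg.band_bins,
        )
        lp, lr = loop_views(stats_, p_cap=cfg.loop_p_cap, r_cap=cfg.loop_r_cap)
        out["loop_p"], out["loop_r"] = lp, lr
    ordered = tuple(c for c in CHANNEL_NAMES if c in channels)
    stack = np.stack([out[c] for c in ordered])
    return MultiviewStack(
        channels=stack, channel_names=ordered, chrom=cmap.chrom, resolution=cmap.resolution
    )
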