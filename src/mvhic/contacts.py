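"""Contact-matrix containers, NPZ I/O, preprocessing, downsampling and tiling.

A :class:`ContactMap` is a dense symmetric matrix of intrachromosomal contact
counts for one chromosome at a fixed bin size (default 10 kb).  Enhancement
operates on the near-diagonal band (|i - j| <= 2 Mb), cut into non-overlapping
40 x 40 tiles.  Bins are 0-based; bin ``i`` covers the half-open genomic
interval ``[i * resolution, (i + 1) * resolution)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

TILE_SIZE = 40
BAND_BINS = 200  # 2 Mb at 10 kb resolution

__all__ = [
    "ContactMap",
    "Tile",
    "TileSet",
    "read_contact_map",
    "write_contact_map",
    "downsample",
    "clamp_normalize",
    "tile_band",
    "assemble_tiles",
    "band_mask",
]


class FormatError(ValueError):
    """Raised for unrecognized on-disk matrix dialects."""


@dataclass
class ContactMap:
    """Symmetric binned intrachromosomal contact matrix.

    Parameters
    ----------
    chrom:
        Chromosome label, e.g. ``"chr17"``.
    resolution:
        Bin size in base pairs.
    counts:
        ``(n_bins, n_bins)`` non-negative symmetric matrix.  Raw maps hold
        read counts; after :func:`clamp_normalize` values lie in ``[0, 1]``.
    normalized:
        Whether ``counts`` has been clamp-normalized to ``[0, 1]``.
    """

    chrom: str
    resolution: int
    counts: np.ndarray
    normalized: bool = False

    _SYM_TOL = 1e-8

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError(f"counts must be square, got shape {self.counts.shape}")
        scale = max(1.0, float(np.abs(self.counts).max(initial=0.0)))
        if np.abs(self.counts - self.counts.T).max(initial=0.0) > self._SYM_TOL * scale:
            raise ValueError("contact matrix is asymmetric beyond tolerance")
        if self.counts.min(initial=0.0) < 0:
            raise ValueError("contact matrix has negative entries")
        if self.normalized and self.counts.max(initial=0.0) > 1.0 + self._SYM_TOL:
            raise ValueError("normalized map has entries > 1")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def total_reads(self) -> float:
        """Total counts over the upper triangle including the diagonal."""
        return float(np.triu(self.counts).sum())


@dataclass
class Tile:
    """One 40 x 40 (or C x 40 x 40) block cut from the banded region."""

    chrom: str
    row_offset: int
    col_offset: int
    values: np.ndarray

    @property
    def tile_size(self) -> int:
        return self.values.shape[-1]


@dataclass
class TileSet:
    tiles: list[Tile] = field(default_factory=list)
    tile_size: int = TILE_SIZE
    band_bins: int = BAND_BINS

    def __len__(self) -> int:
        return len(self.tiles)

    def __iter__(self):
        return iter(self.tiles)

    @property
    def n_pairs(self) -> int:
        return len(self.tiles)

    def keys(self) -> list[tuple[str, int, int]]:
        return [(t.chrom, t.row_offset, t.col_offset) for t in self.tiles]


def read_contact_map(path, chrom: str = "chr?", resolution: int = 10_000) -> ContactMap:
    """Load a contact map from NPZ (dense or sparse-COO triplet dialect).

    Dense files carry a ``counts`` array.  Sparse files carry 1-D arrays
    ``row``, ``col``, ``val`` plus a scalar ``n_bins``; triplets may cover
    only the upper triangle and are mirrored on load.
    """
    with np.load(path) as npz:
        if "counts" in npz:
            counts = np.asarray(npz["counts"], dtype=float)
            if "chrom" in npz:
                chrom = str(npz["chrom"])
            if "resolution" in npz:
                resolution = int(npz["resolution"])
            return ContactMap(chrom=chrom, resolution=resolution, counts=counts)
        if {"row", "col", "val", "n_bins"} <= set(npz.files):
            n = int(npz["n_bins"])
            counts = np.zeros((n, n))
            row = np.asarray(npz["row"], dtype=int)
            col = np.asarray(npz["col"], dtype=int)
            val = np.asarray(npz["val"], dtype=float)
            counts[row, col] = val
            counts[col, row] = val
            if "chrom" in npz:
                chrom = str(npz["chrom"])
            if "resolution" in npz:
                resolution = int(npz["resolution"])
            return ContactMap(chrom=chrom, resolution=resolution, counts=counts)
        raise FormatError(
            f"{path}: unrecognized NPZ dialect (keys {sorted(npz.files)}); "
            "expected 'counts' or 'row'/'col'/'val'/'n_bins'"
        )


def write_contact_map(path, cmap: ContactMap, sparse: bool = False) -> None:
    """Write a contact map as NPZ; sparse mode stores upper-triangle triplets."""
    if sparse:
        row, col = np.nonzero(np.triu(cmap.counts))
        np.savez(
            path,
            row=row,
            col=col,
            val=cmap.counts[row, col],
            n_bins=cmap.n_bins,
            chrom=cmap.chrom,
            resolution=cmap.resolution,
        )
    else:
        np.savez(
            path,
            counts=cmap.counts,
            chrom=cmap.chrom,
            resolution=cmap.resolution,
        )


def downsample(cmap: ContactMap, rate: float, seed: int) -> ContactMap:
    """Binomially thin a raw contact map, retaining each read with ``rate``.

    Thinning is applied to the upper triangle (including the diagonal) and
    mirrored, so the output stays symmetric.  ``rate=1`` is the identity.
    """
    if cmap.normalized:
        raise ValueError("downsample requires raw (unnormalized) counts")
    if not 0 < rate <= 1:
        raise ValueError(f"rate must be in (0, 1], got {rate}")
    ints = np.rint(cmap.counts)
    if np.abs(cmap.counts - ints).max(initial=0.0) > 1e-6:
        raise ValueError("downsample requires integer read counts")
    rng = np.random.default_rng(seed)
    upper = np.triu(ints.astype(np.int64))
    thinned = rng.binomial(upper, rate)
    out = thinned + np.triu(thinned, 1).T
    return replace(cmap, counts=out.astype(float))


def clamp_normalize(cmap: ContactMap, cap: float) -> ContactMap:
    """Clamp counts to ``[0, cap]`` and rescale to ``[0, 1]``.

    High-coverage maps use ``cap=255`` and low-coverage maps ``cap=100`` by
    default, mirroring common resolution-enhancement preprocessing.
    """
    if cap <= 0:
        raise ValueError("cap must be positive")
    return replace(cmap, counts=np.minimum(cmap.counts, cap) / cap, normalized=True)


def _tile_offsets(n_bins: int, tile_size: int, band_bins: int) -> list[tuple[int, int]]:
    """Upper-triangle tile grid offsets whose full extent stays in the band."""
    offsets = []
    for r in range(0, n_bins - tile_size + 1, tile_size):
        for c in range(r, n_bins - tile_size + 1, tile_size):
            # farthest corner of tile (r, c) from the diagonal
            if c + tile_size - 1 - r <= band_bins:
                offsets.append((r, c))
    return offsets


def tile_band(
    cmap_or_stack,
    tile_size: int = TILE_SIZE,
    band_bins: int = BAND_BINS,
    chrom: str | None = None,
) -> TileSet:
    """Cut the banded upper triangle into non-overlapping tiles.

    Accepts a :class:`ContactMap` or a raw ``(n, n)`` / ``(C, n, n)`` array
    (the latter for multiview stacks).  A tile at grid offset ``(r, c)`` is
    kept iff its farthest-from-diagonal corner satisfies
    ``|i - j| <= band_bins``; diagonal blocks are always inside the band.
    Ordering is deterministic by ``(row_offset, col_offset)``.
    """
    if isinstance(cmap_or_stack, ContactMap):
        values = cmap_or_stack.counts
        chrom = cmap_or_stack.chrom if chrom is None else chrom
    else:
        values = np.asarray(cmap_or_stack)
        chrom = "chr?" if chrom is None else chrom
    n = values.shape[-1]
    if n < tile_size:
        raise ValueError(f"matrix dimension {n} smaller than tile size {tile_size}")
    tiles = [
        Tile(chrom, r, c, values[..., r : r + tile_size, c : c + tile_size].copy())
        for r, c in _tile_offsets(n, tile_size, band_bins)
    ]
    return TileSet(tiles=tiles, tile_size=tile_size, band_bins=band_bins)


def assemble_tiles(tiles: TileSet, n_bins: int):
    """Reassemble tiles into a full symmetric array (zero outside tiles).

    The upper triangle is filled from the tiles and mirrored.  Returns an
    ``(n, n)`` array, or ``(C, n, n)`` when the tiles are stacked views.
    Overlapping tiles raise ``ValueError``.
    """
    if len(tiles) and len(set(tiles.keys())) != len(tiles):
        raise ValueError("overlapping tiles: duplicate (chrom, row, col) offsets")
    lead = () if not len(tiles) else tiles.tiles[0].values.shape[:-2]
    out = np.zeros(lead + (n_bins, n_bins))
    ts = tiles.tile_size
    for t in tiles:
        r, c = t.row_offset, t.col_offset
        if r % ts or c % ts:
            raise ValueError(f"tile offset ({r}, {c}) not a multiple of {ts}")
        out[..., r : r + ts, c : c + ts] = t.values
        if r != c:
            out[..., c : c + ts, r : r + ts] = np.swapaxes(t.values, -1, -2)
    return out


def band_mask(n_bins: int, band_bins: int = BAND_BINS) -> np.ndarray:
    """Boolean mask of pixels with |i - j| <= band_bins."""
    d = np.abs(np.subtract.outer(np.arange(n_bins), np.arange(n_bins)))
    return d <= band_bins


def tiled_mask(n_bins: int, tile_size: int = TILE_SIZE, band_bins: int = BAND_BINS) -> np.ndarray:
    """Symmetric mask of pixels covered by the tiling grid (and mirrors)."""
    mask = np.zeros((n_bins, n_bins), dtype=bool)
    for r, c in _tile_offsets(n_bins, tile_size, band_bins):
        mask[r : r + tile_size, c : c + tile_size] = True
        mask[c : c + tile_size, r : r + tile_size] = True
    return mask
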