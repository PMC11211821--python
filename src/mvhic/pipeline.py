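"""End-to-end orchestration: simulate -> views -> weights -> train -> enhance
-> evaluate -> ctcf-validate, with a JSON run manifest.

Synthetic chromosomes stand in for the train/validation/test split; the
chromosome lists used with real data (validation {4, 5, 11, 14} in the
cross-cell-line design; validation {2, 6, 10, 12} and test {4, 14, 16, 20}
in the cross-chromosome design, with K562 chr9 excluded for sparsity) are
exposed as constants for real-data runs.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import synthetic
from .contacts import (
    BAND_BINS,
    TILE_SIZE,
    ContactMap,
    assemble_tiles,
    clamp_normalize,
    tile_band,
    tiled_mask,
)
from .diffusion import (
    DenoiserConfig,
    DenoiserModel,
    extract_primary,
    make_schedule,
    sample,
    train,
)
from .evaluation import loop_f1
from .loops import LoopCallConfig, call_loops_matrix
from .ctcf import validation_report
from .views import CHANNEL_NAMES, MultiviewStack, ViewConfig, build_stack
from .weighting import (
    ViewWeights,
    apply_weights,
    initial_weights,
    refine_weights,
    unweight_array,
)

VALIDATION_CHROMS_CROSS_CELL_LINE = ("chr4", "chr5", "chr11", "chr14")
VALIDATION_CHROMS_CROSS_CHROMOSOME = ("chr2", "chr6", "chr10", "chr12")
TEST_CHROMS_CROSS_CHROMOSOME = ("chr4", "chr14", "chr16", "chr20")
K562_EXCLUDED_CHROMS = ("chr9",)

ABLATION_CHANNELS = {
    "full_five_view": (CHANNEL_NAMES, CHANNEL_NAMES),
    "five_view_input": (CHANNEL_NAMES, ("primary",)),
    "primary_only": (("primary",), ("primary",)),
}

__all__ = [
    "RunConfig",
    "run_pipeline",
    "enhance_map",
    "VALIDATION_CHROMS_CROSS_CELL_LINE",
    "VALIDATION_CHROMS_CROSS_CHROMOSOME",
    "TEST_CHROMS_CROSS_CHROMOSOME",
    "K562_EXCLUDED_CHROMS",
]


@dataclass
class RunConfig:
    """Configuration for one synthetic end-to-end run."""

    synthetic: synthetic.SyntheticSpec = field(default_factory=synthetic.SyntheticSpec)
    n_train_chroms: int = 5
    n_val_chroms: int = 1
    n_test_chroms: int = 1
    high_cap: float = 255.0
    low_cap: float = 100.0
    ablation: str = "full_five_view"
    view: ViewConfig = field(default_factory=ViewConfig)
    T: int = 50
    schedule_kind: str = "cosine"
    hidden: int = 32
    epochs: int = 10
    tuning_epochs: int = 4  # reduced-budget stage-1 run used only to tune omega
    batch_size: int = 2
    lr: float = 3e-3
    loop_call: LoopCallConfig = field(default_factory=LoopCallConfig)
    tolerance: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ablation not in ABLATION_CHANNELS:
            raise ValueError(f"unknown ablation mode {self.ablation!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "synthetic" in kwargs:
            syn = dict(kwargs["synthetic"])
            if "loop_distance" in syn:
                syn["loop_distance"] = tuple(syn["loop_distance"])
            kwargs["synthetic"] = synthetic.SyntheticSpec(**syn)
        if "view" in kwargs:
            kwargs["view"] = ViewConfig(**kwargs["view"])
        if "loop_call" in kwargs:
            kwargs["loop_call"] = LoopCallConfig(**kwargs["loop_call"])
        return cls(**kwargs)


def _stack_tiles(stack: MultiviewStack, band_bins: int) -> np.ndarray:
    ts = tile_band(stack.channels, band_bins=band_bins, chrom=stack.chrom)
    return np.stack([t.values for t in ts]) if len(ts) else np.empty((0,))


def _chrom_data(cfg: RunConfig, role: str, index: int):
    """Simulate one chromosome and build its (low, high) stacks and tiles."""
    spec = replace(
        cfg.synthetic,
        seed=cfg.seed * 1000 + {"train": 0, "val": 300, "test": 600}[role] + index,
        chrom=f"chrS{role}{index}",
    )
    low, high, truth = synthetic.generate_pair(spec)
    in_channels, out_channels = ABLATION_CHANNELS[cfg.ablation]
    low_stack = build_stack(low, cap=cfg.low_cap, config=cfg.view, channels=in_channels)
    high_stack = build_stack(high, cap=cfg.high_cap, config=cfg.view, channels=out_channels)
    return {
        "spec": spec,
        "low": low,
        "high": high,
        "truth": truth,
        "low_stack": low_stack,
        "high_stack": high_stack,
    }


def _clip_bounds(scaled_targets: np.ndarray) -> tuple[float, float]:
    """Data range used to clip the implied x0 during reverse sampling."""
    return float(scaled_targets.min()), float(scaled_targets.max())


def _unit_scale(tiles: np.ndarray) -> float:
    """Scalar bringing weighted tiles to unit standard deviation.

    The diffusion objective regresses N(0, 1) noise, so the data must live
    on an O(1) scale for the epsilon-residual not to dwarf the signal; the
    scalar preserves the relative channel weighting and is inverted after
    sampling.
    """
    std = float(tiles.std())
    if std == 0:
        return 1.0
    return 1.0 / std


def enhance_map(
    model: DenoiserModel,
    schedule,
    low_stack: MultiviewStack,
    w_in: ViewWeights,
    w_out: ViewWeights,
    seed: int,
    band_bins: int = BAND_BINS,
    scale_in: float = 1.0,
    scale_out: float = 1.0,
    clip_x0: tuple[float, float] | None = None,
) -> ContactMap:
    """Sample the reverse process per tile and reassemble the primary channel."""
    cond_ts = tile_band(low_stack.channels, band_bins=band_bins, chrom=low_stack.chrom)
    cond = np.stack([t.values for t in cond_ts]) * w_in.omega[:, None, None] * scale_in
    gen = sample(model, cond, schedule, seed=seed, clip_x0=clip_x0) / scale_out
    gen = unweight_array(gen, w_out)
    primary = extract_primary(gen)
    for tile, vals in zip(cond_ts, primary):
        tile.values = vals
    counts = assemble_tiles(cond_ts, low_stack.n_bins)
    counts = np.minimum(counts, counts.T)  # enforce symmetry on diagonal blocks
    counts = np.triu(counts) + np.triu(counts, 1).T
    return ContactMap(
        chrom=low_stack.chrom,
        resolution=low_stack.resolution,
        counts=np.clip(counts, 0.0, 1.0),
        normalized=True,
    )


def _per_view_val_mse(model, schedule, chroms, w_in, w_out, cfg, s_in, s_out, clip) -> np.ndarray:
    """Per-channel MSE of generated vs target stacks on validation tiles."""
    errs = []
    for data in chroms:
        cond = _stack_tiles(apply_weights(data["low_stack"], w_in), cfg.view.band_bins)
        target = _stack_tiles(apply_weights(data["high_stack"], w_out), cfg.view.band_bins)
        gen = sample(model, cond * s_in, schedule, seed=cfg.seed + 77, clip_x0=clip) / s_out
        errs.append(((gen - target) ** 2).mean(axis=(0, 2, 3)))
    return np.mean(errs, axis=0)


def run_pipeline(cfg: RunConfig, outdir) -> dict:
    """Execute all stages; writes manifest.json and metrics.json in outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": {}, "config": _config_dict(cfg)}
    t_start = time.time()

    def mark(stage: str, t0: float) -> None:
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3)}

    t0 = time.time()
    train_data = [_chrom_data(cfg, "train", k) for k in range(cfg.n_train_chroms)]
    val_data = [_chrom_data(cfg, "val", k) for k in range(cfg.n_val_chroms)]
    test_data = [_chrom_data(cfg, "test", k) for k in range(cfg.n_test_chroms)]
    mark("simulate+views", t0)

    in_channels, out_channels = ABLATION_CHANNELS[cfg.ablation]
    t0 = time.time()
    # omega is derived from the low-coverage representation only and applied
    # to both inputs and targets; ablations with a primary-only target use a
    # trivial unit output weight.
    w_in0 = initial_weights([d["low_stack"] for d in train_data])
    w_out0 = (
        w_in0
        if out_channels == in_channels
        else ViewWeights(np.ones(len(out_channels)), out_channels, "initial")
    )
    schedule = make_schedule(cfg.T, cfg.schedule_kind)
    cond_tiles = np.concatenate(
        [_stack_tiles(apply_weights(d["low_stack"], w_in0), cfg.view.band_bins) for d in train_data]
    )
    target_tiles = np.concatenate(
        [_stack_tiles(apply_weights(d["high_stack"], w_out0), cfg.view.band_bins) for d in train_data]
    )
    model_cfg = DenoiserConfig(
        c_data=len(out_channels), c_cond=len(in_channels), hidden=cfg.hidden, seed=cfg.seed
    )
    s_in, s_out = _unit_scale(cond_tiles), _unit_scale(target_tiles)
    clip = _clip_bounds(target_tiles * s_out)
    if len(out_channels) > 1 and cfg.tuning_epochs > 0:
        tuned = DenoiserModel(model_cfg)
        train(
            tuned,
            cond_tiles * s_in,
            target_tiles * s_out,
            schedule,
            epochs=cfg.tuning_epochs,
            batch_size=cfg.batch_size,
            lr=cfg.lr,
            seed=cfg.seed + 1,
        )
        val_mse = _per_view_val_mse(
            tuned, schedule, val_data, w_in0, w_out0, cfg, s_in, s_out, clip
        )
        w_out = refine_weights(w_out0, val_mse)
        w_in = refine_weights(w_in0, val_mse) if in_channels == out_channels else w_in0
    else:
        w_in, w_out = w_in0, w_out0
    manifest["weights"] = {
        "initial": dict(zip(out_channels, w_out0.omega.tolist())),
        "refined": dict(zip(out_channels, w_out.omega.tolist())),
    }
    mark("weights", t0)

    t0 = time.time()
    cond_tiles = np.concatenate(
        [_stack_tiles(apply_weights(d["low_stack"], w_in), cfg.view.band_bins) for d in train_data]
    )
    target_tiles = np.concatenate(
        [_stack_tiles(apply_weights(d["high_stack"], w_out), cfg.view.band_bins) for d in train_data]
    )
    s_in, s_out = _unit_scale(cond_tiles), _unit_scale(target_tiles)
    clip = _clip_bounds(target_tiles * s_out)
    manifest["data_scale"] = {"condition": s_in, "target": s_out, "clip_x0": list(clip)}
    model = DenoiserModel(model_cfg)
    losses = train(
        model,
        cond_tiles * s_in,
        target_tiles * s_out,
        schedule,
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        lr=cfg.lr,
        seed=cfg.seed + 2,
    )
    manifest["train_losses"] = [round(x, 6) for x in losses]
    manifest["n_train_tiles"] = int(cond_tiles.shape[0])
    mark("train", t0)

    t0 = time.time()
    metrics: dict = {"per_chrom": []}
    call_cfg = cfg.loop_call
    for data in test_data:
        enhanced = enhance_map(
            model, schedule, data["low_stack"], w_in, w_out, seed=cfg.seed + 3,
            band_bins=cfg.view.band_bins, scale_in=s_in, scale_out=s_out, clip_x0=clip,
        )
        high_norm = clamp_normalize(data["high"], cfg.high_cap)
        cover = tiled_mask(enhanced.n_bins, TILE_SIZE, cfg.view.band_bins)
        lc_baseline = clamp_normalize(
            replace(
                data["low"], counts=data["low"].counts / cfg.synthetic.downsample_rate
            ),
            cfg.high_cap,
        )
        mse_enhanced = float(np.mean((enhanced.counts[cover] - high_norm.counts[cover]) ** 2))
        mse_lc = float(np.mean((lc_baseline.counts[cover] - high_norm.counts[cover]) ** 2))

        loops_high = call_loops_matrix(data["high"], call_cfg, band_bins=cfg.view.band_bins)
        loops_low = call_loops_matrix(data["low"], call_cfg, band_bins=cfg.view.band_bins)
        loops_enh = call_loops_matrix(
            enhanced, call_cfg, band_bins=cfg.view.band_bins, cap=cfg.high_cap
        )
        truth_pixels = synthetic.planted_truth_pixels(data["truth"])
        entry = {
            "chrom": data["spec"].chrom,
            "mse_enhanced": mse_enhanced,
            "mse_lc_baseline": mse_lc,
            "loops_called": {
                "high": len(loops_high),
                "low": len(loops_low),
                "enhanced": len(loops_enh),
            },
            "f1_vs_planted": {
                "high": loop_f1(loops_high.pixels(), truth_pixels, cfg.tolerance).f1,
                "low": loop_f1(loops_low.pixels(), truth_pixels, cfg.tolerance).f1,
                "enhanced": loop_f1(loops_enh.pixels(), truth_pixels, cfg.tolerance).f1,
            },
            "f1_vs_high_called": {
                "low": loop_f1(loops_low.pixels(), loops_high.pixels(), cfg.tolerance).f1,
                "enhanced": loop_f1(loops_enh.pixels(), loops_high.pixels(), cfg.tolerance).f1,
            },
        }
        tracks, motifs = synthetic.generate_annotations(data["spec"], data["truth"])
        report = validation_report(loops_enh, tracks, motifs)
        entry["ctcf"] = {
            "total_loops": report.total_loops,
            "peak_associated": report.peak_associated,
            "ctcf_validated": report.ctcf_validated,
            "validation_rate": report.validation_rate,
        }
        metrics["per_chrom"].append(entry)
    for key in ("mse_enhanced", "mse_lc_baseline"):
        metrics[key] = float(np.mean([e[key] for e in metrics["per_chrom"]]))
    for key in ("high", "low", "enhanced"):
        metrics[f"f1_planted_{key}"] = float(
            np.mean([e["f1_vs_planted"][key] for e in metrics["per_chrom"]])
        )
    mark("enhance+evaluate", t0)

    manifest["metrics"] = metrics
    manifest["total_seconds"] = round(time.time() - t_start, 3)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    with open(outdir / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2)
    return manifest


def _config_dict(cfg: RunConfig) -> dict:
    out = asdict(cfg)
    out["synthetic"]["loop_distance"] = list(out["synthetic"]["loop_distance"])
    return out
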