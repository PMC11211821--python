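"""Two-stage view weighting.

Stage 1 equalizes channel scales: omega0[c] = std(primary) / std(channel c)
over the training stacks, so every weighted channel has the primary's
standard deviation.  Stage 2 rescales by sqrt of the per-view validation MSE
ratio — scaling a channel by s scales its MSE by s^2, so this equalizes
per-view difficulty to first order — and renormalizes so the primary weight
stays 1.  Weights multiply both model inputs and targets; generated outputs
are divided by them before use.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np

from .views import MultiviewStack

__all__ = ["ViewWeights", "initial_weights", "refine_weights", "apply_weights", "unapply_weights"]


@dataclass
class ViewWeights:
    omega: np.ndarray
    channel_names: tuple[str, ...]
    stage: str = "initial"  # "initial" (omega0) or "refined"

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        if self.omega.ndim != 1 or len(self.omega) != len(self.channel_names):
            raise ValueError("omega must align with channel_names")
        if not (self.omega > 0).all():
            raise ValueError("weights must be positive")
        if abs(self.omega[0] - 1.0) > 1e-9:
            raise ValueError("primary-channel weight must be 1")

    def to_json(self, path) -> None:
        payload = {
            "stage": self.stage,
            "weights": dict(zip(self.channel_names, self.omega.tolist())),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ViewWeights":
        with open(path) as fh:
            payload = json.load(fh)
        names = tuple(payload["weights"])
        return cls(
            omega=np.array([payload["weights"][n] for n in names]),
            channel_names=names,
            stage=payload["stage"],
        )


def initial_weights(stacks: list[MultiviewStack]) -> ViewWeights:
    """omega0[c] = std(channel 0) / std(channel c) over all training stacks."""
    if not stacks:
        raise ValueError("need at least one stack")
    names = stacks[0].channel_names
    flat = [np.concatenate([s.channels[c].ravel() for s in stacks]) for c in range(len(names))]
    stds = np.array([v.std() for v in flat])
    zero = [names[c] for c in range(len(names)) if stds[c] == 0]
    if zero:
        raise ValueError(f"channel(s) with zero standard deviation: {', '.join(zero)}")
    omega = stds[0] / stds
    return ViewWeights(omega=omega, channel_names=names, stage="initial")


def refine_weights(omega0: ViewWeights, val_mse: np.ndarray) -> ViewWeights:
    """Refine weights by per-view validation difficulty.

    omega[c] = omega0[c] * sqrt(val_mse[0] / val_mse[c]), then renormalized by
    the primary entry.  Scale-equivariant in val_mse.
    """
    val_mse = np.asarray(val_mse, dtype=float)
    if val_mse.shape != omega0.omega.shape:
        raise ValueError("val_mse must align with omega")
    if not (val_mse > 0).all():
        raise ValueError("validation MSEs must be positive")
    omega = omega0.omega * np.sqrt(val_mse[0] / val_mse)
    omega = omega / omega[0]
    return replace(omega0, omega=omega, stage="refined")


def apply_weights(stack: MultiviewStack, weights: ViewWeights) -> MultiviewStack:
    """Multiply each channel by its weight."""
    if stack.channel_names != weights.channel_names:
        raise ValueError("stack channels do not match weights")
    return replace(stack, channels=stack.channels * weights.omega[:, None, None])


def unapply_weights(stack: MultiviewStack, weights: ViewWeights) -> MultiviewStack:
    """Inverse of :func:`apply_weights`."""
    if stack.channel_names != weights.channel_names:
        raise ValueError("stack channels do not match weights")
    return replace(stack, channels=stack.channels / weights.omega[:, None, None])


def weight_array(values: np.ndarray, weights: ViewWeights) -> np.ndarray:
    """Apply weights to a bare (..., C, h, w) array (e.g. a batch of tiles)."""
    return values * weights.omega[:, None, None]


def unweight_array(values: np.ndarray, weights: ViewWeights) -> np.ndarray:
    return values / weights.omega[:, None, None]
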