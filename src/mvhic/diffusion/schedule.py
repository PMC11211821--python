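"""Noise schedules and the closed-form forward (noising) process.

The forward chain q(y_t | y_0) has the marginal

    y_t = sqrt(alpha_bar_t) * y_0 + sqrt(1 - alpha_bar_t) * eps,  eps ~ N(0, I),

with alpha_t = 1 - beta_t and alpha_bar_t the running product of alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DiffusionSchedule", "make_schedule", "forward_sample"]


@dataclass
class DiffusionSchedule:
    beta: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.ndim != 1 or len(self.beta) < 1:
            raise ValueError("beta must be a non-empty 1-D array")
        if not ((self.beta > 0) & (self.beta < 1)).all():
            raise ValueError("all beta must lie in (0, 1)")
        self.alpha = 1.0 - self.beta
        self.alpha_bar = np.cumprod(self.alpha)

    @property
    def T(self) -> int:
        return len(self.beta)

    def posterior_sigma(self, t: int) -> float:
        """Std of the reverse-process posterior q(y_{t-1} | y_t, y_0)."""
        if t == 0:
            return 0.0
        return float(
            np.sqrt(self.beta[t] * (1.0 - self.alpha_bar[t - 1]) / (1.0 - self.alpha_bar[t]))
        )


def make_schedule(
    T: int,
    kind: str = "linear",
    beta_start: float = 1e-4,
    beta_end: float = 0.02,
) -> DiffusionSchedule:
    """Build a T-step schedule.

    ``linear`` interpolates beta from ``beta_start`` to ``beta_end`` (the
    usual DDPM defaults for T=1000).  ``cosine`` uses the squared-cosine
    alpha_bar profile with offset s=0.008, with beta clipped to 0.999; it
    degrades more gracefully at small T and is the desk-scale default.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if kind == "linear":
        beta = np.linspace(beta_start, beta_end, T)
    elif kind == "cosine":
        s = 0.008
        t = np.arange(T + 1) / T
        f = np.cos((t + s) / (1 + s) * np.pi / 2) ** 2
        alpha_bar = f / f[0]
        beta = np.clip(1.0 - alpha_bar[1:] / alpha_bar[:-1], 1e-8, 0.999)
    else:
        raise ValueError(f"unknown schedule kind {kind!r}")
    return DiffusionSchedule(beta=beta)


def forward_sample(
    y0: np.ndarray, t: int | np.ndarray, schedule: DiffusionSchedule, noise: np.ndarray
) -> np.ndarray:
    """Closed-form marginal sample y_t given y_0 and a standard-normal draw.

    ``t`` may be a scalar or a per-example vector for batched ``y0`` of shape
    (B, C, H, W).
    """
    y0 = np.asarray(y0, dtype=float)
    noise = np.asarray(noise, dtype=float)
    if noise.shape != y0.shape:
        raise ValueError(f"noise shape {noise.shape} != y0 shape {y0.shape}")
    t = np.asarray(t)
    if (t < 0).any() or (t >= schedule.T).any():
        raise ValueError("t out of range")
    ab = schedule.alpha_bar[t]
    if t.ndim:  # per-example steps: broadcast over trailing axes
        ab = ab.reshape((-1,) + (1,) * (y0.ndim - 1))
    return np.sqrt(ab) * y0 + np.sqrt(1.0 - ab) * noise
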