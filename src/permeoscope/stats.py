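"""Shared numerics: voltage relation, percentile/block bootstrap, minimum image."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "field_to_voltage",
    "round_voltage",
    "BootstrapCI",
    "bootstrap_ci",
    "minimum_image",
]


def field_to_voltage(field_magnitude: float, box_z: float, direction_sign: int = -1) -> float:
    """Transmembrane voltage (mV) from a uniform electric field.

    A uniform field E (mV/nm) applied across a periodic box of z-dimension
    L_z (nm) produces a transmembrane potential ``sign * E * L_z`` in mV.
    ``direction_sign=-1`` corresponds to a field pointing towards the
    intracellular side (hyperpolarising).
    """
    if field_magnitude < 0:
        raise ValueError("field magnitude must be non-negative")
    if box_z <= 0:
        raise ValueError("box z-dimension must be positive")
    if direction_sign not in (-1, 1):
        raise ValueError("direction_sign must be +1 or -1")
    return direction_sign * field_magnitude * box_z


def round_voltage(voltage_mv: float, nearest: float = 100.0) -> float:
    """Round a voltage to the nearest multiple of ``nearest`` mV."""
    return float(np.round(voltage_mv / nearest) * nearest)


def minimum_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors.

    ``delta`` has shape (..., k) and ``box`` shape (k,) (orthorhombic box
    lengths); components are folded into [-box/2, box/2).
    """
    box = np.asarray(box, dtype=float)
    return delta - box * np.round(delta / box)


@dataclass
class BootstrapCI:
    """Percentile bootstrap confidence interval."""

    point_estimate: float
    lower: float
    upper: float
    level: float = 0.99
    n_resamples: int = 1000

    def __post_init__(self) -> None:
        if not 0 < self.level < 1:
            raise ValueError("confidence level must be in (0, 1)")
        if not (self.lower <= self.point_estimate + 1e-12 and self.point_estimate <= self.upper + 1e-12):
            raise ValueError("CI must bracket the point estimate")

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


_REDUCERS: dict[str, Callable[[np.ndarray], float]] = {
    "mean": np.mean,
    "median": np.median,
    "sum": np.sum,
    "std": np.std,
}


def bootstrap_ci(
    samples,
    statistic: str | Callable[[np.ndarray], float] = "mean",
    level: float = 0.99,
    n_resamples: int = 1000,
    seed: int | None = None,
) -> BootstrapCI:
    """Percentile bootstrap CI of a reducer over samples or sample blocks.

    ``samples`` is either a flat sequence of numbers (resampled per element)
    or a sequence of 1-D arrays treated as blocks (whole blocks are resampled
    with replacement, the statistic evaluated on the concatenation).  Block
    resampling is the appropriate unit for autocorrelated series such as
    per-frame trajectory observables grouped by simulation run.
    """
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    stat = _REDUCERS[statistic] if isinstance(statistic, str) else statistic
    rng = np.random.default_rng(seed)

    blocked = (
        isinstance(samples, (list, tuple))
        and len(samples) > 0
        and np.ndim(samples[0]) >= 1
    )
    if blocked:
        blocks = [np.asarray(b, dtype=float) for b in samples]
        if any(b.size == 0 for b in blocks):
            raise ValueError("empty block in bootstrap input")
        n = len(blocks)
        point = float(stat(np.concatenate(blocks)))
        estimates = np.empty(n_resamples)
        for i in range(n_resamples):
            pick = rng.integers(0, n, size=n)
            estimates[i] = stat(np.concatenate([blocks[j] for j in pick]))
    else:
        data = np.asarray(samples, dtype=float).ravel()
        if data.size == 0:
            raise ValueError("empty sample in bootstrap input")
        if data.size < 2:
            raise ValueError("need at least 2 samples to bootstrap")
        point = float(stat(data))
        if stat is np.mean:
            # fast path: resampled means by index gather
            idx = rng.integers(0, data.size, size=(n_resamples, data.size))
            estimates = data[idx].mean(axis=1)
        else:
            estimates = np.empty(n_resamples)
            for i in range(n_resamples):
                estimates[i] = stat(data[rng.integers(0, data.size, size=data.size)])

    alpha = (1.0 - level) / 2.0
    lower, upper = np.quantile(estimates, [alpha, 1.0 - alpha])
    # degenerate data can place the point estimate marginally outside through fp noise
    lower = min(float(lower), point)
    upper = max(float(upper), point)
    return BootstrapCI(point_estimate=point, lower=lower, upper=upper, level=level, n_resamples=n_resamples)
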