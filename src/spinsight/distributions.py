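"""Distance distributions P(r) on a regular grid in nanometres."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks


@dataclass
class DistanceDistribution:
    """A normalized probability density over spin–spin distance.

    ``r`` is a strictly increasing grid in nm; ``p`` is non-negative and is
    normalized on construction so that sum(p * dr) = 1, with dr taken from
    the local grid spacing.
    """

    r: np.ndarray
    p: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.r.ndim != 1 or self.r.shape != self.p.shape:
            raise ValueError("r and p must be 1-D arrays of equal length")
        if len(self.r) < 2 or np.any(np.diff(self.r) <= 0):
            raise ValueError("r grid must be strictly increasing with >= 2 points")
        if np.any(self.p < -1e-12) or not np.all(np.isfinite(self.p)):
            raise ValueError("p must be finite and non-negative")
        self.p = np.clip(self.p, 0.0, None)
        total = float(np.sum(self.p * self.widths))
        if total <= 0:
            raise ValueError("p must have positive mass")
        self.p = self.p / total

    @property
    def widths(self) -> np.ndarray:
        """Local grid spacing dr (np.gradient of the r grid)."""
        return np.gradient(self.r)

    def mean(self) -> float:
        """First moment <r> in nm."""
        return float(np.sum(self.r * self.p * self.widths))

    def std(self) -> float:
        m = self.mean()
        return float(np.sqrt(np.sum((self.r - m) ** 2 * self.p * self.widths)))

    @classmethod
    def from_gaussians(
        cls,
        components: list[tuple[float, float, float]],
        r_grid: np.ndarray | None = None,
    ) -> "DistanceDistribution":
        """Mixture of Gaussians given as (mean nm, sigma nm, weight) triples."""
        if r_grid is None:
            r_grid = default_r_grid()
        r = np.asarray(r_grid, dtype=float)
        weights = np.array([w for _, _, w in components], dtype=float)
        if not np.isclose(weights.sum(), 1.0, atol=1e-6):
            raise ValueError("component weights must sum to 1")
        p = np.zeros_like(r)
        for mu, sigma, w in components:
            p += w * np.exp(-0.5 * ((r - mu) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
        return cls(r=r, p=p, metadata={"components": list(components)})


def default_r_grid(r_min: float = 1.0, r_max: float = 10.0, step: float = 0.02) -> np.ndarray:
    """The package-wide default distance grid: 1–10 nm in 0.02 nm steps."""
    n = int(round((r_max - r_min) / step))
    return r_min + step * np.arange(n + 1)


def find_modes(dist: DistanceDistribution, min_rel_height: float = 0.05) -> list[float]:
    """Positions (nm) of local maxima of p with height >= min_rel_height * max(p).

    A flat distribution has no interior local maxima and yields an empty list.
    """
    if np.all(dist.p == 0):
        return []
    idx, _ = find_peaks(dist.p, height=min_rel_height * float(dist.p.max()))
    return [float(dist.r[i]) for i in idx]
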