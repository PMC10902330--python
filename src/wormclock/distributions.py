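"""Small parametric distribution specs used by the synthetic generators.

Each spec is a frozen dataclass with a ``draw(rng, n)`` method so that a
simulation design is fully serializable and reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class Fixed:
    value: float

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.full(n, float(self.value))

    def mean(self) -> float:
        return float(self.value)


@dataclass(frozen=True)
class Uniform:
    low: float
    high: float

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.uniform(self.low, self.high, size=n)

    def mean(self) -> float:
        return 0.5 * (self.low + self.high)


@dataclass(frozen=True)
class Normal:
    mean_: float
    sd: float

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.normal(self.mean_, self.sd, size=n)

    def mean(self) -> float:
        return float(self.mean_)


@dataclass(frozen=True)
class TruncatedNormal:
    """Normal draw clipped at ``low`` (default 0).

    Used for amplitudes: negative draws are truncated to the bound rather
    than re-drawn, so the consumed random stream has fixed length and runs
    are reproducible regardless of how many draws would have been negative.
    """

    mean_: float
    sd: float
    low: float = 0.0

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.maximum(rng.normal(self.mean_, self.sd, size=n), self.low)

    def mean(self) -> float:
        # exact mean of the clipped (not re-drawn) variable
        from scipy.stats import norm

        a = (self.low - self.mean_) / self.sd
        return float(
            norm.cdf(a) * self.low
            + (1 - norm.cdf(a)) * self.mean_
            + self.sd * norm.pdf(a)
        )


@dataclass(frozen=True)
class WrappedNormalMixture:
    """Mixture of wrapped normals on [0, 2pi) for phase draws.

    ``components`` is a tuple of (center_radians, sd_radians, weight).
    The default elsewhere in the package is a 3-component mixture centered
    at pi/3, 2pi/3 and 3pi/2, mimicking the three phase peaks seen in
    temperature-entrained adult worms.
    """

    components: tuple[tuple[float, float, float], ...]

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        centers = np.array([c[0] for c in self.components])
        sds = np.array([c[1] for c in self.components])
        w = np.array([c[2] for c in self.components], dtype=float)
        w = w / w.sum()
        which = rng.choice(len(self.components), size=n, p=w)
        return np.mod(rng.normal(centers[which], sds[which]), TWO_PI)

    def component_labels(self, phases: np.ndarray) -> np.ndarray:
        """Nearest-center component index for each phase (circular)."""
        centers = np.array([c[0] for c in self.components])
        d = np.abs(np.angle(np.exp(1j * (phases[:, None] - centers[None, :]))))
        return d.argmin(axis=1)


DEFAULT_PHASE_MIXTURE = WrappedNormalMixture(
    components=(
        (np.pi / 3.0, 0.15, 1.0),
        (2.0 * np.pi / 3.0, 0.15, 1.0),
        (3.0 * np.pi / 2.0, 0.15, 1.0),
    )
)

DEFAULT_AMPLITUDE_DIST = TruncatedNormal(mean_=1.5, sd=0.5, low=0.0)
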