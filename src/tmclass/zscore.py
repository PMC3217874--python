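"""Signed z-score classification of TM segments.

A segment's (complexity, hydrophobicity) pair is normalized against
reference statistics estimated from functional TM helices and collapsed
into one signed score

    z = (-1)^s * (x~_phi^2 + x~_c^2),      x~ = (x - mu) / sigma,

where the sign exponent s is 1 on the high-hydrophobicity/low-complexity
side of the normal to the complexity-hydrophobicity regression line
(x~_phi >= -(1/rho) x~_c) and 0 otherwise.  Simple hydrophobic anchors
therefore receive large negative z while functional segments cluster
around 0.

Thresholds come from the one-tailed normal quantile f via z = -2 f^2;
a twilight zone between two thresholds (default -5.41 .. -3.29, i.e.
f = 1.645 and f = 1.282) withholds classification.
"""

from __future__ import annotations

import enum
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .measures import MeasurePair

__all__ = [
    "ReferenceStats",
    "RegressionLine",
    "TwilightZone",
    "TMClass",
    "ZScoreResult",
    "DEFAULT_REFERENCE_STATS",
    "DEFAULT_TWILIGHT_ZONE",
    "zscore",
    "threshold_from_f",
    "classify",
    "estimate_reference_stats",
]


@dataclass(frozen=True)
class ReferenceStats:
    """Summary constants of a reference TM set: means, SDs and correlation.

    ``rho`` is the Pearson correlation between complexity and
    hydrophobicity; the sign rule uses its reciprocal, so rho must be
    nonzero and strictly inside (-1, 1).
    """

    mu_phi: float
    sigma_phi: float
    mu_c: float
    sigma_c: float
    rho: float

    def __post_init__(self) -> None:
        if self.sigma_phi <= 0 or self.sigma_c <= 0:
            raise ValueError("standard deviations must be positive")
        if not (-1.0 < self.rho < 1.0) or self.rho == 0.0:
            raise ValueError("rho must lie strictly in (-1, 1) and be nonzero")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ReferenceStats":
        p = Path(source)
        text = p.read_text(encoding="utf-8") if p.exists() else str(source)
        return cls(**json.loads(text))


#: Published reference constants of the UniProt-derived functional TM set
#: (complexity window 12, IVL grouped).
DEFAULT_REFERENCE_STATS = ReferenceStats(
    mu_phi=0.64, sigma_phi=2.85, mu_c=2.40, sigma_c=0.30, rho=-0.436
)


@dataclass(frozen=True)
class RegressionLine:
    """Least-squares line x_phi = intercept + slope * x_c and its normal."""

    intercept: float
    slope: float
    normal_slope: float


@dataclass(frozen=True)
class TwilightZone:
    """z interval where classification is withheld (boundaries inclusive)."""

    lower: float = -5.41
    upper: float = -3.29

    def __post_init__(self) -> None:
        if not (self.lower < self.upper <= 0):
            raise ValueError("require lower < upper <= 0")


DEFAULT_TWILIGHT_ZONE = TwilightZone()

#: Alternative, wider zone discussed for single-spanning proteins
#: (f = 1.980 .. 1.282).
WIDE_TWILIGHT_ZONE = TwilightZone(lower=-7.84, upper=-3.29)


class TMClass(str, enum.Enum):
    SIMPLE = "simple"
    TWILIGHT = "twilight"
    COMPLEX = "complex"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ZScoreResult:
    z: float
    s: int
    x_tilde_c: float
    x_tilde_phi: float


def zscore(pair: MeasurePair, ref: ReferenceStats = DEFAULT_REFERENCE_STATS) -> ZScoreResult:
    """Signed z-score of a (x_c, x_phi) pair relative to reference stats."""
    xt_c = (pair.x_c - ref.mu_c) / ref.sigma_c
    xt_phi = (pair.x_phi - ref.mu_phi) / ref.sigma_phi
    s = 1 if xt_phi >= -(1.0 / ref.rho) * xt_c else 0
    z = ((-1.0) ** s) * (xt_phi**2 + xt_c**2)
    return ZScoreResult(z=z, s=s, x_tilde_c=xt_c, x_tilde_phi=xt_phi)


def threshold_from_f(f: float) -> float:
    """z threshold -2 f^2 at one-tailed normal quantile f (f >= 0)."""
    if f < 0:
        raise ValueError("f must be nonnegative")
    return -2.0 * f * f


def classify(z: float, zone: TwilightZone = DEFAULT_TWILIGHT_ZONE) -> TMClass:
    """simple below the zone, complex above it, twilight inside (inclusive)."""
    if z < zone.lower:
        return TMClass.SIMPLE
    if z > zone.upper:
        return TMClass.COMPLEX
    return TMClass.TWILIGHT


def estimate_reference_stats(
    pairs: Iterable[MeasurePair],
) -> tuple[ReferenceStats, RegressionLine]:
    """Sample means/SDs/correlation of a set of measure pairs.

    Also returns the least-squares regression of hydrophobicity on
    complexity (slope = rho * sigma_phi / sigma_c, intercept =
    mu_phi - slope * mu_c) and the slope of its normal, -1/rho.
    """
    arr = np.asarray([(p.x_c, p.x_phi) for p in pairs], dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 measure pairs")
    x_c, x_phi = arr[:, 0], arr[:, 1]
    sigma_c = float(np.std(x_c, ddof=1))
    sigma_phi = float(np.std(x_phi, ddof=1))
    if sigma_c == 0.0 or sigma_phi == 0.0:
        raise ValueError("degenerate input: zero variance on one axis")
    rho = float(np.corrcoef(x_c, x_phi)[0, 1])
    ref = ReferenceStats(
        mu_phi=float(np.mean(x_phi)),
        sigma_phi=sigma_phi,
        mu_c=float(np.mean(x_c)),
        sigma_c=sigma_c,
        rho=rho,
    )
    slope = rho * sigma_phi / sigma_c
    line = RegressionLine(
        intercept=ref.mu_phi - slope * ref.mu_c,
        slope=slope,
        normal_slope=-1.0 / rho,
    )
    return ref, line
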