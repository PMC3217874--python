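"""Seeded synthetic sequences, annotations, measure clouds and hit tables.

The generators emulate the statistical structure the classifier assumes:
anchor-like TM helices are drawn from a composition heavy in aliphatic
hydrophobics (I/V/L with F and A), functional-like helices keep a
hydrophobic background but carry elevated charged (R/D/E/H), structural
(G/P) and aromatic (F/W) residues, and loops are polar-biased.  Every
generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .annotations_io import ProteinRecord
from .benchstats import ConfusionCounts, HitRecord
from .measures import MeasurePair
from .scales import STANDARD_RESIDUES

__all__ = [
    "CompositionProfile",
    "ANCHOR_LIKE",
    "FUNCTIONAL_LIKE",
    "LOOP_LIKE",
    "UNIFORM",
    "gen_tm",
    "gen_protein",
    "gen_measure_cloud",
    "gen_hit_table",
]

#: Median TM helix length in curated annotation sets, used as the default.
DEFAULT_TM_LENGTH = 21


@dataclass(frozen=True)
class CompositionProfile:
    """Per-residue sampling probabilities over the 20 standard amino acids."""

    name: str
    probs: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.probs) - set(STANDARD_RESIDUES):
            raise ValueError("profile contains nonstandard residues")
        total = sum(self.probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"profile {self.name!r} probabilities sum to {total}")

    def as_arrays(self) -> tuple[list[str], np.ndarray]:
        residues = [aa for aa in STANDARD_RESIDUES if self.probs.get(aa, 0) > 0]
        p = np.array([self.probs[aa] for aa in residues])
        return residues, p / p.sum()


ANCHOR_LIKE = CompositionProfile(
    "anchor-like",
    {
        "L": 0.30, "I": 0.15, "V": 0.15, "A": 0.12, "F": 0.08,
        "G": 0.04, "M": 0.04, "S": 0.03, "T": 0.03,
        "W": 0.02, "C": 0.02, "Y": 0.02,
    },
)

FUNCTIONAL_LIKE = CompositionProfile(
    "functional-like",
    {
        "L": 0.12, "I": 0.08, "V": 0.08, "A": 0.08, "F": 0.07,
        "G": 0.07, "P": 0.05, "W": 0.04, "Y": 0.04, "S": 0.04,
        "T": 0.04, "M": 0.03, "C": 0.02, "R": 0.05, "K": 0.04,
        "D": 0.04, "E": 0.04, "H": 0.03, "N": 0.02, "Q": 0.02,
    },
)

LOOP_LIKE = CompositionProfile(
    "loop-like",
    {
        "S": 0.10, "T": 0.08, "N": 0.07, "Q": 0.06, "G": 0.10,
        "P": 0.08, "D": 0.08, "E": 0.08, "K": 0.08, "R": 0.08,
        "A": 0.05, "L": 0.04, "V": 0.02, "I": 0.02, "H": 0.02,
        "Y": 0.01, "F": 0.01, "M": 0.01, "W": 0.005, "C": 0.005,
    },
)

UNIFORM = CompositionProfile(
    "uniform", {aa: 0.05 for aa in STANDARD_RESIDUES}
)


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def gen_tm(
    profile: CompositionProfile,
    length: int = DEFAULT_TM_LENGTH,
    seed: int | np.random.Generator = 0,
) -> str:
    """An i.i.d. sequence draw from a composition profile."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = _rng(seed)
    residues, p = profile.as_arrays()
    return "".join(rng.choice(residues, size=length, p=p))


def gen_protein(
    protein_id: str,
    n_tms: int,
    tm_length: int = DEFAULT_TM_LENGTH,
    loop_length: int = 15,
    mix: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> ProteinRecord:
    """A protein with alternating loop/TM architecture and attached segments.

    Each TM is drawn from the anchor-like profile with probability ``mix``
    (else functional-like); loops come from the polar-biased loop profile.
    Segment coordinates are recorded 1-based inclusive as they are laid
    down, so annotations are consistent by construction.
    """
    if n_tms < 0:
        raise ValueError("n_tms must be >= 0")
    if not (0.0 <= mix <= 1.0):
        raise ValueError("mix must be in [0, 1]")
    rng = _rng(seed)
    parts: list[str] = [gen_tm(LOOP_LIKE, loop_length, rng)]
    coords: list[tuple[int, int, str]] = []
    pos = loop_length
    for _ in range(n_tms):
        simple_like = rng.random() < mix
        profile = ANCHOR_LIKE if simple_like else FUNCTIONAL_LIKE
        tm = gen_tm(profile, tm_length, rng)
        parts.append(tm)
        coords.append((pos + 1, pos + tm_length, profile.name))
        pos += tm_length
        loop = gen_tm(LOOP_LIKE, loop_length, rng)
        parts.append(loop)
        pos += loop_length
    record = ProteinRecord(protein_id=protein_id, sequence="".join(parts))
    for start, end, category in coords:
        record.add_segment(start, end, category)
    return record


def gen_measure_cloud(
    mu_c: float,
    sigma_c: float,
    mu_phi: float,
    sigma_phi: float,
    rho: float,
    n: int,
    seed: int | np.random.Generator = 0,
) -> list[MeasurePair]:
    """A bivariate-normal (x_c, x_phi) sample with the given correlation."""
    if sigma_c < 0 or sigma_phi < 0:
        raise ValueError("standard deviations must be nonnegative")
    if not (-1.0 <= rho <= 1.0):
        raise ValueError("rho must lie in [-1, 1]")
    rng = _rng(seed)
    cov = np.array(
        [
            [sigma_c**2, rho * sigma_c * sigma_phi],
            [rho * sigma_c * sigma_phi, sigma_phi**2],
        ]
    )
    draws = rng.multivariate_normal([mu_c, mu_phi], cov, size=n)
    return [MeasurePair(x_c=float(c), x_phi=float(p)) for c, p in draws]


def gen_hit_table(
    query_family: str = "FAM1",
    n_same_family: int = 5,
    n_other: int = 10,
    masked_score_range: tuple[float, float] = (60.0, 120.0),
    other_score_range: tuple[float, float] = (20.0, 100.0),
    score_jitter: float = 10.0,
    seed: int | np.random.Generator = 0,
) -> tuple[list[HitRecord], dict[str, ConfusionCounts]]:
    """A synthetic hit table plus its ground-truth confusion counts.

    Same-family masked scores are drawn uniformly in ``masked_score_range``
    so the minimum-masked-score cutoff is recoverable; original and control
    scores jitter around the masked score, and off-family hits draw from
    ``other_score_range``.  All hits carry E-values below the conventional
    0.001 cutoff and a family label, so none is filtered.  The returned
    ground truth is computed by direct enumeration against the cutoff and
    matches :func:`tmclass.benchstats.search_eval` on the same table.
    """
    if n_same_family < 1:
        raise ValueError("need at least one same-family hit")
    rng = _rng(seed)
    hits: list[HitRecord] = []
    for i in range(n_same_family):
        masked = float(rng.uniform(*masked_score_range))
        hits.append(
            HitRecord(
                query_id="query",
                subject_id=f"same{i}",
                family=query_family,
                e_value=float(rng.uniform(0, 5e-4)),
                score_original=masked + float(rng.uniform(-score_jitter, score_jitter)),
                score_masked=masked,
                score_control=masked + float(rng.uniform(-score_jitter, score_jitter)),
            )
        )
    for i in range(n_other):
        base = float(rng.uniform(*other_score_range))
        hits.append(
            HitRecord(
                query_id="query",
                subject_id=f"other{i}",
                family=f"OTHER{i % 3}",
                e_value=float(rng.uniform(0, 5e-4)),
                score_original=base + float(rng.uniform(-score_jitter, score_jitter)),
                score_masked=base,
                score_control=base + float(rng.uniform(-score_jitter, score_jitter)),
            )
        )
    cutoff = min(h.score_masked for h in hits if h.family == query_family)
    truth: dict[str, ConfusionCounts] = {}
    for variant in ("original", "masked", "control"):
        tp = fp = tn = fn = 0
        for h in hits:
            score = getattr(h, f"score_{variant}")
            if h.family == query_family:
                tp, fn = (tp + 1, fn) if score >= cutoff else (tp, fn + 1)
            else:
                fp, tn = (fp + 1, tn) if score >= cutoff else (fp, tn + 1)
        truth[variant] = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
    return hits, truth
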