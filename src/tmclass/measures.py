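"""Windowed hydrophobicity and sequence-complexity measures for TM segments.

Each transmembrane (TM) segment is reduced to a pair of numbers:

``x_phi``
    membrane-insertion propensity: every full-length window (default 19
    residues, stride 1) is scored as the *sum* of per-residue values of the
    sign-reversed octanol-minus-interface scale, and the segment value is
    the mean over windows (kcal/mol).

``x_c``
    sequence complexity: every full-length window (default 12 residues,
    stride 1) is scored as the Shannon entropy (bits) of its residue-group
    composition, with isoleucine, valine and leucine pooled into a single
    group so that variation among the aliphatic hydrophobics does not
    inflate complexity; the segment value is the mean over windows.

Segments shorter than the window are scored as a single window of their own
length.  Nonstandard residues contribute 0 to hydrophobicity and are pooled
into one extra entropy group; a warning is emitted per affected sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .scales import STANDARD_RESIDUES, ResidueScale, default_scale

__all__ = [
    "WindowConfig",
    "TMSegment",
    "MeasurePair",
    "hydrophobicity",
    "complexity",
    "measure_segment",
]

_STANDARD_SET = frozenset(STANDARD_RESIDUES)
_IVL = frozenset("IVL")


class NonstandardResidueWarning(UserWarning):
    """A sequence contained residues outside the 20 standard amino acids."""


@dataclass(frozen=True)
class WindowConfig:
    """Moving-window sizes for the two measures.

    Defaults follow the established convention: 19 residues for
    hydrophobicity (the canonical TM-scanning window) and 12 for
    complexity, with IVL grouping enabled.
    """

    hydro_window: int = 19
    complexity_window: int = 12
    group_ivl: bool = True

    def __post_init__(self) -> None:
        if self.hydro_window < 1 or self.complexity_window < 1:
            raise ValueError("window lengths must be >= 1")


@dataclass(frozen=True)
class TMSegment:
    """One annotated TM helix: 1-based inclusive coordinates plus sequence."""

    protein_id: str
    start: int
    end: int
    sequence: str
    category: str | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"{self.protein_id}: invalid coordinates {self.start}..{self.end}"
            )
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError(
                f"{self.protein_id}: sequence length {len(self.sequence)} does not "
                f"match coordinates {self.start}..{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class MeasurePair(NamedTuple):
    """The (complexity, hydrophobicity) coordinates of one segment."""

    x_c: float
    x_phi: float


def _clean(sequence: str, *, what: str) -> str:
    seq = "".join(sequence.split()).upper()
    if not seq:
        raise ValueError(f"cannot compute {what} of an empty sequence")
    return seq


def _warn_nonstandard(seq: str) -> None:
    odd = sorted(set(seq) - _STANDARD_SET)
    if odd:
        warnings.warn(
            f"nonstandard residue(s) {''.join(odd)} in sequence; they contribute "
            "0 to hydrophobicity and form one pooled complexity group",
            NonstandardResidueWarning,
            stacklevel=3,
        )


def hydrophobicity(
    sequence: str,
    scale: ResidueScale | None = None,
    window: int = 19,
) -> float:
    """Mean over all full windows of the per-window sum of scale values.

    A sequence shorter than ``window`` is scored as one window of its own
    length (i.e. the plain sum of its residue values).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    seq = _clean(sequence, what="hydrophobicity")
    if scale is None:
        scale = default_scale()
    _warn_nonstandard(seq)
    values = np.array([scale[aa] for aa in seq])
    if len(seq) <= window:
        return float(values.sum())
    window_sums = np.convolve(values, np.ones(window), mode="valid")
    return float(window_sums.mean())


def _group_indices(seq: str, group_ivl: bool) -> np.ndarray:
    """Map residues to integer group labels.

    With IVL grouping there are 18 standard groups ({IVL} plus 17 singletons);
    without it, 20 singletons.  Nonstandard residues share one pooled group.
    """
    groups: dict[str, int] = {}
    nxt = 0
    if group_ivl:
        for aa in _IVL:
            groups[aa] = 0
        nxt = 1
    out = np.empty(len(seq), dtype=np.intp)
    other = -1
    for i, aa in enumerate(seq):
        if aa in groups:
            out[i] = groups[aa]
        elif aa in _STANDARD_SET:
            groups[aa] = nxt
            out[i] = nxt
            nxt += 1
        else:
            if other < 0:
                other = nxt
                nxt += 1
            out[i] = other
    return out


def _window_entropy(labels: np.ndarray) -> float:
    counts = np.bincount(labels)
    counts = counts[counts > 0]
    p = counts / labels.size
    return float(-(p * np.log2(p)).sum())


def complexity(sequence: str, window: int = 12, group_ivl: bool = True) -> float:
    """Mean windowed Shannon entropy (bits) of the residue-group composition."""
    if window < 1:
        raise ValueError("window must be >= 1")
    seq = _clean(sequence, what="complexity")
    _warn_nonstandard(seq)
    labels = _group_indices(seq, group_ivl)
    if len(seq) <= window:
        return _window_entropy(labels)
    ent = [
        _window_entropy(labels[i : i + window])
        for i in range(len(seq) - window + 1)
    ]
    return float(np.mean(ent))


def measure_segment(
    segment: TMSegment,
    config: WindowConfig | None = None,
    scale: ResidueScale | None = None,
) -> MeasurePair:
    """Score one segment under a window configuration and scale."""
    cfg = config or WindowConfig()
    return MeasurePair(
        x_c=complexity(segment.sequence, cfg.complexity_window, cfg.group_ivl),
        x_phi=hydrophobicity(segment.sequence, scale, cfg.hydro_window),
    )
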