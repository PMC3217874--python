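"""Masking of TM segments with runs of 'X' prior to similarity searches.

Masking uses a single z cutoff (derived from the quantile f): in
``simple`` mode every segment with z strictly below the cutoff is replaced
position-wise by 'X'; in ``control`` mode the complement (z at or above
the cutoff) is masked instead.  All other positions are untouched and the
output length always equals the input length.  A position covered by
overlapping segments is masked if any covering segment is directed to be
masked.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .annotations_io import ProteinRecord

__all__ = ["MaskReport", "mask_sequence", "mask_ratio_summary"]

MaskMode = Literal["simple", "control"]


@dataclass(frozen=True)
class MaskReport:
    """Per-protein masking outcome; mask_ratio is None when there are no TMs."""

    protein_id: str
    n_tms: int
    n_masked: int
    mode: MaskMode

    @property
    def mask_ratio(self) -> float | None:
        if self.n_tms == 0:
            return None
        return self.n_masked / self.n_tms


def mask_sequence(
    record: ProteinRecord,
    zscores: Sequence[float],
    mode: MaskMode = "simple",
    cutoff: float = -3.29,
) -> tuple[str, MaskReport]:
    """Mask the record's TM segments selected by their z-scores.

    ``zscores`` aligns with ``record.segments``.  ``cutoff`` is the single z
    threshold (use :func:`tmclass.zscore.threshold_from_f` to derive it from
    f): simple mode masks z < cutoff, control mode masks z >= cutoff.
    """
    if len(zscores) != len(record.segments):
        raise ValueError(
            f"{record.protein_id}: {len(zscores)} z-scores for "
            f"{len(record.segments)} segments"
        )
    if mode not in ("simple", "control"):
        raise ValueError(f"unknown mask mode {mode!r}")
    seq = list(record.sequence)
    n_masked = 0
    for seg, z in zip(record.segments, zscores):
        masked = (z < cutoff) if mode == "simple" else (z >= cutoff)
        if masked:
            n_masked += 1
            seq[seg.start - 1 : seg.end] = "X" * seg.length
    report = MaskReport(
        protein_id=record.protein_id,
        n_tms=len(record.segments),
        n_masked=n_masked,
        mode=mode,
    )
    return "".join(seq), report


def mask_ratio_summary(reports: Iterable[MaskReport]) -> dict[str, float | int]:
    """Median mask ratio and count of partially masked entries (0 < m < 1).

    Entries without TMs (ratio undefined) are excluded from the median.
    """
    ratios = [r.mask_ratio for r in reports if r.mask_ratio is not None]
    if not ratios:
        raise ValueError("no reports with defined mask ratio")
    arr = np.asarray(ratios)
    return {
        "n": int(arr.size),
        "median_mask_ratio": float(np.median(arr)),
        "n_partial": int(np.sum((arr > 0) & (arr < 1))),
        "n_fully_masked": int(np.sum(arr == 1)),
        "n_unmasked": int(np.sum(arr == 0)),
    }
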