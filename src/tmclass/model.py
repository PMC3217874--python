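"""Model/Results interface over the TM classification pipeline.

`TMComplexityModel` holds a set of annotated TM segments together with the
window configuration and hydrophobicity scale; `fit()` computes the
(complexity, hydrophobicity) measures, normalizes them against reference
statistics — either the published functional-TM constants (the default) or
statistics estimated from the data itself — and returns a
`TMClassificationResults` carrying per-segment z-scores, class labels, the
regression diagnostics and a `summary()` table.  Masking and report
writing hang off the results object.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotations_io import ProteinRecord, TMReportRow, write_report
from .masking import MaskReport, mask_sequence
from .measures import MeasurePair, TMSegment, WindowConfig, measure_segment
from .scales import ResidueScale, default_scale
from .zscore import (
    DEFAULT_REFERENCE_STATS,
    DEFAULT_TWILIGHT_ZONE,
    ReferenceStats,
    RegressionLine,
    TwilightZone,
    classify,
    estimate_reference_stats,
    threshold_from_f,
    zscore,
)

__all__ = ["TMComplexityModel", "TMClassificationResults"]


class TMComplexityModel:
    """Simple/complex classification model for a set of TM segments."""

    def __init__(
        self,
        segments: Sequence[TMSegment],
        config: WindowConfig | None = None,
        scale: ResidueScale | None = None,
    ) -> None:
        if not segments:
            raise ValueError("need at least one TM segment")
        self.segments = list(segments)
        self.config = config or WindowConfig()
        self.scale = scale or default_scale()

    @classmethod
    def from_records(
        cls, records: Iterable[ProteinRecord], **kwargs
    ) -> "TMComplexityModel":
        segs = [s for r in records for s in r.segments]
        return cls(segs, **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "TMComplexityModel":
        """Build from columns protein_id, start, end, sequence[, category]."""
        segs = [
            TMSegment(
                protein_id=str(row.protein_id),
                start=int(row.start),
                end=int(row.end),
                sequence=str(row.sequence),
                category=getattr(row, "category", None),
            )
            for row in df.itertuples(index=False)
        ]
        return cls(segs, **kwargs)

    def measure(self) -> list[MeasurePair]:
        return [measure_segment(s, self.config, self.scale) for s in self.segments]

    def fit(
        self,
        ref: ReferenceStats | None = DEFAULT_REFERENCE_STATS,
        zone: TwilightZone = DEFAULT_TWILIGHT_ZONE,
    ) -> "TMClassificationResults":
        """Classify all segments.

        With ``ref=None`` the reference statistics (and the regression
        diagnostics) are estimated from this model's own segments, which
        requires at least 3 segments with non-degenerate variance.
        """
        pairs = self.measure()
        line: RegressionLine | None = None
        if ref is None:
            ref, line = estimate_reference_stats(pairs)
        results = [zscore(p, ref) for p in pairs]
        return TMClassificationResults(
            model=self, pairs=pairs, zresults=results, ref=ref, zone=zone,
            regression=line,
        )


class TMClassificationResults:
    """Per-segment measures, z-scores and class labels from a fitted model."""

    def __init__(self, model, pairs, zresults, ref, zone, regression=None) -> None:
        self.model = model
        self.pairs = pairs
        self.zresults = zresults
        self.ref_stats: ReferenceStats = ref
        self.zone: TwilightZone = zone
        self.regression: RegressionLine | None = regression
        self.classes = [classify(r.z, zone) for r in zresults]

    @property
    def z(self) -> np.ndarray:
        return np.array([r.z for r in self.zresults])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for seg, pair, zres, cls in zip(
            self.model.segments, self.pairs, self.zresults, self.classes
        ):
            rows.append(
                {
                    "protein_id": seg.protein_id,
                    "start": seg.start,
                    "end": seg.end,
                    "category": seg.category,
                    "x_c": pair.x_c,
                    "x_phi": pair.x_phi,
                    "z": zres.z,
                    "s": zres.s,
                    "class": cls.value,
                }
            )
        return pd.DataFrame(rows)

    def class_counts(self) -> dict[str, int]:
        out = {"simple": 0, "twilight": 0, "complex": 0}
        for c in self.classes:
            out[c.value] += 1
        return out

    def write_report(self, path) -> None:
        rows = [
            TMReportRow(
                protein_id=seg.protein_id, start=seg.start, end=seg.end,
                x_c=pair.x_c, x_phi=pair.x_phi, z=zres.z,
                tm_class=cls.value, category=seg.category,
            )
            for seg, pair, zres, cls in zip(
                self.model.segments, self.pairs, self.zresults, self.classes
            )
        ]
        write_report(rows, path)

    def mask_records(
        self,
        records: Iterable[ProteinRecord],
        mode: str = "simple",
        f: float = 1.282,
    ) -> tuple[dict[str, str], list[MaskReport]]:
        """Mask each record's segments at the single threshold z = -2f^2.

        Segments are re-scored with this result's reference statistics, so
        records need not coincide with the fitted segments.
        """
        cutoff = threshold_from_f(f)
        masked: dict[str, str] = {}
        reports: list[MaskReport] = []
        for rec in records:
            zs = [
                zscore(
                    measure_segment(s, self.model.config, self.model.scale),
                    self.ref_stats,
                ).z
                for s in rec.segments
            ]
            seq, rep = mask_sequence(rec, zs, mode=mode, cutoff=cutoff)
            masked[rec.protein_id] = seq
            reports.append(rep)
        return masked, reports

    def summary(self) -> str:
        counts = self.class_counts()
        ref = self.ref_stats
        lines = [
            "TM complexity classification",
            "=" * 60,
            f"segments: {len(self.model.segments)}   "
            f"hydro window: {self.model.config.hydro_window}   "
            f"complexity window: {self.model.config.complexity_window}   "
            f"IVL grouped: {self.model.config.group_ivl}",
            f"reference: mu_phi={ref.mu_phi:.2f} sigma_phi={ref.sigma_phi:.2f} "
            f"mu_c={ref.mu_c:.2f} sigma_c={ref.sigma_c:.2f} rho={ref.rho:.3f}",
            f"twilight zone: [{self.zone.lower:.2f}, {self.zone.upper:.2f}]",
            f"classes: {counts['simple']} simple / {counts['twilight']} twilight / "
            f"{counts['complex']} complex",
        ]
        if self.regression is not None:
            reg = self.regression
            lines.append(
                f"regression: x_phi = {reg.intercept:.3f} + {reg.slope:.3f} x_c "
                f"(normal slope {reg.normal_slope:.3f})"
            )
        lines.append("-" * 60)
        frame = self.to_frame().drop(columns=["category"])
        lines.append(
            frame.to_string(
                index=False,
                float_format=lambda v: f"{v:.2f}",
            )
        )
        return "\n".join(lines)

    def plot_measures(self, ax=None):
        """Scatter of segments in the complexity/hydrophobicity plane.

        Draws the regression line and its normal through the reference
        origin; requires matplotlib.
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        frame = self.to_frame()
        colors = {"simple": "tab:blue", "twilight": "tab:gray", "complex": "tab:red"}
        for cls, sub in frame.groupby("class"):
            ax.scatter(sub["x_c"], sub["x_phi"], s=12, label=cls, c=colors[cls])
        ref = self.ref_stats
        xc = np.linspace(frame["x_c"].min(), frame["x_c"].max(), 50)
        slope = ref.rho * ref.sigma_phi / ref.sigma_c
        ax.plot(xc, ref.mu_phi + slope * (xc - ref.mu_c), "k-", lw=1, label="regression")
        ax.plot(
            xc,
            ref.mu_phi + (-1.0 / ref.rho) * (ref.sigma_phi / ref.sigma_c) * (xc - ref.mu_c),
            "k--", lw=1, label="normal",
        )
        ax.set_xlabel("sequence complexity $x_c$ (bits)")
        ax.set_ylabel("hydrophobicity $x_\\phi$ (kcal/mol)")
        ax.legend(fontsize=8)
        return ax
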