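"""Evaluation statistics for the simple/complex TM classification.

Covers the confusion-matrix rates (FPR, FNR, FDR, sensitivity),
anchor-versus-functional error-rate estimation at z thresholds -2f^2,
amino-acid composition tests (20x2 chi-square and per-residue 2x2
enrichment with Bonferroni correction), the correlation of enrichment
with a hydrophobicity scale, per-TM-count occurrence tables with a
zero-intercept slope fit, and the masked-search cutoff evaluation.

Rates with an empty denominator are reported as None (a not-applicable
sentinel), never as a silent 0/0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .measures import MeasurePair
from .scales import STANDARD_RESIDUES, ResidueScale
from .zscore import ReferenceStats, threshold_from_f, zscore

__all__ = [
    "ConfusionCounts",
    "RateSet",
    "HitRecord",
    "rates",
    "anchor_vs_functional_rates",
    "composition_test_20x2",
    "residue_enrichment",
    "scale_correlation",
    "occurrence_table",
    "origin_slope",
    "search_eval",
    "read_hit_table",
    "write_hit_table",
]

#: Chi-square critical value at df = 19, alpha = 0.05, as conventionally printed.
CHI2_CRITICAL_20x2 = 30.14


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be nonnegative")


@dataclass(frozen=True)
class RateSet:
    """FPR = FP/(FP+TN); FNR = FN/(TP+FN); FDR = FP/(FP+TP); sens = 1-FNR."""

    fpr: float | None
    fnr: float | None
    fdr: float | None
    sensitivity: float | None


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def rates(counts: ConfusionCounts) -> RateSet:
    fnr = _ratio(counts.fn, counts.tp + counts.fn)
    return RateSet(
        fpr=_ratio(counts.fp, counts.fp + counts.tn),
        fnr=fnr,
        fdr=_ratio(counts.fp, counts.fp + counts.tp),
        sensitivity=None if fnr is None else 1.0 - fnr,
    )


def anchor_vs_functional_rates(
    anchors: Sequence[MeasurePair],
    functionals: Sequence[MeasurePair],
    ref: ReferenceStats,
    f: float,
) -> tuple[float, float]:
    """(FPR, FNR) of the z < -2f^2 simple/complex call.

    The positive class is "complex": a functional segment with z below the
    threshold is a false negative, an anchor with z at or above it a false
    positive (anchors being the presumed-simple set).
    """
    if not anchors or not functionals:
        raise ValueError("both the anchor and functional sets must be non-empty")
    cut = threshold_from_f(f)
    anchor_z = np.array([zscore(p, ref).z for p in anchors])
    func_z = np.array([zscore(p, ref).z for p in functionals])
    fpr = float(np.mean(anchor_z >= cut))
    fnr = float(np.mean(func_z < cut))
    return fpr, fnr


def _as_count_vector(counts: Mapping[str, int] | Sequence[int]) -> np.ndarray:
    if isinstance(counts, Mapping):
        vec = np.array([counts.get(aa, 0) for aa in STANDARD_RESIDUES], dtype=float)
    else:
        vec = np.asarray(counts, dtype=float)
    if vec.shape != (20,) or (vec < 0).any():
        raise ValueError("expected 20 nonnegative residue counts")
    if vec.sum() == 0:
        raise ValueError("count vector sums to zero")
    return vec


def composition_test_20x2(
    counts_a: Mapping[str, int] | Sequence[int],
    counts_b: Mapping[str, int] | Sequence[int],
    critical: float = CHI2_CRITICAL_20x2,
) -> dict[str, float | bool | int]:
    """Pearson chi-square proportion test on the 20x2 composition table.

    Residue rows that are zero in both samples contribute nothing and are
    dropped before the test (their expected counts are zero).  Significance
    is reported both against the fixed printed critical value and against
    the exact chi-square(df) quantile.
    """
    a, b = _as_count_vector(counts_a), _as_count_vector(counts_b)
    table = np.stack([a, b], axis=1)
    nonzero = table.sum(axis=1) > 0
    chi2, pvalue, dof, _ = stats.chi2_contingency(table[nonzero], correction=False)
    return {
        "chi2": float(chi2),
        "df": int(dof),
        "pvalue": float(pvalue),
        "significant_fixed_critical": bool(chi2 > critical),
        "significant": bool(pvalue < 0.05),
        "reliable": bool(nonzero.all()),
    }


def residue_enrichment(
    counts_a: Mapping[str, int] | Sequence[int],
    counts_b: Mapping[str, int] | Sequence[int],
    familywise_alpha: float = 0.05,
) -> tuple[set[str], set[str], pd.DataFrame]:
    """Per-residue two-sided 2x2 proportion tests with Bonferroni correction.

    Each residue is tested as a binomial comparative trial (residue vs all
    others, sample A vs sample B) at per-test alpha = familywise_alpha / 20.
    A significant residue joins the enriched set of the sample where its
    proportion is higher.  Returns (enriched_in_A, enriched_in_B, detail).
    """
    a, b = _as_count_vector(counts_a), _as_count_vector(counts_b)
    total_a, total_b = a.sum(), b.sum()
    alpha = familywise_alpha / 20.0
    rows = []
    for i, aa in enumerate(STANDARD_RESIDUES):
        table = np.array(
            [[a[i], total_a - a[i]], [b[i], total_b - b[i]]], dtype=float
        )
        if a[i] + b[i] == 0:
            pvalue, chi2 = 1.0, 0.0
        else:
            chi2, pvalue, _, _ = stats.chi2_contingency(table, correction=False)
        prop_a, prop_b = a[i] / total_a, b[i] / total_b
        rows.append(
            {
                "residue": aa,
                "prop_a": prop_a,
                "prop_b": prop_b,
                "chi2": float(chi2),
                "pvalue": float(pvalue),
                "significant": pvalue < alpha,
                "enriched_in": (
                    ("A" if prop_a > prop_b else "B") if pvalue < alpha else ""
                ),
            }
        )
    detail = pd.DataFrame(rows)
    enriched_a = set(detail.loc[detail.enriched_in == "A", "residue"])
    enriched_b = set(detail.loc[detail.enriched_in == "B", "residue"])
    return enriched_a, enriched_b, detail


def scale_correlation(
    freq_diff: Mapping[str, float] | Sequence[float], scale: ResidueScale
) -> float | None:
    """Pearson correlation of per-residue frequency differences with a scale.

    ``freq_diff`` holds, per residue, the relative-frequency difference
    between two samples (A minus B); this is the documented representation
    of "statistically enriched residues" used for the correlation.
    Returns None when either vector has zero variance.
    """
    if isinstance(freq_diff, Mapping):
        diff = np.array([freq_diff.get(aa, 0.0) for aa in STANDARD_RESIDUES])
    else:
        diff = np.asarray(freq_diff, dtype=float)
    if diff.shape != (20,):
        raise ValueError("expected 20 per-residue values")
    vals = np.array([scale[aa] for aa in STANDARD_RESIDUES])
    if np.std(diff) == 0 or np.std(vals) == 0:
        return None
    return float(stats.pearsonr(diff, vals).statistic)


def origin_slope(n_tm: Sequence[float], expected: Sequence[float]) -> tuple[float, float]:
    """Zero-intercept least-squares slope of expected counts on TM count.

    slope = sum(n * sh) / sum(n^2); the goodness of fit R^2 is reported
    against the mean of the response.
    """
    x = np.asarray(n_tm, dtype=float)
    y = np.asarray(expected, dtype=float)
    slope = float(np.sum(x * y) / np.sum(x * x))
    resid = y - slope * x
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
    return slope, r2


def occurrence_table(
    groups: Mapping[int, Sequence[MeasurePair]],
    ref: ReferenceStats,
    f: float,
) -> tuple[pd.DataFrame, float, float]:
    """Per-TM-count simple/complex occurrence ratios and the origin-slope fit.

    ``groups`` maps a protein's TM count to the measure pairs of all TMs in
    that bin.  A TM is counted simple when z < -2f^2.  The expected number
    of simple TMs per protein is ratio_simple * n_tm; the zero-intercept
    regression of that column on n_tm gives (slope, R^2).
    """
    cut = threshold_from_f(f)
    rows = []
    for n_tm in sorted(groups):
        pairs = groups[n_tm]
        if not pairs:
            warnings.warn(f"empty bin for {n_tm} TMs; skipped", stacklevel=2)
            continue
        z = np.array([zscore(p, ref).z for p in pairs])
        ratio_simple = float(np.mean(z < cut))
        rows.append(
            {
                "n_tm": n_tm,
                "n_segments": len(pairs),
                "ratio_complex": 1.0 - ratio_simple,
                "ratio_simple": ratio_simple,
                "expected_simple": ratio_simple * n_tm,
            }
        )
    if not rows:
        raise ValueError("no non-empty bins")
    table = pd.DataFrame(rows)
    slope, r2 = origin_slope(table["n_tm"], table["expected_simple"])
    return table, slope, r2


@dataclass(frozen=True)
class HitRecord:
    """One similarity-search hit with scores for the three query variants."""

    query_id: str
    subject_id: str
    family: str | None
    e_value: float
    score_original: float
    score_masked: float
    score_control: float

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError("e_value must be nonnegative")
        for s in (self.score_original, self.score_masked, self.score_control):
            if not np.isfinite(s):
                raise ValueError("scores must be finite")


_HIT_COLUMNS = [
    "query_id", "subject_id", "family", "e_value",
    "score_original", "score_masked", "score_control",
]


def read_hit_table(path) -> list[HitRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"family": str})
    missing = set(_HIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    hits = []
    for row in df.itertuples(index=False):
        fam = getattr(row, "family")
        hits.append(
            HitRecord(
                query_id=str(row.query_id),
                subject_id=str(row.subject_id),
                family=None if pd.isna(fam) or fam == "" else str(fam),
                e_value=float(row.e_value),
                score_original=float(row.score_original),
                score_masked=float(row.score_masked),
                score_control=float(row.score_control),
            )
        )
    return hits


def write_hit_table(hits: Iterable[HitRecord], path) -> None:
    df = pd.DataFrame(
        [
            (h.query_id, h.subject_id, h.family or "", h.e_value,
             h.score_original, h.score_masked, h.score_control)
            for h in hits
        ],
        columns=_HIT_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def search_eval(
    hits: Sequence[HitRecord],
    query_family: str,
    evalue_cutoff: float = 0.001,
) -> dict[str, dict] | None:
    """Score one query's hits against the minimum-masked-score cutoff.

    Hits with E-value above the cutoff or without a family label are
    discarded.  The score cutoff is the minimum masked score over the
    surviving hits of the query's own family: for each scored variant
    (original / masked / control) a same-family hit scoring at or above the
    cutoff is a TP (below: FN) and a different-family hit at or above it a
    FP (below: TN).  The masked variant's sensitivity is 1 by construction.
    Returns None when no same-family hit survives the filters.
    """
    kept = [h for h in hits if h.family is not None and h.e_value <= evalue_cutoff]
    same = [h for h in kept if h.family == query_family]
    if not same:
        return None
    cutoff = min(h.score_masked for h in same)
    out: dict[str, dict] = {"cutoff": {"score": cutoff, "n_hits": len(kept)}}
    for variant in ("original", "masked", "control"):
        tp = fp = tn = fn = 0
        for h in kept:
            score = getattr(h, f"score_{variant}")
            if h.family == query_family:
                if score >= cutoff:
                    tp += 1
                else:
                    fn += 1
            elif score >= cutoff:
                fp += 1
            else:
                tn += 1
        counts = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
        r = rates(counts)
        out[variant] = {"counts": counts, "fdr": r.fdr, "sensitivity": r.sensitivity}
    return out
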