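"""Prediction-response concordance: confusion matrices over strata.

Every expressed gene is classified against a target-prediction table for a
chosen orientation of miRNA action:

* canonical orientation expects the transcript to fall with miRNA
  over-expression and rise with inhibition (negative miRNA-mRNA
  correlation);
* non-canonical orientation expects the reverse (positive correlation).

A predicted gene responding in the expected direction is a true positive;
a predicted gene responding otherwise (including the opposite direction)
is a false positive; a non-predicted gene responding in the expected
direction is a false negative; everything else is a true negative.  From
the tallies: accuracy = (TP+TN)/N, sensitivity = TP/(TP+FN), specificity =
TN/(TN+FP), FNR = 1-sensitivity, FPR = 1-specificity.  Rates with a zero
denominator are reported as absent, never coerced to 0 or 1.

Strata combine a modulation model (single arm, or the bidirectional
intersection), a cell type, and a prediction parameter: all predictions,
conservation status, or one of the seed-match site classes.  For a
parameter stratum the positive class is "predicted with that parameter";
every other retained gene (including genes predicted under a different
parameter) forms the negative class.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .expression import (
    EXPECTED_DIRECTION,
    MODULATIONS,
    ORIENTATIONS,
    bidirectional_set,
)

logger = logging.getLogger(__name__)

PREDICTION_PARAMETERS = (
    "all", "conserved", "nonconserved", "8mer", "7mer-m8", "7mer-1A",
)
MODULATION_MODELS = ("miR", "anti_miR", "bidirectional")
OUTCOMES = ("TP", "TN", "FP", "FN")


@dataclass(frozen=True)
class Stratum:
    """Labels identifying one evaluation cell."""

    modulation: str            # "miR" | "anti_miR" | "bidirectional"
    cell_type: str
    prediction_parameter: str  # one of PREDICTION_PARAMETERS
    orientation: str           # "canonical" | "noncanonical"

    def __post_init__(self) -> None:
        if self.modulation not in MODULATION_MODELS:
            raise ValidationError(f"unknown modulation {self.modulation!r}")
        if self.prediction_parameter not in PREDICTION_PARAMETERS:
            raise ValidationError(
                f"unknown prediction parameter {self.prediction_parameter!r}"
            )
        if self.orientation not in ORIENTATIONS:
            raise ValidationError(f"unknown orientation {self.orientation!r}")


def _safe_ratio(num: float, den: float) -> Optional[float]:
    if den == 0:
        return None
    return num / den


@dataclass(frozen=True)
class ConfusionSummary:
    """TP/TN/FP/FN tallies and derived rates for one stratum."""

    stratum: Stratum
    tp: float
    tn: float
    fp: float
    fn: float
    accuracy: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]
    fpr: Optional[float]
    fnr: Optional[float]

    @classmethod
    def from_counts(
        cls, stratum: Stratum, tp: float, tn: float, fp: float, fn: float
    ) -> "ConfusionSummary":
        total = tp + tn + fp + fn
        sens = _safe_ratio(tp, tp + fn)
        spec = _safe_ratio(tn, tn + fp)
        return cls(
            stratum=stratum, tp=tp, tn=tn, fp=fp, fn=fn,
            accuracy=_safe_ratio(tp + tn, total),
            sensitivity=sens,
            specificity=spec,
            fpr=None if spec is None else 1.0 - spec,
            fnr=None if sens is None else 1.0 - sens,
        )

    @property
    def universe_size(self) -> float:
        return self.tp + self.tn + self.fp + self.fn


def classify_gene(
    predicted: bool, direction: str, modulation: str, orientation: str
) -> str:
    """Confusion class of one gene in a single modulation arm.

    ``direction`` is the observed call ("up", "down" or "unchanged");
    the orientation and arm fix the expected direction.  A gene changed in
    the unexpected direction counts as not differentially expressed for
    this orientation.
    """
    if modulation not in MODULATIONS:
        raise ValidationError(
            f"unknown modulation arm {modulation!r}; use classify_responsive "
            f"for the bidirectional model"
        )
    if orientation not in ORIENTATIONS:
        raise ValidationError(f"unknown orientation {orientation!r}")
    if direction not in ("up", "down", "unchanged"):
        raise ValidationError(f"unknown direction {direction!r}")
    responsive = direction == EXPECTED_DIRECTION[(orientation, modulation)]
    return classify_responsive(predicted, responsive)


def classify_responsive(predicted: bool, responsive: bool) -> str:
    if predicted:
        return "TP" if responsive else "FP"
    return "FN" if responsive else "TN"


def predicted_gene_sets(predictions: pd.DataFrame) -> Dict[str, Set[str]]:
    """Map each prediction parameter to its set of predicted genes."""
    required = {"gene", "site_type"}
    missing = required - set(predictions.columns)
    if missing:
        raise ValidationError(
            f"prediction table missing column(s): {sorted(missing)}"
        )
    sets: Dict[str, Set[str]] = {p: set() for p in PREDICTION_PARAMETERS}
    sets["all"] = set(predictions["gene"])
    if "conserved" in predictions.columns:
        cons = predictions["conserved"]
        cons_bool = cons.map(
            lambda v: None if pd.isna(v) else bool(int(v))
            if not isinstance(v, bool) else v
        )
        sets["conserved"] = set(predictions.loc[cons_bool == True, "gene"])  # noqa: E712
        sets["nonconserved"] = set(predictions.loc[cons_bool == False, "gene"])  # noqa: E712
    for site in ("8mer", "7mer-m8", "7mer-1A"):
        sets[site] = set(
            predictions.loc[predictions["site_type"] == site, "gene"]
        )
    return sets


def _responsive_set(
    calls: pd.DataFrame, stratum: Stratum
) -> Tuple[Set[str], pd.Index]:
    """(responsive genes, retained universe) for a stratum's cell/model."""
    cell_calls = calls[calls["cell_type"] == stratum.cell_type]
    if cell_calls.empty:
        raise ValidationError(
            f"no calls for cell type {stratum.cell_type!r}"
        )
    universe = pd.Index(sorted(set(cell_calls["gene"])))
    if stratum.modulation == "bidirectional":
        responsive = bidirectional_set(
            calls, stratum.cell_type, stratum.orientation
        )
    else:
        arm = cell_calls[cell_calls["modulation"] == stratum.modulation]
        if arm.empty:
            raise ValidationError(
                f"no {stratum.modulation!r} calls for {stratum.cell_type!r}"
            )
        expected = EXPECTED_DIRECTION[(stratum.orientation, stratum.modulation)]
        responsive = set(arm.loc[arm["direction"] == expected, "gene"])
    return responsive, universe


def evaluate_stratum(
    calls: pd.DataFrame, predictions: pd.DataFrame, stratum: Stratum
) -> ConfusionSummary:
    """Tally every retained gene of the stratum's cell type exactly once."""
    responsive, universe = _responsive_set(calls, stratum)
    if len(universe) == 0:
        raise ValidationError("empty gene universe")
    predicted = predicted_gene_sets(predictions)[stratum.prediction_parameter]
    pred = universe.isin(predicted)
    resp = universe.isin(responsive)
    tp = int((pred & resp).sum())
    fp = int((pred & ~resp).sum())
    fn = int((~pred & resp).sum())
    tn = int((~pred & ~resp).sum())
    return ConfusionSummary.from_counts(stratum, tp, tn, fp, fn)


def stratified_evaluation(
    calls: pd.DataFrame,
    predictions: pd.DataFrame,
    cell_types: Optional[Sequence[str]] = None,
    modulations: Sequence[str] = MODULATION_MODELS,
    parameters: Sequence[str] = PREDICTION_PARAMETERS,
    orientations: Sequence[str] = ORIENTATIONS,
) -> List[ConfusionSummary]:
    """One :class:`ConfusionSummary` per grid cell, in grid order."""
    if cell_types is None:
        cell_types = list(dict.fromkeys(calls["cell_type"]))
    out = []
    for orientation in orientations:
        for modulation in modulations:
            for cell in cell_types:
                for param in parameters:
                    out.append(
                        evaluate_stratum(
                            calls, predictions,
                            Stratum(modulation, cell, param, orientation),
                        )
                    )
    return out


def summaries_to_frame(summaries: Iterable[ConfusionSummary]) -> pd.DataFrame:
    """Tidy frame, one summary per row (absent rates as NaN)."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "modulation": s.stratum.modulation,
                "cell_type": s.stratum.cell_type,
                "prediction_parameter": s.stratum.prediction_parameter,
                "orientation": s.stratum.orientation,
                "tp": s.tp, "tn": s.tn, "fp": s.fp, "fn": s.fn,
                "accuracy": np.nan if s.accuracy is None else s.accuracy,
                "sensitivity": np.nan if s.sensitivity is None else s.sensitivity,
                "specificity": np.nan if s.specificity is None else s.specificity,
                "fpr": np.nan if s.fpr is None else s.fpr,
                "fnr": np.nan if s.fnr is None else s.fnr,
            }
        )
    return pd.DataFrame(rows)


def mean_over_parameters(
    summaries: pd.DataFrame,
    statistic: str = "accuracy",
    group_by: Sequence[str] = ("modulation",),
) -> pd.Series:
    """Arithmetic mean of a statistic across parameter strata per group."""
    if statistic not in summaries.columns:
        raise ValidationError(f"unknown statistic {statistic!r}")
    grouped = summaries.groupby(list(group_by))[statistic].mean()
    if grouped.isna().any() or len(grouped) == 0:
        empty = grouped[grouped.isna()].index.tolist()
        if len(grouped) == 0 or empty:
            raise ValidationError(f"empty group(s) for {statistic!r}: {empty}")
    return grouped


def paired_ttest(
    values_a: Sequence[float], values_b: Sequence[float]
) -> Tuple[Optional[float], Optional[float]]:
    """Paired two-tailed Student's t-test.

    Identical vectors give (0.0, 1.0) by convention.  A non-zero constant
    difference has zero variance, so no t statistic exists; (None, None)
    is returned with a logged diagnostic.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("paired vectors must have equal length")
    if a.size < 2:
        raise ValidationError("need at least two pairs")
    d = a - b
    if np.allclose(d.var(ddof=0), 0.0):
        if np.allclose(d, 0.0):
            return 0.0, 1.0
        logger.warning(
            "paired_ttest: zero variance of non-zero differences; "
            "t statistic undefined"
        )
        return None, None
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def rm_anova(values: np.ndarray) -> Tuple[float, float]:
    """One-way repeated-measures ANOVA on a subjects x conditions matrix.

    Classical within-subject decomposition with F on
    ``(k-1, (k-1)(n-1))`` degrees of freedom.  An all-equal column profile
    gives (0.0, 1.0); a perfect profile with no residual gives
    (inf, 0.0).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2:
        raise ValidationError("values must be a 2-D subjects x conditions array")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValidationError("need >= 2 subjects and >= 2 conditions")
    if not np.isfinite(x).all():
        raise ValidationError("incomplete matrix: non-finite entries present")
    grand = x.mean()
    ss_cond = n * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((x - grand) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    if math.isclose(ss_cond, 0.0, abs_tol=1e-12 * max(1.0, ss_tot)):
        return 0.0, 1.0
    if ss_err <= 1e-12 * max(1.0, ss_tot):
        return math.inf, 0.0
    f = (ss_cond / df1) / (ss_err / df2)
    return float(f), float(stats.f.sf(f, df1, df2))


def orientation_correlation(
    stats_canonical: Sequence[float], stats_noncanonical: Sequence[float]
) -> Tuple[Optional[float], Optional[float]]:
    """Squared Pearson correlation (sign-blind) between paired statistics.

    Returns (R^2, two-tailed p); (None, None) with a diagnostic when either
    vector has zero variance.
    """
    a = np.asarray(stats_canonical, dtype=float)
    b = np.asarray(stats_noncanonical, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("paired vectors must have equal length")
    if a.size < 3:
        raise ValidationError("need at least three paired strata")
    if np.allclose(a.var(), 0.0) or np.allclose(b.var(), 0.0):
        logger.warning("orientation_correlation: zero variance input")
        return None, None
    r, p = stats.pearsonr(a, b)
    return float(r * r), float(p)


def pct_fraction_below(
    pcts: Iterable[float], cutoff: float = 0.1
) -> float:
    """Fraction of PCT scores strictly below ``cutoff``.

    A score exactly at the cutoff is not counted.  Raises on empty or
    missing input: PCT must be present on every supplied record.
    """
    vals = np.asarray(list(pcts), dtype=float)
    if vals.size == 0:
        raise ValidationError("no PCT values supplied")
    if not np.isfinite(vals).all():
        raise ValidationError("missing PCT value(s) in input")
    return float((vals < cutoff).mean())
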