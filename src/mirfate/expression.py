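"""Expression-matrix processing for bidirectional miRNA modulation designs.

The experimental layout modelled here is an array-style intensity matrix
over three conditions per cell type -- untreated ``control``, ``miR``
(synthetic miRNA over-expression) and ``anti_miR`` (antisense inhibition of
the endogenous miRNA) -- with at least two replicates per condition.

Processing follows the classic array workflow:

1. genes expressed below background in more than half of a cell line's
   samples are excluded (:func:`filter_background`);
2. per-chip scaling brings every sample's median over retained genes to
   1.0, then per-gene scaling divides each gene by the median of its
   control samples within the cell type (:func:`normalize`);
3. a gene is called modulated when its treatment/control fold change
   exceeds a threshold (1.5-fold by default), optionally gated by an
   uncorrected two-sample t-test on log2 values (:func:`call_modulation`).

Set logic over the resulting calls expresses the bidirectional criterion
(down with the miR and up with the anti-miR, or the reverse for the
non-canonical orientation) and multi-cell-type intersections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Dict, Iterable, Mapping, Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

logger = logging.getLogger(__name__)

CONDITIONS = ("control", "miR", "anti_miR")
MODULATIONS = ("miR", "anti_miR")
ORIENTATIONS = ("canonical", "noncanonical")

#: Expected call direction per (orientation, modulation arm).
EXPECTED_DIRECTION = {
    ("canonical", "miR"): "down",
    ("canonical", "anti_miR"): "up",
    ("noncanonical", "miR"): "up",
    ("noncanonical", "anti_miR"): "down",
}


@dataclass
class ExpressionExperiment:
    """A genes x samples intensity matrix with sample metadata.

    ``matrix`` is indexed by gene id with sample ids as columns;
    ``samples`` is indexed by sample id with columns ``cell_type``,
    ``condition`` and ``replicate``.  ``background_threshold`` is the raw
    intensity below which a measurement counts as unexpressed.
    """

    matrix: pd.DataFrame
    samples: pd.DataFrame
    background_threshold: float

    def __post_init__(self) -> None:
        if self.matrix.index.has_duplicates:
            dup = self.matrix.index[self.matrix.index.duplicated()].unique()
            raise ValidationError(f"duplicate gene ids: {list(dup)[:5]}")
        missing = set(self.matrix.columns) - set(self.samples.index)
        if missing:
            raise ValidationError(
                f"samples without metadata: {sorted(missing)[:5]}"
            )
        bad_cond = set(self.samples["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise ValidationError(
                f"unknown conditions {sorted(bad_cond)}; expected {CONDITIONS}"
            )
        counts = self.samples.groupby(["cell_type", "condition"]).size()
        if (counts < 2).any():
            offenders = counts[counts < 2].index.tolist()
            raise ValidationError(
                f"need >= 2 replicates per (cell_type, condition); "
                f"short groups: {offenders}"
            )
        if (self.matrix.to_numpy() < 0).any():
            raise ValidationError("intensities must be non-negative")

    @property
    def cell_types(self) -> Sequence[str]:
        return list(dict.fromkeys(self.samples["cell_type"]))

    def sample_ids(
        self, cell_type: str, condition: Optional[str] = None
    ) -> Sequence[str]:
        meta = self.samples[self.samples["cell_type"] == cell_type]
        if condition is not None:
            meta = meta[meta["condition"] == condition]
        return [s for s in self.matrix.columns if s in set(meta.index)]

    def _single_cell(self, cell_type: Optional[str]) -> str:
        cells = self.cell_types
        if cell_type is None:
            if len(cells) != 1:
                raise ValidationError(
                    f"experiment has cell types {cells}; specify cell_type"
                )
            return cells[0]
        if cell_type not in cells:
            raise ValidationError(f"unknown cell type {cell_type!r}")
        return cell_type


def filter_background(
    experiment: ExpressionExperiment, cell_type: Optional[str] = None
) -> pd.Index:
    """Genes expressed above background in at least half the cell's samples.

    The exclusion rule removes genes below background in *more than* half of
    a cell line's samples; a gene at exactly half is retained.  Raw (not
    normalised) intensities are compared against ``background_threshold``.
    """
    cell = experiment._single_cell(cell_type)
    cols = experiment.sample_ids(cell)
    sub = experiment.matrix[cols]
    above = (sub >= experiment.background_threshold).sum(axis=1)
    retained = experiment.matrix.index[above >= len(cols) / 2.0]
    return retained


def normalize_per_chip(
    experiment: ExpressionExperiment,
    retained: Optional[Mapping[str, pd.Index]] = None,
) -> ExpressionExperiment:
    """Scale each sample so its median over retained genes equals 1.0.

    Exactly idempotent: after one application every sample median over the
    retained set is 1, so a second application is the identity.
    """
    matrix = experiment.matrix.copy()
    for cell in experiment.cell_types:
        keep = (
            retained[cell]
            if retained is not None
            else filter_background(experiment, cell)
        )
        for col in experiment.sample_ids(cell):
            med = float(matrix.loc[keep, col].median())
            if med <= 0:
                raise ValidationError(
                    f"sample {col!r}: non-positive median over retained genes"
                )
            matrix[col] = matrix[col] / med
    return replace(experiment, matrix=matrix)


def normalize_per_gene(experiment: ExpressionExperiment) -> ExpressionExperiment:
    """Divide each gene by the median of its control samples per cell type.

    Genes whose control median is zero in any cell type cannot be
    referenced and are excluded with a logged reason.  Exactly idempotent:
    after one application every control median is 1.
    """
    matrix = experiment.matrix.copy()
    drop: Set[str] = set()
    for cell in experiment.cell_types:
        ctrl = experiment.sample_ids(cell, "control")
        if not ctrl:
            raise ValidationError(f"cell type {cell!r} has no control samples")
        cell_cols = experiment.sample_ids(cell)
        ctrl_median = matrix[ctrl].median(axis=1)
        zero = ctrl_median[ctrl_median <= 0].index
        if len(zero):
            logger.warning(
                "excluding %d gene(s) with zero control median in %s: %s",
                len(zero), cell, list(zero[:5]),
            )
            drop.update(zero)
        safe = ctrl_median.replace(0, np.nan)
        matrix[cell_cols] = matrix[cell_cols].div(safe, axis=0)
    if drop:
        matrix = matrix.drop(index=sorted(drop))
        samples = experiment.samples
        return ExpressionExperiment(matrix, samples, experiment.background_threshold)
    return replace(experiment, matrix=matrix)


def normalize(experiment: ExpressionExperiment) -> ExpressionExperiment:
    """Per-chip then per-gene normalisation (both steps idempotent alone)."""
    return normalize_per_gene(normalize_per_chip(experiment))


@dataclass(frozen=True)
class ModulationCall:
    gene: str
    cell_type: str
    modulation: str  # "miR" | "anti_miR"
    direction: str   # "up" | "down" | "unchanged"
    fold_change: float
    p_value: Optional[float]


def _direction(fold: float, threshold: float) -> str:
    if fold >= threshold:
        return "up"
    if fold <= 1.0 / threshold:
        return "down"
    return "unchanged"


def call_modulation(
    normalized: ExpressionExperiment,
    genes: Optional[Iterable[str]] = None,
    fc_threshold: float = 1.5,
    p_threshold: float = 0.05,
    mode: str = "fc_and_p",
    cell_type: Optional[str] = None,
) -> pd.DataFrame:
    """Call per-gene modulation for both treatment arms of one cell type.

    ``fold_change`` is the ratio of linear means, treatment over control.
    In ``fc_and_p`` mode an uncorrected two-sample pooled-variance t-test on
    log2 values must reach ``p_threshold`` for a direction call; in
    ``fc_only`` mode fold change alone decides and ``p_value`` is absent.
    The threshold is inclusive: a fold change of exactly ``fc_threshold``
    (or its reciprocal) counts as modulated.

    Returns a tidy frame with one row per (gene, modulation arm), covering
    every requested gene including the unchanged ones.
    """
    if mode not in ("fc_and_p", "fc_only"):
        raise ValidationError(f"unknown mode {mode!r}")
    if fc_threshold < 1.0:
        raise ValidationError("fc_threshold must be >= 1")
    cell = normalized._single_cell(cell_type)
    gene_index = (
        normalized.matrix.index
        if genes is None
        else pd.Index([g for g in genes if g in normalized.matrix.index])
    )
    ctrl_cols = normalized.sample_ids(cell, "control")

    rows = []
    for arm in MODULATIONS:
        treat_cols = normalized.sample_ids(cell, arm)
        if not treat_cols:
            raise ValidationError(f"cell type {cell!r} has no {arm!r} samples")
        ctrl = normalized.matrix.loc[gene_index, ctrl_cols].to_numpy(float)
        treat = normalized.matrix.loc[gene_index, treat_cols].to_numpy(float)
        ctrl_mean = ctrl.mean(axis=1)
        treat_mean = treat.mean(axis=1)
        zero_ctrl = ctrl_mean <= 0
        if zero_ctrl.any():
            logger.warning(
                "skipping %d gene(s) with zero control mean in %s/%s",
                int(zero_ctrl.sum()), cell, arm,
            )
        fold = np.divide(
            treat_mean, ctrl_mean, out=np.full_like(treat_mean, np.nan),
            where=~zero_ctrl,
        )
        if mode == "fc_and_p":
            with np.errstate(divide="ignore", invalid="ignore"):
                tres = stats.ttest_ind(
                    np.log2(np.where(treat > 0, treat, np.nan)),
                    np.log2(np.where(ctrl > 0, ctrl, np.nan)),
                    axis=1, equal_var=True, nan_policy="omit",
                )
            pvals = np.asarray(tres.pvalue, dtype=float)
        else:
            pvals = np.full(len(gene_index), np.nan)

        for gene, f, p, skip in zip(gene_index, fold, pvals, zero_ctrl):
            if skip:
                continue
            direction = _direction(float(f), fc_threshold)
            if mode == "fc_and_p" and direction != "unchanged":
                if not (np.isfinite(p) and p < p_threshold):
                    direction = "unchanged"
            rows.append(
                {
                    "gene": gene,
                    "cell_type": cell,
                    "modulation": arm,
                    "direction": direction,
                    "fold_change": float(f),
                    "p_value": float(p) if np.isfinite(p) else np.nan,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["gene", "cell_type", "modulation", "direction",
                 "fold_change", "p_value"],
    )


def _arm_direction_set(
    calls: pd.DataFrame, cell_type: str, modulation: str, direction: str
) -> Set[str]:
    mask = (
        (calls["cell_type"] == cell_type)
        & (calls["modulation"] == modulation)
        & (calls["direction"] == direction)
    )
    return set(calls.loc[mask, "gene"])


def bidirectional_set(
    calls: pd.DataFrame, cell_type: str, orientation: str = "canonical"
) -> Set[str]:
    """Genes responding in the expected direction under *both* arms.

    Canonical: down under the miR and up under the anti-miR; non-canonical
    is the reverse (positive miRNA-mRNA correlation).
    """
    if orientation not in ORIENTATIONS:
        raise ValidationError(f"unknown orientation {orientation!r}")
    present = set(
        calls.loc[calls["cell_type"] == cell_type, "modulation"].unique()
    )
    missing = set(MODULATIONS) - present
    if missing:
        raise ValidationError(
            f"calls for {cell_type!r} lack modulation arm(s): {sorted(missing)}"
        )
    first = _arm_direction_set(
        calls, cell_type, "miR", EXPECTED_DIRECTION[(orientation, "miR")]
    )
    second = _arm_direction_set(
        calls, cell_type, "anti_miR",
        EXPECTED_DIRECTION[(orientation, "anti_miR")],
    )
    return first & second


def either_arm_set(
    calls: pd.DataFrame, cell_type: str, orientation: Optional[str] = None
) -> Set[str]:
    """Genes modulated by either arm.

    With ``orientation`` set, only direction-consistent responses count
    (e.g. canonical: down under miR or up under anti-miR); otherwise any
    change in either arm qualifies.
    """
    if orientation is None:
        out: Set[str] = set()
        for arm in MODULATIONS:
            out |= _arm_direction_set(calls, cell_type, arm, "up")
            out |= _arm_direction_set(calls, cell_type, arm, "down")
        return out
    if orientation not in ORIENTATIONS:
        raise ValidationError(f"unknown orientation {orientation!r}")
    return _arm_direction_set(
        calls, cell_type, "miR", EXPECTED_DIRECTION[(orientation, "miR")]
    ) | _arm_direction_set(
        calls, cell_type, "anti_miR",
        EXPECTED_DIRECTION[(orientation, "anti_miR")],
    )


def multi_celltype_set(
    per_cell_sets: Mapping[str, Set[str]], min_cells: int
) -> Set[str]:
    """Genes present in at least ``min_cells`` of the per-cell gene sets."""
    if min_cells < 1:
        raise ValidationError("min_cells must be >= 1")
    if min_cells > len(per_cell_sets):
        raise ValidationError(
            f"min_cells={min_cells} exceeds number of cell types "
            f"({len(per_cell_sets)})"
        )
    counts: Dict[str, int] = {}
    for genes in per_cell_sets.values():
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    return {g for g, c in counts.items() if c >= min_cells}
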