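"""End-to-end orchestration on synthetic data.

:func:`run_synthetic_pipeline` chains the whole analysis -- simulate,
scan, call differential expression, evaluate prediction-response
concordance, attribute modulated genes, test the TF-regulon secondary
layer, and recover reporter-assay effects -- and returns a single
JSON-serialisable summary.  Identical configuration and seed give an
identical summary.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import io as mio
from .attribution import (
    attribute_genes,
    explained_fraction,
    tf_secondary_consistency,
)
from .concordance import (
    mean_over_parameters,
    orientation_correlation,
    pct_fraction_below,
    stratified_evaluation,
    summaries_to_frame,
)
from .errors import ValidationError
from .expression import (
    bidirectional_set,
    call_modulation,
    either_arm_set,
    filter_background,
    multi_celltype_set,
    normalize,
)
from .reporter import analyze_measurements
from .simulate import (
    SimulationConfig,
    generate_expression,
    generate_reporter_data,
    generate_truth,
    generate_utrs,
    regulon_annotation,
)
from .sites import MatureMiRNA, scan_to_predictions

logger = logging.getLogger(__name__)

REGULON_TERM = "TF_REGULON"

#: Planted reporter effects exercised by the demo pipeline: strong,
#: moderate and weak repression, a null construct, and an elevation of the
#: magnitude seen for TF-type non-canonical responses.
DEFAULT_REPORTER_EFFECTS: Dict[str, float] = {
    "MRE_strong": -60.0,
    "MRE_moderate": -20.0,
    "MRE_weak": -10.0,
    "MRE_null": 0.0,
    "TF_3UTR": 52.0,
}


def bundled_mirna(mirna_id: str = "hsa-miR-181b-5p") -> MatureMiRNA:
    """One of the packaged public mature miRNA sequences."""
    path = resources.files("mirfate.data").joinpath("mature_mirnas.fasta")
    with resources.as_file(path) as p:
        for mir in mio.read_mirnas(p):
            if mir.id == mirna_id:
                return mir
    raise ValidationError(f"no bundled miRNA named {mirna_id!r}")


def run_synthetic_pipeline(
    config: SimulationConfig,
    *,
    fc_threshold: float = 1.5,
    p_threshold: float = 0.05,
    mode: str = "fc_only",
    pct_cutoff: float = 0.1,
    tf_alpha: float = 1e-4,
    utr_length: int = 80,
    scan_utrs: bool = True,
    reporter_effects: Optional[Mapping[str, float]] = None,
    outdir: Optional[Path] = None,
) -> Dict:
    """Run the full analysis chain on one simulated study.

    Returns a nested summary dict; when ``outdir`` is given, all
    intermediate artifacts (FASTA, TSV tables, JSON summary) are written
    there as well.
    """
    config.validate()
    mir = bundled_mirna()
    truth = generate_truth(config)
    predictions = truth.prediction_table(mir.id)

    summary: Dict = {
        "seed": config.rng_seed,
        "config": config.to_dict(),
        "thresholds": {
            "fc_threshold": fc_threshold, "p_threshold": p_threshold,
            "mode": mode, "pct_cutoff": pct_cutoff, "tf_alpha": tf_alpha,
        },
    }

    utrs = None
    if scan_utrs:
        utrs = generate_utrs(truth, mir, utr_length=utr_length)
        scanned = scan_to_predictions(utrs, [mir])
        planted = set(predictions["gene"])
        found = set(scanned["gene"])
        summary["scanner"] = {
            "genes_with_sites": len(found),
            "planted_targets": len(planted),
            "agreement": bool(found == planted),
        }

    experiments = generate_expression(truth)
    all_calls = []
    retained_by_cell: Dict[str, list] = {}
    for ct, exp in experiments.items():
        retained = filter_background(exp)
        retained_by_cell[ct] = list(retained)
        norm = normalize(exp)
        calls = call_modulation(
            norm, genes=retained, fc_threshold=fc_threshold,
            p_threshold=p_threshold, mode=mode,
        )
        all_calls.append(calls)
    calls = pd.concat(all_calls, ignore_index=True)

    cells = list(experiments)
    summaries = stratified_evaluation(calls, predictions, cell_types=cells)
    frame = summaries_to_frame(summaries)
    canonical = frame[frame["orientation"] == "canonical"]
    mean_acc = mean_over_parameters(canonical, "accuracy", ("modulation",))
    summary["concordance"] = {
        "n_strata": len(frame),
        "mean_accuracy_pct": {
            m: float(v) * 100.0 for m, v in mean_acc.items()
        },
        "rows": frame.to_dict(orient="records"),
    }

    # canonical vs non-canonical parallelism: statistics averaged across
    # cell types per (modulation, parameter), then paired by orientation
    correlations = {}
    for stat in ("accuracy", "fpr", "fnr"):
        pair = frame.groupby(
            ["modulation", "prediction_parameter", "orientation"]
        )[stat].mean().unstack("orientation").dropna()
        if len(pair) >= 3:
            r2, p = orientation_correlation(
                pair["canonical"].to_numpy(), pair["noncanonical"].to_numpy()
            )
            correlations[stat] = {"r2": r2, "p": p, "n_strata": len(pair)}
    summary["orientation_correlation"] = correlations

    # conservation of modulated predicted targets
    modulated_union = set()
    for ct in cells:
        modulated_union |= either_arm_set(calls, ct, orientation="canonical")
    mod_predicted = predictions[predictions["gene"].isin(modulated_union)]
    if len(mod_predicted):
        summary["pct_below_cutoff_fraction"] = pct_fraction_below(
            mod_predicted["pct"].to_numpy(float), cutoff=pct_cutoff
        )

    # per-cell bidirectional gene counts and the stringent multi-cell set
    bidir_sets = {
        ct: bidirectional_set(calls, ct, "canonical") for ct in cells
    }
    summary["bidirectional_counts"] = {
        ct: len(s) for ct, s in bidir_sets.items()
    }
    min_cells = min(2, len(cells))
    stringent = multi_celltype_set(bidir_sets, min_cells=min_cells)
    regulon = set(truth.genes.index[truth.genes["in_tf_regulon"]])

    if stringent:
        table, fractions = attribute_genes(
            stringent, predictions, alt_predictions=(),
            tf_regulon=regulon, pct_cutoff=pct_cutoff,
        )
        summary["attribution"] = {
            "set_size": len(stringent),
            "stringency": f"bidirectional in >= {min_cells} cell types",
            "fractions": fractions,
            "explained_fraction": explained_fraction(fractions),
        }

    # secondary regulation through the TF regulon
    if regulon:
        either_sets = {
            ct: either_arm_set(calls, ct, orientation="canonical")
            for ct in cells
        }
        modulated_multi = multi_celltype_set(either_sets, min_cells=min_cells)
        predicted_genes = set(predictions["gene"])
        universe = set().union(*(set(v) for v in retained_by_cell.values()))
        no_mre = (modulated_multi - predicted_genes) & universe
        if no_mre:
            annotation = regulon_annotation(truth, regulon_term=REGULON_TERM)
            report = tf_secondary_consistency(
                no_mre, universe, annotation, REGULON_TERM, alpha=tf_alpha
            )
            summary["tf_secondary"] = {
                "set_size": len(no_mre),
                "p_value": report.p_value,
                "rank": report.rank,
                "motif_fraction": report.motif_fraction,
                "significant": report.significant,
            }

    effects = dict(reporter_effects
                   if reporter_effects is not None else DEFAULT_REPORTER_EFFECTS)
    measurements = generate_reporter_data(effects, rng_seed=config.rng_seed)
    reporter_results = analyze_measurements(measurements)
    summary["reporter"] = {
        row["construct"]: {
            "planted_percent": effects[row["construct"]],
            "recovered_percent": row["percent_change"],
            "p_value": None if np.isnan(row["p_value"]) else row["p_value"],
            "validated": bool(row["validated"]),
        }
        for _, row in reporter_results.iterrows()
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        mio.write_truth(truth, outdir / "truth.tsv")
        mio.write_predictions(predictions, outdir / "predictions.tsv")
        if utrs is not None:
            mio.write_fasta(utrs, outdir / "utrs.fasta")
        for ct, exp in experiments.items():
            mio.write_expression(
                exp, outdir / f"expression_{ct}.tsv",
                outdir / f"samples_{ct}.tsv",
            )
        mio.write_calls(calls, outdir / "calls.tsv")
        frame.to_csv(outdir / "concordance.tsv", sep="\t",
                     na_rep="NA", index=False)
        mio.write_json_summary(summary, outdir / "summary.json")
    return summary
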