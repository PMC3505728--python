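"""Dual-luciferase reporter statistics and the MRE validation filter.

A candidate miRNA recognition element is cloned downstream of a firefly
luciferase gene; a renilla luciferase co-transfection controls for
transfection efficiency.  Each construct is assayed under the miRNA
(``treatment``) and under a mutant/scrambled oligo (``control``) in four
independent experiments of three wells each.  Per well the readout is the
firefly/renilla ratio; per experiment the mean treatment ratio is
normalised against the mean control ratio; the construct's response is the
grand mean of the four experiment-level normalised ratios, expressed as a
signed percent change, tested against no change with a one-tailed paired
t-test across experiments (tail in the observed direction).

A bundled validation table of 14 miR-181b recognition elements across 11
genes (suffixes ``_1``/``_2`` mark distinct elements of one gene) ships as
package data for the summary filter: a record validates when it is
repressed (negative percent change) at p < 0.05.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Iterable, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SchemaError, ValidationError

_OLIGO_ALIASES = {"treatment": "treatment", "miR": "treatment",
                  "control": "control"}

_LABEL_RE = re.compile(r"^(?P<base>.+?)(?:_(?P<site>\d+))?$")


@dataclass(frozen=True)
class ReporterResult:
    construct: str
    percent_change: float
    p_value: Optional[float]   # one-tailed; None when variance is zero
    validated: bool            # p < 0.05


def _normalize_oligo(value: str) -> str:
    if value not in _OLIGO_ALIASES:
        raise ValidationError(
            f"unknown oligo {value!r}; expected treatment/miR or control"
        )
    return _OLIGO_ALIASES[value]


def reporter_response(
    measurements: pd.DataFrame, construct: Optional[str] = None
) -> ReporterResult:
    """Normalised response of one construct from its raw well readings.

    ``measurements`` needs columns construct, oligo, experiment, replicate,
    firefly, renilla, with complete matching experiment blocks for both
    oligos.  Missing wells and non-positive renilla readings raise with a
    message naming the gap.
    """
    required = {"construct", "oligo", "experiment", "replicate",
                "firefly", "renilla"}
    missing = required - set(measurements.columns)
    if missing:
        raise SchemaError(
            f"measurement table missing column(s): {sorted(missing)}"
        )
    df = measurements.copy()
    if construct is not None:
        df = df[df["construct"] == construct]
    names = df["construct"].unique()
    if len(names) != 1:
        raise ValidationError(
            f"expected exactly one construct, got {sorted(map(str, names))}"
        )
    name = str(names[0])
    if (df["renilla"] <= 0).any():
        bad = df.loc[df["renilla"] <= 0]
        raise ValidationError(
            f"construct {name!r}: non-positive renilla reading in "
            f"experiment {bad['experiment'].iloc[0]}"
        )
    df = df.assign(oligo=df["oligo"].map(_normalize_oligo),
                   ratio=df["firefly"] / df["renilla"])
    by_exp: Dict[int, Dict[str, float]] = {}
    for (oligo, exp), grp in df.groupby(["oligo", "experiment"]):
        by_exp.setdefault(int(exp), {})[str(oligo)] = float(grp["ratio"].mean())
    experiments = sorted(by_exp)
    for exp in experiments:
        for oligo in ("treatment", "control"):
            if oligo not in by_exp[exp]:
                raise ValidationError(
                    f"construct {name!r}: missing {oligo} wells in "
                    f"experiment {exp}"
                )
    counts = df.groupby(["oligo", "experiment"]).size()
    if counts.nunique() > 1:
        raise ValidationError(
            f"construct {name!r}: unbalanced replicate counts across "
            f"(oligo, experiment) blocks: {sorted(set(counts))}"
        )
    normalised = np.array(
        [by_exp[e]["treatment"] / by_exp[e]["control"] for e in experiments]
    )
    percent = float((normalised.mean() - 1.0) * 100.0)
    if np.allclose(normalised.var(ddof=0), 0.0) or len(normalised) < 2:
        return ReporterResult(name, percent, None, False)
    res = stats.ttest_1samp(normalised, 1.0)
    p_one = float(res.pvalue) / 2.0   # tail in the observed direction
    return ReporterResult(name, percent, p_one, p_one < 0.05)


def analyze_measurements(measurements: pd.DataFrame) -> pd.DataFrame:
    """One :class:`ReporterResult` row per construct, in input order."""
    rows = []
    for construct in dict.fromkeys(measurements["construct"]):
        r = reporter_response(measurements, construct=construct)
        rows.append(
            {"construct": r.construct, "percent_change": r.percent_change,
             "p_value": np.nan if r.p_value is None else r.p_value,
             "validated": r.validated}
        )
    return pd.DataFrame(rows)


def parse_signed_percent(value) -> float:
    """Parse values like ``-10.38%`` (unicode minus tolerated)."""
    if isinstance(value, (int, float)):
        return float(value)
    text = str(value).strip().replace("−", "-").rstrip("%")
    try:
        return float(text)
    except ValueError as exc:
        raise ValidationError(f"cannot parse percent value {value!r}") from exc


def parse_p_value(value) -> float:
    """Parse p-values, treating a censored ``<x`` as its bound ``x``."""
    if isinstance(value, (int, float)):
        return float(value)
    text = str(value).strip()
    if text.startswith("<"):
        text = text[1:]
    try:
        return float(text)
    except ValueError as exc:
        raise ValidationError(f"cannot parse p-value {value!r}") from exc


def strip_site_suffix(label: str) -> str:
    """Gene symbol with a trailing ``_<n>`` site index removed."""
    if not isinstance(label, str) or not label.strip():
        raise ValidationError(f"malformed gene label {label!r}")
    return _LABEL_RE.match(label.strip()).group("base")


def summarize_validation(table: pd.DataFrame) -> Tuple[int, int]:
    """(validated records, distinct genes) from a reporter results table.

    A record validates when its percent change is negative (repression) at
    p < 0.05.  Accepts columns ``gene``/``construct``, ``percent_change``/
    ``fold_change`` (signed percent) and ``p_value``.
    """
    cols = set(table.columns)
    label_col = "gene" if "gene" in cols else "construct"
    change_col = "percent_change" if "percent_change" in cols else "fold_change"
    if label_col not in cols or change_col not in cols or "p_value" not in cols:
        raise SchemaError(
            "validation table needs gene/construct, percent_change/"
            f"fold_change and p_value columns; got {sorted(cols)}"
        )
    n_records = 0
    genes = set()
    for _, row in table.iterrows():
        change = parse_signed_percent(row[change_col])
        p = parse_p_value(row["p_value"])
        if p < 0.05 and change < 0:
            n_records += 1
            genes.add(strip_site_suffix(row[label_col]))
    return n_records, len(genes)


def load_mre_validation_table() -> pd.DataFrame:
    """The bundled miR-181b MRE dual-luciferase validation table.

    Columns: gene (with ``_n`` site suffixes), fold_change (signed
    percent), p_value (possibly censored as ``<x``) and the assayed MRE
    sequence.
    """
    with resources.files("mirfate.data").joinpath(
        "mir181b_mre_validation.tsv"
    ).open("r") as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)
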