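"""Readers and writers for the package's interchange formats.

Everything rectangular travels as TSV with a header row, tab separation,
``NA`` for missing values, UTF-8 and no quoting; sequences travel as FASTA
(wrapped or unwrapped accepted on read, unwrapped on write); gene-set
annotations as GMT.  Every writer's output round-trips through its reader.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Union

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import SchemaError, ValidationError
from .expression import ExpressionExperiment
from .simulate import GroundTruth, SimulationConfig
from .sites import MatureMiRNA

PathLike = Union[str, Path]

_TSV_KW = dict(sep="\t", na_rep="NA", index=False)


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}")


# -- FASTA ------------------------------------------------------------------

def read_fasta(path: PathLike) -> Dict[str, str]:
    out: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValidationError(f"duplicate FASTA id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(sequences: Mapping[str, str], path: PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        # unwrapped lines for bit-exact round trips
        for rec in records:
            fh.write(f">{rec.id}\n{rec.seq}\n")


def read_mirnas(path: PathLike) -> List[MatureMiRNA]:
    return [MatureMiRNA(name, seq) for name, seq in read_fasta(path).items()]


# -- expression matrices ----------------------------------------------------

def write_expression(
    experiment: ExpressionExperiment, matrix_path: PathLike, meta_path: PathLike
) -> None:
    mat = experiment.matrix.copy()
    mat.insert(0, "gene", mat.index)
    mat.to_csv(matrix_path, **_TSV_KW)
    meta = experiment.samples.reset_index()
    meta.to_csv(meta_path, **_TSV_KW)


def read_expression(
    matrix_path: PathLike,
    meta_path: PathLike,
    background_threshold: float,
) -> ExpressionExperiment:
    mat = pd.read_csv(matrix_path, sep="\t")
    _require_columns(mat, ["gene"], f"expression matrix {matrix_path}")
    mat = mat.set_index("gene")
    meta = pd.read_csv(meta_path, sep="\t")
    _require_columns(
        meta, ["sample_id", "cell_type", "condition", "replicate"],
        f"sample metadata {meta_path}",
    )
    meta = meta.set_index("sample_id")
    return ExpressionExperiment(mat, meta, background_threshold)


# -- prediction tables ------------------------------------------------------

_PREDICTION_COLUMNS = ["gene", "mirna", "site_type", "conserved", "pct"]


def write_predictions(predictions: pd.DataFrame, path: PathLike) -> None:
    _require_columns(predictions, _PREDICTION_COLUMNS, "prediction table")
    predictions[_PREDICTION_COLUMNS].to_csv(path, **_TSV_KW)


def read_predictions(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, _PREDICTION_COLUMNS, f"prediction table {path}")
    return df


# -- modulation calls -------------------------------------------------------

_CALL_COLUMNS = ["gene", "cell_type", "modulation", "direction",
                 "fold_change", "p_value"]


def write_calls(calls: pd.DataFrame, path: PathLike) -> None:
    _require_columns(calls, _CALL_COLUMNS, "modulation calls")
    calls[_CALL_COLUMNS].to_csv(path, **_TSV_KW)


def read_calls(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, _CALL_COLUMNS, f"modulation calls {path}")
    return df


# -- ground truth -----------------------------------------------------------

def write_truth(truth: GroundTruth, path: PathLike) -> None:
    df = truth.genes.copy()
    df.insert(0, "gene", df.index)
    df.to_csv(path, **_TSV_KW)


# -- gene lists and GMT -----------------------------------------------------

def read_gene_list(path: PathLike, column: str = "gene") -> List[str]:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, [column], f"gene list {path}")
    return list(df[column].astype(str))


def write_gene_list(genes: Iterable[str], path: PathLike,
                    column: str = "gene") -> None:
    pd.DataFrame({column: sorted(set(map(str, genes)))}).to_csv(path, **_TSV_KW)


def read_gmt(path: PathLike) -> Dict[str, Set[str]]:
    annotation: Dict[str, Set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise SchemaError(
                    f"{path}:{lineno}: GMT lines need term, description and "
                    f"at least one gene"
                )
            term = parts[0]
            if term in annotation:
                raise ValidationError(f"duplicate GMT term {term!r}")
            annotation[term] = {g for g in parts[2:] if g}
    return annotation


def write_gmt(annotation: Mapping[str, Set[str]], path: PathLike,
              descriptions: Optional[Mapping[str, str]] = None) -> None:
    with open(path, "w") as fh:
        for term in annotation:
            desc = (descriptions or {}).get(term, "NA")
            genes = "\t".join(sorted(annotation[term]))
            fh.write(f"{term}\t{desc}\t{genes}\n")


# -- configuration and summaries --------------------------------------------

def read_simulation_config(path: PathLike) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: configuration must be a mapping")
    return SimulationConfig.from_dict(data)


def write_simulation_config(config: SimulationConfig, path: PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_json_summary(summary: Mapping, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(dict(summary)), fh, indent=2, sort_keys=True)
        fh.write("\n")
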