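"""Ground-truthed simulation of a bidirectional miRNA transfection study.

The generator emulates the structure of a multi-cell-line transfection
experiment: for each cell type, control, miRNA over-expression (``miR``)
and antisense inhibition (``anti_miR``) conditions with replicated
array-style intensity measurements.  A configurable fraction of genes
carries a planted seed-match site of a known class, with known
conservation status and PCT score; planted responders change expression
canonically (down with the miR, up with the anti-miR), non-canonically
(the reverse), or not at all.  One planted target gene acts as a
transcription factor whose regulon -- genes with no seed site of their own
-- responds secondarily, mirroring how a miRNA can reach E2F1-regulated
genes through E2F1's own 3'-UTR.

Model choices
-------------
Intensities are log-normal: a per-gene baseline times a condition effect
times ``2**N(0, noise_sd_log2)`` replicate noise.  Effects are
multiplicative on the linear scale, matching fold-change thresholding on
array intensities.  The anti-miR arm is attenuated: a planted fold ``f``
appears as ``f ** anti_mir_attenuation`` under inhibition, reflecting that
inhibiting an endogenous miRNA perturbs it far less than flooding the cell
with a synthetic one.  Background (spurious, transfection-style) calls are
planted per arm on unresponsive *non-target* genes: each is independently
pushed down with probability ``background_de_rate``, up with the same
probability, using effect folds from the same range as real responders.
Genes below background are drawn near the intensity floor per cell type
and receive no effects.

:func:`expected_confusion` is the analytic oracle for the downstream
confusion-matrix pipeline: it converts the planted per-gene effects plus
the noise model into exact per-gene call probabilities (normal tail
probabilities of the log2 ratio of replicate means) and aggregates them
into expected tallies, rates, and their Monte-Carlo standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .concordance import ConfusionSummary, Stratum, PREDICTION_PARAMETERS
from .errors import ConfigError, ValidationError
from .expression import CONDITIONS, ExpressionExperiment
from .sites import MatureMiRNA, SITE_CLASSES, scan_seed_sites, seed_site_strings

RESPONSE_MODES = ("canonical", "noncanonical", "unresponsive")
_DEFAULT_CELL_NAMES = ("HEK293", "HeLa", "SHSY5Y")

#: log2 range (relative to the background level) of expressed baselines.
_BASELINE_LOG2_RANGE = (3.0, 8.0)


def _cell_names(n: int) -> Tuple[str, ...]:
    names = list(_DEFAULT_CELL_NAMES[:n])
    names += [f"cell{i + 1}" for i in range(len(names), n)]
    return tuple(names)


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study design.

    Proportions are fractions of the relevant pool; ``effect_fold_range``
    bounds the linear fold change planted on responders under
    over-expression.  The anti-miR arm sees ``fold ** anti_mir_attenuation``.
    """

    n_genes: int = 2000
    n_cell_types: int = 3
    replicates_per_condition: int = 2
    frac_predicted_targets: float = 0.2
    frac_conserved_among_predicted: float = 0.25
    frac_canonical_responders: float = 0.4
    frac_noncanonical_responders: float = 0.1
    background_de_rate: float = 0.05
    effect_fold_range: Tuple[float, float] = (2.5, 4.0)
    noise_sd_log2: float = 0.15
    background_expression_level: float = 100.0
    frac_below_background_per_cell: float = 0.1
    tf_regulon_size: int = 150
    tf_effect_orientation: str = "canonical"
    anti_mir_attenuation: float = 0.5
    rng_seed: int = 0

    def validate(self) -> None:
        proportions = (
            "frac_predicted_targets", "frac_conserved_among_predicted",
            "frac_canonical_responders", "frac_noncanonical_responders",
            "frac_below_background_per_cell",
        )
        for name in proportions:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(name, f"must be in [0, 1], got {v}")
        if self.frac_canonical_responders + self.frac_noncanonical_responders > 1:
            raise ConfigError(
                "frac_canonical_responders",
                "responder fractions must sum to at most 1",
            )
        if not 0.0 <= self.background_de_rate <= 0.5:
            raise ConfigError(
                "background_de_rate",
                "must be in [0, 0.5] (planted per direction)",
            )
        if self.n_genes < 1:
            raise ConfigError("n_genes", "must be positive")
        if self.n_cell_types < 1:
            raise ConfigError("n_cell_types", "must be positive")
        if self.replicates_per_condition < 2:
            raise ConfigError("replicates_per_condition", "must be >= 2")
        lo, hi = self.effect_fold_range
        if lo < 1.0 or hi < lo:
            raise ConfigError(
                "effect_fold_range", f"need 1 <= lo <= hi, got ({lo}, {hi})"
            )
        if self.noise_sd_log2 < 0:
            raise ConfigError("noise_sd_log2", "must be non-negative")
        if self.background_expression_level <= 0:
            raise ConfigError("background_expression_level", "must be positive")
        if self.tf_regulon_size < 0:
            raise ConfigError("tf_regulon_size", "must be non-negative")
        if self.tf_effect_orientation not in ("canonical", "noncanonical"):
            raise ConfigError(
                "tf_effect_orientation", "must be canonical or noncanonical"
            )
        if not 0.0 < self.anti_mir_attenuation <= 1.0:
            raise ConfigError("anti_mir_attenuation", "must be in (0, 1]")
        n_pred = round(self.frac_predicted_targets * self.n_genes)
        if self.tf_regulon_size > 0 and n_pred == 0:
            raise ConfigError(
                "tf_regulon_size",
                "a TF regulon requires at least one predicted target "
                "(the TF gene is itself a target)",
            )
        if self.tf_regulon_size > self.n_genes - n_pred:
            raise ConfigError(
                "tf_regulon_size",
                "regulon cannot exceed the number of non-target genes",
            )

    @property
    def cell_types(self) -> Tuple[str, ...]:
        return _cell_names(self.n_cell_types)

    def to_dict(self) -> Dict:
        d = asdict(self)
        d["effect_fold_range"] = list(self.effect_fold_range)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigError(sorted(unknown)[0], "unknown configuration field")
        kwargs = dict(d)
        if "effect_fold_range" in kwargs:
            kwargs["effect_fold_range"] = tuple(kwargs["effect_fold_range"])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


@dataclass
class GroundTruth:
    """Planted per-gene labels; the oracle for every downstream stage.

    ``genes`` is indexed by gene id with columns: ``is_predicted_target``,
    ``site_class`` ('none' for non-targets), ``conserved``, ``pct`` (NaN for
    non-targets), ``response_mode``, ``in_tf_regulon``, ``is_tf_gene``,
    ``true_effect_fold`` and one boolean ``expressed_<cell>`` per cell type.
    """

    genes: pd.DataFrame
    cell_types: Tuple[str, ...]
    config: SimulationConfig
    _cache: Dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def tf_gene(self) -> Optional[str]:
        hits = self.genes.index[self.genes["is_tf_gene"]]
        return None if len(hits) == 0 else str(hits[0])

    def expressed_genes(self, cell_type: str) -> pd.Index:
        col = f"expressed_{cell_type}"
        if col not in self.genes.columns:
            raise ValidationError(f"unknown cell type {cell_type!r}")
        return self.genes.index[self.genes[col]]

    def predicted_mask(self, parameter: str) -> pd.Series:
        """Boolean mask of genes predicted under a prediction parameter."""
        g = self.genes
        if parameter == "all":
            return g["is_predicted_target"]
        if parameter == "conserved":
            return g["is_predicted_target"] & g["conserved"]
        if parameter == "nonconserved":
            return g["is_predicted_target"] & ~g["conserved"]
        if parameter in SITE_CLASSES:
            return g["site_class"] == parameter
        raise ValidationError(f"unknown prediction parameter {parameter!r}")

    def prediction_table(self, mirna_id: str = "hsa-miR-181b-5p") -> pd.DataFrame:
        """TargetScan-style table of the planted predictions."""
        pred = self.genes[self.genes["is_predicted_target"]]
        return pd.DataFrame(
            {
                "gene": pred.index,
                "mirna": mirna_id,
                "site_type": pred["site_class"].to_numpy(),
                "conserved": pred["conserved"].astype(int).to_numpy(),
                "pct": pred["pct"].to_numpy(),
            }
        ).reset_index(drop=True)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams per generation stage
    return np.random.default_rng([config.rng_seed % (2**31), stream])


def generate_truth(config: SimulationConfig) -> GroundTruth:
    """Draw the planted study design implied by ``config``.

    Category counts match the configured proportions to within rounding and
    the result is bit-identical for a fixed ``rng_seed``.
    """
    config.validate()
    rng = _rng(config, 0)
    n = config.n_genes
    genes = pd.Index([f"G{i:05d}" for i in range(n)], name="gene")

    is_pred = np.zeros(n, dtype=bool)
    n_pred = round(config.frac_predicted_targets * n)
    pred_idx = rng.choice(n, size=n_pred, replace=False)
    is_pred[pred_idx] = True

    site_class = np.array(["none"] * n, dtype=object)
    shuffled = rng.permutation(pred_idx)
    for j, gi in enumerate(shuffled):
        site_class[gi] = SITE_CLASSES[j % len(SITE_CLASSES)]

    conserved = np.zeros(n, dtype=bool)
    n_cons = round(config.frac_conserved_among_predicted * n_pred)
    conserved[rng.permutation(pred_idx)[:n_cons]] = True

    # PCT: conserved sites score high; non-conserved sites mostly < 0.1,
    # emulating the strong skew of poorly conserved sites among targets.
    pct = np.full(n, np.nan)
    for gi in pred_idx:
        if conserved[gi]:
            pct[gi] = rng.uniform(0.3, 1.0)
        elif rng.random() < 0.9:
            pct[gi] = rng.uniform(0.0, 0.1)
        else:
            pct[gi] = rng.uniform(0.1, 1.0)

    response = np.array(["unresponsive"] * n, dtype=object)
    n_can = round(config.frac_canonical_responders * n_pred)
    n_non = round(config.frac_noncanonical_responders * n_pred)
    n_non = min(n_non, n_pred - n_can)
    resp_order = rng.permutation(pred_idx)
    response[resp_order[:n_can]] = "canonical"
    response[resp_order[n_can : n_can + n_non]] = "noncanonical"

    in_regulon = np.zeros(n, dtype=bool)
    is_tf = np.zeros(n, dtype=bool)
    if config.tf_regulon_size > 0:
        non_pred = np.flatnonzero(~is_pred)
        regulon = rng.choice(
            non_pred, size=config.tf_regulon_size, replace=False
        )
        in_regulon[regulon] = True
        response[regulon] = config.tf_effect_orientation
        # the TF is itself a planted target; prefer a responding one so the
        # secondary layer has a primary cause
        for pool_mode in ("canonical", "noncanonical", "unresponsive"):
            pool = [gi for gi in pred_idx if response[gi] == pool_mode]
            if pool:
                is_tf[pool[int(rng.integers(len(pool)))]] = True
                break

    lo, hi = config.effect_fold_range
    fold = np.ones(n)
    responders = response != "unresponsive"
    fold[responders] = rng.uniform(lo, hi, size=int(responders.sum()))

    df = pd.DataFrame(
        {
            "is_predicted_target": is_pred,
            "site_class": site_class,
            "conserved": conserved,
            "pct": pct,
            "response_mode": response,
            "in_tf_regulon": in_regulon,
            "is_tf_gene": is_tf,
            "true_effect_fold": fold,
        },
        index=genes,
    )
    n_below = round(config.frac_below_background_per_cell * n)
    tf_idx = np.flatnonzero(is_tf)
    level = config.background_expression_level
    for ct in config.cell_types:
        expressed = np.ones(n, dtype=bool)
        # the TF gene stays expressed everywhere so its regulon's secondary
        # response always has its cause on the array
        candidates = np.setdiff1d(np.arange(n), tf_idx)
        below = rng.choice(candidates, size=min(n_below, len(candidates)),
                           replace=False)
        expressed[below] = False
        df[f"expressed_{ct}"] = expressed
        # per-gene control-condition intensity: log-uniform over ~1.5
        # orders of magnitude for expressed genes, near the floor otherwise
        df[f"baseline_{ct}"] = np.where(
            expressed,
            level * 2.0 ** rng.uniform(*_BASELINE_LOG2_RANGE, size=n),
            level * rng.uniform(0.2, 0.6, size=n),
        )
    return GroundTruth(genes=df, cell_types=config.cell_types, config=config)


def generate_utrs(
    truth: GroundTruth, mir: MatureMiRNA, utr_length: int = 80
) -> Dict[str, str]:
    """Synthetic 3'-UTRs with exactly the planted site content.

    Every predicted target carries at least one site of its assigned class
    and no site of any other class; non-target UTRs carry no site at all.
    Sequences are rejection-sampled until the scanner confirms the label,
    so truth labels are exact by construction.
    """
    if utr_length < 30:
        raise ValidationError(
            f"utr_length must be >= 30 to host a site, got {utr_length}"
        )
    rng = _rng(truth.config, 1)
    patterns = seed_site_strings(mir)
    bases = np.array(list("ACGT"))
    utrs: Dict[str, str] = {}
    for gene, row in truth.genes.iterrows():
        target_class = row["site_class"] if row["is_predicted_target"] else None
        while True:
            seq = "".join(rng.choice(bases, size=utr_length))
            if target_class is not None:
                site = patterns[target_class]
                pos = int(rng.integers(0, utr_length - len(site) + 1))
                seq = seq[:pos] + site + seq[pos + len(site):]
            found = {s.site_class for s in scan_seed_sites(seq, mir, gene=gene)}
            wanted = {target_class} if target_class else set()
            if found == wanted:
                utrs[str(gene)] = seq
                break
    return utrs


def _effect_matrix(
    truth: GroundTruth, rng: np.random.Generator, expressed: np.ndarray
) -> Dict[str, np.ndarray]:
    """Linear condition-effect multipliers per gene for one cell type."""
    cfg = truth.config
    mode = truth.genes["response_mode"].to_numpy()
    fold = truth.genes["true_effect_fold"].to_numpy(float)
    a = cfg.anti_mir_attenuation
    eff = {c: np.ones(cfg.n_genes) for c in CONDITIONS}

    canonical = (mode == "canonical") & expressed
    noncanon = (mode == "noncanonical") & expressed
    eff["miR"][canonical] = 1.0 / fold[canonical]
    eff["anti_miR"][canonical] = fold[canonical] ** a
    eff["miR"][noncanon] = fold[noncanon]
    eff["anti_miR"][noncanon] = fold[noncanon] ** -a

    # spurious (transfection-style) background effects on unresponsive
    # non-target genes, planted independently per arm with random direction
    spur_pool = (
        (mode == "unresponsive")
        & ~truth.genes["is_predicted_target"].to_numpy()
        & expressed
    )
    lo, hi = cfg.effect_fold_range
    bg = cfg.background_de_rate
    for arm in ("miR", "anti_miR"):
        u = rng.random(cfg.n_genes)
        sf = rng.uniform(lo, hi, size=cfg.n_genes)
        down = spur_pool & (u < bg)
        up = spur_pool & (u >= bg) & (u < 2 * bg)
        eff[arm][down] = 1.0 / sf[down]
        eff[arm][up] = sf[up]
    return eff


def generate_expression(
    truth: GroundTruth, config: Optional[SimulationConfig] = None
) -> Dict[str, ExpressionExperiment]:
    """One intensity experiment per cell type implied by the ground truth."""
    cfg = config if config is not None else truth.config
    cfg.validate()
    rng = _rng(cfg, 2)
    level = cfg.background_expression_level
    out: Dict[str, ExpressionExperiment] = {}
    for ct in truth.cell_types:
        expressed = truth.genes[f"expressed_{ct}"].to_numpy()
        baseline = truth.genes[f"baseline_{ct}"].to_numpy(float)
        eff = _effect_matrix(truth, rng, expressed)
        cols, meta = {}, []
        for cond in CONDITIONS:
            for rep in range(1, cfg.replicates_per_condition + 1):
                sid = f"{ct}_{cond}_{rep}"
                noise = (
                    2.0 ** rng.normal(0.0, cfg.noise_sd_log2, cfg.n_genes)
                    if cfg.noise_sd_log2 > 0
                    else np.ones(cfg.n_genes)
                )
                cols[sid] = baseline * eff[cond] * noise
                meta.append(
                    {"sample_id": sid, "cell_type": ct,
                     "condition": cond, "replicate": rep}
                )
        matrix = pd.DataFrame(cols, index=truth.genes.index)
        samples = pd.DataFrame(meta).set_index("sample_id")
        out[ct] = ExpressionExperiment(matrix, samples, background_threshold=level)
    return out


def generate_reporter_data(
    planted_percent_changes: Mapping[str, float],
    *,
    rng_seed: int = 0,
    noise_sd_log2: float = 0.03,
    well_sd_log2: float = 0.02,
    between_experiment_sd_log2: float = 0.05,
    n_experiments: int = 4,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Dual-reporter luminescence readings for planted construct effects.

    For each construct and oligo (``treatment`` = the miRNA, ``control`` =
    a mutant/scrambled oligo) the table holds ``n_experiments`` independent
    experiments of ``n_replicates`` wells each, with firefly/renilla pairs.
    The planted signed percent change of the firefly/renilla ratio under
    treatment is recoverable by :func:`mirfate.reporter.reporter_response`.
    Between-experiment variation is shared by both oligos of an experiment
    (it cancels under paired normalisation); ``noise_sd_log2`` is the
    per-(oligo, experiment) noise that drives the t-test variance.
    """
    if not planted_percent_changes:
        raise ValidationError("at least one construct must be requested")
    rng = np.random.default_rng([rng_seed % (2**31), 7])
    rows = []
    for construct, delta in planted_percent_changes.items():
        effect = 1.0 + delta / 100.0
        if effect <= 0:
            raise ValidationError(
                f"construct {construct!r}: percent change {delta} implies a "
                "non-positive ratio"
            )
        for e in range(1, n_experiments + 1):
            base = 2.0 ** rng.normal(0.0, between_experiment_sd_log2)
            for oligo in ("treatment", "control"):
                mult = effect if oligo == "treatment" else 1.0
                block = base * mult * 2.0 ** rng.normal(0.0, noise_sd_log2)
                for rep in range(1, n_replicates + 1):
                    renilla = 1e5 * rng.uniform(0.5, 1.5)
                    firefly = (
                        renilla * block * 2.0 ** rng.normal(0.0, well_sd_log2)
                    )
                    rows.append(
                        {"construct": construct, "oligo": oligo,
                         "experiment": e, "replicate": rep,
                         "firefly": firefly, "renilla": renilla}
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# analytic oracle
# ---------------------------------------------------------------------------


def _deterministic_log2_effects(
    truth: GroundTruth, cell_type: str, arm: str
) -> Tuple[np.ndarray, np.ndarray]:
    """(expected log2 effect per expressed gene, spurious-pool mask)."""
    cfg = truth.config
    g = truth.genes.loc[truth.expressed_genes(cell_type)]
    mode = g["response_mode"].to_numpy()
    lf = np.log2(g["true_effect_fold"].to_numpy(float))
    a = cfg.anti_mir_attenuation
    if arm == "miR":
        d = np.where(mode == "canonical", -lf,
                     np.where(mode == "noncanonical", lf, 0.0))
    elif arm == "anti_miR":
        d = np.where(mode == "canonical", a * lf,
                     np.where(mode == "noncanonical", -a * lf, 0.0))
    else:
        raise ValidationError(f"unknown modulation arm {arm!r}")
    spur = (mode == "unresponsive") & ~g["is_predicted_target"].to_numpy()
    return d, spur


def _expressed_log2_baselines(truth: GroundTruth, cell_type: str) -> np.ndarray:
    cfg = truth.config
    expressed = truth.expressed_genes(cell_type)
    b = truth.genes.loc[expressed, f"baseline_{cell_type}"].to_numpy(float)
    return np.log2(b / cfg.background_expression_level)


def _sample_median_log2(
    x: np.ndarray,
    d: np.ndarray,
    spur: np.ndarray,
    spur_grid: np.ndarray,
    bg: float,
    sd: float,
) -> float:
    """Expected log2 median of one sample, conditional on baselines ``x``.

    Deterministic genes sit at ``x + d`` smeared by replicate noise;
    spurious-pool genes contribute their three-state mixture.  The median
    solves the smoothed empirical CDF = 1/2 by bisection.
    """

    def gene_cdf(m: float, offs: np.ndarray) -> np.ndarray:
        if sd == 0:
            return (offs <= m).astype(float)
        return sstats.norm.cdf((m - offs) / sd)

    det = x + d
    xs = x[spur]

    def cdf(m: float) -> float:
        total = float(gene_cdf(m, det[~spur]).sum())
        if xs.size:
            p_dn = gene_cdf(m, xs[:, None] - spur_grid[None, :]).mean(axis=1)
            p_up = gene_cdf(m, xs[:, None] + spur_grid[None, :]).mean(axis=1)
            p_0 = gene_cdf(m, xs)
            total += float(
                (bg * p_dn + bg * p_up + (1 - 2 * bg) * p_0).sum()
            )
        return total / len(x)

    lo_m = float(x.min() + min(d.min(), -spur_grid.max()) - 4 * sd - 1.0)
    hi_m = float(x.max() + max(d.max(), spur_grid.max()) + 4 * sd + 1.0)
    for _ in range(60):
        mid = 0.5 * (lo_m + hi_m)
        if cdf(mid) < 0.5:
            lo_m = mid
        else:
            hi_m = mid
    return 0.5 * (lo_m + hi_m)


def chip_median_shift(truth: GroundTruth, cell_type: str, arm: str) -> float:
    """Expected log2 shift of a treatment sample's median vs control.

    Per-chip normalisation rescales every sample to median 1.0 over
    retained genes, so any asymmetry in the planted effects (more genes
    falling than rising, say) moves the treatment median relative to the
    control median and thereby biases every normalised fold change
    coherently.  Conditioning on the planted baselines (part of the
    ground truth) removes the dominant quantile-sampling noise; what
    remains stochastic is the spurious-effect states, entered here as
    their per-gene mixture expectation, and the replicate noise, entered
    as a smoothing kernel.
    """
    key = ("chip_shift", cell_type, arm)
    if key in truth._cache:
        return truth._cache[key]
    cfg = truth.config
    x = _expressed_log2_baselines(truth, cell_type)
    d, spur = _deterministic_log2_effects(truth, cell_type, arm)
    lo, hi = cfg.effect_fold_range
    grid = np.log2(np.linspace(lo, hi, 65))
    sd = cfg.noise_sd_log2
    m_treat = _sample_median_log2(x, d, spur, grid, cfg.background_de_rate, sd)
    m_ctrl = _sample_median_log2(
        x, np.zeros_like(d), np.zeros_like(spur, dtype=bool), grid, 0.0, sd
    )
    shift = m_treat - m_ctrl
    truth._cache[key] = shift
    return shift


def _call_probabilities(
    mu: np.ndarray, sd: float, log2_threshold: float
) -> Tuple[np.ndarray, np.ndarray]:
    """P(called down), P(called up) for log2 ratios ~ N(mu, sd).

    With sd = 0 the call is deterministic; thresholds are inclusive, as in
    :func:`mirfate.expression.call_modulation`.
    """
    t = log2_threshold
    if sd == 0:
        return (mu <= -t).astype(float), (mu >= t).astype(float)
    p_down = sstats.norm.cdf((-t - mu) / sd)
    p_up = sstats.norm.sf((t - mu) / sd)
    return p_down, p_up


def _shift_variance(
    truth: GroundTruth, cell_type: str, arm: str, shift: float
) -> float:
    """Variance of the realised chip-median shift around its expectation.

    Conditional on the planted baselines (which are shared between the
    treatment and control samples of a cell type), the remaining
    randomness in the shift is the binomial fluctuation of the planted
    spurious-effect states.  Delta method on the smoothed empirical CDF
    at the treatment median.
    """
    cfg = truth.config
    sd = cfg.noise_sd_log2
    if sd == 0:
        # call probabilities are step functions with zero gradient, so the
        # coherent term is not propagated in the noiseless limit
        return 0.0
    x = _expressed_log2_baselines(truth, cell_type)
    d, spur = _deterministic_log2_effects(truth, cell_type, arm)
    n = len(x)
    if not spur.any():
        return 0.0
    m_ctrl = _sample_median_log2(
        x, np.zeros_like(d), np.zeros_like(spur, dtype=bool),
        np.array([0.0]), 0.0, sd,
    )
    m = m_ctrl + shift
    lo, hi = cfg.effect_fold_range
    grid = np.log2(np.linspace(lo, hi, 65))
    bg = cfg.background_de_rate

    xs = x[spur]
    p_dn = sstats.norm.cdf((m - xs[:, None] + grid[None, :]) / sd).mean(axis=1)
    p_up = sstats.norm.cdf((m - xs[:, None] - grid[None, :]) / sd).mean(axis=1)
    p_0 = sstats.norm.cdf((m - xs) / sd)
    p_bar = bg * p_dn + bg * p_up + (1 - 2 * bg) * p_0
    var_gene = (
        bg * p_dn**2 + bg * p_up**2 + (1 - 2 * bg) * p_0**2 - p_bar**2
    )
    var_cdf = float(var_gene.sum()) / n**2

    # smoothed density of the sample distribution at the median
    dens_det = sstats.norm.pdf((m - (x + d)[~spur]) / sd) / sd
    dens_dn = (sstats.norm.pdf((m - xs[:, None] + grid[None, :]) / sd) / sd
               ).mean(axis=1)
    dens_up = (sstats.norm.pdf((m - xs[:, None] - grid[None, :]) / sd) / sd
               ).mean(axis=1)
    dens_0 = sstats.norm.pdf((m - xs) / sd) / sd
    dens_spur = bg * dens_dn + bg * dens_up + (1 - 2 * bg) * dens_0
    density = (float(dens_det.sum()) + float(dens_spur.sum())) / n
    return var_cdf / max(density, 1e-9) ** 2


def _arm_response_model(
    truth: GroundTruth,
    cell_type: str,
    arm: str,
    orientation: str,
    fc_threshold: float,
) -> Tuple[np.ndarray, np.ndarray, float]:
    """(p_responsive, dp/dshift, Var(shift)) for one modulation arm.

    ``p`` uses the normal approximation for the log2 ratio of replicate
    means (exact at zero noise), with the planted effect corrected by the
    expected chip-median shift.  ``dp/dshift`` is the per-gene sensitivity
    to that shift, used to propagate its coherent fluctuation into the
    oracle's standard errors.  Results are memoised per ground truth.
    """
    key = ("arm_model", cell_type, arm, orientation, fc_threshold)
    if key in truth._cache:
        return truth._cache[key]
    cfg = truth.config
    r = cfg.replicates_per_condition
    sd = cfg.noise_sd_log2 * np.sqrt(2.0 / r)
    t = np.log2(fc_threshold)
    d, spur = _deterministic_log2_effects(truth, cell_type, arm)
    shift = chip_median_shift(truth, cell_type, arm)
    mu = d - shift
    expected_dir_down = (orientation == "canonical") == (arm == "miR")

    def prob_and_grad(mu_vals: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        p_down, p_up = _call_probabilities(mu_vals, sd, t)
        if sd == 0:
            grad = np.zeros_like(mu_vals)
        elif expected_dir_down:
            # p = Phi((-t - mu)/sd), mu = d - s  =>  dp/ds = +phi(.)/sd
            grad = sstats.norm.pdf((-t - mu_vals) / sd) / sd
        else:
            # p = 1 - Phi((t - mu)/sd)  =>  dp/ds = -phi(.)/sd
            grad = -sstats.norm.pdf((t - mu_vals) / sd) / sd
        return (p_down if expected_dir_down else p_up), grad

    p, grad = prob_and_grad(mu)
    if spur.any():
        lo, hi = cfg.effect_fold_range
        grid = np.log2(np.linspace(lo, hi, 257))
        bg = cfg.background_de_rate
        p_dn, g_dn = prob_and_grad(-grid - shift)
        p_up_, g_up = prob_and_grad(grid - shift)
        p_0, g_0 = prob_and_grad(np.array([-shift]))
        p_spur = bg * p_dn.mean() + bg * p_up_.mean() + (1 - 2 * bg) * p_0[0]
        g_spur = bg * g_dn.mean() + bg * g_up.mean() + (1 - 2 * bg) * g_0[0]
        p = np.where(spur, p_spur, p)
        grad = np.where(spur, g_spur, grad)
    result = (p, grad, _shift_variance(truth, cell_type, arm, shift))
    truth._cache[key] = result
    return result


def response_probabilities(
    truth: GroundTruth,
    cell_type: str,
    modulation: str,
    orientation: str,
    fc_threshold: float = 1.5,
) -> pd.Series:
    """Per-gene probability of being called responsive in a stratum.

    For the bidirectional model the two arms are conditionally independent
    given the planted effect, so per-gene probabilities multiply.
    """
    if orientation not in ("canonical", "noncanonical"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    expressed = truth.expressed_genes(cell_type)
    if len(expressed) == 0:
        raise ValidationError(f"no expressed genes in {cell_type!r}")
    if modulation == "bidirectional":
        p1, _, _ = _arm_response_model(
            truth, cell_type, "miR", orientation, fc_threshold
        )
        p2, _, _ = _arm_response_model(
            truth, cell_type, "anti_miR", orientation, fc_threshold
        )
        p = p1 * p2
    elif modulation in ("miR", "anti_miR"):
        p, _, _ = _arm_response_model(
            truth, cell_type, modulation, orientation, fc_threshold
        )
    else:
        raise ValidationError(f"unknown modulation {modulation!r}")
    return pd.Series(p, index=expressed, name="p_responsive")


@dataclass(frozen=True)
class ExpectedConfusion:
    """Analytic expectation of a :class:`ConfusionSummary` plus MC errors.

    ``se`` maps each statistic (``tp`` ... ``fnr``) to the standard error
    of a single simulated realisation around the expectation, from
    independent per-gene Bernoulli variances (delta method for the rates).
    """

    summary: ConfusionSummary
    se: Dict[str, float]


def expected_confusion(
    truth: GroundTruth,
    stratum: Stratum,
    fc_threshold: float = 1.5,
) -> ExpectedConfusion:
    """Expected confusion statistics implied by the planted parameters.

    Standard errors combine the independent per-gene Bernoulli variance
    with the coherent component propagated from the chip-median shift
    fluctuation (one independent shift per modulation arm), via the delta
    method for the derived rates.
    """
    if stratum.modulation == "bidirectional":
        p1, g1, sv1 = _arm_response_model(
            truth, stratum.cell_type, "miR", stratum.orientation, fc_threshold
        )
        p2, g2, sv2 = _arm_response_model(
            truth, stratum.cell_type, "anti_miR", stratum.orientation,
            fc_threshold,
        )
        pv = p1 * p2
        # dp/dshift_k per arm, with the other arm's probability fixed
        coherent = [(g1 * p2, sv1), (p1 * g2, sv2)]
    else:
        p, g, sv = _arm_response_model(
            truth, stratum.cell_type, stratum.modulation, stratum.orientation,
            fc_threshold,
        )
        pv = p
        coherent = [(g, sv)]

    expressed = truth.expressed_genes(stratum.cell_type)
    pred = truth.predicted_mask(stratum.prediction_parameter).loc[expressed]
    pm = pred.to_numpy(bool)
    var = pv * (1 - pv)

    tp = float(pv[pm].sum())
    fp = float((1 - pv)[pm].sum())
    fn = float(pv[~pm].sum())
    tn = float((1 - pv)[~pm].sum())
    n_total = len(expressed)
    summary = ConfusionSummary.from_counts(stratum, tp, tn, fp, fn)

    var_tp = float(var[pm].sum())
    var_fn = float(var[~pm].sum())
    var_acc = float(var.sum()) / n_total**2
    den_s, den_p = tp + fn, tn + fp
    var_sens = (
        ((fn / den_s**2) ** 2 * var_tp + (tp / den_s**2) ** 2 * var_fn)
        if den_s > 0 else None
    )
    var_spec = (
        ((fp / den_p**2) ** 2 * var_fn + (tn / den_p**2) ** 2 * var_tp)
        if den_p > 0 else None
    )
    for grad, svar in coherent:
        s_tp = float(grad[pm].sum())
        s_fn = float(grad[~pm].sum())
        var_tp += s_tp**2 * svar
        var_fn += s_fn**2 * svar
        var_acc += ((s_tp - s_fn) / n_total) ** 2 * svar
        if var_sens is not None:
            var_sens += ((fn * s_tp - tp * s_fn) / den_s**2) ** 2 * svar
        if var_spec is not None:
            # S_tn = -s_fn, S_fp = -s_tp
            var_spec += ((tn * s_tp - fp * s_fn) / den_p**2) ** 2 * svar

    se: Dict[str, float] = {
        "tp": float(np.sqrt(var_tp)), "fp": float(np.sqrt(var_tp)),
        "fn": float(np.sqrt(var_fn)), "tn": float(np.sqrt(var_fn)),
        "accuracy": float(np.sqrt(var_acc)),
    }
    if var_sens is not None:
        se["sensitivity"] = float(np.sqrt(var_sens))
        se["fnr"] = se["sensitivity"]
    if var_spec is not None:
        se["specificity"] = float(np.sqrt(var_spec))
        se["fpr"] = se["specificity"]
    return ExpectedConfusion(summary=summary, se=se)


def regulon_annotation(
    truth: GroundTruth,
    n_decoy_terms: int = 25,
    decoy_size: int = 30,
    regulon_term: str = "TF_REGULON",
) -> Dict[str, Set[str]]:
    """A GMT-style annotation: the planted regulon plus random decoy terms.

    Decoy terms are drawn from the whole gene universe and stand in for the
    bulk of a motif/pathway database; only the regulon term carries planted
    secondary signal.
    """
    rng = _rng(truth.config, 3)
    genes = truth.genes.index.to_numpy()
    annotation: Dict[str, Set[str]] = {
        regulon_term: set(truth.genes.index[truth.genes["in_tf_regulon"]])
    }
    for i in range(n_decoy_terms):
        size = min(decoy_size, len(genes))
        annotation[f"DECOY_{i:03d}"] = set(
            rng.choice(genes, size=size, replace=False)
        )
    return annotation
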