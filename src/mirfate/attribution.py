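"""Attribution of modulated genes and gene-set over-representation.

Each modulated gene is assigned to exactly one explanation category, the
first that matches in a fixed preferential order:

1. ``TS_conserved`` -- carries a conserved predicted seed site;
2. ``TS_nonconserved_pct_lt`` -- non-conserved site with PCT below the
   cutoff (0.1 by default);
3. ``TS_nonconserved_pct_ge`` -- non-conserved site with PCT at or above
   the cutoff (records without a PCT fall here);
4. ``alt_algorithm_only`` -- predicted only by an alternative algorithm;
5. ``tf_motif_only`` -- no seed site, but carries the transcription
   factor's recognition motif (the secondary-regulation layer);
6. ``unexplained``.

The over-representation test is the hypergeometric upper tail of the
overlap between a gene set and an annotation term within a universe,
the standard replacement for database-bound motif/pathway services; the
default significance threshold for TF-motif terms is p < 1e-4 and for
pathway-style terms p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

CATEGORIES = (
    "TS_conserved",
    "TS_nonconserved_pct_lt",
    "TS_nonconserved_pct_ge",
    "alt_algorithm_only",
    "tf_motif_only",
    "unexplained",
)

TF_MOTIF_ALPHA = 1e-4
PATHWAY_ALPHA = 0.05


def _ts_lookup(
    ts_predictions: pd.DataFrame,
) -> Tuple[Set[str], Dict[str, float]]:
    """(conserved genes, best PCT per non-conserved gene)."""
    required = {"gene", "conserved"}
    missing = required - set(ts_predictions.columns)
    if missing:
        raise ValidationError(
            f"prediction table missing column(s): {sorted(missing)}"
        )
    conserved: Set[str] = set()
    noncons_pct: Dict[str, float] = {}
    for _, row in ts_predictions.iterrows():
        gene = row["gene"]
        cons = row["conserved"]
        if not pd.isna(cons) and bool(int(cons)):
            conserved.add(gene)
        else:
            pct = row.get("pct", np.nan)
            pct = np.nan if pd.isna(pct) else float(pct)
            prev = noncons_pct.get(gene, np.nan)
            # keep the lowest (most non-conserved-looking) PCT per gene
            if np.isnan(prev) or (not np.isnan(pct) and pct < prev):
                noncons_pct[gene] = pct
    return conserved, noncons_pct


def attribute_genes(
    genes: Iterable[str],
    ts_predictions: pd.DataFrame,
    alt_predictions: Iterable[str] = (),
    tf_regulon: Iterable[str] = (),
    pct_cutoff: float = 0.1,
) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Assign every gene to its first matching category.

    Returns the per-gene table and the category fractions (which sum to 1
    over the input set).  Raises on an empty gene set.
    """
    gene_list = sorted(set(genes))
    if not gene_list:
        raise ValidationError("empty gene set")
    conserved, noncons_pct = _ts_lookup(ts_predictions)
    alt = set(alt_predictions)
    regulon = set(tf_regulon)

    records = []
    for gene in gene_list:
        if gene in conserved:
            cat = "TS_conserved"
        elif gene in noncons_pct:
            pct = noncons_pct[gene]
            if not np.isnan(pct) and pct < pct_cutoff:
                cat = "TS_nonconserved_pct_lt"
            else:
                cat = "TS_nonconserved_pct_ge"
        elif gene in alt:
            cat = "alt_algorithm_only"
        elif gene in regulon:
            cat = "tf_motif_only"
        else:
            cat = "unexplained"
        records.append({"gene": gene, "category": cat})
    table = pd.DataFrame(records, columns=["gene", "category"])
    counts = table["category"].value_counts()
    fractions = {
        cat: float(counts.get(cat, 0)) / len(gene_list) for cat in CATEGORIES
    }
    return table, fractions


def explained_fraction(fractions: Mapping[str, float]) -> float:
    """1 minus the unexplained fraction."""
    return 1.0 - fractions.get("unexplained", 0.0)


def enrich(
    gene_set: Iterable[str],
    universe: Iterable[str],
    annotation: Mapping[str, Set[str]],
    alpha: float = TF_MOTIF_ALPHA,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each term in ``gene_set``.

    For a term with ``K`` universe genes, a set of size ``n`` drawn from a
    universe of size ``N`` and an observed overlap ``k``, the p-value is
    the upper tail P(X >= k) of Hypergeom(N, K, n).  Results are sorted by
    ascending p with ties broken by term id.
    """
    uni = set(universe)
    genes = set(gene_set)
    offenders = genes - uni
    if offenders:
        raise ValidationError(
            f"gene set is not a subset of the universe; offenders include "
            f"{sorted(offenders)[:5]}"
        )
    if not annotation:
        raise ValidationError("no annotation terms supplied")
    n, N = len(genes), len(uni)
    rows = []
    for term, members in annotation.items():
        term_genes = set(members) & uni
        if not set(members):
            raise ValidationError(f"annotation term {term!r} is empty")
        K = len(term_genes)
        k = len(genes & term_genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {"term": term, "overlap": k, "set_size": n, "term_size": K,
             "universe_size": N, "p_value": p, "significant": p < alpha}
        )
    frame = pd.DataFrame(rows)
    return frame.sort_values(
        ["p_value", "term"], kind="stable"
    ).reset_index(drop=True)


@dataclass(frozen=True)
class TFSecondaryReport:
    """Consistency check for secondary regulation through a TF's regulon."""

    regulon_term: str
    p_value: float
    rank: int                 # 1-based rank of the regulon term by p-value
    motif_fraction: float     # fraction of the MRE-devoid set in the regulon
    significant: bool
    enrichment: pd.DataFrame


def tf_secondary_consistency(
    modulated_no_mre: Iterable[str],
    universe: Iterable[str],
    annotation: Mapping[str, Set[str]],
    regulon_term: str,
    alpha: float = TF_MOTIF_ALPHA,
) -> TFSecondaryReport:
    """Enrichment of the TF regulon within seed-site-devoid modulated genes.

    With a planted regulon responding secondarily the regulon term should
    rank first; without one its significance rate is a type-I error check.
    """
    genes = set(modulated_no_mre)
    if not genes:
        raise ValidationError("empty MRE-devoid modulated set")
    if regulon_term not in annotation:
        raise ValidationError(f"regulon term {regulon_term!r} not in annotation")
    table = enrich(genes, universe, annotation, alpha=alpha)
    pos = table.index[table["term"] == regulon_term][0]
    row = table.loc[pos]
    motif_fraction = len(genes & set(annotation[regulon_term])) / len(genes)
    return TFSecondaryReport(
        regulon_term=regulon_term,
        p_value=float(row["p_value"]),
        rank=int(pos) + 1,
        motif_fraction=float(motif_fraction),
        significant=bool(row["significant"]),
        enrichment=table,
    )
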