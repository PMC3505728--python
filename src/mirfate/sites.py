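"""miRNA seed-match site discovery in 3'-UTR sequences.

A miRNA recognises its targets chiefly through Watson-Crick pairing of the
seed region, bases 2-7 counted from the miRNA 5' end.  On the mRNA sense
strand this pairing leaves a short, exactly spellable DNA signature, and
three canonical site classes are distinguished by the pairing span and by
the presence of an adenosine opposite miRNA position 1:

``8mer``
    an 'A' opposite position 1 plus perfect complementarity to miRNA
    positions 2-8 (site length 8 on the UTR);
``7mer-m8``
    perfect complementarity to positions 2-8, no terminal 'A' (length 7);
``7mer-1A``
    an 'A' opposite position 1 plus perfect complementarity to positions
    2-7 only (length 7).

The 'A' opposite position 1 is required literally on the target, regardless
of the identity of the miRNA's first base.  Because the 8mer string is the
7mer-m8 string followed by 'A', and contains the 7mer-1A string as a suffix,
site classes are reported with the precedence 8mer > 7mer-m8 > 7mer-1A at
overlapping coordinates: an 8mer occurrence is never additionally reported
as either of its embedded 7mers.

The module also provides a minimal AU-rich-element (ARE) scan that counts
non-overlapping ATTTA pentamers, the core destabilisation motif.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple, Union

import pandas as pd

from .errors import ValidationError

#: Site classes in precedence order (strongest first).
SITE_CLASSES: Tuple[str, ...] = ("8mer", "7mer-m8", "7mer-1A")

_RNA_ALPHABET = frozenset("ACGU")
_UTR_ALPHABET = frozenset("ACGTN")

# RNA base -> complementary DNA base (A-T, C-G, G-C, U-A)
_RNA_TO_DNA_COMPLEMENT = str.maketrans("ACGU", "TGCA")

_ARE_PENTAMER = "ATTTA"


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA: an identifier and its 5'->3' RNA sequence.

    Position indexing is 1-based from the 5' end; the seed is positions 2-7.
    The sequence is upper-cased and DNA 'T's are accepted and converted to
    'U' on construction.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("T", "U")
        object.__setattr__(self, "sequence", seq)
        if not self.id:
            raise ValidationError("miRNA id must be non-empty")
        bad = set(seq) - _RNA_ALPHABET
        if bad or not seq:
            raise ValidationError(
                f"miRNA {self.id!r}: sequence must be non-empty RNA over "
                f"{{A,C,G,U}}, offending characters: {sorted(bad)}"
            )

    @property
    def seed(self) -> str:
        """Seed region, miRNA positions 2-7 (RNA)."""
        return self.sequence[1:7]

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SeedSite:
    """A located, classified seed-match site on a UTR sense strand.

    Coordinates are 0-based, half-open on the UTR; ``site_sequence`` equals
    the UTR slice ``utr[start:end]``.
    """

    gene: str
    mirna: str
    site_class: str
    start: int
    end: int
    site_sequence: str


@dataclass(frozen=True)
class AREAnnotation:
    """Result of the ATTTA pentamer scan for one UTR."""

    gene: str
    pentamer_count: int
    positions: Tuple[int, ...]
    are_positive: bool


def _reverse_complement_to_dna(rna: str) -> str:
    """Reverse complement of an RNA string, written in the DNA alphabet."""
    return rna.translate(_RNA_TO_DNA_COMPLEMENT)[::-1]


def clean_utr(sequence: str) -> str:
    """Upper-case a UTR sequence, map U->T, and validate the alphabet.

    'N' is accepted (it never matches any site pattern).  Raises
    :class:`ValidationError` on any other character.
    """
    seq = sequence.upper().replace("U", "T")
    bad = set(seq) - _UTR_ALPHABET
    if bad:
        raise ValidationError(
            f"UTR sequence contains characters outside {{A,C,G,T,U,N}}: "
            f"{sorted(bad)}"
        )
    return seq


def seed_site_strings(mir: MatureMiRNA) -> Dict[str, str]:
    """DNA match strings on the UTR sense strand for each site class.

    The 8mer string is the reverse complement (in DNA) of miRNA positions
    2-8 followed by a literal 'A'; 7mer-m8 drops the 'A'; 7mer-1A pairs
    positions 2-7 only and keeps the 'A'.
    """
    if len(mir.sequence) < 8:
        raise ValidationError(
            f"miRNA {mir.id!r}: need at least 8 bases to derive seed sites, "
            f"got {len(mir.sequence)}"
        )
    rc_2_8 = _reverse_complement_to_dna(mir.sequence[1:8])
    rc_2_7 = _reverse_complement_to_dna(mir.sequence[1:7])
    return {
        "8mer": rc_2_8 + "A",
        "7mer-m8": rc_2_8,
        "7mer-1A": rc_2_7 + "A",
    }


def scan_seed_sites(
    utr_sequence: str, mir: MatureMiRNA, gene: str = ""
) -> List[SeedSite]:
    """Scan one UTR (sense strand only) for seed-match sites of ``mir``.

    Every maximal match is reported exactly once, with 8mer subsuming its
    embedded 7mers at overlapping coordinates.  Sites are returned sorted
    by start.  Input is case-insensitive and may use U in place of T; an
    empty sequence yields an empty list.
    """
    seq = clean_utr(utr_sequence)
    if not seq:
        return []
    patterns = seed_site_strings(mir)
    p8 = patterns["8mer"]          # == p7m8 + "A"
    p7m8 = patterns["7mer-m8"]
    p71a = patterns["7mer-1A"]     # == p8[1:]

    sites: List[SeedSite] = []
    n = len(seq)
    for i in range(n):
        if seq[i : i + 8] == p8:
            sites.append(SeedSite(gene, mir.id, "8mer", i, i + 8, p8))
            continue
        # 7mer-m8: positions 2-8 pair but no 'A' follows (otherwise the
        # match is the 8mer handled above).
        if seq[i : i + 7] == p7m8:
            sites.append(SeedSite(gene, mir.id, "7mer-m8", i, i + 7, p7m8))
        # 7mer-1A: suffix of the 8mer; suppressed when the preceding base
        # completes the 8mer (that occurrence was reported at i-1).  For
        # degenerate miRNAs where the two 7mer patterns coincide, the
        # 7mer-m8 report above takes precedence.
        elif seq[i : i + 7] == p71a and not (i > 0 and seq[i - 1] == p8[0]):
            sites.append(SeedSite(gene, mir.id, "7mer-1A", i, i + 7, p71a))
    return sites


def scan_are(utr_sequence: str, gene: str = "") -> AREAnnotation:
    """Count non-overlapping, left-greedy ATTTA pentamers in a UTR."""
    seq = clean_utr(utr_sequence)
    positions = tuple(m.start() for m in re.finditer(_ARE_PENTAMER, seq))
    return AREAnnotation(gene, len(positions), positions, len(positions) >= 1)


def best_site_class(classes: Iterable[str]) -> str:
    """Strongest site class among ``classes`` (8mer > 7mer-m8 > 7mer-1A)."""
    ranked = sorted(classes, key=SITE_CLASSES.index)
    if not ranked:
        raise ValidationError("no site classes supplied")
    return ranked[0]


UTRCollection = Union[Mapping[str, str], Sequence[Tuple[str, str]]]


def _utr_items(utrs: UTRCollection) -> List[Tuple[str, str]]:
    if isinstance(utrs, Mapping):
        return list(utrs.items())
    items = list(utrs)
    seen = set()
    for gene, _ in items:
        if gene in seen:
            raise ValidationError(f"duplicate gene id in UTR collection: {gene!r}")
        seen.add(gene)
    return items


def scan_to_predictions(
    utrs: UTRCollection, mirs: Iterable[MatureMiRNA]
) -> pd.DataFrame:
    """Reduce scanner output to a prediction table.

    One row per (gene, miRNA) pair with at least one site, recording the
    best site class; conservation status and PCT are not computable from
    sequence alone and are emitted as missing.
    """
    records = []
    for gene, seq in _utr_items(utrs):
        for mir in mirs:
            found = scan_seed_sites(seq, mir, gene=gene)
            if found:
                records.append(
                    {
                        "gene": gene,
                        "mirna": mir.id,
                        "site_type": best_site_class(s.site_class for s in found),
                        "conserved": pd.NA,
                        "pct": pd.NA,
                    }
                )
    return pd.DataFrame(
        records, columns=["gene", "mirna", "site_type", "conserved", "pct"]
    )
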