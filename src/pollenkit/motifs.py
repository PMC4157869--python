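"""Promoter extraction and literal cis-element scanning.

Positions are reported upstream-relative: the base immediately 5' of the
start codon is position 1 and positions increase moving away from the gene.
The five preloaded motifs are short literal elements repeatedly associated
with pollen-specific promoter activity in flowering plants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_core import (
    SequenceRecord,
    ValidationError,
    get_logger,
    reverse_complement,
)

log = get_logger("motifs")


@dataclass(frozen=True)
class Motif:
    label: str
    pattern: str

    def __post_init__(self) -> None:
        if not self.pattern or set(self.pattern) - set("ACGT"):
            raise ValidationError(
                f"motif {self.label!r} pattern must be non-empty over A/C/G/T"
            )


# Literal pollen-specificity elements scanned by default.
DEFAULT_MOTIFS: tuple[Motif, ...] = (
    Motif("AGAAA", "AGAAA"),
    Motif("GTGA", "GTGA"),
    Motif("AAATGA", "AAATGA"),
    Motif("AGGTCA", "AGGTCA"),
    Motif("TGTGGTT", "TGTGGTT"),
)


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence in one promoter.

    ``upstream_pos`` is the 1-based distance of the motif's 3'-most base
    from the base immediately 5' of the start codon.
    """

    promoter_id: str
    motif: str
    upstream_pos: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.upstream_pos < 1:
            raise ValidationError("upstream_pos must be >= 1")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"bad strand {self.strand!r}")


def extract_promoter(
    genome: SequenceRecord, tss_coordinate: int, strand: str, length: int
) -> SequenceRecord:
    """The ``length`` bases immediately upstream of a start codon.

    ``tss_coordinate`` is the 1-based top-strand position of the start
    codon's first base (the A of ATG for + strand genes; for - strand genes
    the position of the codon's first base on the minus strand, i.e. its
    3'-most top-strand base).  The returned sequence always reads 5'->3'
    toward the gene.  A window extending past the sequence bounds is an
    error, never a silent truncation.
    """
    if length < 1:
        raise ValidationError("promoter length must be positive")
    n = len(genome.sequence)
    if strand == "+":
        start = tss_coordinate - length  # 1-based
        if start < 1 or tss_coordinate - 1 > n:
            raise ValidationError(
                f"promoter window [{start}, {tss_coordinate - 1}] outside sequence "
                f"of length {n}"
            )
        seq = genome.sequence[start - 1: tss_coordinate - 1]
    elif strand == "-":
        end = tss_coordinate + length
        if end > n or tss_coordinate < 1:
            raise ValidationError(
                f"promoter window [{tss_coordinate + 1}, {end}] outside sequence "
                f"of length {n}"
            )
        seq = reverse_complement(genome.sequence[tss_coordinate: end])
    else:
        raise ValidationError(f"strand must be '+' or '-', got {strand!r}")
    return SequenceRecord(
        f"{genome.id}_prom{tss_coordinate}{strand}", seq,
        f"{length} bp upstream of position {tss_coordinate} ({strand})",
    )


def _as_motifs(motifs: Iterable[Motif | str]) -> list[Motif]:
    return [m if isinstance(m, Motif) else Motif(m, m) for m in motifs]


def scan_motifs(
    promoters: Sequence[SequenceRecord],
    motifs: Iterable[Motif | str] = DEFAULT_MOTIFS,
    both_strands: bool = False,
) -> list[MotifHit]:
    """All (overlapping) motif occurrences in every promoter.

    Promoter sequences are assumed to read 5'->3' toward the gene, so the
    last base sits at upstream position 1.  With ``both_strands`` the
    reverse complement of each motif is additionally matched on the given
    sequence and reported on the '-' strand (position of the motif's
    3'-most base on that strand).  Hits are ordered by
    (promoter, position, motif).
    """
    if not promoters:
        raise ValidationError("no promoters to scan")
    motif_list = _as_motifs(motifs)
    hits: list[MotifHit] = []
    for prom in promoters:
        seq = prom.sequence
        n = len(seq)
        for motif in motif_list:
            m = len(motif.pattern)
            for i in range(n - m + 1):
                if seq[i:i + m] == motif.pattern:
                    hits.append(MotifHit(prom.id, motif.label, n - (i + m - 1), "+"))
            if both_strands:
                rc = reverse_complement(motif.pattern)
                for i in range(n - m + 1):
                    if seq[i:i + m] == rc:
                        # on the minus strand the motif's 3'-most base is the
                        # match's first top-strand base
                        hits.append(MotifHit(prom.id, motif.label, n - i, "-"))
    hits.sort(key=lambda h: (h.promoter_id, h.upstream_pos, h.motif, h.strand))
    log.info("scanned %d promoters for %d motifs: %d hits",
             len(promoters), len(motif_list), len(hits))
    return hits


def presence_summary(
    hits: Sequence[MotifHit],
    promoters: Sequence[SequenceRecord],
    motifs: Iterable[Motif | str] = DEFAULT_MOTIFS,
) -> pd.Series:
    """Per-motif fraction of promoters containing at least one hit.

    Promoters with zero hits count in the denominator, so the overlap rule
    cannot change these fractions.
    """
    motif_list = _as_motifs(motifs)
    n = len(promoters)
    if n == 0:
        raise ValidationError("presence fractions need at least one promoter")
    with_hit = {m.label: set() for m in motif_list}
    for h in hits:
        if h.motif in with_hit:
            with_hit[h.motif].add(h.promoter_id)
    return pd.Series(
        {label: len(ids) / n for label, ids in with_hit.items()}, name="presence_fraction"
    )


@dataclass(frozen=True)
class PositionalSummary:
    near_fraction: pd.Series  # per-motif fraction of hits within the window
    histogram: pd.DataFrame   # hit counts per position bin x motif
    near_window: int


def positional_summary(
    hits: Sequence[MotifHit],
    near_window: int = 1500,
    bin_width: int = 100,
) -> PositionalSummary:
    """Fraction of hits at or within ``near_window`` bp of the start codon
    (inclusive boundary), plus a binned position histogram."""
    if near_window < 1 or bin_width < 1:
        raise ValidationError("near_window and bin_width must be positive")
    labels = sorted({h.motif for h in hits})
    frac = {}
    for label in labels:
        pos = [h.upstream_pos for h in hits if h.motif == label]
        frac[label] = sum(p <= near_window for p in pos) / len(pos)
    max_pos = max((h.upstream_pos for h in hits), default=bin_width)
    n_bins = int(np.ceil(max_pos / bin_width))
    edges = [(b * bin_width + 1, (b + 1) * bin_width) for b in range(n_bins)]
    hist = pd.DataFrame(
        0,
        index=[f"{a}-{b}" for a, b in edges],
        columns=labels if labels else pd.Index([], dtype=object),
    )
    for h in hits:
        hist.iloc[(h.upstream_pos - 1) // bin_width, hist.columns.get_loc(h.motif)] += 1
    return PositionalSummary(
        pd.Series(frac, name="near_fraction"), hist, near_window
    )


def hits_to_frame(hits: Sequence[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [(h.promoter_id, h.motif, h.upstream_pos, h.strand) for h in hits],
        columns=["promoter_id", "motif", "upstream_pos", "strand"],
    )
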