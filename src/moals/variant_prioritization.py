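"""Rare-variant filtering, consequence-tier scoring and gene-burden features.

Variants annotated with VEP-style consequences are filtered to rare,
canonical-transcript, gene-anchored records; each record is scored by the
severity tier of its consequence terms; and qualifying records are
aggregated into a per-sample, per-gene burden matrix that enters the model
as the genomic omics layer.

Filtering keeps a record iff it is on a canonical transcript, carries a
recognised gene symbol, and its population allele frequency is below 0.01
or absent from the reference populations. The default severity tiers are

* 5 — frameshift_variant, stop_gained, transcript_ablation
* 3 — stop_lost, start_lost, transcript_amplification
* 2 — splice_donor_variant, splice_acceptor_variant
* 0 — everything else (excluded from the burden)

The tier-to-consequence pairing is fully overridable because published
descriptions of such scoring schemes rarely pin the exact assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import OmicsBlock

AF_THRESHOLD = 0.01

DEFAULT_SCORE_MAP: dict[str, int] = {
    "frameshift_variant": 5,
    "stop_gained": 5,
    "transcript_ablation": 5,
    "stop_lost": 3,
    "start_lost": 3,
    "transcript_amplification": 3,
    "splice_donor_variant": 2,
    "splice_acceptor_variant": 2,
}


@dataclass
class AnnotatedVariant:
    """One variant-consequence record with per-sample alternate-allele counts.

    ``allele_frequency`` is the population AF in [0,1], or None when the
    variant is absent from the reference populations (absence is
    information, not a zero). ``allele_counts`` maps sample id to the
    number of non-reference alleles (1 het, 2 hom-alt); reference-genotype
    samples are omitted.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str | None
    consequences: tuple[str, ...]
    canonical: bool
    allele_frequency: float | None
    allele_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.consequences = tuple(self.consequences)
        if self.allele_frequency is not None and not 0.0 <= self.allele_frequency <= 1.0:
            raise ValueError(
                f"{self.chrom}:{self.pos} allele frequency {self.allele_frequency} outside [0,1]"
            )
        for s, c in self.allele_counts.items():
            if c not in (0, 1, 2):
                raise ValueError(f"{self.chrom}:{self.pos} sample {s}: allele count {c} not in {{0,1,2}}")


class ConsequenceScoreMap:
    """Mapping from consequence term to a non-negative integer severity score.

    Unknown terms score 0.
    """

    def __init__(self, scores: Mapping[str, int] | None = None):
        scores = dict(DEFAULT_SCORE_MAP if scores is None else scores)
        for term, s in scores.items():
            if not (isinstance(s, (int, np.integer)) and s >= 0):
                raise ValueError(f"score for {term!r} must be a non-negative integer, got {s!r}")
        self._scores = {t: int(s) for t, s in scores.items()}

    def __getitem__(self, term: str) -> int:
        return self._scores.get(term, 0)

    def items(self):
        return self._scores.items()


def filter_variants(records: Iterable[AnnotatedVariant]
                    ) -> tuple[list[AnnotatedVariant], dict[str, int]]:
    """Apply the rare-variant filters; returns (kept records, drop log).

    Keep iff canonical AND gene symbol present AND (AF absent OR AF < 0.01).
    The drop log counts, per rule, records removed by that rule (a record
    failing several rules is charged to the first failing rule, in the
    order canonical, symbol, frequency). Input order is preserved.
    """
    kept: list[AnnotatedVariant] = []
    log = {"canonical": 0, "symbol": 0, "frequency": 0}
    for rec in records:
        if not rec.canonical:
            log["canonical"] += 1
        elif not rec.gene:
            log["symbol"] += 1
        elif rec.allele_frequency is not None and rec.allele_frequency >= AF_THRESHOLD:
            log["frequency"] += 1
        else:
            kept.append(rec)
    return kept, log


def score_variant(record: AnnotatedVariant,
                  score_map: ConsequenceScoreMap | None = None) -> int:
    """Severity score of a record: max score over its consequence terms."""
    score_map = score_map or ConsequenceScoreMap()
    return max((score_map[t] for t in record.consequences), default=0)


def build_gene_burden(records: Sequence[AnnotatedVariant],
                      sample_ids: Sequence[str],
                      score_map: ConsequenceScoreMap | None = None,
                      mode: str = "weighted",
                      name: str = "burden") -> OmicsBlock:
    """Aggregate scored records into a samples x genes burden block.

    ``mode='weighted'`` (default): burden[s, g] = sum over g's records of
    score x allele count. ``mode='count'``: sum of allele counts over
    records with positive score. Zero-score records never contribute;
    genes whose column would be all-zero are dropped.
    """
    if mode not in ("weighted", "count"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    score_map = score_map or ConsequenceScoreMap()
    sample_ids = list(sample_ids)
    sample_index = {s: i for i, s in enumerate(sample_ids)}
    gene_order: list[str] = []
    gene_index: dict[str, int] = {}
    entries: list[tuple[int, int, float]] = []
    for rec in records:
        s = score_variant(rec, score_map)
        if s == 0 or not rec.gene:
            continue
        if rec.gene not in gene_index:
            gene_index[rec.gene] = len(gene_order)
            gene_order.append(rec.gene)
        g = gene_index[rec.gene]
        w = float(s) if mode == "weighted" else 1.0
        for sample, count in rec.allele_counts.items():
            if sample not in sample_index:
                raise ValueError(f"sample {sample!r} in variant records but not in sample table")
            if count:
                entries.append((sample_index[sample], g, w * count))
    values = np.zeros((len(sample_ids), len(gene_order)))
    for i, j, v in entries:
        values[i, j] += v
    nonzero = values.any(axis=0)
    values = values[:, nonzero]
    genes = [g for g, keep in zip(gene_order, nonzero) if keep]
    return OmicsBlock(name=name, samples=sample_ids, features=genes, values=values)
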