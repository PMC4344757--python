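"""Mappability-filtered read counting and RPKUM expression.

A read is kept only when it is uniquely aligned AND lands on trustworthy
sequence: an unspliced read must start at a mappable position, a spliced
read must cross a junction whose k-mer occurs exactly once in genome plus
transcriptome. Expression is then reported in RPKUM — Reads per Kilobase of
Uniquely mappable transcript per Million reads — i.e. RPKM with the length
denominator replaced by the gene's mappable-base count and the numerator
restricted to filtered reads:

    RPKUM = mappable_reads * 1e9 / (mappable_bases * total_reads)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotations import GeneModel, build_consensus_model
from .mappability import MappabilityTrack, MappableBaseCount, SyntheticRegion

__all__ = [
    "Alignment",
    "ReadAlignmentRecord",
    "MappableReadSet",
    "ExpressionMatrix",
    "TranscriptionCall",
    "filter_reads",
    "naive_unique_counts",
    "compute_rpkum",
    "build_expression_matrix",
    "call_transcribed",
    "load_alignments_sam",
]


@dataclass(frozen=True)
class Alignment:
    """One candidate alignment of a read: spliced segments + mismatch count."""

    chrom: str
    start: int
    blocks: tuple[tuple[int, int], ...]
    mismatches: int = 0

    def __post_init__(self) -> None:
        if self.mismatches < 0:
            raise ValueError("mismatches must be >= 0")
        for (s1, e1), (s2, e2) in zip(self.blocks, self.blocks[1:]):
            if not (s1 < e1 <= s2 < e2):
                raise ValueError("alignment blocks must be sorted and disjoint")

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.blocks)

    @property
    def spliced(self) -> bool:
        return len(self.blocks) > 1


@dataclass
class ReadAlignmentRecord:
    """All candidate alignments reported for one read."""

    read_id: str
    sample_id: str
    alignments: list[Alignment]

    @property
    def is_unique(self) -> bool:
        return len(self.alignments) == 1


@dataclass
class MappableReadSet:
    """Per-gene retained read counts for one sample, with a discard ledger.

    ``total_reads`` is the RPKUM denominator: all aligned reads in the
    sample before filtering. ``ledger`` keys: retained, dropped_unaligned,
    dropped_multi, dropped_unmappable, dropped_nongenic; they sum to the
    number of input reads.
    """

    sample_id: str
    counts: dict[str, int]
    total_reads: int
    ledger: dict[str, int] = field(default_factory=dict)


@dataclass
class TranscriptionCall:
    gene_id: str
    n_samples_transcribed: int
    is_transcribed: bool
    is_recurrent: bool
    unquantifiable: bool = False


class ExpressionMatrix:
    """RPKUM values (genes x samples) with the companion raw-count matrix.

    Genes with fewer than ``min_bases`` mappable bases are flagged
    unquantifiable; their RPKUM rows are NaN (undefined, not zero).
    """

    def __init__(
        self,
        rpkum: pd.DataFrame,
        counts: pd.DataFrame,
        mappable_bases: pd.Series,
        min_bases: int = 50,
    ):
        if not rpkum.index.equals(counts.index) or not rpkum.columns.equals(
            counts.columns
        ):
            raise ValueError("RPKUM and count matrices must share axes")
        self.rpkum = rpkum
        self.counts = counts
        self.mappable_bases = mappable_bases
        self.min_bases = min_bases
        self.unquantifiable = mappable_bases < min_bases

    @property
    def gene_ids(self) -> list[str]:
        return list(self.rpkum.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.rpkum.columns)

    def to_tsv(self, rpkum_path: str | Path, counts_path: str | Path | None = None) -> None:
        self.rpkum.to_csv(rpkum_path, sep="\t", index_label="gene_id")
        if counts_path is not None:
            self.counts.to_csv(counts_path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# Read filtering


class _GeneIndex:
    """Stabbing index: alignment start -> genes; junction key -> genes."""

    def __init__(self, models: list[GeneModel]):
        self.trees: dict[str, IntervalTree] = {}
        self.junction_owners: dict[tuple, set[str]] = {}
        for model in models:
            consensus = build_consensus_model(model)
            tree = self.trees.setdefault(consensus.chrom, IntervalTree())
            for s, e in consensus.intervals:
                tree.addi(s, e, model.gene_id)
            for chain in model.transcripts.values():
                for donor, acceptor in zip(chain, chain[1:]):
                    if donor.strand == "+":
                        key = (donor.chrom, donor.end, acceptor.start)
                    else:
                        key = (donor.chrom, acceptor.end, donor.start)
                    self.junction_owners.setdefault(key, set()).add(model.gene_id)

    def genes_at(self, chrom: str, pos: int) -> set[str]:
        tree = self.trees.get(chrom)
        if tree is None:
            return set()
        return {iv.data for iv in tree.at(pos)}

    def genes_of_junction(self, key: tuple) -> set[str]:
        return self.junction_owners.get(key, set())


def filter_reads(
    records: list[ReadAlignmentRecord] | "iter",
    track: MappabilityTrack,
    regions: list[SyntheticRegion],
    models: list[GeneModel],
    sample_id: str | None = None,
) -> MappableReadSet:
    """Apply the mappable-read filter and assign retained reads to genes.

    Retention rule: the read is uniquely aligned AND either (1) unspliced
    with a mappable start position, or (2) spliced across an annotated
    junction whose crossing k-mer is flagged unique. Retained reads are
    assigned to every gene whose consensus model contains the alignment
    start (unspliced) or that owns the junction (spliced). Reads spanning
    more than one junction are conservatively dropped as unmappable.
    """
    index = _GeneIndex(models)
    region_by_key = {r.genomic_key: r for r in regions}
    k = track.k
    counts: dict[str, int] = {}
    ledger = {
        "retained": 0,
        "dropped_unaligned": 0,
        "dropped_multi": 0,
        "dropped_unmappable": 0,
        "dropped_nongenic": 0,
    }
    total = 0
    sid = sample_id
    for record in records:
        total += 1
        if sid is None:
            sid = record.sample_id
        if len(record.alignments) == 0:
            ledger["dropped_unaligned"] += 1
            continue
        if not record.is_unique:
            ledger["dropped_multi"] += 1
            continue
        aln = record.alignments[0]
        if aln.length != k:
            raise ValueError(
                f"read {record.read_id!r} has length {aln.length}, track k={k}"
            )
        if not aln.spliced:
            vec = track.vectors.get(aln.chrom)
            if vec is None or aln.start >= len(vec) or not vec[aln.start]:
                ledger["dropped_unmappable"] += 1
                continue
            genes = index.genes_at(aln.chrom, aln.start)
        elif len(aln.blocks) == 2:
            (s1, e1), (s2, e2) = aln.blocks
            key = (aln.chrom, e1, s2)
            region = region_by_key.get(key)
            if region is None or region.unique_kmers is None:
                ledger["dropped_unmappable"] += 1
                continue
            b1 = e1 - s1
            if region.strand == "+":
                offset = region.boundary_offset - b1
            else:
                offset = region.boundary_offset + b1 - k
            if not (0 <= offset < len(region.unique_kmers)) or not region.unique_kmers[
                offset
            ]:
                ledger["dropped_unmappable"] += 1
                continue
            genes = index.genes_of_junction(key)
        else:
            ledger["dropped_unmappable"] += 1
            continue
        if not genes:
            ledger["dropped_nongenic"] += 1
            continue
        ledger["retained"] += 1
        for gene_id in genes:
            counts[gene_id] = counts.get(gene_id, 0) + 1
    aligned = total - ledger["dropped_unaligned"]
    if aligned == 0:
        raise ValueError(f"sample {sid!r} has no aligned reads")
    return MappableReadSet(
        sample_id=sid or "sample", counts=counts, total_reads=aligned, ledger=ledger
    )


def naive_unique_counts(
    records: list[ReadAlignmentRecord], models: list[GeneModel]
) -> dict[str, int]:
    """Uniquely-aligned read counting with no mappability filter.

    The baseline that uniquely *misaligned* reads contaminate; kept for
    comparison against :func:`filter_reads`.
    """
    index = _GeneIndex(models)
    counts: dict[str, int] = {}
    for record in records:
        if not record.is_unique:
            continue
        aln = record.alignments[0]
        if aln.spliced and len(aln.blocks) == 2:
            (s1, e1), (s2, e2) = aln.blocks
            genes = index.genes_of_junction((aln.chrom, e1, s2))
        else:
            genes = index.genes_at(aln.chrom, aln.start)
        for gene_id in genes:
            counts[gene_id] = counts.get(gene_id, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# RPKUM


def compute_rpkum(retained_reads: int, mappable_bases: int, total_reads: int) -> float:
    """RPKUM = retained_reads * 1e9 / (mappable_bases * total_reads).

    Returns NaN (undefined) when the gene has no mappable bases; zero reads
    over a positive denominator give 0.0.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if mappable_bases < 0:
        raise ValueError("mappable_bases must be >= 0")
    if mappable_bases == 0:
        return float("nan")
    return retained_reads * 1e9 / (mappable_bases * total_reads)


def build_expression_matrix(
    samples: list[MappableReadSet],
    base_counts: list[MappableBaseCount],
    min_bases: int = 50,
) -> ExpressionMatrix:
    """Apply :func:`compute_rpkum` cellwise over genes x samples."""
    gene_ids = [c.gene_id for c in base_counts]
    bases = pd.Series({c.gene_id: c.mappable_bases for c in base_counts})
    sample_ids = []
    count_cols = {}
    rpkum_cols = {}
    for s in samples:
        if s.total_reads <= 0:
            raise ValueError(f"sample {s.sample_id!r} has zero total reads")
        sample_ids.append(s.sample_id)
        cnt = np.array([s.counts.get(g, 0) for g in gene_ids], dtype=np.int64)
        count_cols[s.sample_id] = cnt
        rpkum_cols[s.sample_id] = [
            compute_rpkum(c, b, s.total_reads)
            for c, b in zip(cnt, bases[gene_ids])
        ]
    counts = pd.DataFrame(count_cols, index=gene_ids)
    rpkum = pd.DataFrame(rpkum_cols, index=gene_ids)
    return ExpressionMatrix(rpkum, counts, bases, min_bases=min_bases)


def call_transcribed(
    matrix: ExpressionMatrix,
    min_bases: int = 50,
    min_reads: int = 50,
    min_rpkum: float = 1.0,
    recurrence_fraction: float = 0.10,
) -> list[TranscriptionCall]:
    """Call transcribed / recurrent genes.

    A gene is transcribed if it has at least ``min_bases`` mappable bases
    and, in at least one sample, at least ``min_reads`` filtered reads and
    ``min_rpkum`` RPKUM. It is recurrent if the per-sample thresholds hold
    in at least floor(recurrence_fraction * n_samples) samples (minimum 1).
    """
    n_samples = len(matrix.sample_ids)
    needed = max(1, math.floor(recurrence_fraction * n_samples))
    calls = []
    for gene_id in matrix.gene_ids:
        unquant = bool(matrix.mappable_bases[gene_id] < min_bases)
        passes = (
            (matrix.counts.loc[gene_id] >= min_reads)
            & (matrix.rpkum.loc[gene_id] >= min_rpkum)
        )
        n_pass = 0 if unquant else int(passes.sum())
        transcribed = (not unquant) and n_pass >= 1
        calls.append(
            TranscriptionCall(
                gene_id=gene_id,
                n_samples_transcribed=n_pass,
                is_transcribed=transcribed,
                is_recurrent=transcribed and n_pass >= needed,
                unquantifiable=unquant,
            )
        )
    return calls


def write_calls(calls: list[TranscriptionCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "gene_id\tn_samples_transcribed\tis_transcribed\tis_recurrent\tunquantifiable\n"
        )
        for c in calls:
            fh.write(
                f"{c.gene_id}\t{c.n_samples_transcribed}\t{int(c.is_transcribed)}\t"
                f"{int(c.is_recurrent)}\t{int(c.unquantifiable)}\n"
            )


def write_ledger(samples: list[MappableReadSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "sample_id\ttotal_reads\tretained\tdropped_unaligned\tdropped_multi\t"
            "dropped_unmappable\tdropped_nongenic\n"
        )
        for s in samples:
            led = s.ledger
            fh.write(
                f"{s.sample_id}\t{s.total_reads}\t{led['retained']}\t"
                f"{led['dropped_unaligned']}\t{led['dropped_multi']}\t"
                f"{led['dropped_unmappable']}\t{led['dropped_nongenic']}\n"
            )


# ---------------------------------------------------------------------------
# SAM input


def load_alignments_sam(path: str | Path, sample_id: str) -> list[ReadAlignmentRecord]:
    """Read a SAM/BAM file into per-read alignment records.

    All alignments of a read (primary and secondary) must be present;
    mismatch counts come from the NM tag, spliced blocks from N CIGAR
    operations.
    """
    import pysam

    grouped: dict[str, list[Alignment]] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                grouped.setdefault(rec.query_name, [])
                continue
            blocks = _merge_adjacent(rec.get_blocks())
            grouped.setdefault(rec.query_name, []).append(
                Alignment(
                    chrom=rec.reference_name,
                    start=rec.reference_start,
                    blocks=tuple(blocks),
                    mismatches=int(rec.get_tag("NM")) if rec.has_tag("NM") else 0,
                )
            )
    return [
        ReadAlignmentRecord(read_id=rid, sample_id=sample_id, alignments=alns)
        for rid, alns in grouped.items()
    ]


def _merge_adjacent(blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    # pysam splits blocks on I/D as well as N; merge abutting blocks so only
    # true splice gaps remain
    merged: list[tuple[int, int]] = []
    for s, e in blocks:
        if merged and s == merged[-1][1]:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged
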