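"""Discrete, mismatch-tolerant transcriptome mappability.

A genomic position ``i`` is mappable at read length ``k`` and safety margin
``epsilon`` iff the k-mer starting at ``i`` is NOT within Hamming distance
``epsilon`` of any *other* k-mer occurrence — at any other genomic start, on
either strand, or inside any synthetic junction region. The safety margin
guarantees that a read carrying up to ``epsilon`` base-call errors or SNPs
cannot be uniquely misaligned onto a mappable position.

Synthetic regions extend the k-mer universe to the transcriptome: for every
annotated splice junction, the last ``k-1`` transcript bases of the donor
exon are concatenated with the first ``k-1`` of the acceptor exon, so every
junction-crossing k-mer occurs in exactly one such region.

The accelerated search uses pigeonhole partitioning: each k-mer is split
into ``epsilon + 1`` segments, and two k-mers within Hamming distance
``epsilon`` must agree exactly on at least one segment. A brute-force
all-pairs implementation with the identical contract serves as the oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotations import (
    ConsensusGeneModel,
    GeneModel,
    GenomeSequence,
    reverse_complement,
)

__all__ = [
    "MappabilityTrack",
    "SyntheticRegion",
    "MappableBaseCount",
    "build_synthetic_regions",
    "compute_mappability",
    "brute_force_mappability",
    "count_mappable_bases",
    "write_mappability_bed",
    "load_mappability_bed",
    "write_base_count_report",
]

_N_BYTE = ord("N")

BRUTE_FORCE_GUARD = 50_000  # total bases (genome + regions) the oracle accepts


@dataclass
class MappabilityTrack:
    """Boolean mappability of every k-mer start position, per chromosome.

    ``vectors[chrom][i]`` is the mappability of the k-mer starting at
    genomic position ``i``; vectors have length ``chrom_length - k + 1``
    (empty for chromosomes shorter than ``k``).
    """

    k: int
    epsilon: int
    vectors: dict[str, np.ndarray]

    def chrom_length(self, chrom: str) -> int:
        return len(self.vectors[chrom]) + self.k - 1

    def base_cover(self, chrom: str) -> np.ndarray:
        """Per-base mappability: a base is mappable iff covered by at least
        one mappable k-mer window."""
        vec = self.vectors[chrom]
        length = len(vec) + self.k - 1 if len(vec) else self.k - 1
        diff = np.zeros(length + 1, dtype=np.int64)
        starts = np.flatnonzero(vec)
        np.add.at(diff, starts, 1)
        np.add.at(diff, starts + self.k, -1)
        return np.cumsum(diff[:-1]) > 0


@dataclass
class SyntheticRegion:
    """Transcript sequence flanking one splice junction.

    ``sequence`` is in transcript orientation, normally of length
    ``2(k-1)``; ``genome_pos[j]`` is the genomic coordinate each sequence
    offset derives from. ``unique_kmers[j]`` flags whether the k-mer at
    offset ``j`` occurs exactly once (up to the safety margin) in genome
    plus transcriptome; it is filled in by :func:`compute_mappability`.
    """

    junction_id: str
    chrom: str
    strand: str
    sequence: str
    genome_pos: np.ndarray
    donor_interval: tuple[int, int]
    acceptor_interval: tuple[int, int]
    genomic_key: tuple[str, int, int]
    boundary_offset: int
    truncated: bool = False
    unique_kmers: np.ndarray | None = None

    def kmer_count(self, k: int) -> int:
        return max(0, len(self.sequence) - k + 1)


@dataclass
class MappableBaseCount:
    gene_id: str
    mappable_bases: int
    total_consensus_bases: int

    @property
    def mappability_fraction(self) -> float:
        if self.total_consensus_bases == 0:
            return float("nan")
        return self.mappable_bases / self.total_consensus_bases


# ---------------------------------------------------------------------------
# Synthetic regions


def build_synthetic_regions(
    models: list[GeneModel], genome: GenomeSequence, k: int
) -> list[SyntheticRegion]:
    """One region per distinct junction: donor-exon suffix + acceptor-exon
    prefix of ``k-1`` transcript bases each.

    Exons shorter than ``k-1`` contribute what they have and the region is
    flagged truncated (never padded). Junctions shared between transcripts
    are emitted once, using the longest available flanks.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    # key -> (donor exon, acceptor exon) with maximal flank lengths
    best: dict[tuple, tuple] = {}
    for model in models:
        for chain in model.transcripts.values():
            for donor, acceptor in zip(chain, chain[1:]):
                if donor.strand == "+":
                    key = (donor.chrom, donor.strand, donor.end, acceptor.start)
                else:
                    key = (donor.chrom, donor.strand, donor.start, acceptor.end)
                prev = best.get(key)
                if prev is None or len(donor) + len(acceptor) > len(prev[0]) + len(prev[1]):
                    best[key] = (donor, acceptor)

    regions = []
    for idx, (key, (donor, acceptor)) in enumerate(best.items()):
        chrom, strand = key[0], key[1]
        seq = genome[chrom]
        d_avail = min(k - 1, len(donor))
        a_avail = min(k - 1, len(acceptor))
        if strand == "+":
            donor_part = seq[donor.end - d_avail : donor.end]
            acceptor_part = seq[acceptor.start : acceptor.start + a_avail]
            pos = np.concatenate(
                [
                    np.arange(donor.end - d_avail, donor.end),
                    np.arange(acceptor.start, acceptor.start + a_avail),
                ]
            )
            region_seq = donor_part + acceptor_part
            gkey = (chrom, donor.end, acceptor.start)
        else:
            donor_part = reverse_complement(seq[donor.start : donor.start + d_avail])
            acceptor_part = reverse_complement(seq[acceptor.end - a_avail : acceptor.end])
            pos = np.concatenate(
                [
                    np.arange(donor.start + d_avail - 1, donor.start - 1, -1),
                    np.arange(acceptor.end - 1, acceptor.end - a_avail - 1, -1),
                ]
            )
            region_seq = donor_part + acceptor_part
            gkey = (chrom, acceptor.end, donor.start)
        regions.append(
            SyntheticRegion(
                junction_id=f"J{idx:05d}",
                chrom=chrom,
                strand=strand,
                sequence=region_seq,
                genome_pos=pos,
                donor_interval=(donor.start, donor.end),
                acceptor_interval=(acceptor.start, acceptor.end),
                genomic_key=gkey,
                boundary_offset=d_avail,
                truncated=(d_avail < k - 1 or a_avail < k - 1),
            )
        )
    return regions


# ---------------------------------------------------------------------------
# Occurrence collection (shared input representation)


def _seq_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _windows(arr: np.ndarray, k: int) -> np.ndarray:
    if len(arr) < k:
        return np.empty((0, k), dtype=np.uint8)
    return np.lib.stride_tricks.sliding_window_view(arr, k)


def _collect_occurrences(genome: GenomeSequence, regions: list[SyntheticRegion], k: int):
    """Build the k-mer occurrence universe.

    Returns (matrix, loc_ids, query_slots) where ``query_slots[i] >= 0``
    marks rows whose mappability is reported (forward genome positions and
    forward region k-mers); reverse-complement rows share the loc id of
    their forward counterpart, so a palindromic k-mer is not its own
    neighbor.
    """
    mats, locs, slots = [], [], []
    loc_base = 0
    slot_base = 0
    slot_layout: dict[str, tuple[int, int]] = {}
    for chrom in genome.chrom_names:
        seq = genome[chrom]
        n_pos = max(0, len(seq) - k + 1)
        fwd = _windows(_seq_bytes(seq), k)
        ids = np.arange(loc_base, loc_base + n_pos)
        mats.append(fwd)
        locs.append(ids)
        slots.append(np.arange(slot_base, slot_base + n_pos))
        # reverse complement occurrences, mapped back to forward start coords
        rc = _windows(_seq_bytes(reverse_complement(seq)), k)
        mats.append(rc[::-1])
        locs.append(ids)
        slots.append(np.full(n_pos, -1))
        slot_layout[chrom] = (slot_base, n_pos)
        loc_base += n_pos
        slot_base += n_pos
    region_layout: list[tuple[int, int]] = []
    for region in regions:
        n_kmers = region.kmer_count(k)
        fwd = _windows(_seq_bytes(region.sequence), k)
        ids = np.arange(loc_base, loc_base + n_kmers)
        mats.append(fwd)
        locs.append(ids)
        slots.append(np.arange(slot_base, slot_base + n_kmers))
        rc = _windows(_seq_bytes(reverse_complement(region.sequence)), k)
        mats.append(rc[::-1])
        locs.append(ids)
        slots.append(np.full(n_kmers, -1))
        region_layout.append((slot_base, n_kmers))
        loc_base += n_kmers
        slot_base += n_kmers
    matrix = np.vstack(mats) if mats else np.empty((0, k), dtype=np.uint8)
    return (
        matrix,
        np.concatenate(locs) if locs else np.empty(0, dtype=np.int64),
        np.concatenate(slots) if slots else np.empty(0, dtype=np.int64),
        slot_layout,
        region_layout,
        slot_base,
    )


def _assemble(
    genome: GenomeSequence,
    regions: list[SyntheticRegion],
    k: int,
    epsilon: int,
    mappable_slots: np.ndarray,
    slot_layout: dict[str, tuple[int, int]],
    region_layout: list[tuple[int, int]],
) -> MappabilityTrack:
    vectors = {}
    for chrom in genome.chrom_names:
        base, n = slot_layout[chrom]
        vectors[chrom] = mappable_slots[base : base + n].copy()
        if n == 0 and genome.length(chrom) >= 1:
            warnings.warn(f"chromosome {chrom!r} shorter than k={k}; all-unmappable")
    for region, (base, n) in zip(regions, region_layout):
        region.unique_kmers = mappable_slots[base : base + n].copy()
    return MappabilityTrack(k=k, epsilon=epsilon, vectors=vectors)


# ---------------------------------------------------------------------------
# Accelerated computation (pigeonhole partitioning)


def compute_mappability(
    genome: GenomeSequence,
    regions: list[SyntheticRegion],
    k: int,
    epsilon: int,
    _block: int = 256,
) -> MappabilityTrack:
    """Compute the mappability track and fill region ``unique_kmers`` flags.

    Two k-mer occurrences at different locations within Hamming distance
    ``epsilon`` render each other unmappable; a k-mer is never compared
    against its own occurrence (forward and reverse-complement at the same
    location count as the same occurrence). K-mers containing N are
    unmappable and are excluded from being anyone's neighbor.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    matrix, locs, slots, slot_layout, region_layout, n_slots = _collect_occurrences(
        genome, regions, k
    )
    valid = ~(matrix == _N_BYTE).any(axis=1)
    ambiguous = np.zeros(len(matrix), dtype=bool)

    seg_bounds = np.linspace(0, k, epsilon + 2).astype(int)
    valid_idx = np.flatnonzero(valid)
    sub = matrix[valid_idx]
    sub_locs = locs[valid_idx]
    sub_query = slots[valid_idx] >= 0
    sub_amb = np.zeros(len(valid_idx), dtype=bool)

    for s0, s1 in zip(seg_bounds[:-1], seg_bounds[1:]):
        seg = np.ascontiguousarray(sub[:, s0:s1])
        keys = seg.view([("", np.uint8)] * (s1 - s0)).ravel()
        order = np.argsort(keys, kind="stable")
        sorted_keys = keys[order]
        boundaries = np.flatnonzero(sorted_keys[1:] != sorted_keys[:-1]) + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [len(order)]])
        for gs, ge in zip(starts, ends):
            if ge - gs < 2:
                continue
            members = order[gs:ge]
            queries = members[sub_query[members] & ~sub_amb[members]]
            if len(queries) == 0:
                continue
            tgt = sub[members]
            tgt_locs = sub_locs[members]
            for b0 in range(0, len(queries), _block):
                q = queries[b0 : b0 + _block]
                dist = (sub[q][:, None, :] != tgt[None, :, :]).sum(axis=2)
                hit = (dist <= epsilon) & (sub_locs[q][:, None] != tgt_locs[None, :])
                sub_amb[q] |= hit.any(axis=1)

    ambiguous[valid_idx] = sub_amb
    mappable = valid & ~ambiguous
    mappable_slots = np.zeros(n_slots, dtype=bool)
    is_query = slots >= 0
    mappable_slots[slots[is_query]] = mappable[is_query]
    return _assemble(
        genome, regions, k, epsilon, mappable_slots, slot_layout, region_layout
    )


# ---------------------------------------------------------------------------
# Brute-force oracle


def brute_force_mappability(
    genome: GenomeSequence,
    regions: list[SyntheticRegion],
    k: int,
    epsilon: int,
) -> MappabilityTrack:
    """Exhaustive all-pairs Hamming-distance mappability (test oracle).

    Identical contract to :func:`compute_mappability`; refuses inputs above
    ``BRUTE_FORCE_GUARD`` total bases.
    """
    total = sum(genome.length(c) for c in genome.chrom_names) + sum(
        len(r.sequence) for r in regions
    )
    if total > BRUTE_FORCE_GUARD:
        raise ValueError(f"brute-force oracle refuses inputs over {BRUTE_FORCE_GUARD} bases")
    if k < 2:
        raise ValueError("k must be >= 2")

    # Build occurrences with plain loops, independently of the fast path.
    target_kmers: list[str] = []
    target_locs: list[int] = []
    query_kmers: list[str] = []
    query_locs: list[int] = []
    query_slots: list[tuple] = []  # ("g", chrom, i) or ("r", region_idx, j)
    loc = 0
    for chrom in genome.chrom_names:
        seq = genome[chrom]
        for i in range(max(0, len(seq) - k + 1)):
            kmer = seq[i : i + k]
            target_kmers.append(kmer)
            target_locs.append(loc)
            target_kmers.append(reverse_complement(kmer))
            target_locs.append(loc)
            query_kmers.append(kmer)
            query_locs.append(loc)
            query_slots.append(("g", chrom, i))
            loc += 1
        if len(seq) < k:
            warnings.warn(f"chromosome {chrom!r} shorter than k={k}; all-unmappable")
    for ridx, region in enumerate(regions):
        seq = region.sequence
        for j in range(max(0, len(seq) - k + 1)):
            kmer = seq[j : j + k]
            target_kmers.append(kmer)
            target_locs.append(loc)
            target_kmers.append(reverse_complement(kmer))
            target_locs.append(loc)
            query_kmers.append(kmer)
            query_locs.append(loc)
            query_slots.append(("r", ridx, j))
            loc += 1

    tmat = np.array([list(s.encode()) for s in target_kmers], dtype=np.uint8).reshape(
        len(target_kmers), k
    ) if target_kmers else np.empty((0, k), np.uint8)
    qmat = np.array([list(s.encode()) for s in query_kmers], dtype=np.uint8).reshape(
        len(query_kmers), k
    ) if query_kmers else np.empty((0, k), np.uint8)
    tlocs = np.array(target_locs, dtype=np.int64)
    qlocs = np.array(query_locs, dtype=np.int64)
    t_valid = ~(tmat == _N_BYTE).any(axis=1)
    q_valid = ~(qmat == _N_BYTE).any(axis=1)
    tmat_v = tmat[t_valid]
    tlocs_v = tlocs[t_valid]

    mappable = np.zeros(len(qmat), dtype=bool)
    block = 128
    for b0 in range(0, len(qmat), block):
        b1 = min(b0 + block, len(qmat))
        dist = (qmat[b0:b1, None, :] != tmat_v[None, :, :]).sum(axis=2)
        neighbor = (dist <= epsilon) & (qlocs[b0:b1, None] != tlocs_v[None, :])
        mappable[b0:b1] = ~neighbor.any(axis=1)
    mappable &= q_valid

    vectors = {
        chrom: np.zeros(max(0, genome.length(chrom) - k + 1), dtype=bool)
        for chrom in genome.chrom_names
    }
    for region in regions:
        region.unique_kmers = np.zeros(region.kmer_count(k), dtype=bool)
    for slot, m in zip(query_slots, mappable):
        kind, a, b = slot
        if kind == "g":
            vectors[a][b] = m
        else:
            regions[a].unique_kmers[b] = m
    return MappabilityTrack(k=k, epsilon=epsilon, vectors=vectors)


# ---------------------------------------------------------------------------
# Per-gene mappable-base counting


def count_mappable_bases(
    consensus: ConsensusGeneModel,
    track: MappabilityTrack,
    regions: list[SyntheticRegion] | None = None,
) -> MappableBaseCount:
    """Count consensus positions that are mappable.

    A position counts as mappable iff (1) it is covered by at least one
    mappable k-mer window in the genome track, or (2) it falls within the
    genomic provenance of a unique synthetic-region k-mer (the
    spliced-read clause).
    """
    if consensus.chrom not in track.vectors:
        raise KeyError(f"chromosome {consensus.chrom!r} absent from mappability track")
    base_vec = track.base_cover(consensus.chrom)
    junction_vec = np.zeros(len(base_vec), dtype=bool)
    k = track.k
    for region in regions or []:
        if region.chrom != consensus.chrom or region.unique_kmers is None:
            continue
        for j in np.flatnonzero(region.unique_kmers):
            pos = region.genome_pos[j : j + k]
            junction_vec[pos[(pos >= 0) & (pos < len(junction_vec))]] = True
    covered = base_vec | junction_vec
    mappable = sum(int(covered[s:e].sum()) for s, e in consensus.intervals)
    total = consensus.n_positions
    return MappableBaseCount(consensus.gene_id, mappable, total)


def write_base_count_report(counts: list[MappableBaseCount], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tmappable_bases\tconsensus_bases\tfraction\n")
        for c in counts:
            fh.write(
                f"{c.gene_id}\t{c.mappable_bases}\t{c.total_consensus_bases}\t"
                f"{c.mappability_fraction:.6g}\n"
            )


# ---------------------------------------------------------------------------
# BED I/O


def write_mappability_bed(track: MappabilityTrack, path: str | Path) -> None:
    """Write maximal runs of mappable k-mer start positions as BED intervals.

    The track line records k and epsilon; per-chromosome vector lengths are
    kept in header comments so the round trip is lossless.
    """
    with open(path, "w") as fh:
        fh.write(f'track type=mappability k={track.k} epsilon={track.epsilon}\n')
        for chrom, vec in track.vectors.items():
            fh.write(f"#chrom\t{chrom}\t{len(vec)}\n")
        for chrom, vec in track.vectors.items():
            if len(vec) == 0:
                continue
            padded = np.concatenate([[False], vec, [False]])
            diff = np.diff(padded.astype(np.int8))
            starts = np.flatnonzero(diff == 1)
            ends = np.flatnonzero(diff == -1)
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\n")


def load_mappability_bed(path: str | Path) -> MappabilityTrack:
    k = epsilon = None
    vectors: dict[str, np.ndarray] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("track"):
                fields = dict(
                    f.split("=", 1) for f in line.split() if "=" in f
                )
                k = int(fields.get("k", -1))
                epsilon = int(fields.get("epsilon", -1))
            elif line.startswith("#chrom"):
                _, chrom, n = line.split("\t")
                vectors[chrom] = np.zeros(int(n), dtype=bool)
            elif line:
                chrom, s, e = line.split("\t")
                if chrom not in vectors:
                    raise ValueError(f"BED interval for undeclared chrom {chrom!r}")
                vectors[chrom][int(s) : int(e)] = True
    if k is None or k < 0 or epsilon is None or epsilon < 0:
        raise ValueError("mappability BED lacks k/epsilon header metadata")
    return MappabilityTrack(k=k, epsilon=epsilon, vectors=vectors)
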