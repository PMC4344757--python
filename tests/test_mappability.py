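"""Mappability track computation, synthetic regions, base counting, BED I/O."""

import numpy as np
import pytest

from pseudoquant import (
    Exon,
    GeneModel,
    GenomeSequence,
    brute_force_mappability,
    build_consensus_model,
    build_synthetic_regions,
    compute_mappability,
    count_mappable_bases,
    load_mappability_bed,
    write_mappability_bed,
)
from pseudoquant.annotations import reverse_complement
from pseudoquant.mappability import BRUTE_FORCE_GUARD

from conftest import random_genome


def _gene(chrom, exons, strand="+", gene_id="G1"):
    chain = [Exon(chrom, s, e, strand) for s, e in exons]
    if strand == "-":
        chain = chain[::-1]
    return GeneModel(gene_id, "coding", transcripts={f"{gene_id}.t1": chain})


# ---------------------------------------------------------------------------
# Synthetic regions


def test_synthetic_region_concatenates_donor_and_acceptor():
    #        donor ends AACC          acceptor begins GGTT
    seq = "TTTT" + "GTAACC" + "CACACA" + "GGTTAG" + "TTTT"
    genome = GenomeSequence(["c"], {"c": seq})
    gene = _gene("c", [(4, 10), (16, 22)])
    (region,) = build_synthetic_regions([gene], genome, k=5)
    assert region.sequence == "AACC" + "GGTT"
    assert len(region.sequence) == 2 * (5 - 1)
    assert region.kmer_count(5) == 4  # four junction-crossing 5-mers
    assert not region.truncated


def test_minus_strand_region_is_reverse_complement_of_plus_extraction():
    genome = random_genome(3, 600)
    plus = _gene("c1", [(100, 200), (300, 400)], "+")
    minus = _gene("c1", [(100, 200), (300, 400)], "-")
    (rp,) = build_synthetic_regions([plus], genome, k=12)
    (rm,) = build_synthetic_regions([minus], genome, k=12)
    assert rm.sequence == reverse_complement(rp.sequence)
    # provenance runs through the same genomic bases in opposite order
    assert sorted(rm.genome_pos) == sorted(rp.genome_pos)


def test_single_exon_transcripts_produce_no_regions(small_genome):
    gene = _gene("c1", [(100, 400)])
    assert build_synthetic_regions([gene], small_genome, k=10) == []


def test_short_exon_region_truncated_not_padded():
    genome = random_genome(5, 300)
    gene = _gene("c1", [(10, 15), (100, 200)])  # 5-base donor, k-1 = 9
    (region,) = build_synthetic_regions([gene], genome, k=10)
    assert region.truncated
    assert len(region.sequence) == 5 + 9
    assert region.boundary_offset == 5


def test_every_junction_crossing_kmer_occurs_in_region(small_genome):
    k = 9
    gene = _gene("c1", [(50, 200), (400, 600), (800, 900)])
    regions = build_synthetic_regions([gene], small_genome, k)
    tx = gene.transcript_sequence("G1.t1", small_genome)
    # junction positions in transcript coordinates
    boundaries = [150, 350]
    region_kmers = {
        r.sequence[j : j + k]
        for r in regions
        for j in range(r.kmer_count(k))
    }
    for b in boundaries:
        for p in range(b - k + 1, b):
            assert tx[p : p + k] in region_kmers


# ---------------------------------------------------------------------------
# Track computation


def test_all_distinct_kmers_are_mappable():
    # a sequence whose 4-mers are all unique and pairwise >2 apart is fully
    # mappable at epsilon 0; verified directly via the oracle
    genome = random_genome(17, 400)
    track = compute_mappability(genome, [], 15, 0)
    oracle = brute_force_mappability(genome, [], 15, 0)
    assert np.array_equal(track.vectors["c1"], oracle.vectors["c1"])
    assert track.vectors["c1"].all()  # random 400-mer: 15-mers unique


def test_exact_duplicate_block_is_unmappable_at_any_epsilon():
    rng = np.random.default_rng(0)
    block = "".join(rng.choice(list("ACGT"), 30))
    filler1 = "".join(rng.choice(list("ACGT"), 100))
    filler2 = "".join(rng.choice(list("ACGT"), 100))
    genome = GenomeSequence(["c"], {"c": filler1 + block + filler2 + block})
    for eps in (0, 2):
        track = compute_mappability(genome, [], 30, eps)
        vec = track.vectors["c"]
        assert not vec[100]  # first copy start
        assert not vec[230]  # second copy start


def test_self_exclusion_unique_kmer_is_mappable():
    # distance 0 to itself must not disqualify a unique k-mer
    genome = GenomeSequence(["c"], {"c": "ACGTACCGGTTAAGCTTGCA"})
    track = compute_mappability(genome, [], 20, 0)
    assert track.vectors["c"].all()


def test_kmers_containing_n_are_unmappable_and_not_neighbors():
    rng = np.random.default_rng(2)
    base = "".join(rng.choice(list("ACGT"), 60))
    genome = GenomeSequence(["c"], {"c": base[:30] + "N" + base[31:]})
    track = compute_mappability(genome, [], 10, 0)
    vec = track.vectors["c"]
    for i in range(21, 31):  # windows covering the N
        assert not vec[i]


def test_epsilon_monotonicity_on_random_genomes():
    for seed in range(4):
        genome = random_genome(seed, 500)
        prev = None
        for eps in (0, 1, 2):
            vec = compute_mappability(genome, [], 10, eps).vectors["c1"]
            if prev is not None:
                assert not (vec & ~prev).any()  # mappable set shrinks
            prev = vec


def test_appending_duplicate_substring_never_increases_mappability():
    genome = random_genome(23, 300)
    k = 12
    base_vec = compute_mappability(genome, [], k, 1).vectors["c1"]
    seq = genome["c1"]
    for start in (0, 100, 250):
        extended = GenomeSequence(["c1"], {"c1": seq + seq[start : start + k]})
        vec = compute_mappability(extended, [], k, 1).vectors["c1"]
        assert vec[: len(base_vec)].sum() <= base_vec.sum()


def test_fast_path_matches_oracle_with_regions():
    genome = random_genome(31, 900)
    gene = _gene("c1", [(100, 300), (500, 700)], "-")
    for k, eps in ((8, 1), (15, 2), (25, 0)):
        regions_a = build_synthetic_regions([gene], genome, k)
        regions_b = build_synthetic_regions([gene], genome, k)
        fast = compute_mappability(genome, regions_a, k, eps)
        slow = brute_force_mappability(genome, regions_b, k, eps)
        assert np.array_equal(fast.vectors["c1"], slow.vectors["c1"]), (k, eps)
        assert np.array_equal(regions_a[0].unique_kmers, regions_b[0].unique_kmers)


def test_brute_force_refuses_oversized_input():
    big = GenomeSequence(["c"], {"c": "A" * (BRUTE_FORCE_GUARD + 1)})
    with pytest.raises(ValueError, match="refuses"):
        brute_force_mappability(big, [], 50, 0)


# ---------------------------------------------------------------------------
# Mappable-base counting


def test_fully_mappable_single_exon_gene_counts_all_bases():
    genome = random_genome(41, 1500)
    gene = _gene("c1", [(200, 1200)])
    track = compute_mappability(genome, [], 25, 0)
    count = count_mappable_bases(build_consensus_model(gene), track, [])
    assert count.total_consensus_bases == 1000
    assert count.mappable_bases == 1000
    assert count.mappability_fraction == 1.0


def test_gene_inside_duplicated_block_has_zero_mappable_bases():
    rng = np.random.default_rng(6)
    block = "".join(rng.choice(list("ACGT"), 400))
    pad = "".join(rng.choice(list("ACGT"), 200))
    k = 30
    genome = GenomeSequence(["c"], {"c": pad + block + pad[::-1] + block + pad})
    gene = _gene("c", [(200 + k, 600 - k)])  # interior of the first copy
    track = compute_mappability(genome, [], k, 0)
    count = count_mappable_bases(build_consensus_model(gene), track, [])
    assert count.mappable_bases == 0


def test_junction_only_distinctiveness_counts_via_spliced_clause():
    # two-exon gene duplicated as a contiguous (junction-less) block: exonic
    # sequence is ambiguous everywhere except across the splice junction
    rng = np.random.default_rng(8)
    k = 16
    ex1 = "".join(rng.choice(list("ACGT"), 60))
    ex2 = "".join(rng.choice(list("ACGT"), 60))
    intron = "".join(rng.choice(list("ACGT"), 50))
    pad = "".join(rng.choice(list("ACGT"), 80))
    # genome: gene (ex1-intron-ex2), then an unspliced copy of each exon
    seq = pad + ex1 + intron + ex2 + pad[::-1] + ex1 + "TT" + ex2 + pad
    genome = GenomeSequence(["c"], {"c": seq})
    g_start = len(pad)
    gene = _gene("c", [(g_start, g_start + 60), (g_start + 110, g_start + 170)])
    regions = build_synthetic_regions([gene], genome, k)
    track = compute_mappability(genome, regions, k, 0)
    count_without = count_mappable_bases(build_consensus_model(gene), track, [])
    count_with = count_mappable_bases(build_consensus_model(gene), track, regions)
    assert regions[0].unique_kmers.any()
    assert count_with.mappable_bases > count_without.mappable_bases
    # hand enumeration: unique junction k-mers cover the union of their
    # provenance bases
    expected_extra = set()
    for j in np.flatnonzero(regions[0].unique_kmers):
        expected_extra.update(regions[0].genome_pos[j : j + k])
    base = track.base_cover("c")
    extra = {p for p in expected_extra if not base[p]}
    assert count_with.mappable_bases == count_without.mappable_bases + len(extra)


def test_gene_on_missing_chrom_is_an_error(small_genome):
    gene = _gene("c1", [(0, 100)])
    track = compute_mappability(small_genome, [], 10, 0)
    track.vectors.pop("c1")
    track.vectors["other"] = np.ones(10, dtype=bool)
    with pytest.raises(KeyError):
        count_mappable_bases(build_consensus_model(gene), track, [])


# ---------------------------------------------------------------------------
# BED round trip


def test_bed_round_trip_is_lossless(tmp_path):
    genome = random_genome(51, 700)
    track = compute_mappability(genome, [], 12, 1)
    path = tmp_path / "map.bed"
    write_mappability_bed(track, path)
    back = load_mappability_bed(path)
    assert back.k == track.k and back.epsilon == track.epsilon
    assert np.array_equal(back.vectors["c1"], track.vectors["c1"])


def test_bed_intervals_are_maximal_runs(tmp_path):
    track_vec = np.array([1, 1, 0, 1, 0, 0, 1, 1, 1], dtype=bool)
    from pseudoquant.mappability import MappabilityTrack

    track = MappabilityTrack(k=5, epsilon=0, vectors={"c": track_vec})
    path = tmp_path / "map.bed"
    write_mappability_bed(track, path)
    lines = [
        l for l in path.read_text().splitlines() if not l.startswith(("track", "#"))
    ]
    assert lines == ["c\t0\t2", "c\t3\t4", "c\t6\t9"]


def test_bed_missing_header_is_an_error(tmp_path):
    path = tmp_path / "bad.bed"
    path.write_text("#chrom\tc\t9\nc\t0\t5\n")
    with pytest.raises(ValueError, match="header"):
        load_mappability_bed(path)
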