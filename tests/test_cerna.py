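"""Pseudo-3' UTR annotation, seed matching, correlation and permutation screen."""

import numpy as np
import pandas as pd
import pytest

from pseudoquant import (
    Exon,
    GeneModel,
    UTRSet,
    annotate_pseudo3utr,
    bh_adjust,
    extract_context,
    find_seed_matches,
    identify_cerna_triples,
    local_align,
    pairwise_correlation,
    permutation_null,
    read_blast_tabular,
    shared_mirnas,
    simulate_cerna_expression,
    top_expressed_mirnas,
)
from pseudoquant.annotations import reverse_complement
from pseudoquant.cerna import CorrelationRecord, SeedMatchSite

from conftest import random_genome


def _rand_seq(seed, n):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), n))


# ---------------------------------------------------------------------------
# Context extraction


def test_context_includes_flanks_and_clips_at_edges():
    genome = random_genome(1, 50_000)
    gene = GeneModel(
        "P", "pseudogene", pseudo_class="processed",
        transcripts={"t": [Exon("c1", 20_000, 21_000, "+")]},
    )
    ctx = extract_context(gene, genome, flank=10_000)
    assert len(ctx.sequence) == 21_000
    assert not ctx.clipped_left and not ctx.clipped_right
    near_edge = GeneModel(
        "P2", "pseudogene", pseudo_class="processed",
        transcripts={"t": [Exon("c1", 5_000, 5_500, "+")]},
    )
    ctx2 = extract_context(near_edge, genome, flank=10_000)
    assert ctx2.clipped_left and ctx2.offset == 0
    assert len(ctx2.sequence) == 15_500


def test_context_position_round_trip():
    genome = random_genome(2, 30_000)
    gene = GeneModel(
        "P", "pseudogene", pseudo_class="processed",
        transcripts={"t": [Exon("c1", 12_000, 12_400, "+")]},
    )
    ctx = extract_context(gene, genome, flank=5_000)
    for local in (0, 100, len(ctx.sequence) - 1):
        gpos = ctx.to_genomic(local)
        assert ctx.sequence[local] == genome["c1"][gpos]
        assert ctx.to_local(gpos) == local


# ---------------------------------------------------------------------------
# Local alignment and pseudo-3' UTR annotation


def test_identical_sequences_align_full_length():
    seq = _rand_seq(3, 300)
    (aln,) = local_align(seq, seq)
    assert aln.subject_interval == (0, 300)
    assert aln.query_interval == (0, 300)
    assert aln.evalue < 1e-50


def test_unrelated_sequences_fail_significance():
    utr = UTRSet("G", [_rand_seq(4, 300)])
    assert annotate_pseudo3utr(utr, _rand_seq(5, 2000)) is None


def test_diverged_copy_recovered_with_high_overlap():
    rng = np.random.default_rng(6)
    utr_seq = _rand_seq(7, 400)
    mutated = list(utr_seq)
    for i in rng.choice(400, 20, replace=False):  # 5% divergence
        mutated[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[i]]
    ctx = _rand_seq(8, 1500)
    subject = ctx[:700] + "".join(mutated) + ctx[700:]
    res = annotate_pseudo3utr(UTRSet("G", [utr_seq]), subject, pseudogene_id="P")
    lo, hi = res.interval
    overlap = max(0, min(hi, 1100) - max(lo, 700))
    assert overlap / 400 >= 0.9


def test_longest_significant_alignment_wins():
    utr_a = _rand_seq(9, 150)
    utr_b = _rand_seq(10, 220)
    ctx = _rand_seq(11, 1000)
    subject = ctx[:200] + utr_a + ctx[200:500] + utr_b + ctx[500:]
    res = annotate_pseudo3utr(UTRSet("G", [utr_a, utr_b]), subject)
    assert res.alignment_length == 220
    assert res.interval == (200 + 300 + 150, 200 + 300 + 150 + 220)


def test_blast_tabular_reader_converts_coordinates(tmp_path):
    path = tmp_path / "hits.tsv"
    path.write_text(
        "q1\ts1\t98.5\t200\t3\t0\t1\t200\t501\t700\t1e-50\t370\n"
        "q1\ts1\t90.0\t50\t5\t0\t10\t59\t900\t851\t1e-10\t80\n"
    )
    hits = read_blast_tabular(path)["q1"]
    assert hits[0].query_interval == (0, 200)
    assert hits[0].subject_interval == (500, 700)
    assert hits[1].subject_interval == (850, 900)  # reverse hit normalised


# ---------------------------------------------------------------------------
# Seed matching


def test_seed_match_site_types_classified():
    mirna = ("m1", "UGAGGUAGUAGGUUGUAUAGUU")  # seed 2-8 = GAGGUAG
    core = reverse_complement("GAGGTA")  # TACCTC
    m8c = reverse_complement("G")  # C
    utr = (
        "TTTT" + m8c + core + "A"  # 8mer
        + "GGGG" + m8c + core + "G"  # 7mer-m8
        + "GGGG" + "T" + core + "A"  # 7mer-A1
        + "GGGG" + "T" + core + "G"  # 6mer
        + "TTTT"
    )
    sites = find_seed_matches(utr, [mirna])
    assert [s.site_type for s in sites] == ["8mer", "7mer-m8", "7mer-A1", "6mer"]


def test_no_complementary_sites_gives_empty_list():
    # UTR of A/T only cannot complement a G/C-rich seed
    sites = find_seed_matches("ATATATATATATATAT", [("m1", "GCGCGCGCGC")])
    assert sites == []


def test_short_mirna_skipped_with_warning():
    with pytest.warns(UserWarning, match="shorter"):
        assert find_seed_matches("ACGTACGT", [("tiny", "ACGU")]) == []


def _brute_force_sites(utr, mirnas):
    """Independent oracle: test every UTR position against each explicit
    site pattern, longest class first."""
    found = []
    for mid, mat in mirnas:
        mat = mat.upper().replace("U", "T")
        if len(mat) < 8:
            continue
        rc78 = reverse_complement(mat[1:8])  # 7 nt, rc of bases 2-8
        rc27 = reverse_complement(mat[1:7])  # 6 nt, rc of bases 2-7
        patterns = [
            ("8mer", rc78 + "A"),
            ("7mer-m8", rc78),
            ("7mer-A1", rc27 + "A"),
            ("6mer", rc27),
        ]
        claimed = set()
        for site_type, pat in patterns:
            for p in range(len(utr) - len(pat) + 1):
                if utr[p : p + len(pat)] != pat:
                    continue
                core = p + (1 if site_type in ("8mer", "7mer-m8") else 0)
                if core in claimed:
                    continue
                claimed.add(core)
                found.append((mid, site_type, p))
    return sorted(found)


def test_seed_matches_equal_brute_force_scan():
    rng = np.random.default_rng(12)
    for trial in range(30):
        utr = "".join(rng.choice(list("ACGT"), 300))
        mirnas = [
            (f"m{j}", "".join(rng.choice(list("ACGU"), 21))) for j in range(5)
        ]
        got = sorted(
            (s.mirna_id, s.site_type, s.position)
            for s in find_seed_matches(utr, mirnas)
        )
        assert got == _brute_force_sites(utr, mirnas), trial


def test_shared_mirnas_is_site_intersection():
    ps = [SeedMatchSite("m1", "6mer", 0), SeedMatchSite("m2", "8mer", 5)]
    gs = [SeedMatchSite("m2", "7mer-m8", 1), SeedMatchSite("m3", "6mer", 2)]
    assert shared_mirnas(ps, gs) == {"m2"}
    assert shared_mirnas([], gs) == set()
    assert shared_mirnas(ps, []) == set()


# ---------------------------------------------------------------------------
# Top expressed miRNAs


def test_top_mirnas_ranked_by_mean_expression():
    mat = pd.DataFrame(
        {"s1": [10, 8, 6, 4, 2], "s2": [10, 8, 6, 4, 2]},
        index=["a", "b", "c", "d", "e"],
    )
    assert top_expressed_mirnas(mat, 3) == ["a", "b", "c"]
    assert top_expressed_mirnas(mat, 5) == ["a", "b", "c", "d", "e"]


def test_top_mirnas_ties_included_and_deterministic():
    mat = pd.DataFrame({"s1": [5.0, 5.0, 5.0, 1.0]}, index=["z", "a", "m", "q"])
    top = top_expressed_mirnas(mat, 2)
    assert top == ["a", "m", "z"]  # all tied at the cutoff, id-ordered
    with pytest.raises(ValueError):
        top_expressed_mirnas(mat, 9)


# ---------------------------------------------------------------------------
# Correlation records


def _expr(rows: dict, n=40) -> pd.DataFrame:
    return pd.DataFrame(rows, index=[f"s{i}" for i in range(n)]).T


def test_identical_rows_correlate_perfectly():
    rng = np.random.default_rng(13)
    x = rng.uniform(2, 50, 40)
    a = _expr({"A": x})
    b = _expr({"B": x})
    (rec,) = pairwise_correlation(a, b, [("A", "B")])
    assert rec.r == pytest.approx(1.0)
    assert not rec.excluded


def test_pair_below_presence_threshold_excluded():
    # co-present in only 19 of 40 samples
    x = np.concatenate([np.full(19, 10.0), np.full(21, 0.1)])
    y = np.full(40, 10.0)
    (rec,) = pairwise_correlation(_expr({"A": x}), _expr({"B": y}), [("A", "B")])
    assert rec.n_samples_used == 19
    assert rec.excluded


def test_missing_id_is_an_error():
    a = _expr({"A": np.ones(40)})
    with pytest.raises(KeyError):
        pairwise_correlation(a, a, [("A", "NOPE")])


def test_correlation_estimates_calibrated_on_bivariate_normal():
    rng = np.random.default_rng(14)
    true_r, n, reps = 0.5, 200, 300
    hits = 0
    for _ in range(reps):
        x = rng.normal(size=n)
        y = true_r * x + np.sqrt(1 - true_r**2) * rng.normal(size=n)
        a = _expr({"A": 2.0 ** (5 + x)}, n)
        b = _expr({"B": 2.0 ** (5 + y)}, n)
        (rec,) = pairwise_correlation(a, b, [("A", "B")])
        hits += abs(rec.r - true_r) < 0.15
    assert hits / reps >= 0.95


def test_anticorrelation_p_value_direction():
    rng = np.random.default_rng(15)
    x = rng.normal(size=100)
    y = -0.8 * x + 0.6 * rng.normal(size=100)
    a = _expr({"A": 2.0 ** (5 + x)}, 100)
    b = _expr({"B": 2.0 ** (5 + y)}, 100)
    (neg,) = pairwise_correlation(a, b, [("A", "B")], direction="negative")
    (pos,) = pairwise_correlation(a, b, [("A", "B")], direction="positive")
    assert neg.p_one_sided < 1e-6
    assert pos.p_one_sided > 0.99


# ---------------------------------------------------------------------------
# BH adjustment


def test_bh_hand_worked_example():
    # step-up: q3 = 0.03; q2 = min(0.03, 0.02*3/2) = 0.03; q1 = min(q2, 0.01*3)
    q = bh_adjust([0.01, 0.02, 0.03])
    assert np.allclose(q, [0.03, 0.03, 0.03])


def test_bh_edge_cases():
    assert bh_adjust([0.2]) == pytest.approx([0.2])
    assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])


def test_bh_invariant_under_input_permutation():
    rng = np.random.default_rng(16)
    p = rng.uniform(size=25)
    perm = rng.permutation(25)
    q = bh_adjust(p)
    q_perm = bh_adjust(p[perm])
    assert np.allclose(q[perm], q_perm)


# ---------------------------------------------------------------------------
# Permutation null


def test_observed_zero_gives_p_one():
    rng = np.random.default_rng(17)
    a = _expr({f"A{i}": 2.0 ** (5 + rng.normal(size=40)) for i in range(10)})
    b = _expr({f"B{i}": 2.0 ** (5 + rng.normal(size=40)) for i in range(10)})
    res = permutation_null(
        a, b, [(f"A{i}", f"B{i}") for i in range(10)],
        n_permutations=100, threshold=0.99, seed=0,
    )
    assert res.observed_count == 0
    assert res.empirical_p == 1.0


def test_permutation_null_reproducible_and_calibrated():
    rng = np.random.default_rng(18)
    pairs = [(f"A{i}", f"B{i}") for i in range(50)]
    a = _expr({p: 2.0 ** (5 + rng.normal(size=60)) for p, _ in pairs}, 60)
    b = _expr({q: 2.0 ** (5 + rng.normal(size=60)) for _, q in pairs}, 60)
    r1 = permutation_null(a, b, pairs, n_permutations=200, threshold=0.3, seed=5)
    r2 = permutation_null(a, b, pairs, n_permutations=200, threshold=0.3, seed=5)
    assert r1.null_counts == r2.null_counts  # bit-reproducible
    # independent data: observed count lies within the null range
    assert min(r1.null_counts) <= r1.observed_count <= max(r1.null_counts)


def test_planted_correlation_is_detected_as_significant():
    rng = np.random.default_rng(19)
    n = 100
    rows_a, rows_b, pairs = {}, {}, []
    for i in range(100):
        x = rng.normal(size=n)
        if i < 30:  # planted r ~ 0.8
            y = 0.8 * x + 0.6 * rng.normal(size=n)
        else:
            y = rng.normal(size=n)
        rows_a[f"A{i}"] = 2.0 ** (5 + x)
        rows_b[f"B{i}"] = 2.0 ** (5 + y)
        pairs.append((f"A{i}", f"B{i}"))
    res = permutation_null(
        _expr(rows_a, n), _expr(rows_b, n), pairs,
        n_permutations=1000, threshold=0.3, direction="positive", seed=7,
    )
    assert res.empirical_p <= 0.001


# ---------------------------------------------------------------------------
# Triple identification


def _screen(gene, pseudo, mirna, truth, **kwargs):
    pg_pairs = sorted(truth.shared_mirnas)
    pm_pairs = sorted({(p, m) for (p, _), ms in truth.shared_mirnas.items() for m in ms})
    gm_pairs = sorted({(g, m) for (_, g), ms in truth.shared_mirnas.items() for m in ms})
    pg = pairwise_correlation(pseudo, gene, pg_pairs, direction="positive")
    pm = pairwise_correlation(pseudo, mirna, pm_pairs, direction="negative")
    gm = pairwise_correlation(gene, mirna, gm_pairs, direction="negative")
    return identify_cerna_triples(pg, pm, gm, truth.shared_mirnas, **kwargs)


def test_planted_triple_recovered_among_nulls():
    gene, pseudo, mirna, truth = simulate_cerna_expression(
        n_samples=200, n_triples=1, n_null_pairs=9, seed=23
    )
    triples = _screen(gene, pseudo, mirna, truth)
    assert [(t.pseudogene_id, t.parent_gene_id, t.mirna_id) for t in triples] == list(
        truth.planted_triples
    )


def test_gene_correlation_threshold_is_strict():
    rec_eq = CorrelationRecord("P", "G", r=0.3, n_samples_used=100, p_one_sided=0.5)
    pm = CorrelationRecord("P", "m", r=-0.5, n_samples_used=100, p_one_sided=1e-8)
    gm = CorrelationRecord("G", "m", r=-0.5, n_samples_used=100, p_one_sided=1e-8)
    triples = identify_cerna_triples([rec_eq], [pm], [gm], {("P", "G"): {"m"}})
    assert triples == []  # r = 0.3 exactly does not pass r > 0.3


def test_no_shared_mirna_never_reported():
    gene, pseudo, mirna, truth = simulate_cerna_expression(
        n_samples=200, n_triples=2, n_null_pairs=0, seed=29
    )
    triples = _screen(gene, pseudo, mirna, TruthlikeEmpty())
    assert triples == []


class TruthlikeEmpty:
    shared_mirnas: dict = {}
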