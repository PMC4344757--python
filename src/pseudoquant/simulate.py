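"""Synthetic genomes, reads and expression matrices with known truth.

The generator produces every input the pipeline consumes: a genome carrying
parent genes plus processed (intron-less, junction-spanning), duplicated and
unitary pseudogenes at controlled sequence divergence; subject-genome SNPs
applied to the expressed copies; uniform-coverage reads with base-call
errors, aligned exhaustively by an ideal aligner; and expression matrices
with planted pseudogene-gene-miRNA correlation structure for the ceRNA
screen. Every generator is fully deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .annotations import (
    Exon,
    GeneModel,
    GenomeSequence,
    reverse_complement,
)
from .mappability import SyntheticRegion, build_synthetic_regions, _seq_bytes, _windows
from .quantify import Alignment, ReadAlignmentRecord

__all__ = [
    "SimulationConfig",
    "PseudogenePlan",
    "TruthTable",
    "ReadSet",
    "simulate_genome",
    "simulate_reads",
    "enumerate_alignments",
    "misalignment_scenario",
    "rpkum_robustness_simulation",
    "simulate_cerna_expression",
    "write_fastq",
    "write_alignments_tsv",
    "load_alignments_tsv",
    "write_sam",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class PseudogenePlan:
    """How to derive one pseudogene from a parent gene."""

    parent_index: int
    pseudo_class: str = "processed"  # processed | duplicated | unitary
    divergence_rate: float = 0.05
    include_utr: bool = True


@dataclass
class SimulationConfig:
    seed: int = 0
    n_parent_genes: int = 3
    pseudogene_plans: list[PseudogenePlan] = field(default_factory=list)
    read_length: int = 50
    error_rate: float = 0.005
    subject_snps_per_gene: int = 0
    library_size: int = 1_000_000
    rpkm_range: tuple[float, float] = (20.0, 200.0)
    pseudogene_rpkm: float = 0.0
    exon_count_range: tuple[int, int] = (2, 5)
    exon_length_range: tuple[int, int] = (150, 400)
    intron_length_range: tuple[int, int] = (80, 200)
    gap_length_range: tuple[int, int] = (300, 800)
    utr_length: int = 200

    def __post_init__(self) -> None:
        if not (0.0 <= self.error_rate <= 1.0):
            raise ValueError("error_rate must be in [0, 1]")
        for plan in self.pseudogene_plans:
            if not (0.0 <= plan.divergence_rate <= 1.0):
                raise ValueError("divergence_rate must be in [0, 1]")

    def to_json(self, path: str | Path) -> None:
        payload = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
            if k != "pseudogene_plans"
        }
        payload["pseudogene_plans"] = [p.__dict__ for p in self.pseudogene_plans]
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class TruthTable:
    """Ground truth carried alongside simulated data."""

    seed: int
    true_rpkm: dict[str, float] = field(default_factory=dict)
    read_origin: dict[str, tuple[str, int]] = field(default_factory=dict)
    subject_snps: dict[str, list[int]] = field(default_factory=dict)
    misaligned_reads: set[str] = field(default_factory=set)
    planted_triples: list[tuple[str, str, str]] = field(default_factory=list)
    shared_mirnas: dict[tuple[str, str], set[str]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "true_rpkm": self.true_rpkm,
            "read_origin": {k: list(v) for k, v in self.read_origin.items()},
            "subject_snps": self.subject_snps,
            "misaligned_reads": sorted(self.misaligned_reads),
            "planted_triples": [list(t) for t in self.planted_triples],
            "shared_mirnas": {
                f"{a}|{b}": sorted(v) for (a, b), v in self.shared_mirnas.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class ReadSet:
    """Simulated reads: per-read candidate alignments plus raw sequences."""

    records: list[ReadAlignmentRecord]
    sequences: dict[str, str]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Point-mutate each base independently with probability ``rate``."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def _mutate_at(rng: np.random.Generator, seq: str, positions: list[int]) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    for i in positions:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# Genome simulation


def simulate_genome(
    config: SimulationConfig,
) -> tuple[GenomeSequence, list[GeneModel], dict[str, tuple[str | None, str]], TruthTable]:
    """Random genome with parent genes and planned pseudogenes.

    Parent genes have 2-5 exons on alternating strands; processed
    pseudogenes are the parent's spliced transcript (junctions included)
    re-inserted with point divergence as a single exon; duplicated
    pseudogenes copy the parent's genomic span including introns and keep
    its exon structure; unitary pseudogenes are independent gene-like loci
    with no parent. Parents receive true RPKM levels drawn from
    ``config.rpkm_range``; pseudogenes receive ``config.pseudogene_rpkm``.
    """
    rng = np.random.default_rng(config.seed)
    chrom = "chrS"
    pieces: list[str] = []
    cursor = 0
    models: list[GeneModel] = []
    truth = TruthTable(seed=config.seed)

    def emit_gap() -> None:
        nonlocal cursor
        n = int(rng.integers(*config.gap_length_range))
        pieces.append(_random_seq(rng, n))
        cursor += n

    parent_spans: list[tuple[int, int]] = []
    for gi in range(config.n_parent_genes):
        emit_gap()
        strand = "+" if gi % 2 == 0 else "-"
        n_exons = int(rng.integers(config.exon_count_range[0], config.exon_count_range[1] + 1))
        exons: list[Exon] = []
        gene_start = cursor
        for ei in range(n_exons):
            if ei > 0:
                n_intron = int(rng.integers(*config.intron_length_range))
                pieces.append(_random_seq(rng, n_intron))
                cursor += n_intron
            n_exon = int(rng.integers(*config.exon_length_range))
            pieces.append(_random_seq(rng, n_exon))
            exons.append(Exon(chrom, cursor, cursor + n_exon, strand))
            cursor += n_exon
        parent_spans.append((gene_start, cursor))
        chain = exons if strand == "+" else exons[::-1]
        gene_id = f"GENE{gi:03d}"
        models.append(
            GeneModel(
                gene_id=gene_id,
                biotype="coding",
                transcripts={f"{gene_id}.t1": chain},
            )
        )
        truth.true_rpkm[gene_id] = float(rng.uniform(*config.rpkm_range))

    for pi, plan in enumerate(config.pseudogene_plans):
        emit_gap()
        pid = f"PSG{pi:03d}"
        if plan.pseudo_class == "unitary":
            n_exon = int(rng.integers(*config.exon_length_range))
            pieces.append(_random_seq(rng, n_exon))
            exon = Exon(chrom, cursor, cursor + n_exon, "+")
            cursor += n_exon
            models.append(
                GeneModel(
                    gene_id=pid,
                    biotype="pseudogene",
                    pseudo_class="unitary",
                    transcripts={f"{pid}.t1": [exon]},
                )
            )
        else:
            parent = models[plan.parent_index]
            genome_tmp = GenomeSequence([chrom], {chrom: "".join(pieces)})
            if plan.pseudo_class == "processed":
                tx = parent.transcript_sequence(
                    next(iter(parent.transcripts)), genome_tmp
                )
                if not plan.include_utr:
                    tx = tx[: max(1, len(tx) - config.utr_length)]
                seq = _mutate(rng, tx, plan.divergence_rate)
                pieces.append(seq)
                exon = Exon(chrom, cursor, cursor + len(seq), "+")
                cursor += len(seq)
                transcripts = {f"{pid}.t1": [exon]}
            else:  # duplicated: genomic copy, exon structure preserved
                span = parent_spans[plan.parent_index]
                src = "".join(pieces)[span[0] : span[1]]
                seq = _mutate(rng, src, plan.divergence_rate)
                offset = cursor - span[0]
                pieces.append(seq)
                cursor += len(seq)
                chain = [
                    Exon(chrom, e.start + offset, e.end + offset, e.strand)
                    for e in next(iter(parent.transcripts.values()))
                ]
                transcripts = {f"{pid}.t1": chain}
            models.append(
                GeneModel(
                    gene_id=pid,
                    biotype="pseudogene",
                    pseudo_class=plan.pseudo_class,
                    parent_gene_id=parent.gene_id,
                    transcripts=transcripts,
                )
            )
        truth.true_rpkm[pid] = float(config.pseudogene_rpkm)
    emit_gap()

    genome = GenomeSequence([chrom], {chrom: "".join(pieces)})
    parent_map = {
        m.gene_id: (m.parent_gene_id, m.pseudo_class)
        for m in models
        if m.biotype == "pseudogene"
    }
    return genome, models, parent_map, truth


# ---------------------------------------------------------------------------
# Ideal exhaustive aligner


def enumerate_alignments(
    sequences: dict[str, str],
    genome: GenomeSequence,
    regions: list[SyntheticRegion],
    max_mismatches: int = 2,
    _block: int = 128,
    _pos_chunk: int = 4096,
) -> dict[str, list[Alignment]]:
    """All alignments of each read within ``max_mismatches``, both strands.

    Direct alignments are found by exhaustive Hamming comparison against
    every genomic window; spliced alignments by comparison against every
    junction k-mer of the synthetic regions, translated back to two-block
    genomic coordinates. This is the idealised aligner: no heuristics, no
    missed hits.
    """
    read_ids = list(sequences)
    if not read_ids:
        return {}
    k = len(sequences[read_ids[0]])
    reads = np.vstack([_seq_bytes(sequences[r]) for r in read_ids])
    rc_reads = np.vstack(
        [_seq_bytes(reverse_complement(sequences[r])) for r in read_ids]
    )
    out: dict[str, list[Alignment]] = {r: [] for r in read_ids}

    targets: list[tuple[np.ndarray, object]] = []  # (windows, resolver)
    for chrom in genome.chrom_names:
        win = _windows(_seq_bytes(genome[chrom]), k)
        targets.append((win, ("g", chrom)))
    for region in regions:
        win = _windows(_seq_bytes(region.sequence), k)
        targets.append((win, ("r", region)))

    for b0 in range(0, len(reads), _block):
        b1 = min(b0 + _block, len(reads))
        batch_hits: list[set] = [set() for _ in range(b1 - b0)]
        for orient, mat in (("+", reads[b0:b1]), ("-", rc_reads[b0:b1])):
            for win, resolver in targets:
                for p0 in range(0, len(win), _pos_chunk):
                    p1 = min(p0 + _pos_chunk, len(win))
                    dist = (mat[:, None, :] != win[None, p0:p1, :]).sum(axis=2)
                    rows, cols = np.nonzero(dist <= max_mismatches)
                    for ri, ci in zip(rows, cols):
                        pos = int(p0 + ci)
                        kind = resolver[0]
                        if kind == "g":
                            batch_hits[ri].add(
                                (resolver[1], pos, ((pos, pos + k),), int(dist[ri, ci]))
                            )
                        else:
                            region = resolver[1]
                            gpos = np.sort(region.genome_pos[pos : pos + k])
                            gaps = np.flatnonzero(np.diff(gpos) > 1)
                            if len(gaps) != 1:
                                continue  # truncated/degenerate region window
                            g = gaps[0]
                            blocks = (
                                (int(gpos[0]), int(gpos[g]) + 1),
                                (int(gpos[g + 1]), int(gpos[-1]) + 1),
                            )
                            batch_hits[ri].add(
                                (region.chrom, int(gpos[0]), blocks, int(dist[ri, ci]))
                            )
        for ri, hits in enumerate(batch_hits):
            rid = read_ids[b0 + ri]
            # deduplicate by location; keep the smallest mismatch count
            best: dict[tuple, int] = {}
            for chrom, start, blocks, mm in hits:
                key = (chrom, start, blocks)
                if key not in best or mm < best[key]:
                    best[key] = mm
            out[rid] = [
                Alignment(chrom=key[0], start=key[1], blocks=key[2], mismatches=mm)
                for key, mm in sorted(best.items())
            ]
    return out


# ---------------------------------------------------------------------------
# Read simulation


def simulate_reads(
    genome: GenomeSequence,
    models: list[GeneModel],
    truth: TruthTable,
    config: SimulationConfig,
    max_mismatches: int = 2,
) -> tuple[ReadSet, TruthTable]:
    """Uniform-coverage reads from every expressed transcript.

    Per gene, the read count is Poisson with mean
    ``RPKM * (transcript_kb) * (library_size / 1e6)``; subject SNPs are
    applied to the expressed copy before reads are drawn; per-base errors
    are applied to each read. All candidate alignments within
    ``max_mismatches`` are pre-computed with the ideal aligner.
    """
    rng = np.random.default_rng(config.seed + 1)
    k = config.read_length
    sequences: dict[str, str] = {}
    for model in models:
        rpkm = truth.true_rpkm.get(model.gene_id, 0.0)
        if rpkm <= 0:
            continue
        tx_id = next(iter(model.transcripts))
        tx = model.transcript_sequence(tx_id, genome)
        if len(tx) < k:
            raise ValueError(f"transcript {tx_id!r} shorter than read length")
        if config.subject_snps_per_gene > 0:
            snp_pos = sorted(
                rng.choice(len(tx), size=config.subject_snps_per_gene, replace=False)
            )
            tx_subject = _mutate_at(rng, tx, snp_pos)
            truth.subject_snps[model.gene_id] = [int(p) for p in snp_pos]
        else:
            tx_subject = tx
        n_reads = rng.poisson(rpkm * (len(tx) / 1000.0) * config.library_size / 1e6)
        starts = rng.integers(0, len(tx) - k + 1, size=n_reads)
        for i, p in enumerate(starts):
            read = tx_subject[p : p + k]
            if config.error_rate > 0:
                read = _mutate(rng, read, config.error_rate)
            rid = f"{model.gene_id}:{i:06d}"
            sequences[rid] = read
            truth.read_origin[rid] = (model.gene_id, int(p))

    regions = build_synthetic_regions(models, genome, k)
    alignments = enumerate_alignments(sequences, genome, regions, max_mismatches)
    records = [
        ReadAlignmentRecord(read_id=rid, sample_id=f"sim{config.seed}", alignments=alignments[rid])
        for rid in sequences
    ]
    return ReadSet(records=records, sequences=sequences), truth


# ---------------------------------------------------------------------------
# Unique-misalignment showcase scenario


def misalignment_scenario(
    seed: int = 0, k: int = 50, n_reads: int = 300
) -> dict:
    """Gene/pseudogene pair one nucleotide apart; subject gene with 3 SNPs.

    The subject copy of the gene carries three clustered SNPs, one of which
    converts the divergent site to the pseudogene's base. Reads covering
    all three SNPs are then within two mismatches of the pseudogene only,
    so an ideal aligner reports them as uniquely aligned — to the wrong
    locus. The whole duplicated region is unmappable at epsilon >= 1, so
    the mappability filter removes every such read.

    Returns a dict with genome, models, parent_map, read set, truth and the
    scenario's read length.
    """
    rng = np.random.default_rng(seed)
    gene_len = 400
    background = _random_seq(rng, 1000)
    gene_seq = _random_seq(rng, gene_len)
    d = gene_len // 2  # divergent site
    # pseudogene: the duplicated block one nucleotide away from the gene,
    # plus a unique transcribed tail so the locus has mappable bases and a
    # well-defined (zero) RPKUM
    pseudo_tail = 100
    pseudo_seq = _mutate_at(rng, gene_seq, [d]) + _random_seq(rng, pseudo_tail)
    mid = _random_seq(rng, 1200)
    tail = _random_seq(rng, 1000)

    chrom = "chrS"
    gene_start = len(background)
    pseudo_start = gene_start + gene_len + len(mid)
    genome = GenomeSequence(
        [chrom], {chrom: background + gene_seq + mid + pseudo_seq + tail}
    )
    gene = GeneModel(
        gene_id="GENE000",
        biotype="coding",
        transcripts={"GENE000.t1": [Exon(chrom, gene_start, gene_start + gene_len, "+")]},
    )
    pseudo = GeneModel(
        gene_id="PSG000",
        biotype="pseudogene",
        pseudo_class="processed",
        parent_gene_id="GENE000",
        transcripts={
            "PSG000.t1": [
                Exon(chrom, pseudo_start, pseudo_start + gene_len + pseudo_tail, "+")
            ]
        },
    )
    models = [gene, pseudo]

    # subject gene: SNP at the divergent site (-> pseudogene base) plus two
    # more within one read length
    snp_positions = [d, d + 10, d + 20]
    subject = list(gene_seq)
    subject[d] = pseudo_seq[d]
    for p in snp_positions[1:]:
        choices = [b for b in "ACGT" if b != subject[p]]
        subject[p] = choices[int(rng.integers(len(choices)))]
    subject_seq = "".join(subject)

    truth = TruthTable(seed=seed, true_rpkm={"GENE000": 100.0, "PSG000": 0.0})
    truth.subject_snps["GENE000"] = snp_positions
    sequences: dict[str, str] = {}
    starts = rng.integers(0, gene_len - k + 1, size=n_reads)
    for i, p in enumerate(starts):
        rid = f"GENE000:{i:06d}"
        sequences[rid] = subject_seq[p : p + k]
        truth.read_origin[rid] = ("GENE000", int(p))
        if p <= snp_positions[0] and snp_positions[2] < p + k:
            truth.misaligned_reads.add(rid)

    regions = build_synthetic_regions(models, genome, k)
    alignments = enumerate_alignments(sequences, genome, regions, max_mismatches=2)
    records = [
        ReadAlignmentRecord(read_id=rid, sample_id="scenario", alignments=alignments[rid])
        for rid in sequences
    ]
    parent_map = {"PSG000": ("GENE000", "processed")}
    return {
        "genome": genome,
        "models": models,
        "parent_map": parent_map,
        "reads": ReadSet(records=records, sequences=sequences),
        "truth": truth,
        "k": k,
    }


# ---------------------------------------------------------------------------
# RPKUM robustness simulation


def rpkum_robustness_simulation(
    n_genes: int = 1000,
    rpkm_range: tuple[float, float] = (1.0, 200.0),
    mappable_bases_options: tuple[int, ...] = (50, 100, 500),
    library_size: int = 5_000_000,
    gene_length: int = 1000,
    seed: int = 0,
    log_uniform: bool = False,
) -> dict[int, float]:
    """Rank agreement between RPKUM from few sampled mappable bases and RPKM.

    For each gene a true RPKM is drawn across ``rpkm_range`` and
    uniform-coverage reads are generated at the fixed library size. For
    each option ``m``, ``m`` random transcript positions are declared the
    gene's only mappable bases; reads starting at those positions are the
    gene's mappable reads, and RPKUM is computed from them. Returns
    Spearman rho(RPKUM, true RPKM) per ``m``.
    """
    if n_genes < 50:
        raise ValueError("n_genes must be >= 50")
    rng = np.random.default_rng(seed)
    if log_uniform:
        rpkm = np.exp(rng.uniform(np.log(rpkm_range[0]), np.log(rpkm_range[1]), n_genes))
    else:
        rpkm = rng.uniform(rpkm_range[0], rpkm_range[1], n_genes)
    n_reads = rng.poisson(rpkm * (gene_length / 1000.0) * library_size / 1e6)
    result: dict[int, float] = {}
    read_starts = [
        rng.integers(0, gene_length, size=n) if n > 0 else np.empty(0, dtype=np.int64)
        for n in n_reads
    ]
    for m in mappable_bases_options:
        counts = np.empty(n_genes, dtype=np.int64)
        for g in range(n_genes):
            sampled = rng.choice(gene_length, size=m, replace=False)
            mask = np.zeros(gene_length, dtype=bool)
            mask[sampled] = True
            counts[g] = int(mask[read_starts[g]].sum())
        rpkum = counts * 1e9 / (m * library_size)
        result[m] = float(spearmanr(rpkum, rpkm).statistic)
    return result


# ---------------------------------------------------------------------------
# Planted ceRNA expression matrices


def simulate_cerna_expression(
    n_samples: int = 200,
    n_triples: int = 5,
    n_null_pairs: int = 20,
    effect: tuple[float, float] = (1.0, 1.0),
    noise_sd: float = 0.8,
    seed: int = 0,
    baseline_log2: float = 5.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, TruthTable]:
    """Expression matrices with planted ceRNA structure.

    Planted triple model per sample: a latent miRNA level ``c`` and a
    shared positive factor ``f`` drive pseudogene and gene log-expression
    ``a*f - b*c + noise``; the miRNA represses both, so pseudogene and gene
    are positively correlated with each other and negatively with the
    miRNA. Null pairs are independent of everything (but still share a
    decoy miRNA, so the screen must reject them on correlation, not on
    annotation). Values are emitted on an RPKUM-like scale,
    ``2**(baseline + latent) - 1``, so the log2(x+1) transform recovers the
    latent scale exactly.
    """
    if n_samples < 20:
        raise ValueError("n_samples must be >= 20")
    rng = np.random.default_rng(seed)
    a, b = effect
    truth = TruthTable(seed=seed)
    pseudo_rows, gene_rows, mirna_rows = {}, {}, {}
    for t in range(n_triples):
        c = rng.normal(size=n_samples)
        f = rng.normal(size=n_samples)
        x = a * f - b * c + noise_sd * rng.normal(size=n_samples)
        y = a * f - b * c + noise_sd * rng.normal(size=n_samples)
        pid, gid, mid = f"PSG{t:03d}", f"GENE{t:03d}", f"mir-{t:03d}"
        pseudo_rows[pid] = x
        gene_rows[gid] = y
        mirna_rows[mid] = c
        truth.planted_triples.append((pid, gid, mid))
        truth.shared_mirnas[(pid, gid)] = {mid}
    for t in range(n_null_pairs):
        pid, gid = f"NPSG{t:03d}", f"NGENE{t:03d}"
        mid = f"mir-null-{t:03d}"
        pseudo_rows[pid] = rng.normal(size=n_samples)
        gene_rows[gid] = rng.normal(size=n_samples)
        mirna_rows[mid] = rng.normal(size=n_samples)
        truth.shared_mirnas[(pid, gid)] = {mid}
    samples = [f"S{i:03d}" for i in range(n_samples)]

    def expand(rows: dict) -> pd.DataFrame:
        mat = np.vstack([2.0 ** (baseline_log2 + v) - 1.0 for v in rows.values()])
        return pd.DataFrame(np.maximum(mat, 0.0), index=list(rows), columns=samples)

    return expand(gene_rows), expand(pseudo_rows), expand(mirna_rows), truth


# ---------------------------------------------------------------------------
# Emitters


def write_fastq(read_set: ReadSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in read_set.sequences.items():
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_alignments_tsv(records: list[ReadAlignmentRecord], path: str | Path) -> None:
    """SAM-like TSV: one row per candidate alignment (or a '.' row for
    unaligned reads)."""
    with open(path, "w") as fh:
        fh.write("read_id\tsample_id\tchrom\tstart\tblocks\tmismatches\n")
        for rec in records:
            if not rec.alignments:
                fh.write(f"{rec.read_id}\t{rec.sample_id}\t.\t-1\t.\t0\n")
            for aln in rec.alignments:
                blocks = ",".join(f"{s}-{e}" for s, e in aln.blocks)
                fh.write(
                    f"{rec.read_id}\t{rec.sample_id}\t{aln.chrom}\t{aln.start}\t"
                    f"{blocks}\t{aln.mismatches}\n"
                )


def load_alignments_tsv(path: str | Path) -> list[ReadAlignmentRecord]:
    grouped: dict[str, ReadAlignmentRecord] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("read_id\t"):
            raise ValueError(f"unexpected alignment TSV header in {path}")
        for line in fh:
            rid, sid, chrom, start, blocks, mm = line.rstrip("\n").split("\t")
            rec = grouped.setdefault(
                rid, ReadAlignmentRecord(read_id=rid, sample_id=sid, alignments=[])
            )
            if chrom == ".":
                continue
            parsed = tuple(
                tuple(int(x) for x in b.split("-")) for b in blocks.split(",")
            )
            rec.alignments.append(
                Alignment(chrom=chrom, start=int(start), blocks=parsed, mismatches=int(mm))
            )
    return list(grouped.values())


def write_sam(
    records: list[ReadAlignmentRecord],
    genome: GenomeSequence,
    path: str | Path,
    sequences: dict[str, str] | None = None,
) -> None:
    """Minimal SAM emitter with NH/NM tags and N-gap CIGARs."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for chrom in genome.chrom_names:
            fh.write(f"@SQ\tSN:{chrom}\tLN:{genome.length(chrom)}\n")
        for rec in records:
            nh = len(rec.alignments)
            if nh == 0:
                seq = (sequences or {}).get(rec.read_id, "*")
                fh.write(f"{rec.read_id}\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t*\n")
                continue
            for i, aln in enumerate(rec.alignments):
                cigar_parts = []
                for (s1, e1), (s2, _) in zip(aln.blocks, aln.blocks[1:]):
                    cigar_parts.append(f"{e1 - s1}M{s2 - e1}N")
                last = aln.blocks[-1]
                cigar_parts.append(f"{last[1] - last[0]}M")
                cigar = "".join(cigar_parts)
                flag = 0 if i == 0 else 256
                seq = (sequences or {}).get(rec.read_id, "*") if i == 0 else "*"
                fh.write(
                    f"{rec.read_id}\t{flag}\t{aln.chrom}\t{aln.start + 1}\t"
                    f"{0 if nh > 1 else 60}\t{cigar}\t*\t0\t0\t{seq}\t*\t"
                    f"NH:i:{nh}\tNM:i:{aln.mismatches}\n"
                )
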