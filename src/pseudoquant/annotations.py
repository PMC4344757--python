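"""Genome sequences, gene models, consensus models and splice junctions.

Coordinate convention: all in-memory coordinates are 0-based half-open
genomic intervals. GTF I/O converts from/to the 1-based closed convention
of the format. Strand matters only for junction orientation and sequence
extraction; consensus models and base counting are strand-agnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

__all__ = [
    "GenomeSequence",
    "Exon",
    "GeneModel",
    "ConsensusGeneModel",
    "SpliceJunction",
    "load_genome",
    "load_annotations",
    "load_parent_map",
    "write_gtf",
    "write_parent_map",
    "build_consensus_model",
    "enumerate_junctions",
    "junction_genomic_key",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

PSEUDO_CLASSES = ("processed", "duplicated", "unitary", "none")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeSequence:
    """A reference genome: ordered chromosome names and uppercase sequences."""

    chrom_names: list[str]
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names")
        for name in self.chrom_names:
            seq = self.sequences[name]
            if not seq:
                raise ValueError(f"empty sequence for {name!r}")
            bad = set(seq) - set("ACGTN")
            if bad:
                raise ValueError(f"invalid characters in {name!r}: {sorted(bad)}")

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])


@dataclass(frozen=True)
class Exon:
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid exon interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    """A gene with one or more transcripts, each an ordered exon chain.

    Exon chains are stored in transcript (5'->3') order: increasing genomic
    coordinates on '+', decreasing on '-'. ``pseudo_class`` is one of
    processed / duplicated / unitary / none; unitary pseudogenes carry no
    parent link.
    """

    gene_id: str
    biotype: str  # {"coding", "pseudogene"}
    pseudo_class: str = "none"
    parent_gene_id: str | None = None
    transcripts: dict[str, list[Exon]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.biotype not in ("coding", "pseudogene"):
            raise ValueError(f"invalid biotype {self.biotype!r}")
        if self.pseudo_class not in PSEUDO_CLASSES:
            raise ValueError(f"invalid pseudogene class {self.pseudo_class!r}")
        if self.pseudo_class == "unitary" and self.parent_gene_id is not None:
            raise ValueError("unitary pseudogenes have no parent gene")
        for tx_id, chain in self.transcripts.items():
            self._check_chain(tx_id, chain)

    @staticmethod
    def _check_chain(tx_id: str, chain: list[Exon]) -> None:
        if not chain:
            raise ValueError(f"transcript {tx_id!r} has no exons")
        strand = chain[0].strand
        for a, b in zip(chain, chain[1:]):
            ordered = b.start >= a.end if strand == "+" else b.end <= a.start
            if not ordered:
                raise ValueError(f"exon chain of {tx_id!r} not ordered along strand")

    @property
    def chrom(self) -> str:
        return next(iter(self.transcripts.values()))[0].chrom

    @property
    def strand(self) -> str:
        return next(iter(self.transcripts.values()))[0].strand

    def span(self) -> tuple[int, int]:
        starts = [e.start for c in self.transcripts.values() for e in c]
        ends = [e.end for c in self.transcripts.values() for e in c]
        return min(starts), max(ends)

    def transcript_sequence(self, tx_id: str, genome: GenomeSequence) -> str:
        """Spliced transcript sequence in transcript orientation."""
        chain = self.transcripts[tx_id]
        parts = []
        for exon in chain:
            seq = genome[exon.chrom][exon.start:exon.end]
            parts.append(seq if exon.strand == "+" else reverse_complement(seq))
        return "".join(parts)


@dataclass
class ConsensusGeneModel:
    """Nonredundant union of all annotated exonic positions of a gene."""

    gene_id: str
    chrom: str
    intervals: list[tuple[int, int]]  # sorted, disjoint, half-open

    @property
    def n_positions(self) -> int:
        return sum(e - s for s, e in self.intervals)

    def contains(self, pos: int) -> bool:
        for s, e in self.intervals:
            if s <= pos < e:
                return True
        return False


@dataclass(frozen=True)
class SpliceJunction:
    """A splice junction in genomic orientation with a strand flag.

    ``donor_end`` is the genomic boundary coordinate on the donor side
    (exclusive end of the donor exon on '+', start of the donor exon on
    '-'); ``acceptor_start`` analogously for the acceptor exon.
    """

    chrom: str
    donor_end: int
    acceptor_start: int
    strand: str
    junction_id: str


def junction_genomic_key(j: SpliceJunction) -> tuple[str, int, int]:
    """Strand-free genomic key (chrom, left exon end, right exon start).

    This is the key a spliced read alignment produces, regardless of the
    strand the annotation lives on.
    """
    if j.strand == "+":
        return (j.chrom, j.donor_end, j.acceptor_start)
    return (j.chrom, j.acceptor_start, j.donor_end)


# ---------------------------------------------------------------------------
# FASTA / GTF / parent-map I/O


def load_genome(fasta_path: str | Path) -> GenomeSequence:
    """Load a FASTA genome; sequences are uppercased, chrom order preserved."""
    names: list[str] = []
    seqs: dict[str, str] = {}
    with open(fasta_path) as fh:
        for record in SeqIO.parse(fh, "fasta"):
            if record.id in seqs:
                raise ValueError(f"duplicate chromosome {record.id!r} in FASTA")
            names.append(record.id)
            seqs[record.id] = str(record.seq).upper()
    if not names:
        raise ValueError(f"no FASTA records found in {fasta_path}")
    return GenomeSequence(names, seqs)


def write_genome(genome: GenomeSequence, fasta_path: str | Path, width: int = 70) -> None:
    with open(fasta_path, "w") as fh:
        for name in genome.chrom_names:
            fh.write(f">{name}\n")
            seq = genome.sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


_BIOTYPE_MAP = {"coding": "protein_coding", "pseudogene": "pseudogene"}
_BIOTYPE_UNMAP = {v: k for k, v in _BIOTYPE_MAP.items()}


def _parse_attributes(attr_field: str) -> dict[str, str]:
    attrs = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def load_annotations(
    gtf_path: str | Path,
    parent_map_path: str | Path | None = None,
    genome: GenomeSequence | None = None,
) -> list[GeneModel]:
    """Load gene models from GTF exon features, joining an optional parent map.

    GTF 1-based closed coordinates are converted to 0-based half-open. When
    a genome is supplied, exons are bounds-checked against it. Parent links
    naming unknown genes are dropped with a warning.
    """
    # gene_id -> transcript_id -> [Exon] in file order
    raw: dict[str, dict[str, list[Exon]]] = {}
    biotypes: dict[str, str] = {}
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"{gtf_path}:{lineno}: expected 9 GTF fields")
            chrom, _, feature, start, end, _, strand, _, attr_field = fields
            if feature != "exon":
                continue
            attrs = _parse_attributes(attr_field)
            try:
                gene_id = attrs["gene_id"]
                tx_id = attrs["transcript_id"]
            except KeyError as exc:
                raise ValueError(f"{gtf_path}:{lineno}: missing {exc} attribute")
            exon = Exon(chrom, int(start) - 1, int(end), strand)
            if genome is not None:
                if chrom not in genome.sequences:
                    raise ValueError(f"{gtf_path}:{lineno}: unknown chrom {chrom!r}")
                if exon.end > genome.length(chrom):
                    raise ValueError(
                        f"{gtf_path}:{lineno}: exon exceeds length of {chrom!r}"
                    )
            raw.setdefault(gene_id, {}).setdefault(tx_id, []).append(exon)
            biotype = attrs.get("gene_biotype", "protein_coding")
            biotypes[gene_id] = _BIOTYPE_UNMAP.get(biotype, "coding")

    parents: dict[str, tuple[str | None, str]] = {}
    if parent_map_path is not None:
        parents = load_parent_map(parent_map_path)

    models = []
    for gene_id, transcripts in raw.items():
        ordered = {}
        for tx_id, chain in transcripts.items():
            strand = chain[0].strand
            ordered[tx_id] = sorted(
                chain, key=lambda e: e.start, reverse=(strand == "-")
            )
        parent_id, pseudo_class = parents.get(gene_id, (None, "none"))
        if parent_id is not None and parent_id not in raw:
            warnings.warn(
                f"parent gene {parent_id!r} of {gene_id!r} not in annotation; "
                "dropping link"
            )
            parent_id = None
        models.append(
            GeneModel(
                gene_id=gene_id,
                biotype=biotypes[gene_id],
                pseudo_class=pseudo_class,
                parent_gene_id=parent_id,
                transcripts=ordered,
            )
        )
    return models


def load_parent_map(path: str | Path) -> dict[str, tuple[str | None, str]]:
    """Read the two/three-column parent map TSV.

    Header: ``pseudogene_id<TAB>parent_gene_id<TAB>pseudo_class``. An empty
    parent field means no parent (unitary pseudogenes).
    """
    out: dict[str, tuple[str | None, str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "pseudogene_id":
            raise ValueError(f"unexpected parent-map header in {path}")
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            pseudo_id = fields[0]
            parent = fields[1] or None
            pclass = fields[2] if len(fields) > 2 and fields[2] else "processed"
            out[pseudo_id] = (parent, pclass)
    return out


def write_parent_map(models: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("pseudogene_id\tparent_gene_id\tpseudo_class\n")
        for m in models:
            if m.biotype == "pseudogene":
                fh.write(f"{m.gene_id}\t{m.parent_gene_id or ''}\t{m.pseudo_class}\n")


def write_gtf(models: list[GeneModel], path: str | Path) -> None:
    """Write exon features, converting back to 1-based closed coordinates."""
    with open(path, "w") as fh:
        for m in models:
            biotype = _BIOTYPE_MAP[m.biotype]
            for tx_id, chain in m.transcripts.items():
                for exon in chain:
                    attrs = (
                        f'gene_id "{m.gene_id}"; transcript_id "{tx_id}"; '
                        f'gene_biotype "{biotype}";'
                    )
                    fh.write(
                        "\t".join(
                            [
                                exon.chrom,
                                "pseudoquant",
                                "exon",
                                str(exon.start + 1),
                                str(exon.end),
                                ".",
                                exon.strand,
                                ".",
                                attrs,
                            ]
                        )
                        + "\n"
                    )


# ---------------------------------------------------------------------------
# Consensus models and junctions


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals as a sorted disjoint list."""
    if not intervals:
        return []
    merged = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def build_consensus_model(gene: GeneModel) -> ConsensusGeneModel:
    """Merge all annotated exons of all transcripts into disjoint intervals."""
    if not gene.transcripts:
        raise ValueError(f"gene {gene.gene_id!r} has no transcripts")
    intervals = [
        (e.start, e.end) for chain in gene.transcripts.values() for e in chain
    ]
    return ConsensusGeneModel(gene.gene_id, gene.chrom, merge_intervals(intervals))


def enumerate_junctions(models: list[GeneModel]) -> list[SpliceJunction]:
    """All distinct splice junctions, one record per (chrom, strand, boundary)."""
    seen: dict[tuple, SpliceJunction] = {}
    for model in models:
        for chain in model.transcripts.values():
            for donor, acceptor in zip(chain, chain[1:]):
                if donor.strand == "+":
                    donor_end, acceptor_start = donor.end, acceptor.start
                else:
                    donor_end, acceptor_start = donor.start, acceptor.end
                key = (donor.chrom, donor.strand, donor_end, acceptor_start)
                if key not in seen:
                    jid = f"J{len(seen):05d}"
                    seen[key] = SpliceJunction(
                        donor.chrom, donor_end, acceptor_start, donor.strand, jid
                    )
    return list(seen.values())
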