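"""ceRNA-potential screen: pseudo-3' UTRs, shared miRNA sites, correlations.

A pseudogene can act as a competing endogenous RNA (ceRNA) for its parent
gene by sequestering miRNAs they both bind. The screen proceeds in stages:

1. locate the "pseudo-3' UTR" — the pseudogene subsequence homologous to
   the parent's 3' UTR — by local alignment of each annotated parent UTR
   against the pseudogene locus plus 10 kb of genomic context;
2. predict canonical miRNA seed-match sites (8mer / 7mer-m8 / 7mer-A1 /
   6mer) on pseudo-3' UTRs and parent UTRs, restricted to the top expressed
   miRNAs, and intersect them to find shared targeting miRNAs;
3. correlate log-transformed expression for pseudogene-gene,
   pseudogene-miRNA and gene-miRNA pairs (co-present samples only, with a
   presence filter), with a permutation null for the pair-count statistics;
4. report triples where the pseudogene-gene correlation is high and the
   pseudogene-miRNA anti-correlation is significant after BH correction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

from .annotations import GeneModel, GenomeSequence, reverse_complement

__all__ = [
    "UTRSet",
    "ContextSequence",
    "LocalAlignment",
    "Pseudo3UTR",
    "SeedMatchSite",
    "CorrelationRecord",
    "PermutationResult",
    "CeRNATriple",
    "extract_context",
    "local_align",
    "read_blast_tabular",
    "annotate_pseudo3utr",
    "find_seed_matches",
    "shared_mirnas",
    "top_expressed_mirnas",
    "pairwise_correlation",
    "permutation_null",
    "bh_adjust",
    "identify_cerna_triples",
]


@dataclass
class UTRSet:
    """All annotated 3' UTR sequences of one gene (one per transcript)."""

    gene_id: str
    utr_sequences: list[str]

    def __post_init__(self) -> None:
        if not self.utr_sequences:
            raise ValueError(f"no UTR sequences for {self.gene_id!r}")


@dataclass
class ContextSequence:
    """A locus plus flanking genomic context, with coordinate mapping."""

    sequence: str
    chrom: str
    offset: int  # genomic coordinate of sequence[0]
    clipped_left: bool = False
    clipped_right: bool = False

    def to_genomic(self, pos: int) -> int:
        return self.offset + pos

    def to_local(self, genomic_pos: int) -> int:
        return genomic_pos - self.offset


@dataclass
class LocalAlignment:
    score: float
    query_interval: tuple[int, int]  # half-open on query
    subject_interval: tuple[int, int]  # half-open on subject
    evalue: float

    @property
    def subject_span(self) -> int:
        return self.subject_interval[1] - self.subject_interval[0]


@dataclass
class Pseudo3UTR:
    pseudogene_id: str
    interval: tuple[int, int]  # within the context sequence
    sequence: str
    alignment_length: int
    alignment_significance: float  # E-value


@dataclass(frozen=True)
class SeedMatchSite:
    mirna_id: str
    site_type: str  # 8mer | 7mer-m8 | 7mer-A1 | 6mer
    position: int  # start of the full site on the UTR
    on_pseudogene: bool = False


@dataclass
class CorrelationRecord:
    id_a: str
    id_b: str
    r: float
    n_samples_used: int
    p_one_sided: float
    q_bh: float = float("nan")
    excluded: bool = False


@dataclass
class PermutationResult:
    observed_count: int
    null_counts: list[int]
    threshold: float
    direction: str
    empirical_p: float
    seed: int | None = None

    def to_json(self, path: str | Path) -> None:
        null = np.array(self.null_counts)
        payload = {
            "observed_count": self.observed_count,
            "threshold": self.threshold,
            "direction": self.direction,
            "empirical_p": self.empirical_p,
            "n_permutations": len(self.null_counts),
            "null_quantiles": {
                q: float(np.quantile(null, float(q))) for q in ("0.05", "0.5", "0.95")
            },
            "null_max": int(null.max()),
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class CeRNATriple:
    pseudogene_id: str
    parent_gene_id: str
    mirna_id: str
    r_pseudo_gene: float
    r_pseudo_mirna: float
    r_gene_mirna: float
    q_pseudo_mirna: float
    q_gene_mirna: float


# ---------------------------------------------------------------------------
# Context extraction and local alignment


def extract_context(
    pseudogene: GeneModel, genome: GenomeSequence, flank: int = 10_000
) -> ContextSequence:
    """Pseudogene locus plus up to ``flank`` bases on each side, clipped at
    chromosome edges."""
    chrom = pseudogene.chrom
    lo, hi = pseudogene.span()
    start = max(0, lo - flank)
    end = min(genome.length(chrom), hi + flank)
    return ContextSequence(
        sequence=genome[chrom][start:end],
        chrom=chrom,
        offset=start,
        clipped_left=start > lo - flank,
        clipped_right=end < hi + flank,
    )


_DEFAULT_SCORING = {"match": 2, "mismatch": -3, "gap_open": 5, "gap_extend": 2}


def _karlin_altschul_lambda(match: float, mismatch: float) -> float:
    """Ungapped Karlin-Altschul lambda for a uniform-composition DNA scoring
    scheme: solves sum_ij p_i p_j exp(lambda*s_ij) = 1."""

    def f(lam: float) -> float:
        return 0.25 * np.exp(lam * match) + 0.75 * np.exp(lam * mismatch) - 1.0

    return brentq(f, 1e-6, 10.0)


_KA_K = 0.1  # standard order-of-magnitude constant for ungapped DNA scoring


def local_align(
    query: str,
    subject: str,
    scoring: dict | None = None,
) -> list[LocalAlignment]:
    """Best Smith-Waterman local alignment of query against subject.

    Affine-gap local alignment via scikit-bio, scored with an ungapped
    Karlin-Altschul E-value, ``E = K*m*n*exp(-lambda*S)``. Returns a list
    (best alignment only, empty for empty inputs) sorted by significance.
    """
    if not query or not subject:
        raise ValueError("sequences must be nonempty")
    from skbio import DNA
    from skbio.alignment import pair_align

    sc = dict(_DEFAULT_SCORING, **(scoring or {}))
    res = pair_align(
        DNA(query),
        DNA(subject),
        mode="local",
        sub_score=(sc["match"], sc["mismatch"]),
        gap_cost=(sc["gap_open"], sc["gap_extend"]),
        max_paths=1,
    )
    if not res.paths or res.score <= 0:
        return []
    path = res.paths[0]
    q0, s0 = int(path.starts[0]), int(path.starts[1])
    q1, s1 = int(path.stops[0]), int(path.stops[1])
    lam = _karlin_altschul_lambda(sc["match"], sc["mismatch"])
    evalue = _KA_K * len(query) * len(subject) * np.exp(-lam * res.score)
    return [
        LocalAlignment(
            score=float(res.score),
            query_interval=(q0, q1),
            subject_interval=(s0, s1),
            evalue=float(evalue),
        )
    ]


def read_blast_tabular(path: str | Path) -> dict[str, list[LocalAlignment]]:
    """Read BLAST -outfmt 6 output, keyed by query id.

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore. 1-based closed coordinates are converted
    to 0-based half-open; reverse-orientation subject hits are normalised
    to forward intervals.
    """
    out: dict[str, list[LocalAlignment]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            qstart, qend = int(f[6]), int(f[7])
            sstart, send = int(f[8]), int(f[9])
            slo, shi = min(sstart, send), max(sstart, send)
            out.setdefault(f[0], []).append(
                LocalAlignment(
                    score=float(f[11]),
                    query_interval=(qstart - 1, qend),
                    subject_interval=(slo - 1, shi),
                    evalue=float(f[10]),
                )
            )
    return out


def annotate_pseudo3utr(
    parent_utrs: UTRSet,
    context: ContextSequence | str,
    scoring: dict | None = None,
    evalue_cutoff: float = 1e-6,
    pseudogene_id: str = "",
) -> Pseudo3UTR | None:
    """Locate the pseudo-3' UTR: the longest significant local alignment of
    any parent 3' UTR within the pseudogene locus plus context.

    Ties on subject span break toward higher significance, then leftmost
    subject start. Returns None when no alignment passes the cutoff.
    """
    subject = context.sequence if isinstance(context, ContextSequence) else context
    candidates: list[LocalAlignment] = []
    for utr in parent_utrs.utr_sequences:
        for aln in local_align(utr, subject, scoring):
            if aln.evalue <= evalue_cutoff:
                candidates.append(aln)
    if not candidates:
        return None
    best = min(
        candidates,
        key=lambda a: (-a.subject_span, a.evalue, a.subject_interval[0]),
    )
    s0, s1 = best.subject_interval
    return Pseudo3UTR(
        pseudogene_id=pseudogene_id or parent_utrs.gene_id,
        interval=(s0, s1),
        sequence=subject[s0:s1],
        alignment_length=best.subject_span,
        alignment_significance=best.evalue,
    )


# ---------------------------------------------------------------------------
# Seed matching


def _normalize_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def find_seed_matches(
    utr: str, mirnas: list[tuple[str, str]], on_pseudogene: bool = False
) -> list[SeedMatchSite]:
    """Canonical seed-match sites of each miRNA on a UTR sequence.

    For a mature miRNA given 5'->3', the seed is bases 2-8. On the UTR
    (5'->3') a site is the reverse complement of the seed region:

    - 8mer:    rc(bases 2-8) followed by A
    - 7mer-m8: rc(bases 2-8)
    - 7mer-A1: rc(bases 2-7) followed by A
    - 6mer:    rc(bases 2-7), only where not part of a longer site

    Reported positions are the start of the full site on the UTR. miRNAs
    shorter than 8 bases are skipped with a warning.
    """
    utr = _normalize_dna(utr)
    sites: list[SeedMatchSite] = []
    for mirna_id, mature in mirnas:
        mature = _normalize_dna(mature)
        if len(mature) < 8:
            warnings.warn(f"miRNA {mirna_id!r} shorter than 8 bases; skipped")
            continue
        core6 = reverse_complement(mature[1:7])  # rc of bases 2-7
        m8c = reverse_complement(mature[7])  # complement of base 8
        start = 0
        while True:
            p = utr.find(core6, start)
            if p == -1:
                break
            start = p + 1
            has_m8 = p > 0 and utr[p - 1] == m8c
            has_a1 = p + 6 < len(utr) and utr[p + 6] == "A"
            if has_m8 and has_a1:
                site_type, pos = "8mer", p - 1
            elif has_m8:
                site_type, pos = "7mer-m8", p - 1
            elif has_a1:
                site_type, pos = "7mer-A1", p
            else:
                site_type, pos = "6mer", p
            sites.append(SeedMatchSite(mirna_id, site_type, pos, on_pseudogene))
    return sites


def shared_mirnas(
    pseudo_sites: list[SeedMatchSite], parent_sites: list[SeedMatchSite]
) -> set[str]:
    """miRNAs with at least one predicted site on both transcripts."""
    return {s.mirna_id for s in pseudo_sites} & {s.mirna_id for s in parent_sites}


def top_expressed_mirnas(mirna_matrix: pd.DataFrame, n: int = 100) -> list[str]:
    """Top ``n`` miRNAs by mean expression across samples (isomiRs are
    distinct entries). Ties at rank ``n`` are all included; within equal
    means the order is deterministic by id."""
    if n > len(mirna_matrix):
        raise ValueError("n exceeds number of miRNAs")
    means = mirna_matrix.mean(axis=1)
    ranked = means.sort_values(ascending=False, kind="mergesort")
    ranked = ranked.iloc[np.lexsort((ranked.index, -ranked.values))]
    if n == len(ranked):
        return list(ranked.index)
    cutoff = ranked.iloc[n - 1]
    selected = ranked[ranked >= cutoff]
    return list(selected.index)


# ---------------------------------------------------------------------------
# Correlation machinery


def _masked_pearson(
    A: np.ndarray, B: np.ndarray, presence_level: float
) -> tuple[np.ndarray, np.ndarray]:
    """Row-paired Pearson r on log2(x+1), restricted to samples where both
    values reach ``presence_level``. Returns (r, n_used) arrays."""
    mask = (A >= presence_level) & (B >= presence_level)
    la = np.log2(A + 1.0)
    lb = np.log2(B + 1.0)
    n = mask.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sa = np.where(mask, la, 0.0).sum(axis=1)
        sb = np.where(mask, lb, 0.0).sum(axis=1)
        ma = sa / n
        mb = sb / n
        da = np.where(mask, la - ma[:, None], 0.0)
        db = np.where(mask, lb - mb[:, None], 0.0)
        cov = (da * db).sum(axis=1)
        va = (da * da).sum(axis=1)
        vb = (db * db).sum(axis=1)
        r = cov / np.sqrt(va * vb)
    return r, n


def _one_sided_p(r: np.ndarray, n: np.ndarray, direction: str) -> np.ndarray:
    """One-sided p-value from the correlation T-statistic.

    direction='negative' tests H0: rho >= 0 against rho < 0 (left tail);
    direction='positive' the mirror.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        tval = r * np.sqrt(np.maximum(n - 2, 0)) / np.sqrt(1.0 - r**2)
    df = np.maximum(n - 2, 1)
    if direction == "negative":
        p = t_dist.cdf(tval, df)
    elif direction == "positive":
        p = t_dist.sf(tval, df)
    else:
        raise ValueError(f"invalid direction {direction!r}")
    return np.where(np.isfinite(tval), p, np.nan)


def pairwise_correlation(
    mat_a: pd.DataFrame,
    mat_b: pd.DataFrame,
    pairs: list[tuple[str, str]],
    min_present_samples: int = 20,
    presence_level: float = 1.0,
    direction: str = "negative",
) -> list[CorrelationRecord]:
    """Pearson correlation on log2(x+1) expression for given id pairs.

    Samples where either member is below ``presence_level`` are dropped per
    pair; pairs with fewer than ``min_present_samples`` co-present samples
    are marked excluded. The one-sided p-value comes from the correlation
    T-statistic in the requested direction.
    """
    if not mat_a.columns.equals(mat_b.columns):
        raise ValueError("matrices must share the sample axis")
    for id_a, id_b in pairs:
        if id_a not in mat_a.index:
            raise KeyError(f"id {id_a!r} missing from first matrix")
        if id_b not in mat_b.index:
            raise KeyError(f"id {id_b!r} missing from second matrix")
    A = mat_a.loc[[a for a, _ in pairs]].to_numpy(dtype=float)
    B = mat_b.loc[[b for _, b in pairs]].to_numpy(dtype=float)
    r, n = _masked_pearson(A, B, presence_level)
    p = _one_sided_p(r, n, direction)
    records = []
    for i, (id_a, id_b) in enumerate(pairs):
        excluded = bool(n[i] < min_present_samples) or not np.isfinite(r[i])
        records.append(
            CorrelationRecord(
                id_a=id_a,
                id_b=id_b,
                r=float(r[i]) if np.isfinite(r[i]) else float("nan"),
                n_samples_used=int(n[i]),
                p_one_sided=float(p[i]) if np.isfinite(p[i]) else float("nan"),
                excluded=excluded,
            )
        )
    return records


def permutation_null(
    mat_a: pd.DataFrame,
    mat_b: pd.DataFrame,
    true_pairs: list[tuple[str, str]],
    n_permutations: int = 5000,
    threshold: float = 0.3,
    direction: str = "positive",
    seed: int | None = None,
    min_present_samples: int = 20,
    presence_level: float = 1.0,
) -> PermutationResult:
    """Permutation null for the count of strongly correlated pairs.

    Each permutation re-pairs the two sides by a uniform random shuffle of
    the b-side labels, applies the same presence filter and correlation,
    and counts pairs beyond ``threshold`` in the stated direction.
    Empirical p = (#permutations with count >= observed) / n_permutations.
    """
    if len({a for a, _ in true_pairs}) < 2 or len({b for _, b in true_pairs}) < 2:
        raise ValueError("need at least 2 distinct ids on each side")
    rng = np.random.default_rng(seed)
    A = mat_a.loc[[a for a, _ in true_pairs]].to_numpy(dtype=float)
    B = mat_b.loc[[b for _, b in true_pairs]].to_numpy(dtype=float)

    def count(Amat: np.ndarray, Bmat: np.ndarray) -> int:
        r, n = _masked_pearson(Amat, Bmat, presence_level)
        ok = (n >= min_present_samples) & np.isfinite(r)
        if direction == "positive":
            return int((ok & (r > threshold)).sum())
        return int((ok & (r < -threshold)).sum())

    observed = count(A, B)
    null_counts = []
    for _ in range(n_permutations):
        perm = rng.permutation(len(true_pairs))
        null_counts.append(count(A, B[perm]))
    null = np.array(null_counts)
    empirical_p = float((null >= observed).sum() / n_permutations)
    return PermutationResult(
        observed_count=observed,
        null_counts=null_counts,
        threshold=threshold,
        direction=direction,
        empirical_p=empirical_p,
        seed=seed,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    q = np.full_like(p, np.nan)
    valid = np.isfinite(p)
    if valid.any():
        q[valid] = multipletests(p[valid], method="fdr_bh")[1]
    return q


# ---------------------------------------------------------------------------
# Triple identification


def identify_cerna_triples(
    pseudo_gene_corr: list[CorrelationRecord],
    pseudo_mirna_corr: list[CorrelationRecord],
    gene_mirna_corr: list[CorrelationRecord],
    shared: dict[tuple[str, str], set[str]],
    r_gene_threshold: float = 0.3,
    q_threshold: float = 0.05,
) -> list[CeRNATriple]:
    """Pseudogene / parent gene / miRNA triples with ceRNA potential.

    A triple is reported iff the miRNA is a shared predicted targeter of
    both transcripts, the pseudogene-gene correlation strictly exceeds
    ``r_gene_threshold``, and the pseudogene-miRNA anti-correlation is
    significant after BH adjustment at ``q_threshold``. BH is applied
    across all candidate miRNA correlations (pseudogene and gene sides
    each, over shared triples).
    """
    pg = {(c.id_a, c.id_b): c for c in pseudo_gene_corr}
    pm = {(c.id_a, c.id_b): c for c in pseudo_mirna_corr}
    gm = {(c.id_a, c.id_b): c for c in gene_mirna_corr}

    candidates = []
    for (pseudo_id, gene_id), mirna_ids in sorted(
        shared.items(), key=lambda kv: kv[0]
    ):
        for mirna_id in sorted(mirna_ids):
            cpg = pg.get((pseudo_id, gene_id))
            cpm = pm.get((pseudo_id, mirna_id))
            cgm = gm.get((gene_id, mirna_id))
            if cpg is None or cpm is None or cgm is None:
                continue
            if cpg.excluded or cpm.excluded:
                continue
            candidates.append((pseudo_id, gene_id, mirna_id, cpg, cpm, cgm))
    if not candidates:
        return []
    q_pm = bh_adjust([c[4].p_one_sided for c in candidates])
    q_gm = bh_adjust([c[5].p_one_sided for c in candidates])
    triples = []
    for (pseudo_id, gene_id, mirna_id, cpg, cpm, cgm), qp, qg in zip(
        candidates, q_pm, q_gm
    ):
        cpm.q_bh = float(qp)
        cgm.q_bh = float(qg)
        if cpg.r > r_gene_threshold and qp < q_threshold:
            triples.append(
                CeRNATriple(
                    pseudogene_id=pseudo_id,
                    parent_gene_id=gene_id,
                    mirna_id=mirna_id,
                    r_pseudo_gene=cpg.r,
                    r_pseudo_mirna=cpm.r,
                    r_gene_mirna=cgm.r,
                    q_pseudo_mirna=float(qp),
                    q_gene_mirna=float(qg),
                )
            )
    return triples


# ---------------------------------------------------------------------------
# TSV writers


def write_correlations(records: list[CorrelationRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\tr\tn_samples_used\tp_one_sided\tq_bh\texcluded\n")
        for c in records:
            fh.write(
                f"{c.id_a}\t{c.id_b}\t{c.r:.6g}\t{c.n_samples_used}\t"
                f"{c.p_one_sided:.6g}\t{c.q_bh:.6g}\t{int(c.excluded)}\n"
            )


def write_triples(triples: list[CeRNATriple], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "pseudogene_id\tparent_gene_id\tmirna_id\tr_pseudo_gene\t"
            "r_pseudo_mirna\tr_gene_mirna\tq_pseudo_mirna\tq_gene_mirna\n"
        )
        for t in triples:
            fh.write(
                f"{t.pseudogene_id}\t{t.parent_gene_id}\t{t.mirna_id}\t"
                f"{t.r_pseudo_gene:.6g}\t{t.r_pseudo_mirna:.6g}\t"
                f"{t.r_gene_mirna:.6g}\t{t.q_pseudo_mirna:.6g}\t{t.q_gene_mirna:.6g}\n"
            )
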