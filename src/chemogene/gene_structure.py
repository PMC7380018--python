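"""Spliced mRNA-to-genome alignment, intron/exon statistics, gene clusters.

The aligner reconstructs a gene's exon structure by aligning its mRNA to a
genomic window under the GT-AG rule: the mRNA must be covered end to end,
gaps are allowed only in the genomic dimension (introns of at least
``min_intron`` bases), and an intron whose donor/acceptor dinucleotides are
not GT..AG pays an extra penalty.  Scores: +match_score per matching base,
-mismatch_penalty per substitution, -intron_open per intron,
-noncanonical_penalty extra for a non-GT..AG intron.  Ties are broken toward
fewer introns, then the leftmost donor site.

The dynamic programme is O(m*n) in mRNA length m and window length n: the
intron transition is a prefix maximum (with a lag of ``min_intron``) over the
previous mRNA row, kept separately for GT-donor positions and for all
positions, so each row is a handful of vectorised passes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq

from .seq_io import GeneModel, GeneRecord, Interval, SequenceRecord

logger = logging.getLogger("chemogene")

NEG_INF = -1e18
# Sub-integer tie-break: all score terms are integers, so a penalty of 1e-4
# per intron can reorder exact ties only (max ~10 introns -> 1e-3 << 1).
_INTRON_EPS = 1e-4


class UnmappableError(ValueError):
    """No alignment covers the mRNA at the required identity."""


@dataclass
class SplicedAlignment:
    gene_model: GeneModel
    mismatches: int
    introns: list[tuple[Interval, str, str]]  # (interval, donor, acceptor)
    score: float

    @property
    def canonical(self) -> bool:
        return all(d == "GT" and a == "AG" for _, d, a in self.introns)


@dataclass(frozen=True)
class StructureStats:
    """One printed-table row of intron/exon statistics for a gene."""

    genomic_bp: int
    n_introns: int
    total_intron_bp: int
    avg_intron_bp: int
    n_exons: int
    total_exon_bp: int
    avg_exon_bp: int

    def __post_init__(self):
        assert self.genomic_bp == self.total_intron_bp + self.total_exon_bp
        assert self.n_exons == self.n_introns + 1


@dataclass
class GeneCluster:
    """Two or more genes adjacent on one scaffold (a tandem array)."""

    scaffold_id: str
    members: list[GeneRecord]  # ordered by start
    gaps: list[int]  # intergenic distances, len(members) - 1
    orientations: list[str]


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (445 from 444.83,
    3277 from 3276.8, 245 from 244.5)."""
    import math

    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def genomic_span(location: Interval) -> int:
    """Genomic size of a gene from its 1-based inclusive span."""
    return location.stop - location.start + 1


def _running_leftmost_argmax(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Prefix maxima of x and, per prefix, the leftmost index achieving it."""
    acc = np.maximum.accumulate(x)
    prev = np.empty_like(acc)
    prev[0] = NEG_INF
    prev[1:] = acc[:-1]
    idx = np.arange(len(x))
    new_max = x > prev
    arg = np.where(new_max, idx, -1)
    arg = np.maximum.accumulate(arg)
    return acc, arg


def spliced_align(
    mrna: SequenceRecord,
    genomic: SequenceRecord,
    strand: str = "+",
    gene_id: str = "",
    scaffold_id: str = "",
    offset: int = 0,
    match_score: float = 1,
    mismatch_penalty: float = 3,
    intron_open: float = 8,
    noncanonical_penalty: float = 10,
    min_intron: int = 30,
    min_coverage: float = 0.95,
) -> SplicedAlignment:
    """Align an mRNA to a genomic window and return the exon structure.

    For ``strand="-"`` the mRNA is aligned to the reverse complement of the
    window; exon coordinates are always reported on the forward genomic axis,
    shifted by ``offset`` (the window's 1-based start minus one on its
    scaffold).
    """
    if strand not in "+-":
        raise ValueError(f"strand must be + or -, got {strand!r}")
    q = mrna.residues
    g_fwd = genomic.residues
    g = g_fwd if strand == "+" else str(Seq(g_fwd).reverse_complement())
    m, n = len(q), len(g)
    if m > n:
        raise UnmappableError(
            f"{mrna.id}: mRNA ({m} bp) longer than genomic window ({n} bp)"
        )

    q_arr = np.frombuffer(q.encode(), dtype=np.uint8)
    g_arr = np.frombuffer(g.encode(), dtype=np.uint8)

    # donor_ok[k]: an intron starting right after genomic position k (1-based)
    # begins with GT; acceptor_ok[j]: an intron ending right before genomic
    # position j ends with AG.
    donor_ok = np.zeros(n + 1, dtype=bool)
    donor_ok[1 : n - 1] = (g_arr[1:-1] == ord("G")) & (g_arr[2:] == ord("T"))
    acceptor_ok = np.zeros(n + 1, dtype=bool)
    acceptor_ok[3:] = (g_arr[:-2] == ord("A")) & (g_arr[1:-1] == ord("G"))

    # S[j]: best score with current mRNA prefix ending at genomic position j.
    S = np.full(n + 1, NEG_INF)
    ptr = np.zeros((m + 1, n + 1), dtype=np.int32)  # k of intron jump, else 0
    sub = (q_arr[0] != g_arr).astype(np.float64)
    S[1:] = np.where(sub == 0, match_score, -mismatch_penalty)

    intron_cost = intron_open + _INTRON_EPS
    for i in range(2, m + 1):
        sub = q_arr[i - 1] != g_arr
        emit = np.where(sub, -float(mismatch_penalty), float(match_score))

        gt = np.where(donor_ok, S, NEG_INF)
        acc_gt, arg_gt = _running_leftmost_argmax(gt)
        acc_all, arg_all = _running_leftmost_argmax(S)

        newS = np.full(n + 1, NEG_INF)
        prev_diag = S[:-1]  # S[j-1] for j = 1..n

        # intron candidates: previous exon base at k <= j - 1 - min_intron
        cand = np.full(n + 1, NEG_INF)
        cand_k = np.full(n + 1, -1, dtype=np.int64)
        lag = min_intron + 1
        if n >= lag:
            j_idx = np.arange(lag, n + 1)
            t = j_idx - lag  # max admissible k
            best_canon = np.where(
                acceptor_ok[j_idx], acc_gt[t] - intron_cost, NEG_INF
            )
            best_noncanon = acc_all[t] - intron_cost - noncanonical_penalty
            use_canon = best_canon >= best_noncanon
            cand[j_idx] = np.where(use_canon, best_canon, best_noncanon)
            cand_k[j_idx] = np.where(use_canon, arg_gt[t], arg_all[t])

        take_intron = cand[1:] > prev_diag
        newS[1:] = np.where(take_intron, cand[1:], prev_diag) + emit
        ptr[i, 1:] = np.where(take_intron, cand_k[1:], 0)
        S = newS

    end = int(np.argmax(S))
    best = S[end]
    if best <= NEG_INF / 2:
        raise UnmappableError(f"{mrna.id}: no alignment found")

    # Traceback on the strand-local axis.
    exon_ends: list[int] = []
    exon_starts: list[int] = []
    introns_local: list[tuple[int, int]] = []
    j = end
    exon_ends.append(j)
    for i in range(m, 1, -1):
        k = int(ptr[i, j])
        if k > 0:
            introns_local.append((k + 1, j - 1))  # intron occupies k+1..j-1
            exon_starts.append(j)
            exon_ends.append(k)
            j = k
        else:
            j -= 1
    exon_starts.append(j)
    exon_starts.reverse()
    exon_ends.reverse()
    introns_local.reverse()

    mismatches = 0
    pieces = []
    qi = 0
    for s, e in zip(exon_starts, exon_ends):
        pieces.append(g[s - 1 : e])
        qi += e - s + 1
    assert qi == m
    spliced = "".join(pieces)
    mismatches = sum(a != b for a, b in zip(spliced, q))
    identity = (m - mismatches) / m
    if identity < min_coverage:
        raise UnmappableError(
            f"{mrna.id}: best alignment identity {identity:.3f} below "
            f"min_coverage {min_coverage}"
        )

    def to_forward(a: int, b: int) -> Interval:
        if strand == "+":
            return Interval(offset + a, offset + b)
        return Interval(offset + n - b + 1, offset + n - a + 1)

    exons = [to_forward(s, e) for s, e in zip(exon_starts, exon_ends)]
    introns = []
    for s, e in introns_local:
        donor = g[s - 1 : s + 1]
        acceptor = g[e - 2 : e]
        introns.append((to_forward(s, e), donor, acceptor))
    model = GeneModel(
        gene_id=gene_id or mrna.id,
        scaffold_id=scaffold_id or genomic.id,
        strand=strand,
        exons=exons,
        mrna_id=mrna.id,
    )
    return SplicedAlignment(model, mismatches, introns, float(best))


def structure_stats(model: GeneModel) -> StructureStats:
    """Printed-table statistics for a gene model; averages are rounded
    half-away-from-zero to integers."""
    exon_bp = sum(len(e) for e in model.exons)
    introns = model.introns
    intron_bp = sum(len(i) for i in introns)
    n_i, n_e = len(introns), len(model.exons)
    return StructureStats(
        genomic_bp=exon_bp + intron_bp,
        n_introns=n_i,
        total_intron_bp=intron_bp,
        avg_intron_bp=round_half_away(intron_bp / n_i) if n_i else 0,
        n_exons=n_e,
        total_exon_bp=exon_bp,
        avg_exon_bp=round_half_away(exon_bp / n_e),
    )


def detect_clusters(
    genes: list[GeneRecord], max_gap: int = 50_000
) -> tuple[list[GeneCluster], dict[str, int]]:
    """Find tandem arrays and count distinct scaffolds per family.

    A cluster is a maximal chain of same-scaffold genes, ordered by start,
    whose consecutive intergenic gaps (next.start - prev.stop - 1) are all
    at most ``max_gap``; strand is ignored.  Overlapping genes get a gap of
    zero and a warning.  Returns the clusters plus a ``family -> number of
    distinct scaffolds`` summary.
    """
    by_scaffold: dict[str, list[GeneRecord]] = {}
    for gene in genes:
        by_scaffold.setdefault(gene.scaffold_id, []).append(gene)

    clusters: list[GeneCluster] = []
    for scaffold_id in sorted(by_scaffold):
        members = sorted(by_scaffold[scaffold_id], key=lambda g: g.location.start)
        chain = [members[0]]
        gaps: list[int] = []
        for prev, nxt in zip(members, members[1:]):
            gap = nxt.location.start - prev.location.stop - 1
            if gap < 0:
                logger.warning(
                    "overlapping genes %s and %s on scaffold %s",
                    prev.gene_id, nxt.gene_id, scaffold_id,
                )
                gap = 0
            if gap <= max_gap:
                chain.append(nxt)
                gaps.append(gap)
            else:
                if len(chain) >= 2:
                    clusters.append(_mk_cluster(scaffold_id, chain, gaps))
                chain, gaps = [nxt], []
        if len(chain) >= 2:
            clusters.append(_mk_cluster(scaffold_id, chain, gaps))

    summary: dict[str, set] = {}
    for gene in genes:
        summary.setdefault(gene.family, set()).add(gene.scaffold_id)
    return clusters, {fam: len(s) for fam, s in sorted(summary.items())}


def _mk_cluster(scaffold_id, chain, gaps) -> GeneCluster:
    return GeneCluster(
        scaffold_id=scaffold_id,
        members=list(chain),
        gaps=list(gaps),
        orientations=[g.strand for g in chain],
    )
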