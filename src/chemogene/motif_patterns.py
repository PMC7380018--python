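"""Ungapped motif discovery, motif-arrangement patterns and identity matrices.

Motifs are discovered sequentially with an expectation-maximisation fit of a
ZOOPS model (zero or one occurrence per sequence): each sequence either
contains one motif site (probability gamma, uniform over admissible starts)
or is pure background.  The background is uniform over the 20 amino acids.
The EM objective is the log-likelihood ratio of the ZOOPS mixture against
the background-only model; it is non-decreasing across iterations by the
usual EM argument and is asserted so.  Widths from ``min_w`` to ``max_w``
compete through a BIC-penalised ratio (0.5 * 19 * w * ln(expected sites)),
which stops a fully conserved core from being padded with background
columns.  After each rank the called occurrences are masked so later motifs
cannot reuse them.

A protein's *arrangement pattern* is the hyphen-joined string of motif
indices in order of occurrence along the sequence (e.g. "4-8-5-1-7-2-6");
shared arrangements across orthologues indicate conserved domain
architecture.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from Bio import Align
from scipy.special import logsumexp

from .seq_io import SequenceRecord

AA = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA)}
_PSEUDO = 1e-6  # stabilises logs without visibly flattening point masses


@dataclass
class Motif:
    index: int  # 1-based rank; low rank = found first = most conserved
    width: int
    pwm: np.ndarray  # (width, 20), rows sum to 1
    score: float  # penalised log-likelihood-ratio at selection

    def __post_init__(self):
        assert np.allclose(self.pwm.sum(axis=1), 1.0, atol=1e-9)

    @property
    def consensus(self) -> str:
        return "".join(AA[i] for i in self.pwm.argmax(axis=1))


@dataclass(frozen=True)
class MotifOccurrence:
    motif_index: int
    sequence_id: str
    start: int  # 1-based
    site_score: float


@dataclass(frozen=True)
class ArrangementPattern:
    sequence_id: str
    pattern: str


def _encode(seq: str) -> np.ndarray:
    return np.array([AA_INDEX.get(a, -1) for a in seq], dtype=np.int64)


def _window_scores(enc: np.ndarray, log_odds: np.ndarray, ok: np.ndarray) -> np.ndarray:
    """Log-odds of every admissible start (-inf elsewhere)."""
    w = log_odds.shape[0]
    n = len(enc) - w + 1
    if n <= 0:
        return np.zeros(0)
    windows = np.lib.stride_tricks.sliding_window_view(enc, w)
    safe = np.where(windows < 0, 0, windows)  # inadmissible rows masked below
    scores = log_odds[np.arange(w)[None, :], safe].sum(axis=1)
    scores[~ok] = -np.inf
    return scores


def _admissible(enc: np.ndarray, masked: np.ndarray, w: int) -> np.ndarray:
    """Starts whose window contains no unknown residue and no masked position."""
    n = len(enc) - w + 1
    if n <= 0:
        return np.zeros(0, dtype=bool)
    bad = (enc < 0) | masked
    cum = np.concatenate(([0], np.cumsum(bad)))
    return (cum[w:] - cum[:-w]) == 0


def _seed_pwm(w: int, seed_window: np.ndarray) -> np.ndarray:
    pwm = np.full((w, 20), 0.5 / 19)
    pwm[np.arange(w), seed_window] = 0.5
    return pwm


def _e_step(encs, admiss, pwm, gamma):
    """One E-step: returns (llr, posteriors, expected site count)."""
    log_odds = np.log(pwm) + np.log(20.0)
    llr = 0.0
    posteriors = []
    gamma_num = 0.0
    for enc, ok in zip(encs, admiss):
        scores = _window_scores(enc, log_odds, ok)
        m = int(ok.sum())
        if m == 0:
            posteriors.append(np.zeros(len(scores)))
            continue
        log_terms = scores + np.log(gamma / m)
        finite = np.isfinite(log_terms)
        log_num = logsumexp(log_terms[finite]) if finite.any() else -np.inf
        log_z = np.logaddexp(np.log1p(-gamma), log_num)
        llr += log_z
        post = np.exp(log_terms - log_z)
        post[~np.isfinite(post)] = 0.0
        posteriors.append(post)
        gamma_num += post.sum()
    return llr, posteriors, gamma_num


def _em_fit(
    encs,
    admiss,
    w: int,
    seed_window: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-8,
):
    """Run ZOOPS EM from one seed; returns (pwm, gamma, llr, posteriors).

    The log-likelihood ratio against the background-only model is asserted
    non-decreasing across iterations.
    """
    pwm = _seed_pwm(w, seed_window)
    gamma = 0.5
    prev_llr = -np.inf
    posteriors = None
    for _ in range(max_iter):
        llr, posteriors, gamma_num = _e_step(encs, admiss, pwm, gamma)
        assert llr >= prev_llr - 1e-6, "EM objective decreased"
        if llr - prev_llr < tol:
            prev_llr = llr
            break
        prev_llr = llr
        counts = np.full((w, 20), _PSEUDO)
        for enc, post in zip(encs, posteriors):
            sel = np.nonzero(post > 1e-12)[0]
            if sel.size:
                windows = np.lib.stride_tricks.sliding_window_view(enc, w)[sel]
                cols = np.broadcast_to(np.arange(w), windows.shape)
                np.add.at(counts, (cols, windows), post[sel, None])
        pwm = counts / counts.sum(axis=1, keepdims=True)
        gamma = min(max(gamma_num / len(encs), 1e-6), 1 - 1e-6)
    return pwm, gamma, prev_llr, posteriors


def discover_motifs(
    proteins: list[SequenceRecord],
    min_w: int = 6,
    max_w: int = 10,
    n_motifs: int = 8,
    seed: int = 1,
    site_threshold: float = 0.5,
    seed_cap: int = 150,
) -> tuple[list[Motif], list[MotifOccurrence]]:
    """Discover up to ``n_motifs`` ungapped motifs of width 6-10 by ZOOPS EM.

    Ranks are found sequentially: for each rank every admissible length-w
    subsequence seeds a short EM fit (subsampled deterministically above
    ``seed_cap`` seeds per width), the best seed is refined to convergence,
    the best width wins by BIC-penalised log-likelihood ratio, and the called
    occurrences (posterior >= ``site_threshold``) are masked before the next
    rank.  Deterministic given ``seed`` and the input order.
    """
    if len(proteins) < 2:
        raise ValueError("motif discovery needs at least 2 sequences")
    if any(len(p) < min_w for p in proteins):
        raise ValueError(f"all sequences must be at least {min_w} residues")
    rng = np.random.default_rng(seed)
    encs = [_encode(p.residues) for p in proteins]
    masks = [np.zeros(len(e), dtype=bool) for e in encs]

    motifs: list[Motif] = []
    occurrences: list[MotifOccurrence] = []
    for rank in range(1, n_motifs + 1):
        best = None  # (penalised score, w, pwm, gamma, posteriors)
        for w in range(min_w, max_w + 1):
            admiss = [_admissible(enc, msk, w) for enc, msk in zip(encs, masks)]
            seeds = []
            for si, ok in enumerate(admiss):
                seeds.extend((si, j) for j in np.nonzero(ok)[0])
            if not seeds:
                continue
            if len(seeds) > seed_cap:
                pick = rng.choice(len(seeds), size=seed_cap, replace=False)
                seeds = [seeds[i] for i in sorted(pick)]
            # cheap pass: score each seed with a single E-step
            best_seed, best_seed_llr = None, -np.inf
            for si, j in seeds:
                window = encs[si][j : j + w]
                llr, _, _ = _e_step(encs, admiss, _seed_pwm(w, window), 0.5)
                if llr > best_seed_llr:
                    best_seed, best_seed_llr = window, llr
            pwm, gamma, llr, posts = _em_fit(encs, admiss, w, best_seed)
            n_sites = max(sum(p.sum() for p in posts), 2.0)
            penalised = llr - 0.5 * 19 * w * np.log(n_sites)
            if best is None or penalised > best[0] or (
                np.isclose(penalised, best[0]) and w > best[1]
            ):
                best = (penalised, w, pwm, gamma, posts)
        if best is None:
            break
        penalised, w, pwm, gamma, posts = best
        motif = Motif(index=rank, width=w, pwm=pwm, score=float(penalised))
        called = []
        for prot, post, msk in zip(proteins, posts, masks):
            if post.size == 0 or post.max() < site_threshold:
                continue
            j = int(post.argmax())
            called.append(
                MotifOccurrence(rank, prot.id, j + 1, float(post[j]))
            )
            msk[j : j + w] = True
        motifs.append(motif)
        occurrences.extend(called)
    return motifs, occurrences


def arrangement_string(occurrences: list[MotifOccurrence]) -> ArrangementPattern:
    """Order one sequence's occurrences along the protein and join indices.

    Ties on start position put the lower motif index first; an empty
    occurrence list yields the empty pattern.
    """
    ids = {o.sequence_id for o in occurrences}
    if len(ids) > 1:
        raise ValueError(f"occurrences span multiple sequences: {sorted(ids)}")
    ordered = sorted(occurrences, key=lambda o: (o.start, o.motif_index))
    return ArrangementPattern(
        sequence_id=ids.pop() if ids else "",
        pattern="-".join(str(o.motif_index) for o in ordered),
    )


def pattern_frequencies(
    arrangements: list[ArrangementPattern], min_members: int = 4
) -> tuple[list[tuple[str, int]], list[tuple[str, int]]]:
    """Count distinct arrangement patterns and split common vs rare.

    A pattern is *common* when at least ``min_members`` proteins share it
    ("present in more than three" proteins corresponds to
    ``min_members=4``).  Both lists are sorted by descending count then
    pattern string.
    """
    counts = Counter(a.pattern for a in arrangements)
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    common = [(p, c) for p, c in ordered if c >= min_members]
    rare = [(p, c) for p, c in ordered if c < min_members]
    return common, rare


def identity_matrix(proteins: list[SequenceRecord]) -> np.ndarray:
    """Pairwise percent identity from global alignment.

    Scoring: match +1, mismatch 0, gap open -10, gap extend -0.5.  Identity
    is 100 * identical columns / alignment columns of one optimal alignment;
    the diagonal is 100.  The matrix is symmetric and invariant under
    reordering of the input (each unordered pair is aligned once).
    """
    if len(proteins) < 2:
        raise ValueError("identity_matrix needs at least 2 proteins")
    for p in proteins:
        if not p.residues:
            raise ValueError(f"{p.id}: empty sequence")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -0.5
    n = len(proteins)
    mat = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            aln = aligner.align(proteins[i].residues, proteins[j].residues)[0]
            identities = aln.counts().identities
            mat[i, j] = mat[j, i] = 100.0 * identities / aln.length
    return mat
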