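"""Cysteine-spacing signature scanning, ORF finding and OBP/CSP candidate calls.

Insect odorant binding proteins (OBPs) and chemosensory proteins (CSPs) are
recognised by the spacing of their conserved cysteines.  The classical OBP
signature is six cysteines spaced C1-X15-39-C2-X3-C3-X21-44-C4-X7-12-C5-X8-C6,
where X_k-m means k to m arbitrary residues strictly between consecutive
cysteines; the CSP signature is four cysteines spaced C1-X6-8-C2-X16-21-C3-X2-C4.
The plus-C OBP subfamily additionally carries a conserved proline immediately
after C6 and an extra cysteine (C6a) downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .seq_io import Interval, SequenceRecord


class AlphabetError(ValueError):
    pass


class MatchError(ValueError):
    pass


@dataclass(frozen=True)
class CysteinePattern:
    """An ordered list of inter-cysteine gap ranges (residues between Cs)."""

    label: str
    gaps: tuple[tuple[int, int], ...]

    def __post_init__(self):
        for lo, hi in self.gaps:
            if not (0 <= lo <= hi):
                raise ValueError(f"invalid gap range ({lo},{hi})")

    @property
    def n_cys(self) -> int:
        return len(self.gaps) + 1

    @property
    def min_span(self) -> int:
        return self.n_cys + sum(lo for lo, _ in self.gaps)

    @property
    def max_span(self) -> int:
        return self.n_cys + sum(hi for _, hi in self.gaps)


OBP_CLASSICAL = CysteinePattern(
    "OBP_classical", ((15, 39), (3, 3), (21, 44), (7, 12), (8, 8))
)
CSP_PATTERN = CysteinePattern("CSP", ((6, 8), (16, 21), (2, 2)))


@dataclass
class PatternMatch:
    sequence_id: str
    cys_positions: tuple[int, ...]  # 1-based, strictly increasing
    label: str
    subfamily: str = "n/a"  # classical | plus_C | n/a
    extra: dict = field(default_factory=dict)  # c6a / proline positions


@dataclass
class OrfHit:
    """An open reading frame on a transcript.

    ``location`` covers the start codon through the last sense codon on the
    forward axis of the input sequence (stop codon excluded), so
    ``orf_bp = len(location)`` and the protein is ``orf_bp / 3`` residues.
    """

    frame: int  # +1,+2,+3,-1,-2,-3
    location: Interval
    orf_bp: int
    protein: str

    def __post_init__(self):
        assert self.orf_bp % 3 == 0
        assert len(self.protein) == self.orf_bp // 3
        assert self.protein.startswith("M") and "*" not in self.protein


def scan_pattern(
    protein: SequenceRecord,
    pattern: CysteinePattern,
    mode: str = "first",
) -> list[PatternMatch]:
    """Find placements of a cysteine-spacing signature on a protein.

    A placement is an increasing vector of cysteine positions whose
    consecutive gaps (residues strictly between) all lie within the
    pattern's bounds; intervening residues may themselves be cysteines.
    ``mode="all"`` enumerates every placement; ``mode="first"`` returns the
    lexicographically smallest position vector only.
    """
    if protein.alphabet != "protein":
        raise AlphabetError(f"{protein.id}: scan_pattern needs a protein sequence")
    if mode not in ("first", "all"):
        raise ValueError(f"unknown mode {mode!r}")

    seq = protein.residues
    cys = [i + 1 for i, aa in enumerate(seq) if aa == "C"]  # 1-based
    matches: list[PatternMatch] = []

    def extend(placed: list[int], gap_idx: int) -> bool:
        # Returns True when mode=first and a full placement was emitted.
        if gap_idx == len(pattern.gaps):
            matches.append(
                PatternMatch(protein.id, tuple(placed), pattern.label)
            )
            return mode == "first"
        lo, hi = pattern.gaps[gap_idx]
        prev = placed[-1]
        for pos in cys:
            gap = pos - prev - 1
            if gap < lo:
                continue
            if gap > hi:
                break
            if extend(placed + [pos], gap_idx + 1):
                return True
        return False

    for start in cys:
        if extend([start], 0) and mode == "first":
            break
    return matches


def classify_obp(
    protein: SequenceRecord, match: PatternMatch, plusc_window: int = 30
) -> PatternMatch:
    """Assign a classical-pattern OBP match to the classical or plus-C subfamily.

    plus-C requires a proline immediately after C6 and at least one further
    cysteine within ``plusc_window`` residues downstream of C6; otherwise the
    match is classical.  The returned match carries the subfamily and, for
    plus-C, the proline and C6a positions.
    """
    if match.label != "OBP_classical":
        raise MatchError("classify_obp expects a classical OBP match")
    seq = protein.residues
    for pos in match.cys_positions:
        if pos < 1 or pos > len(seq) or seq[pos - 1] != "C":
            raise MatchError(
                f"{protein.id}: position {pos} does not hold a cysteine"
            )
    c6 = match.cys_positions[-1]
    subfamily = "classical"
    extra: dict = {}
    if c6 < len(seq) and seq[c6] == "P":  # residue immediately after C6
        window = seq[c6 + 1 : c6 + 1 + plusc_window]
        offset = window.find("C")
        if offset >= 0:
            subfamily = "plus_C"
            extra = {"proline": c6 + 1, "c6a": c6 + 2 + offset}
    return PatternMatch(
        match.sequence_id, match.cys_positions, match.label, subfamily, extra
    )


_STOPS = {"TAA", "TAG", "TGA"}


def find_orfs(
    transcript: SequenceRecord,
    min_aa: int = 80,
    search_reverse: bool = True,
) -> list[OrfHit]:
    """Find every ATG-to-stop open reading frame of at least ``min_aa`` codons.

    All three forward frames are scanned, plus the three reverse frames when
    ``search_reverse`` is set.  Spans lacking an in-frame stop are excluded.
    Coordinates are reported on the forward axis of the input transcript,
    1-based inclusive, stop codon excluded.  Hits are sorted longest-first
    (ties by forward-axis start, then frame).
    """
    if transcript.alphabet != "dna":
        raise AlphabetError(f"{transcript.id}: find_orfs needs a DNA sequence")
    n = len(transcript.residues)
    hits: list[OrfHit] = []
    strands = [(+1, transcript.residues)]
    if search_reverse:
        strands.append((-1, str(Seq(transcript.residues).reverse_complement())))
    for sign, seq in strands:
        for off in range(3):
            frame = sign * (off + 1)
            codons = [seq[i : i + 3] for i in range(off, len(seq) - 2, 3)]
            # stop positions per frame, then every ATG before its next stop
            stop_idx = [i for i, c in enumerate(codons) if c in _STOPS]
            next_stop = {}
            si = 0
            for i in range(len(codons)):
                while si < len(stop_idx) and stop_idx[si] < i:
                    si += 1
                next_stop[i] = stop_idx[si] if si < len(stop_idx) else None
            for i, codon in enumerate(codons):
                if codon != "ATG":
                    continue
                stop = next_stop[i]
                if stop is None:
                    continue
                n_codons = stop - i
                if n_codons < min_aa:
                    continue
                protein = str(Seq("".join(codons[i:stop])).translate())
                s = off + 3 * i + 1  # 1-based on this strand's axis
                e = off + 3 * stop  # last sense base
                if sign == 1:
                    loc = Interval(s, e)
                else:
                    loc = Interval(n - e + 1, n - s + 1)
                hits.append(OrfHit(frame, loc, 3 * n_codons, protein))
    hits.sort(key=lambda h: (-h.orf_bp, h.location.start, h.frame))
    return hits


def annotate_candidates(
    proteins: list[SequenceRecord],
    patterns: tuple[CysteinePattern, CysteinePattern] = (OBP_CLASSICAL, CSP_PATTERN),
    plusc_window: int = 30,
) -> list[dict]:
    """Label each protein OBP / CSP / other by its spacing signatures.

    A protein matching the six-cysteine classical pattern is an OBP (and is
    sub-classified classical vs plus-C); one matching only the four-cysteine
    pattern is a CSP.  A protein matching both is labelled OBP — the
    six-cysteine signature is the more specific — with ``ambiguous`` set.
    """
    obp_pattern, csp_pattern = patterns
    rows: list[dict] = []
    for prot in proteins:
        obp_hits = scan_pattern(prot, obp_pattern, mode="first")
        csp_hits = scan_pattern(prot, csp_pattern, mode="first")
        if obp_hits:
            match = classify_obp(prot, obp_hits[0], plusc_window)
            rows.append({
                "sequence_id": prot.id,
                "family": "OBP",
                "subfamily": match.subfamily,
                "cys_positions": match.cys_positions,
                "ambiguous": bool(csp_hits),
            })
        elif csp_hits:
            rows.append({
                "sequence_id": prot.id,
                "family": "CSP",
                "subfamily": "n/a",
                "cys_positions": csp_hits[0].cys_positions,
                "ambiguous": False,
            })
        else:
            rows.append({
                "sequence_id": prot.id,
                "family": "other",
                "subfamily": "n/a",
                "cys_positions": (),
                "ambiguous": False,
            })
    return rows
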