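"""Seeded generators for every input the pipeline consumes, with planted truth.

These generators emulate the statistical structure of the study system: aphid
scaffolds carrying multi-exon chemosensory genes whose introns obey the GT-AG
rule (intron counts 0-8 and genomic sizes bracketing the published per-gene
ranges), protein families carrying planted cysteine-spacing signatures and
planted ungapped motifs, read-count tables with known true abundances, and
qPCR CT tables generated under known amplification efficiencies and fold
changes.  Every generator is a pure function of its spec and seed, and every
output comes with the ground truth needed to score the downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .motif_scan import CSP_PATTERN, OBP_CLASSICAL, CysteinePattern
from .seq_io import GeneModel, Interval, SequenceRecord

_BASES = np.array(list("ACGT"))
_AAS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


class InfeasibleSpecError(ValueError):
    pass


@dataclass
class GenomeSpec:
    """Parameters of the synthetic scaffold/gene generator.

    Defaults mirror the published gene set: intron counts up to 8 per gene
    and log-uniform intron lengths over [30, 17000] bp, bracketing the
    printed per-gene intron totals (2419-16384 bp for the OBPs).
    """

    n_genes: int = 9
    intron_counts: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8)
    intron_count_probs: tuple[float, ...] | None = None
    intron_len_range: tuple[int, int] = (30, 17_000)
    exon_len_range: tuple[int, int] = (40, 450)
    flank: int = 200
    gc: float = 0.35
    minus_strand_prob: float = 0.5
    seed: int = 1

    def __post_init__(self):
        if self.exon_len_range[0] < 1:
            raise InfeasibleSpecError("exons must be at least 1 bp")
        if self.intron_len_range[0] < 4:
            raise InfeasibleSpecError("introns must fit GT..AG (>= 4 bp)")
        if min(self.intron_counts) < 0 or max(self.intron_counts) > 8:
            raise InfeasibleSpecError("intron counts supported on 0..8")


@dataclass
class FamilySpec:
    """Parameters of the synthetic protein-family generator."""

    pattern: CysteinePattern = OBP_CLASSICAL
    n_members: int = 20
    n_decoys: int = 0
    n_term_range: tuple[int, int] = (15, 30)
    c_term_range: tuple[int, int] = (10, 40)
    motif: str = ""  # planted ungapped motif, inserted in the C-terminal tail
    motif_prob: float = 1.0
    background_freqs: dict[str, float] | None = None
    seed: int = 1


def obp_like_genome_spec(seed: int = 1, n_genes: int = 9) -> GenomeSpec:
    """A GenomeSpec calibrated to the published aphid OBP gene structures.

    Intron counts are drawn from the empirical per-gene counts of the nine
    published OBPs (4,5,6,6,6,6,6,7,8); exon lengths are uniform on
    [40, 120] bp (published mean exon ~78 bp) and intron lengths log-uniform
    on [30, 5600] bp (published mean intron ~1062 bp), so the expected
    genomic length is ~6.9 kb, matching the published family mean.
    """
    return GenomeSpec(
        n_genes=n_genes,
        intron_counts=(4, 5, 6, 6, 6, 6, 6, 7, 8),
        intron_len_range=(30, 5_600),
        exon_len_range=(40, 120),
        seed=seed,
    )


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=n, p=p))


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def gen_genome(
    spec: GenomeSpec,
) -> tuple[list[SequenceRecord], list[GeneModel], list[SequenceRecord]]:
    """Generate scaffolds, truth gene models and the spliced mRNAs.

    One gene per scaffold; every planted intron begins GT and ends AG, and
    intron interiors avoid starting with GT or ending with AG near the
    junctions being trivially ambiguous.  Truth models carry exact exon
    intervals on the forward axis; mRNAs are the spliced exons
    (reverse-complemented for minus-strand genes).  Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    scaffolds: list[SequenceRecord] = []
    models: list[GeneModel] = []
    mrnas: list[SequenceRecord] = []
    lo_i, hi_i = spec.intron_len_range
    for gi in range(spec.n_genes):
        n_introns = int(
            rng.choice(spec.intron_counts, p=spec.intron_count_probs)
        )
        n_exons = n_introns + 1
        exon_lens = rng.integers(
            spec.exon_len_range[0], spec.exon_len_range[1] + 1, size=n_exons
        )
        intron_lens = np.exp(
            rng.uniform(np.log(lo_i), np.log(hi_i), size=n_introns)
        ).astype(int)
        intron_lens = np.clip(intron_lens, lo_i, hi_i)

        exons_seq = [_random_dna(rng, int(l), spec.gc) for l in exon_lens]
        introns_seq = []
        for l in intron_lens:
            interior = _random_dna(rng, int(l) - 4, spec.gc)
            introns_seq.append("GT" + interior + "AG")

        gene_seq_parts = []
        for i, ex in enumerate(exons_seq):
            gene_seq_parts.append(ex)
            if i < n_introns:
                gene_seq_parts.append(introns_seq[i])
        gene_seq = "".join(gene_seq_parts)
        left = _random_dna(rng, spec.flank, spec.gc)
        right = _random_dna(rng, spec.flank, spec.gc)
        strand = "-" if rng.random() < spec.minus_strand_prob else "+"
        scaffold_seq = left + gene_seq + right

        # exon intervals on the forward axis (gene planted in forward sense,
        # then the whole scaffold is reverse-complemented for minus genes so
        # the truth coordinates must be flipped).
        pos = spec.flank + 1
        exons_fwd = []
        for i, l in enumerate(exon_lens):
            exons_fwd.append(Interval(pos, pos + int(l) - 1))
            pos += int(l)
            if i < n_introns:
                pos += int(intron_lens[i])
        mrna_seq = "".join(exons_seq)
        if strand == "-":
            n = len(scaffold_seq)
            scaffold_seq = _revcomp(scaffold_seq)
            exons_fwd = [
                Interval(n - e.stop + 1, n - e.start + 1) for e in exons_fwd
            ][::-1]

        sid = f"scaffold_{gi + 1}"
        gid = f"gene_{gi + 1}"
        scaffolds.append(SequenceRecord(sid, scaffold_seq, "dna"))
        models.append(GeneModel(gid, sid, strand, exons_fwd, mrna_id=f"{gid}.mrna"))
        mrnas.append(SequenceRecord(f"{gid}.mrna", mrna_seq, "dna"))
    return scaffolds, models, mrnas


def gen_family(
    spec: FamilySpec,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Generate proteins carrying a planted cysteine-spacing signature.

    Members always satisfy the pattern (background residues avoid cysteine
    so the planted placement is the signature); decoys are global shuffles
    of member-like sequences, which scatter the cysteines and generally
    break the spacing.  Returns the proteins and a truth table with the
    planted cysteine positions and motif offsets (1-based; -1 = absent).
    """
    rng = np.random.default_rng(spec.seed)
    if spec.background_freqs:
        letters = np.array(list(spec.background_freqs))
        probs = np.array(list(spec.background_freqs.values()), dtype=float)
        probs = probs / probs.sum()
    else:
        letters = np.array([a for a in _AAS if a != "C"])
        probs = np.full(len(letters), 1 / len(letters))

    def background(n: int) -> str:
        if n == 0:
            return ""
        return "".join(rng.choice(letters, size=n, p=probs))

    proteins: list[SequenceRecord] = []
    truth_rows = []
    for mi in range(spec.n_members):
        n_term = int(rng.integers(*spec.n_term_range))
        parts = [background(n_term), "C"]
        cys_positions = [n_term + 1]
        for lo, hi in spec.pattern.gaps:
            gap = int(rng.integers(lo, hi + 1))
            parts.append(background(gap))
            parts.append("C")
            cys_positions.append(cys_positions[-1] + gap + 1)
        c_term_len = int(rng.integers(*spec.c_term_range))
        motif_offset = -1
        c_term = background(c_term_len)
        if spec.motif and rng.random() < spec.motif_prob:
            if c_term_len < len(spec.motif):
                raise InfeasibleSpecError(
                    "C-terminal tail too short for the planted motif"
                )
            ins = int(rng.integers(0, c_term_len - len(spec.motif) + 1))
            c_term = c_term[:ins] + spec.motif + c_term[ins + len(spec.motif):]
            motif_offset = cys_positions[-1] + ins + 1
        parts.append(c_term)
        seq = "".join(parts)
        pid = f"member_{mi + 1}"
        proteins.append(SequenceRecord(pid, seq, "protein"))
        truth_rows.append({
            "sequence_id": pid,
            "planted": True,
            "cys_positions": tuple(cys_positions),
            "motif_start": motif_offset,
        })

    for di in range(spec.n_decoys):
        template = proteins[di % max(spec.n_members, 1)].residues if spec.n_members else background(
            spec.pattern.max_span + 40
        )
        shuffled = "".join(rng.permutation(list(template)))
        pid = f"decoy_{di + 1}"
        proteins.append(SequenceRecord(pid, shuffled, "protein"))
        truth_rows.append({
            "sequence_id": pid,
            "planted": False,
            "cys_positions": (),
            "motif_start": -1,
        })
    return proteins, pd.DataFrame(truth_rows)


def gen_counts(
    abundances: dict[str, float],
    lengths: dict[str, int],
    N: int,
    seed: int = 1,
    noise: bool = True,
) -> pd.DataFrame:
    """Read counts with expectation proportional to abundance x length.

    With ``noise`` the counts are Poisson around expectation (the simplest
    model under which RPKM is the natural estimator); without it they are
    the expectations themselves, so RPKM recovers the abundances up to one
    global scale factor exactly.
    """
    rng = np.random.default_rng(seed)
    genes = list(abundances)
    weights = np.array(
        [abundances[g] * lengths[g] for g in genes], dtype=float
    )
    if (weights < 0).any():
        raise ValueError("abundances must be non-negative")
    expected = N * weights / weights.sum()
    counts = rng.poisson(expected) if noise else expected
    return pd.DataFrame({
        "gene": genes,
        "count": counts,
        "length": [lengths[g] for g in genes],
        "library_size": N,
        "true_abundance": [abundances[g] for g in genes],
    })


def gen_qpcr(
    folds: dict[str, dict[str, float]],
    reference: str = "GAPDH",
    calibrator: str = "body",
    efficiencies: dict[str, float] | None = None,
    noise_sd: float = 0.15,
    n_bio: int = 3,
    n_tech: int = 3,
    base_ct: float = 22.0,
    dilution_points: int = 5,
    dilution_factor: float = 5.0,
    seed: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """CT observations under known fold changes and efficiencies.

    ``folds[gene][tissue]`` is the true expression relative to the
    calibrator tissue.  CT = base_ct - log_E(template); the reference gene
    has fold 1 everywhere, so with both efficiencies equal to 2 a noiseless
    table makes the ddCT fold recovery exact.  Also returns a fivefold
    dilution series per gene (CT of target and reference at each dilution)
    for the slope and efficiency checks.
    """
    rng = np.random.default_rng(seed)
    efficiencies = efficiencies or {}
    e_ref = efficiencies.get(reference, 2.0)
    tissues = sorted({t for g in folds.values() for t in g})
    rows = []
    all_genes = list(folds) + [reference]
    for gene in all_genes:
        e = efficiencies.get(gene, 2.0)
        for tissue in tissues:
            rel = 1.0 if gene == reference else folds[gene].get(tissue, 1.0)
            if rel <= 0:
                raise ValueError("fold changes must be positive")
            ct_true = base_ct - np.log(rel) / np.log(e)
            for b in range(1, n_bio + 1):
                for t in range(1, n_tech + 1):
                    ct = ct_true + (rng.normal(0, noise_sd) if noise_sd else 0.0)
                    rows.append({
                        "gene": gene, "tissue": tissue, "bio_rep": b,
                        "tech_rep": t, "ct": ct,
                    })
    ct_table = pd.DataFrame(rows)

    dil_rows = []
    factors = dilution_factor ** np.arange(dilution_points)
    for gene in all_genes:
        e = efficiencies.get(gene, 2.0)
        for d in factors:
            template = 1.0 / d
            ct = base_ct - np.log(template) / np.log(e)
            if noise_sd:
                ct += rng.normal(0, noise_sd)
            dil_rows.append({"gene": gene, "dilution": d, "ct": ct})
    dilution = pd.DataFrame(dil_rows)
    return ct_table, dilution
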