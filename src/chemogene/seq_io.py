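"""Sequence, coordinate and table I/O shared by every pipeline stage.

All genomic coordinates are 1-based and fully inclusive: an interval
``(start, stop)`` covers ``stop - start + 1`` bases.  This is the convention
of the published gene tables this package consumes (a gene spanning
340085…345920 has a genomic size of 5836 bp), and every internal data
structure uses it.  Half-open arithmetic appears only inside serialization
helpers, never in the data model.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("chemogene")

DNA_ALPHABET = set("ACGTN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


class SeqIOError(ValueError):
    """Base class for reader/writer errors."""


class MalformedHeaderError(SeqIOError):
    pass


class EmptyRecordError(SeqIOError):
    pass


class DuplicateIdError(SeqIOError):
    pass


class IllegalCharacterError(SeqIOError):
    pass


class CoordinateError(SeqIOError):
    pass


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide or protein sequence.

    ``alphabet`` is ``"dna"`` (A/C/G/T/N) or ``"protein"`` (20 amino acids
    plus X).  Residues are stored upper-case; construction validates them.
    """

    id: str
    residues: str
    alphabet: str = "dna"
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise MalformedHeaderError("sequence id must be non-empty")
        if not self.residues:
            raise EmptyRecordError(f"record {self.id!r} has no residues")
        allowed = DNA_ALPHABET if self.alphabet == "dna" else PROTEIN_ALPHABET
        if self.alphabet not in ("dna", "protein"):
            raise SeqIOError(f"unknown alphabet {self.alphabet!r}")
        bad = set(self.residues) - allowed
        if bad:
            raise IllegalCharacterError(
                f"record {self.id!r}: illegal {self.alphabet} character(s) "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True, order=True)
class Interval:
    """1-based fully inclusive genomic interval."""

    start: int
    stop: int

    def __post_init__(self):
        if self.start < 1:
            raise CoordinateError(f"start must be >= 1, got {self.start}")
        if self.stop < self.start:
            raise CoordinateError(
                f"stop < start ({self.stop} < {self.start})"
            )

    def __len__(self) -> int:
        return self.stop - self.start + 1


@dataclass
class GeneModel:
    """Exon structure of one gene on a scaffold.

    Exons are kept in ascending genomic order regardless of strand; introns
    are exactly the gaps between consecutive exons.
    """

    gene_id: str
    scaffold_id: str
    strand: str
    exons: list[Interval]
    mrna_id: str = ""

    def __post_init__(self):
        if self.strand not in "+-":
            raise CoordinateError(f"strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise CoordinateError(f"gene {self.gene_id}: at least one exon required")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.stop:
                raise CoordinateError(
                    f"gene {self.gene_id}: overlapping exons {a} and {b}"
                )

    @property
    def introns(self) -> list[Interval]:
        return [
            Interval(a.stop + 1, b.start - 1)
            for a, b in zip(self.exons, self.exons[1:])
        ]

    @property
    def span(self) -> Interval:
        return Interval(self.exons[0].start, self.exons[-1].stop)


@dataclass
class GeneRecord:
    """One row of a gene table: family assignment, location, ORF/protein sizes."""

    gene_id: str
    family: str
    scaffold_id: str
    location: Interval
    strand: str
    orf_bp: int = 0
    aa_len: int = 0
    signal_peptide: Interval | None = None
    rpkm: float | None = None
    accession: str = ""

    def __post_init__(self):
        if self.family not in ("OBP", "CSP", "other"):
            raise SeqIOError(f"unknown family {self.family!r}")
        if self.strand not in "+-":
            raise CoordinateError(f"unknown strand token {self.strand!r}")
        if self.orf_bp and self.orf_bp % 3 != 0:
            raise SeqIOError(
                f"{self.gene_id}: orf_bp {self.orf_bp} not divisible by 3"
            )
        if self.orf_bp and self.aa_len and self.aa_len * 3 != self.orf_bp:
            raise SeqIOError(
                f"{self.gene_id}: aa_len {self.aa_len} != orf_bp/3 "
                f"({self.orf_bp}/3)"
            )


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path, alphabet: str = "dna") -> list[SequenceRecord]:
    """Read a FASTA file into validated :class:`SequenceRecord` objects.

    Residues are upper-cased; record order is preserved; duplicate ids,
    empty records and out-of-alphabet characters raise distinct errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        first = fh.read(1)
        if first and first != ">":
            raise MalformedHeaderError(f"{path}: FASTA must start with '>'")
        fh.seek(0)
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise DuplicateIdError(f"{path}: duplicate id {rec.id!r}")
            seen.add(rec.id)
            records.append(
                SequenceRecord(
                    id=rec.id,
                    residues=str(rec.seq).upper(),
                    alphabet=alphabet,
                    description=rec.description[len(rec.id):].strip(),
                )
            )
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60) -> None:
    seqs = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


# ---------------------------------------------------------------------------
# Gene tables

_LOCATION_RE = re.compile(
    r"^\s*(?P<scaffold>\S+)\s*\(\s*(?P<start>[\d,\s]+?)\s*(?:…|\.\.+)\s*"
    r"(?P<stop>[\d,\s]+?)\s*,\s*(?P<strand>[+\-−])\s*\)\s*$"
)


def _parse_int(token: str) -> int:
    cleaned = token.replace(",", "").replace(" ", "").replace(" ", "")
    if not cleaned.isdigit():
        raise CoordinateError(f"non-integer coordinate {token!r}")
    return int(cleaned)


def parse_location(text: str) -> tuple[str, Interval, str]:
    """Parse ``"105 (340085…345920,-)"`` into scaffold, interval and strand.

    Accepts the ellipsis "…" or "..", thousands separators, and either the
    ASCII hyphen or the unicode minus for the reverse strand.
    """
    m = _LOCATION_RE.match(text)
    if m is None:
        raise CoordinateError(f"unparseable location {text!r}")
    start = _parse_int(m.group("start"))
    stop = _parse_int(m.group("stop"))
    strand = "-" if m.group("strand") in "−-" else "+"
    return m.group("scaffold"), Interval(start, stop), strand


GENE_TABLE_COLUMNS = [
    "gene_id", "family", "rpkm", "signal_peptide", "aa_len", "orf_bp",
    "location", "accession",
]


def read_gene_table(path) -> list[GeneRecord]:
    """Read a TSV gene table (one row per gene, printed-table conventions).

    Expected columns: gene_id, family, rpkm, signal_peptide ("1-19" or
    "none"), aa_len, orf_bp, location ("scaffold (start…stop,strand)"),
    accession.  Coordinates follow the 1-based inclusive convention.
    """
    records: list[GeneRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        missing = [c for c in GENE_TABLE_COLUMNS[:7] if c not in idx]
        if missing:
            raise SeqIOError(f"{path}: missing gene-table column(s) {missing}")
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            scaffold, location, strand = parse_location(f[idx["location"]])
            sp_text = f[idx["signal_peptide"]].strip().lower()
            sp = None
            if sp_text not in ("", "none", "no sp"):
                a, b = re.split(r"[–\-]", f[idx["signal_peptide"]].strip())
                sp = Interval(int(a), int(b))
            records.append(
                GeneRecord(
                    gene_id=f[idx["gene_id"]],
                    family=f[idx["family"]],
                    scaffold_id=scaffold,
                    location=location,
                    strand=strand,
                    orf_bp=int(f[idx["orf_bp"]]),
                    aa_len=int(f[idx["aa_len"]]),
                    signal_peptide=sp,
                    rpkm=float(f[idx["rpkm"]]) if f[idx["rpkm"]] else None,
                    accession=f[idx["accession"]] if "accession" in idx and len(f) > idx["accession"] else "",
                )
            )
    return records


def write_gene_table(records: Iterable[GeneRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(GENE_TABLE_COLUMNS) + "\n")
        for r in records:
            sp = f"{r.signal_peptide.start}-{r.signal_peptide.stop}" if r.signal_peptide else "none"
            rpkm = "" if r.rpkm is None else f"{r.rpkm:g}"
            loc = f"{r.scaffold_id} ({r.location.start}..{r.location.stop},{r.strand})"
            fh.write(
                "\t".join([
                    r.gene_id, r.family, rpkm, sp, str(r.aa_len),
                    str(r.orf_bp), loc, r.accession,
                ]) + "\n"
            )


# ---------------------------------------------------------------------------
# Structure tables (intron/exon statistics)

STRUCTURE_TABLE_COLUMNS = [
    "gene_id", "genomic_bp", "n_introns", "total_intron_bp", "avg_intron_bp",
    "n_exons", "total_exon_bp", "avg_exon_bp",
]


def write_structure_table(rows: Sequence[tuple], path) -> None:
    """Write per-gene structure statistics as TSV.

    ``rows`` are ``(gene_id, StructureStats)`` pairs; the column order is the
    printed-table schema (genomic size, intron count/total/average, exon
    count/total/average), averages already rounded to integers.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(STRUCTURE_TABLE_COLUMNS) + "\n")
        for gene_id, s in rows:
            fh.write(
                "\t".join(str(v) for v in (
                    gene_id, s.genomic_bp, s.n_introns, s.total_intron_bp,
                    s.avg_intron_bp, s.n_exons, s.total_exon_bp, s.avg_exon_bp,
                )) + "\n"
            )


def read_structure_table(path) -> list[tuple]:
    """Inverse of :func:`write_structure_table` (round-trip identity)."""
    from .gene_structure import StructureStats  # local import: avoid cycle

    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != STRUCTURE_TABLE_COLUMNS:
            raise SeqIOError(f"{path}: unexpected structure-table header")
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            out.append((
                f[0],
                StructureStats(*(int(v) for v in f[1:])),
            ))
    return out


# ---------------------------------------------------------------------------
# GFF3

def write_gff3(models: Iterable[GeneModel], path) -> None:
    """Write gene models as GFF3 (gene + exon features, 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            span = m.span
            fh.write(
                f"{m.scaffold_id}\tchemogene\tgene\t{span.start}\t{span.stop}"
                f"\t.\t{m.strand}\t.\tID={m.gene_id}\n"
            )
            for i, e in enumerate(m.exons, 1):
                fh.write(
                    f"{m.scaffold_id}\tchemogene\texon\t{e.start}\t{e.stop}"
                    f"\t.\t{m.strand}\t.\tID={m.gene_id}.exon{i};Parent={m.gene_id}\n"
                )


def read_gff3_models(path) -> list[GeneModel]:
    """Read exon features grouped by Parent back into GeneModels."""
    genes: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9:
                raise SeqIOError(f"{path}: malformed GFF3 line: {line!r}")
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            if f[2] == "gene":
                gid = attrs["ID"]
                genes[gid] = {"scaffold": f[0], "strand": f[6], "exons": []}
                order.append(gid)
            elif f[2] == "exon":
                gid = attrs["Parent"]
                genes.setdefault(gid, {"scaffold": f[0], "strand": f[6], "exons": []})
                if gid not in order:
                    order.append(gid)
                genes[gid]["exons"].append(Interval(int(f[3]), int(f[4])))
    return [
        GeneModel(
            gene_id=gid,
            scaffold_id=genes[gid]["scaffold"],
            strand=genes[gid]["strand"],
            exons=genes[gid]["exons"],
        )
        for gid in order
    ]


# ---------------------------------------------------------------------------
# Config & logging

DEFAULT_CONFIG = {
    "plusc_window": 30,
    "cluster_max_gap": 50_000,
    "match_score": 1,
    "mismatch_penalty": 3,
    "intron_open": 8,
    "noncanonical_penalty": 10,
    "min_intron": 30,
    "min_coverage": 0.95,
    "motif_min_w": 6,
    "motif_max_w": 10,
    "motif_n": 8,
    "motif_site_threshold": 0.5,
    "calibrator": "body",
    "reference_gene": "GAPDH",
    "min_orf_aa": 80,
    "qpcr_noise_sd": 0.15,
    "seed": 1,
}


class ConfigError(ValueError):
    pass


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Load the YAML config, rejecting unknown keys; missing keys default."""
    cfg = dict(DEFAULT_CONFIG)
    loaded = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
    for source in (loaded, overrides or {}):
        for key, value in source.items():
            if key not in DEFAULT_CONFIG and not key.startswith("path_"):
                raise ConfigError(f"unknown config key {key!r}")
            cfg[key] = value
    return cfg


def setup_logging(verbose: bool = False) -> None:
    handler = logging.StreamHandler()  # stderr
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)


# ---------------------------------------------------------------------------
# Bundled printed tables (green peach aphid OBP/CSP gene set)

_DATA_DIR = Path(__file__).parent / "data"


def load_reference_gene_table() -> list[GeneRecord]:
    """The published 18-gene green peach aphid OBP/CSP table bundled as data."""
    return read_gene_table(_DATA_DIR / "mper_genes.tsv")


def load_reference_structure_table() -> list[tuple]:
    """The published intron/exon statistics for the same 18 genes."""
    return read_structure_table(_DATA_DIR / "mper_structure.tsv")
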