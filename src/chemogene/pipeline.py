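"""End-to-end orchestration: scan -> structure -> clusters -> motifs -> quantify.

One config (YAML) drives all stages; each stage can also be run alone from
the command line.  A run writes its report tables plus a manifest recording
the package version, the seed, the resolved configuration and its hash, so
re-running with an identical config reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .gene_structure import (
    UnmappableError, detect_clusters, spliced_align, structure_stats,
)
from .motif_patterns import arrangement_string, discover_motifs, pattern_frequencies
from .motif_scan import annotate_candidates
from .quantification import ddct_fold, rpkm_table, tukey_letters
from .seq_io import (
    read_fasta, read_gene_table, write_gff3, write_structure_table,
)

logger = logging.getLogger("chemogene")


class StageError(RuntimeError):
    def __init__(self, stage: str, record: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on {record!r}: {cause}")
        self.stage = stage
        self.record = record
        self.cause = cause


def config_hash(config: dict) -> str:
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _read_map(path) -> list[tuple[str, str, str]]:
    rows = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            if line.strip():
                mrna_id, scaffold_id, strand = line.split()[:3]
                rows.append((mrna_id, scaffold_id, strand))
    return rows


def run_pipeline(config: dict, out_dir) -> dict:
    """Run every configured stage and write the report bundle.

    Input paths come from ``path_*`` config keys (any subset): proteins
    (FASTA), mrnas + genome (+ optional mrna_map TSV: mrna_id, scaffold_id,
    strand), gene_table (TSV), counts (TSV), ct (TSV).  Returns the manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.get("seed", 1),
        "config_hash": config_hash(config),
        "config": {k: str(v) if isinstance(v, Path) else v for k, v in config.items()},
        "tables": [],
    }

    def emit(name: str):
        manifest["tables"].append(name)
        return out / name

    # --- scan: cysteine-signature annotation -----------------------------
    if "path_proteins" in config:
        proteins = read_fasta(config["path_proteins"], alphabet="protein")
        try:
            rows = annotate_candidates(
                proteins, plusc_window=config.get("plusc_window", 30)
            )
        except Exception as exc:  # pragma: no cover - defensive
            raise StageError("scan", "protein set", exc) from exc
        frame = pd.DataFrame(
            rows, columns=["sequence_id", "family", "subfamily", "cys_positions", "ambiguous"]
        )
        frame["cys_positions"] = frame["cys_positions"].map(
            lambda t: ",".join(map(str, t))
        )
        frame.to_csv(emit("candidates.tsv"), sep="\t", index=False)
    else:
        proteins = []

    # --- structure: spliced alignment + statistics ------------------------
    if "path_mrnas" in config and "path_genome" in config:
        mrnas = read_fasta(config["path_mrnas"], alphabet="dna")
        scaffolds = {s.id: s for s in read_fasta(config["path_genome"], alphabet="dna")}
        if "path_mrna_map" in config:
            pairs = _read_map(config["path_mrna_map"])
        else:
            pairs = [
                (m.id, s, "?") for m, s in zip(mrnas, scaffolds)
            ]
        mrna_by_id = {m.id: m for m in mrnas}
        models, stat_rows = [], []
        for mrna_id, scaffold_id, strand in pairs:
            try:
                mrna = mrna_by_id[mrna_id]
                genomic = scaffolds[scaffold_id]
                if strand in "+-":
                    aln = spliced_align(
                        mrna, genomic, strand,
                        match_score=config.get("match_score", 1),
                        mismatch_penalty=config.get("mismatch_penalty", 3),
                        intron_open=config.get("intron_open", 8),
                        noncanonical_penalty=config.get("noncanonical_penalty", 10),
                        min_intron=config.get("min_intron", 30),
                        min_coverage=config.get("min_coverage", 0.95),
                    )
                else:  # strand unknown: take the better of the two
                    best = None
                    for s in "+-":
                        try:
                            cand = spliced_align(mrna, genomic, s)
                        except UnmappableError:
                            continue
                        if best is None or cand.score > best.score:
                            best = cand
                    if best is None:
                        raise UnmappableError(f"{mrna_id}: unmappable on both strands")
                    aln = best
            except Exception as exc:
                raise StageError("structure", mrna_id, exc) from exc
            models.append(aln.gene_model)
            stat_rows.append((aln.gene_model.gene_id, structure_stats(aln.gene_model)))
        write_structure_table(stat_rows, emit("structure.tsv"))
        write_gff3(models, emit("models.gff3"))

    # --- clusters ---------------------------------------------------------
    if "path_gene_table" in config:
        genes = read_gene_table(config["path_gene_table"])
        clusters, summary = detect_clusters(
            genes, max_gap=config.get("cluster_max_gap", 50_000)
        )
        with open(emit("clusters.tsv"), "w") as fh:
            fh.write("scaffold_id\tmembers\tgaps\torientations\n")
            for c in clusters:
                fh.write(
                    f"{c.scaffold_id}\t"
                    + ",".join(m.gene_id for m in c.members) + "\t"
                    + ",".join(map(str, c.gaps)) + "\t"
                    + ",".join(c.orientations) + "\n"
                )
        manifest["scaffold_summary"] = summary

    # --- motifs -----------------------------------------------------------
    if proteins and len(proteins) >= 2:
        try:
            motifs, occurrences = discover_motifs(
                proteins,
                min_w=config.get("motif_min_w", 6),
                max_w=config.get("motif_max_w", 10),
                n_motifs=config.get("motif_n", 8),
                seed=config.get("seed", 1),
                site_threshold=config.get("motif_site_threshold", 0.5),
            )
        except Exception as exc:
            raise StageError("motifs", "protein set", exc) from exc
        pd.DataFrame(
            [
                {"motif": m.index, "width": m.width, "consensus": m.consensus,
                 "score": round(m.score, 4)}
                for m in motifs
            ]
        ).to_csv(emit("motifs.tsv"), sep="\t", index=False)
        by_seq: dict[str, list] = {}
        for occ in occurrences:
            by_seq.setdefault(occ.sequence_id, []).append(occ)
        arrangements = [
            arrangement_string(occs) for occs in by_seq.values()
        ]
        common, rare = pattern_frequencies(arrangements)
        pd.DataFrame(
            [{"sequence_id": a.sequence_id, "pattern": a.pattern} for a in arrangements]
        ).to_csv(emit("patterns.tsv"), sep="\t", index=False)
        pd.DataFrame(
            [{"pattern": p, "count": c, "class": "common"} for p, c in common]
            + [{"pattern": p, "count": c, "class": "rare"} for p, c in rare]
        ).to_csv(emit("pattern_frequencies.tsv"), sep="\t", index=False)

    # --- quantification ---------------------------------------------------
    if "path_counts" in config:
        counts = pd.read_csv(config["path_counts"], sep="\t")
        rpkm_table(counts).to_csv(emit("rpkm.tsv"), sep="\t", index=False)
    if "path_ct" in config:
        cts = pd.read_csv(config["path_ct"], sep="\t")
        reference = config.get("reference_gene", "GAPDH")
        calibrator = config.get("calibrator", "body")
        fold_rows = []
        genes = [g for g in cts["gene"].unique() if g != reference]
        tissues = sorted(cts["tissue"].unique())
        for gene in genes:
            per_tissue = {}
            for tissue in tissues:
                try:
                    fc = ddct_fold(cts, gene, tissue, reference, calibrator)
                except Exception as exc:
                    raise StageError("quantify", f"{gene}/{tissue}", exc) from exc
                per_tissue[tissue] = fc
            try:
                letters = tukey_letters(
                    {t: list(fc.folds) for t, fc in per_tissue.items()}
                )
            except ValueError:
                letters = {t: "" for t in per_tissue}
            for tissue, fc in per_tissue.items():
                fold_rows.append({
                    "gene": gene, "tissue": tissue,
                    "fold": round(fc.fold, 6), "se": round(fc.se, 6),
                    "letters": letters[tissue],
                })
        pd.DataFrame(fold_rows).to_csv(emit("folds.tsv"), sep="\t", index=False)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline finished: %d tables in %s", len(manifest["tables"]), out)
    return manifest
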