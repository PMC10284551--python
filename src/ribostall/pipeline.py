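"""End-to-end pipeline: simulate/load -> tile -> call peaks per library ->
consensus -> tract & motif detection -> association -> occupancy -> report.

Outputs are a pure function of (inputs, config, seed); every run writes a
manifest recording the configuration, input checksums, and package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .consensus import (
    extract_peak_context,
    intersect_library_peaks,
    peaks_to_positions,
    subtract_control_peaks,
)
from .io_formats import (
    CoverageTrack,
    Genome,
    TranscriptModel,
    read_annotation,
    read_bedgraph,
    read_fasta,
    write_bed,
    write_fasta,
)
from .occupancy import classify_occupancy, tract_occupancy
from .peaks import call_all
from .repeats import associated_genes, find_codon_tracts, locate_tracts, peaks_near_tracts

log = logging.getLogger("ribostall")


@dataclass
class PipelineConfig:
    """All tunable thresholds of the peak/repeat analysis, with defaults
    matching the published analysis conditions."""

    tile_width: int = 30
    tile_stat: str = "mean"
    alpha: float = 0.001
    min_tiles: int = 10
    min_support: int = 2
    control_min_support: int = 1  # 1 = exclude positions in ANY control library
    flank: int = 30
    window: int = 30
    min_codons: int = 4
    strict_cag: bool = True
    motif_p: float = 1e-4
    tpm_threshold: float = 1.0
    pct_threshold: float = 20.0
    fold_threshold: float = 2.0
    polysome_p: float = 0.05
    polysome_fold: float = 2.0
    seed: int = 0

    def validate(self, n_ribo_libs: int | None = None) -> None:
        if not 0 < self.alpha < 0.5:
            raise ValueError("alpha must be in (0, 0.5)")
        if self.tile_width < 1 or self.min_tiles < 1 or self.min_codons < 1:
            raise ValueError("tile_width, min_tiles and min_codons must be positive")
        if self.tile_stat not in ("mean", "sum"):
            raise ValueError(f"unknown tile statistic {self.tile_stat!r}")
        if not 0 < self.motif_p <= 1 or not 0 < self.polysome_p <= 1:
            raise ValueError("p-value thresholds must be in (0, 1]")
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")
        if n_ribo_libs is not None and self.min_support > n_ribo_libs:
            raise ValueError(
                f"min_support={self.min_support} exceeds the {n_ribo_libs} Ribo-Seq libraries"
            )

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def analyze_tracks(
    genome: Genome,
    annotation: list[TranscriptModel],
    ribo_tracks: dict[str, CoverageTrack],
    control_tracks: dict[str, CoverageTrack],
    config: PipelineConfig,
) -> dict:
    """Run the in-memory analysis: peaks, consensus, tracts, association,
    occupancy. Returns a result dictionary of intermediate objects."""
    config.validate(n_ribo_libs=len(ribo_tracks))
    ribo_peaks = {}
    for lib, track in sorted(ribo_tracks.items()):
        peaks, _models = call_all(
            track,
            annotation,
            library_id=lib,
            alpha=config.alpha,
            width=config.tile_width,
            stat=config.tile_stat,
            min_tiles=config.min_tiles,
        )
        ribo_peaks[lib] = peaks
        log.info("library %s: %d peak runs", lib, len(peaks))
    control_peaks = {}
    for lib, track in sorted(control_tracks.items()):
        peaks, _models = call_all(
            track,
            annotation,
            library_id=lib,
            alpha=config.alpha,
            width=config.tile_width,
            stat=config.tile_stat,
            min_tiles=config.min_tiles,
        )
        control_peaks[lib] = peaks
    support = intersect_library_peaks(
        [peaks_to_positions(p) for _, p in sorted(ribo_peaks.items())],
        min_support=config.min_support,
    )
    cons = subtract_control_peaks(
        support,
        [peaks_to_positions(p) for _, p in sorted(control_peaks.items())],
        annotation=annotation,
        control_min_support=config.control_min_support,
    )
    extract_peak_context(cons, genome, annotation, flank=config.flank)
    log.info("consensus: %d high-confidence peaks on %d genes",
             len(cons), len({p.gene_id for p in cons if p.gene_id}))
    # codon tracts over all amino-acid classes
    tracts = []
    by_tid = {}
    for t in annotation:
        if t.cds is None:
            continue
        by_tid[t.transcript_id] = t
        cds = t.cds_sequence(genome)
        for aa in ("Q", "S", "A"):
            found = find_codon_tracts(
                cds, aa, min_codons=config.min_codons,
                strict_cag=config.strict_cag, gene_id=t.gene_id,
            )
            tracts.extend(locate_tracts(found, t))
    association = peaks_near_tracts(cons, tracts, window=config.window)
    assoc_genes = associated_genes(association)
    log.info("%d tract/motif genes within %d nt of a consensus peak",
             len(assoc_genes), config.window)
    # occupancy on the first ribo library's coverage averaged across libraries
    mean_track = None
    if ribo_tracks:
        libs = sorted(ribo_tracks)
        data = {}
        for chrom in ribo_tracks[libs[0]].data:
            data[chrom] = sum(ribo_tracks[lib][chrom] for lib in libs) / len(libs)
        mean_track = CoverageTrack(data)
    occupancy_records = []
    if mean_track is not None:
        gene_tx = {}
        for t in annotation:
            gene_tx.setdefault(t.gene_id, t)
        for tract in tracts:
            gene = gene_tx.get(tract.gene_id)
            if gene is None or gene.cds is None:
                continue
            occupancy_records.append(tract_occupancy(mean_track, gene, tract))
    occ_classes = classify_occupancy(
        occupancy_records,
        pct_threshold=config.pct_threshold,
        fold_threshold=config.fold_threshold,
    )
    return {
        "ribo_peaks": ribo_peaks,
        "control_peaks": control_peaks,
        "consensus": cons,
        "tracts": tracts,
        "association": association,
        "associated_genes": assoc_genes,
        "occupancy_records": occupancy_records,
        "occupancy_classes": occ_classes,
    }


def run_pipeline(
    config: PipelineConfig,
    genome_fasta,
    annotation_path,
    ribo_bedgraphs: dict[str, str],
    control_bedgraphs: dict[str, str],
    outdir,
    dialect: str = "gff3",
) -> dict:
    """File-level pipeline entry point; writes BED/FASTA/TSV artifacts and a
    manifest into ``outdir`` and returns the in-memory results."""
    config.validate(n_ribo_libs=len(ribo_bedgraphs))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    failed_marker = outdir / "FAILED"
    try:
        genome = read_fasta(genome_fasta)
        annotation = read_annotation(annotation_path, dialect=dialect)
        ribo = {lib: read_bedgraph(p, genome) for lib, p in ribo_bedgraphs.items()}
        ctrl = {lib: read_bedgraph(p, genome) for lib, p in control_bedgraphs.items()}
        results = analyze_tracks(genome, annotation, ribo, ctrl, config)
        for lib, peaks in results["ribo_peaks"].items():
            write_bed(peaks, outdir / f"peaks_{lib}.bed")
        for lib, peaks in results["control_peaks"].items():
            write_bed(peaks, outdir / f"peaks_{lib}.bed")
        write_bed(results["consensus"], outdir / "consensus_peaks.bed")
        contexts = {
            f"{p.gene_id or 'intergenic'}:{p.chrom}:{p.start}-{p.end}": p.context_seq
            for p in results["consensus"]
            if p.context_seq
        }
        write_fasta(contexts, outdir / "consensus_context.fasta")
        tract_rows = [
            {
                "gene_id": t.gene_id,
                "amino_acid": t.amino_acid,
                "start_codon": t.start_codon,
                "n_codons": t.n_codons,
                "intervals": ";".join(f"{c}:{s}-{e}" for c, s, e in t.genomic_intervals),
            }
            for t in results["tracts"]
        ]
        pd.DataFrame(tract_rows).to_csv(outdir / "tracts.tsv", sep="\t", index=False)
        results["association"].to_csv(outdir / "peak_tract_association.tsv", sep="\t", index=False)
        occ_rows = [
            {
                "gene_id": r.gene_id,
                "amino_acid": r.tract.amino_acid,
                "tract_mean": r.tract_mean,
                "rest_mean": r.rest_mean,
                "ratio": r.ratio,
                "percent_increase": r.percent_increase,
                "defined": r.defined,
            }
            for r in results["occupancy_records"]
        ]
        pd.DataFrame(occ_rows).to_csv(outdir / "occupancy.tsv", sep="\t", index=False)
        manifest = {
            "version": __version__,
            "config": dataclasses.asdict(config),
            "config_hash": config.config_hash(),
            "inputs": {
                str(p): _file_sha256(p)
                for p in [genome_fasta, annotation_path, *ribo_bedgraphs.values(), *control_bedgraphs.values()]
            },
            "n_consensus_peaks": len(results["consensus"]),
            "n_associated_genes": len(results["associated_genes"]),
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        return results
    except Exception:
        failed_marker.write_text("pipeline failed; partial outputs retained\n")
        raise
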