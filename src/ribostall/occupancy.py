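"""Footprint occupancy within codon tracts relative to the rest of the CDS.

For each tract, occupancy is the mean per-base footprint coverage over the
tract's genomic bases divided by the mean over the remaining CDS bases of
the same gene; genes are then classified by a >20% and a >2-fold increase
(both strict inequalities).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import CoverageTrack, TranscriptModel
from .repeats import RepeatTract


@dataclass
class OccupancyRecord:
    gene_id: str
    tract: RepeatTract
    tract_mean: float
    rest_mean: float
    defined: bool = True

    @property
    def ratio(self) -> float:
        if not self.defined:
            return float("nan")
        return self.tract_mean / self.rest_mean

    @property
    def percent_increase(self) -> float:
        return 100.0 * (self.ratio - 1.0)


def tract_occupancy(
    track: CoverageTrack,
    gene: TranscriptModel,
    tract: RepeatTract,
    denominator: str = "cds",
) -> OccupancyRecord:
    """Mean coverage over the tract vs over the gene's CDS minus the tract.

    With ``denominator='transcript'`` the rest is the full exon union minus
    the tract instead of the CDS. A zero rest mean yields a flagged record
    with an undefined ratio.
    """
    if denominator not in ("cds", "transcript"):
        raise ValueError(f"unknown denominator {denominator!r}")
    intervals = tract.genomic_intervals or None
    if intervals is None:
        intervals = gene.codon_span_to_genomic(tract.start_codon, tract.n_codons)
    tract_mask: dict[str, set[int]] = {}
    tract_vals = []
    for chrom, s, e in intervals:
        tract_mask.setdefault(chrom, set()).update(range(s, e))
        tract_vals.append(track[chrom][s:e])
    tract_vals = np.concatenate(tract_vals)
    region = gene.cds_intervals() if denominator == "cds" else gene.exons
    rest_vals = []
    for s, e in region:
        bases = np.arange(s, e)
        keep = ~np.isin(bases, list(tract_mask.get(gene.chrom, ())))
        rest_vals.append(track[gene.chrom][s:e][keep])
    rest_vals = np.concatenate(rest_vals)
    if rest_vals.size == 0:
        raise ValueError(f"tract covers the whole denominator region of {gene.gene_id}")
    tract_mean = float(tract_vals.mean())
    rest_mean = float(rest_vals.mean())
    return OccupancyRecord(
        gene_id=tract.gene_id or gene.gene_id,
        tract=tract,
        tract_mean=tract_mean,
        rest_mean=rest_mean,
        defined=rest_mean > 0,
    )


def classify_occupancy(
    records: list[OccupancyRecord],
    pct_threshold: float = 20.0,
    fold_threshold: float = 2.0,
) -> dict:
    """Count genes with >20% and with >2-fold occupancy increase.

    Both thresholds are strict; a gene with several tracts is summarized by
    its maximum-ratio tract. Returns counts, gene lists, and the per-gene
    best ratios.
    """
    best: dict[str, float] = {}
    for r in records:
        if not r.defined:
            continue
        if r.gene_id not in best or r.ratio > best[r.gene_id]:
            best[r.gene_id] = r.ratio
    class_20 = sorted(g for g, ratio in best.items() if 100.0 * (ratio - 1.0) > pct_threshold)
    class_2x = sorted(g for g, ratio in best.items() if ratio > fold_threshold)
    return {
        "n_genes": len(best),
        "class_20": class_20,
        "class_2x": class_2x,
        "n_class_20": len(class_20),
        "n_class_2x": len(class_2x),
        "best_ratio": best,
    }
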