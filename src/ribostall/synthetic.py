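"""Synthetic genomes, footprint coverage, count tables and MS spectra.

The generator plants known ground truth — in-frame codon tracts, coverage
stalls on tract bases, polysome-shifted genes, and generating AvP values —
so that every downstream caller can be scored for sensitivity and precision
against an exact answer key. All outputs are deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import pandas as pd

from .io_formats import CoverageTrack, Genome, TranscriptModel
from .avp import SpectrumIntensities, CANONICAL_SPECIES

STOP_CODONS = {"TAA", "TAG", "TGA"}
SENSE_CODONS = sorted(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
)


@dataclass
class SimConfig:
    """Conditions for one synthetic Ribo-Seq / RNA-seq study.

    Defaults describe a 50-gene transcriptome in which a fifth of the genes
    carry a planted 5-codon CAG tract whose Ribo-Seq (but not RNA-seq)
    coverage is elevated five-fold — the planted analogue of a ribosome
    stall — over negative-binomial background at 20x mean depth, with
    three footprint libraries and two RNA-seq control libraries.
    """

    n_genes: int = 50
    gene_len_codons: tuple[int, int] = (200, 600)
    tract_genes_frac: float = 0.2
    tract_codon: str = "CAG"
    tract_len_codons: int = 5
    bg_mean: float = 20.0
    bg_dispersion: float = 10.0  # NB size; var = mu + mu^2/size
    stall_factor: float = 5.0
    n_ribo_libs: int = 3
    n_rna_libs: int = 2
    intergenic_gap: tuple[int, int] = (100, 200)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.tract_len_codons < 4:
            raise ValueError("n_genes must be positive and tract_len_codons >= 4")
        if not 0 <= self.tract_genes_frac <= 1:
            raise ValueError("tract_genes_frac must be in [0,1]")
        if self.stall_factor < 1:
            raise ValueError("stall_factor must be >= 1")
        if self.bg_mean < 0 or self.bg_dispersion <= 0:
            raise ValueError("bg_mean >= 0 and bg_dispersion > 0 required")
        if self.tract_codon in STOP_CODONS or len(self.tract_codon) != 3:
            raise ValueError(f"invalid tract codon {self.tract_codon!r}")
        if self.intergenic_gap[0] < 100:
            raise ValueError("intergenic gaps must be >= 100 bp")


@dataclass
class PlantedTract:
    gene_id: str
    codon: str
    start_codon: int  # 0-based codon index in the spliced CDS
    n_codons: int


@dataclass
class PlantedShift:
    gene_id: str
    log2fc: float  # true polysome/input log2 fold change, mutant vs control

    @property
    def direction(self) -> str:
        return "low" if self.log2fc < 0 else "high"


@dataclass
class TruthSet:
    """Planted ground truth for one simulation."""

    tracts: list[PlantedTract] = field(default_factory=list)
    shifts: list[PlantedShift] = field(default_factory=list)

    @property
    def tract_genes(self) -> set[str]:
        return {t.gene_id for t in self.tracts}

    @property
    def shift_genes(self) -> set[str]:
        return {s.gene_id for s in self.shifts}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "tracts": [asdict(t) for t in self.tracts],
                    "shifts": [asdict(s) for s in self.shifts],
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "TruthSet":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            tracts=[PlantedTract(**t) for t in d.get("tracts", [])],
            shifts=[PlantedShift(**s) for s in d.get("shifts", [])],
        )


def _random_gap(rng: np.random.Generator, lo: int, hi: int) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(list("ACGT"), size=n))


def make_genome(config: SimConfig) -> tuple[Genome, list[TranscriptModel], TruthSet]:
    """Build a single-chromosome genome of single-exon coding genes.

    Each gene is ATG + random sense codons + stop; a fraction of genes gets
    an in-frame homopolymer codon tract planted at a random interior codon.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    n_tract_genes = int(round(config.tract_genes_frac * config.n_genes))
    tract_gene_idx = set(
        rng.choice(config.n_genes, size=n_tract_genes, replace=False).tolist()
    )
    chrom = "chrS"
    parts: list[str] = []
    pos = 0
    transcripts: list[TranscriptModel] = []
    truth = TruthSet()
    for gi in range(config.n_genes):
        gap = _random_gap(rng, *config.intergenic_gap)
        parts.append(gap)
        pos += len(gap)
        n_codons = int(rng.integers(config.gene_len_codons[0], config.gene_len_codons[1] + 1))
        if config.tract_len_codons >= n_codons - 2:
            raise ValueError("planted tract longer than the gene interior")
        body = [str(c) for c in rng.choice(SENSE_CODONS, size=n_codons - 2)]
        gene_id = f"gene{gi:04d}"
        if gi in tract_gene_idx:
            # interior codon, keeping clear of the start and stop
            k = config.tract_len_codons
            at = int(rng.integers(1, n_codons - 1 - k))
            body[at - 1 : at - 1 + k] = [config.tract_codon] * k
            truth.tracts.append(
                PlantedTract(gene_id=gene_id, codon=config.tract_codon, start_codon=at, n_codons=k)
            )
        stop = str(rng.choice(sorted(STOP_CODONS)))
        cds = "ATG" + "".join(body) + stop
        start, end = pos, pos + len(cds)
        parts.append(cds)
        pos = end
        transcripts.append(
            TranscriptModel(
                gene_id=gene_id,
                transcript_id=f"{gene_id}.t1",
                chrom=chrom,
                strand="+",
                exons=[(start, end)],
                cds=(start, end),
            )
        )
    parts.append(_random_gap(rng, *config.intergenic_gap))
    genome = Genome({chrom: "".join(parts)})
    return genome, transcripts, truth


def _tract_bases(
    transcripts: Iterable[TranscriptModel], truth: TruthSet
) -> dict[str, list[tuple[int, int]]]:
    """Genomic intervals of planted tracts, keyed by chromosome."""
    by_tid = {t.gene_id: t for t in transcripts}
    out: dict[str, list[tuple[int, int]]] = {}
    for tract in truth.tracts:
        t = by_tid[tract.gene_id]
        for chrom, s, e in t.codon_span_to_genomic(tract.start_codon, tract.n_codons):
            out.setdefault(chrom, []).append((s, e))
    return out


def simulate_coverage(
    genome: Genome,
    annotation: list[TranscriptModel],
    truth: TruthSet,
    config: SimConfig,
    kind: str,
    lib_index: int,
) -> CoverageTrack:
    """Draw one library's per-base footprint (ribo) or RNA-seq coverage.

    Exonic bases are NB(mean=bg_mean, size=bg_dispersion); in ribo libraries
    the mean on planted tract bases is multiplied by the stall factor.
    """
    if kind not in ("ribo", "rna"):
        raise ValueError(f"unknown library kind {kind!r}")
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 202, 0 if kind == "rna" else 1, lib_index])
    )
    mean = {c: np.zeros(n) for c, n in genome.lengths.items()}
    for t in annotation:
        for s, e in t.exons:
            mean[t.chrom][s:e] = config.bg_mean
    if kind == "ribo" and config.stall_factor > 1:
        for chrom, ivs in _tract_bases(annotation, truth).items():
            for s, e in ivs:
                mean[chrom][s:e] *= config.stall_factor
    data = {}
    r = config.bg_dispersion
    for chrom, mu in mean.items():
        counts = np.zeros(mu.size)
        nz = mu > 0
        if nz.any():
            p = r / (r + mu[nz])
            counts[nz] = rng.negative_binomial(r, p)
        data[chrom] = counts
    return CoverageTrack(data)


@dataclass
class PolysomeSimConfig:
    """Conditions for a replicate polysome-seq / input count experiment.

    Defaults: 1000 genes at ~500 mean counts with NB size 50 (dispersion
    0.02, i.e. well-correlated replicate libraries), two replicates per
    condition/fraction as in a typical polysome-gradient experiment, and a
    planted fraction of genes whose mutant polysome/input ratio is shifted
    by ``log2fc``.
    """

    n_genes: int = 1000
    mean_count: float = 500.0
    nb_size: float = 50.0
    n_replicates: int = 2
    shifted_frac: float = 0.05
    log2fc: float = -3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per condition")
        if not 0 <= self.shifted_frac <= 1:
            raise ValueError("shifted_frac must be in [0,1]")


def simulate_polysome_counts(
    config: PolysomeSimConfig, truth: TruthSet | None = None
) -> tuple[pd.DataFrame, TruthSet]:
    """Simulate tidy polysome/input count tables for control and mutant.

    Returns a DataFrame with columns gene, condition, fraction, replicate,
    count, plus the truth set of planted shifts (appended to ``truth`` when
    one is passed in).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    genes = [f"gene{gi:04d}" for gi in range(config.n_genes)]
    n_shift = int(round(config.shifted_frac * config.n_genes))
    shifted = set(rng.choice(config.n_genes, size=n_shift, replace=False).tolist())
    if truth is None:
        truth = TruthSet()
    for gi in sorted(shifted):
        truth.shifts.append(PlantedShift(gene_id=genes[gi], log2fc=config.log2fc))
    # gene-level abundance varies log-normally around the configured mean
    base = config.mean_count * rng.lognormal(mean=0.0, sigma=0.5, size=config.n_genes)
    rows = []
    r = config.nb_size
    for condition in ("control", "mutant"):
        for fraction in ("input", "polysome"):
            for rep in range(1, config.n_replicates + 1):
                mu = base.copy()
                if fraction == "polysome" and condition == "mutant" and n_shift:
                    idx = np.fromiter(shifted, dtype=int)
                    mu[idx] = mu[idx] * 2.0 ** config.log2fc
                counts = rng.negative_binomial(r, r / (r + mu))
                rows.append(
                    pd.DataFrame(
                        {
                            "gene": genes,
                            "condition": condition,
                            "fraction": fraction,
                            "replicate": rep,
                            "count": counts,
                        }
                    )
                )
    return pd.concat(rows, ignore_index=True), truth


def simulate_spectrum(
    n_ptms: int = 5,
    n_replicates: int = 15,
    true_avp: dict[str, float] | None = None,
    noise_cv: float = 0.01,
    seed: int = 0,
) -> list[SpectrumIntensities]:
    """Simulate replicate ribonucleoside MS spectra with known AvP values.

    Each replicate draws four canonical intensities around 2.5e7 counts and
    PTM intensities whose expected AvP (x100-normalized against the summed
    canonicals) equals ``true_avp``; multiplicative log-normal noise with the
    given CV is applied to every species independently.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    if true_avp is None:
        names = [f"ptm{p + 1}" for p in range(n_ptms)]
        levels = rng.uniform(0.05, 2.5, size=n_ptms)
        true_avp = dict(zip(names, levels))
    sigma = np.sqrt(np.log1p(noise_cv**2))
    out = []
    for _ in range(n_replicates):
        canon = {
            sp: 2.5e7 * rng.lognormal(-sigma**2 / 2, sigma) for sp in CANONICAL_SPECIES
        }
        total = sum(canon.values())
        ptms = {
            name: (avp / 100.0) * total * rng.lognormal(-sigma**2 / 2, sigma)
            for name, avp in true_avp.items()
        }
        out.append(SpectrumIntensities(ptm_intensities=ptms, canonical_intensities=canon))
    return out
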