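"""Cross-library consensus peaks and control subtraction.

A high-confidence footprint peak is a 1-bp position called a peak in at
least ``min_support`` Ribo-Seq libraries and absent from the RNA-seq
control libraries' peak sets at the corresponding position. Surviving
positions are merged into maximal contiguous runs and annotated with their
genomic sequence context.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.Seq import Seq

from .io_formats import Genome, TranscriptModel, gene_exon_union
from .peaks import PeakCall

Position = tuple[str, int]  # (chrom, 0-based start of a 1-bp tile)


@dataclass
class ConsensusPeak:
    chrom: str
    start: int
    end: int
    gene_id: str | None
    support: int  # max per-position library support within the run
    value: float = 0.0
    context_seq: str | None = None

    @property
    def library_id(self) -> str:  # for BED name compatibility
        return f"support{self.support}"


def peaks_to_positions(peaks: Iterable[PeakCall]) -> set[Position]:
    """Expand (possibly merged) peak calls into 1-bp peak positions."""
    out: set[Position] = set()
    for p in peaks:
        for i in range(p.start, p.end):
            out.add((p.chrom, i))
    return out


def intersect_library_peaks(
    peak_sets: Sequence[set[Position]], min_support: int = 2
) -> dict[Position, int]:
    """Positions present in at least ``min_support`` libraries, with counts."""
    if min_support > len(peak_sets):
        raise ValueError(
            f"min_support={min_support} exceeds the {len(peak_sets)} libraries given"
        )
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    counts: dict[Position, int] = {}
    for s in peak_sets:
        for pos in s:
            counts[pos] = counts.get(pos, 0) + 1
    return {pos: n for pos, n in counts.items() if n >= min_support}


def subtract_control_peaks(
    consensus_positions: dict[Position, int],
    control_peak_sets: Sequence[set[Position]],
    annotation: list[TranscriptModel] | None = None,
    control_min_support: int = 1,
) -> list[ConsensusPeak]:
    """Drop consensus positions present in the control libraries; merge runs.

    By default a position is excluded when ANY control library calls it
    (``control_min_support=1``); raising the threshold requires control
    consensus instead. Survivors are merged into maximal contiguous runs,
    each keeping the maximum per-position support, and assigned to every
    overlapping gene (duplicated across genes; ``gene_id=None`` when no
    annotation is given or no gene overlaps).
    """
    if control_peak_sets:
        ctrl_counts: dict[Position, int] = {}
        for s in control_peak_sets:
            for pos in s:
                ctrl_counts[pos] = ctrl_counts.get(pos, 0) + 1
        excluded = {pos for pos, n in ctrl_counts.items() if n >= control_min_support}
    else:
        excluded = set()
    survivors = sorted(
        (pos for pos in consensus_positions if pos not in excluded)
    )
    runs: list[ConsensusPeak] = []
    for chrom, start in survivors:
        support = consensus_positions[(chrom, start)]
        if runs and runs[-1].chrom == chrom and runs[-1].end == start:
            runs[-1].end = start + 1
            runs[-1].support = max(runs[-1].support, support)
        else:
            runs.append(ConsensusPeak(chrom=chrom, start=start, end=start + 1, gene_id=None, support=support))
    if annotation is None:
        return runs
    union = gene_exon_union(annotation)
    out: list[ConsensusPeak] = []
    for run in runs:
        owners = [
            gid
            for gid, (chrom, ivs) in union.items()
            if chrom == run.chrom and any(s < run.end and e > run.start for s, e in ivs)
        ]
        if not owners:
            out.append(run)
        else:
            for gid in owners:
                out.append(
                    ConsensusPeak(
                        chrom=run.chrom,
                        start=run.start,
                        end=run.end,
                        gene_id=gid,
                        support=run.support,
                    )
                )
    return out


def extract_peak_context(
    peaks: list[ConsensusPeak],
    genome: Genome,
    annotation: list[TranscriptModel] | None = None,
    flank: int = 30,
) -> list[ConsensusPeak]:
    """Attach the +/- ``flank`` nt genomic context sequence to each peak.

    The window is clipped at chromosome ends and reverse-complemented when
    the owning gene is on the minus strand.
    """
    strand_of = {}
    if annotation is not None:
        for t in annotation:
            strand_of[t.gene_id] = t.strand
    for p in peaks:
        if p.chrom not in genome:
            raise KeyError(f"peak on unknown chromosome {p.chrom!r}")
        length = genome.lengths[p.chrom]
        lo = max(0, p.start - flank)
        hi = min(length, p.end + flank)
        seq = genome.slice(p.chrom, lo, hi)
        if p.gene_id is not None and strand_of.get(p.gene_id) == "-":
            seq = str(Seq(seq).reverse_complement())
        p.context_seq = seq
    return peaks
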