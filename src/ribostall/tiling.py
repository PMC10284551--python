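"""Genome tiling and tile-to-gene assignment.

Coverage tracks are summarized into consecutive fixed-width tiles (30 bp by
default), each tile is optionally broken into 1-bp tiles inheriting its
parent's value, and tiles are assigned to every gene whose exon union they
overlap by at least one base.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

import numpy as np

from .io_formats import CoverageTrack, TranscriptModel, gene_exon_union


@dataclass
class Tile:
    chrom: str
    start: int
    end: int
    value: float = 0.0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"degenerate tile ({self.start},{self.end})")
        if self.value < 0:
            raise ValueError("negative tile value")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class GeneTileSet:
    gene_id: str
    tiles: list[Tile] = field(default_factory=list)

    @property
    def values(self) -> np.ndarray:
        return np.array([t.value for t in self.tiles])


def tile_genome(chrom_lengths: dict[str, int], width: int = 30) -> list[Tile]:
    """Consecutive non-overlapping tiles covering each chromosome.

    The final tile of a chromosome is truncated at the chromosome end.
    """
    if width <= 0:
        raise ValueError("tile width must be positive")
    tiles = []
    for chrom, length in chrom_lengths.items():
        for s in range(0, length, width):
            tiles.append(Tile(chrom, s, min(s + width, length)))
    return tiles


def aggregate_coverage(track: CoverageTrack, tiles: list[Tile], stat: str = "mean") -> list[Tile]:
    """Fill tile values from per-base coverage (mean per base, or sum)."""
    if stat not in ("mean", "sum"):
        raise ValueError(f"unknown tile statistic {stat!r}")
    out = []
    # vectorized per chromosome via cumulative sums
    csums = {c: np.concatenate(([0.0], np.cumsum(a))) for c, a in track.data.items()}
    for t in tiles:
        if t.chrom not in track:
            raise ValueError(f"tile chromosome {t.chrom!r} not in track")
        cs = csums[t.chrom]
        if t.end >= cs.size:
            raise ValueError(f"tile ({t.start},{t.end}) out of bounds on {t.chrom}")
        total = cs[t.end] - cs[t.start]
        v = total / t.width if stat == "mean" else total
        out.append(Tile(t.chrom, t.start, t.end, float(v)))
    return out


def expand_tiles(tiles: list[Tile]) -> list[Tile]:
    """Break each w-bp tile into w 1-bp tiles inheriting the parent value."""
    out = []
    for t in tiles:
        for i in range(t.start, t.end):
            out.append(Tile(t.chrom, i, i + 1, t.value))
    return out


def assign_tiles_to_genes(
    tiles: list[Tile], annotation: list[TranscriptModel]
) -> list[GeneTileSet]:
    """Assign each tile to every gene whose exon union it overlaps.

    A tile overlapping two genes appears in both sets; genes without any
    overlapping tile get an empty set.
    """
    by_chrom: dict[str, list[Tile]] = {}
    for t in tiles:
        by_chrom.setdefault(t.chrom, []).append(t)
    starts = {}
    for chrom, ts in by_chrom.items():
        ts.sort(key=lambda t: (t.start, t.end))
        starts[chrom] = [t.start for t in ts]
    out = []
    for gid, (chrom, exons) in gene_exon_union(annotation).items():
        gts = GeneTileSet(gene_id=gid)
        if chrom in by_chrom:
            ts, ss = by_chrom[chrom], starts[chrom]
            max_w = max(t.width for t in ts)
            seen: set[tuple[int, int]] = set()
            for es, ee in exons:
                # tiles with start < exon end; filter on overlap with exon start
                hi = bisect_left(ss, ee)
                lo = bisect_right(ss, es - max_w)
                for t in ts[lo:hi]:
                    if t.end > es and (t.start, t.end) not in seen:
                        seen.add((t.start, t.end))
                        gts.tiles.append(t)
        gts.tiles.sort(key=lambda t: t.start)
        out.append(gts)
    return out
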