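"""Genomics file formats and shared coordinate conventions.

Everything internal is 0-based half-open (BED/bedGraph native). GFF3/GTF
1-based inclusive coordinates are converted on read and nowhere else.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

_VALID_ALPHABET = set("ACGTN")


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass
class Genome:
    """Reference sequences keyed by chromosome name (uppercase A/C/G/T/N)."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"empty sequence for chromosome {name!r}")
            bad = set(seq) - _VALID_ALPHABET
            if bad:
                raise ValueError(
                    f"chromosome {name!r} contains invalid characters {sorted(bad)}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def slice(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self.sequences:
            raise KeyError(f"unknown chromosome {chrom!r}")
        return self.sequences[chrom][start:end]


@dataclass
class TranscriptModel:
    """One transcript's genomic structure in 0-based half-open coordinates.

    ``exons`` are sorted, non-overlapping ``(start, end)`` genomic intervals;
    ``cds`` is the optional genomic span of the coding region, whose spliced
    length (intersection with the exon union) must be divisible by 3.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r} for {self.transcript_id}")
        exons = sorted((int(s), int(e)) for s, e in self.exons)
        for s, e in exons:
            if s >= e:
                raise ValueError(f"degenerate exon ({s},{e}) in {self.transcript_id}")
        for (_, e0), (s1, _) in zip(exons, exons[1:]):
            if s1 < e0:
                raise ValueError(f"overlapping exons in {self.transcript_id}")
        self.exons = exons
        if self.cds is not None:
            cs, ce = int(self.cds[0]), int(self.cds[1])
            if cs >= ce:
                raise ValueError(f"degenerate CDS in {self.transcript_id}")
            ivs = self.cds_intervals()
            if not ivs or ivs[0][0] != cs or ivs[-1][1] != ce:
                raise ValueError(
                    f"CDS ({cs},{ce}) extends outside exon union in {self.transcript_id}"
                )
            if self.spliced_cds_length % 3 != 0:
                raise ValueError(
                    f"spliced CDS length {self.spliced_cds_length} of "
                    f"{self.transcript_id} not divisible by 3"
                )
            self.cds = (cs, ce)

    def cds_intervals(self) -> list[tuple[int, int]]:
        """Genomic intervals (ascending) of the CDS within the exons."""
        if self.cds is None:
            return []
        cs, ce = self.cds
        out = []
        for s, e in self.exons:
            lo, hi = max(s, cs), min(e, ce)
            if lo < hi:
                out.append((lo, hi))
        return out

    @property
    def spliced_cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals())

    def cds_sequence(self, genome: Genome) -> str:
        """Spliced CDS nucleotides in translation (5'->3') orientation."""
        parts = [genome.slice(self.chrom, s, e) for s, e in self.cds_intervals()]
        seq = "".join(parts)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq

    def codon_span_to_genomic(self, start_codon: int, n_codons: int) -> list[tuple[str, int, int]]:
        """Project a spliced-CDS codon range onto genomic intervals.

        Returns merged ``(chrom, start, end)`` intervals whose total length is
        ``3 * n_codons``. Strand-aware: codon 0 is at the CDS 5' end.
        """
        positions: list[int] = []
        for s, e in self.cds_intervals():
            positions.extend(range(s, e))
        if self.strand == "-":
            positions.reverse()
        lo, hi = 3 * start_codon, 3 * (start_codon + n_codons)
        if hi > len(positions):
            raise ValueError("codon span exceeds CDS length")
        wanted = sorted(positions[lo:hi])
        out: list[tuple[str, int, int]] = []
        for p in wanted:
            if out and out[-1][2] == p:
                out[-1] = (self.chrom, out[-1][1], p + 1)
            else:
                out.append((self.chrom, p, p + 1))
        return out


def gene_exon_union(transcripts: Iterable[TranscriptModel]) -> dict[str, tuple[str, list[tuple[int, int]]]]:
    """Per-gene transcript region: the merged exon union over all isoforms."""
    by_gene: dict[str, tuple[str, list[tuple[int, int]]]] = {}
    for t in transcripts:
        chrom, ivs = by_gene.setdefault(t.gene_id, (t.chrom, []))
        if chrom != t.chrom:
            raise ValueError(f"gene {t.gene_id} spans multiple chromosomes")
        ivs.extend(t.exons)
    merged = {}
    for gid, (chrom, ivs) in by_gene.items():
        ivs.sort()
        out: list[tuple[int, int]] = []
        for s, e in ivs:
            if out and s <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        merged[gid] = (chrom, out)
    return merged


@dataclass
class CoverageTrack:
    """Per-chromosome non-negative per-base signal (float arrays, 0-based)."""

    data: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, arr in self.data.items():
            arr = np.asarray(arr, dtype=float)
            if (arr < 0).any():
                raise ValueError(f"negative coverage on {chrom}")
            self.data[chrom] = arr

    @classmethod
    def zeros(cls, lengths: dict[str, int]) -> "CoverageTrack":
        return cls({c: np.zeros(n) for c, n in lengths.items()})

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.data[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.data


def read_fasta(path) -> Genome:
    """Read a (possibly gzipped) FASTA file into a :class:`Genome`."""
    sequences: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in sequences:
                raise ValueError(f"duplicate FASTA record {rec.id!r}")
            sequences[rec.id] = str(rec.seq).upper()
    if not sequences:
        raise ValueError(f"no FASTA records in {path}")
    return Genome(sequences)


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_annotation(path, dialect: str = "gff3") -> list[TranscriptModel]:
    """Read transcript models from GFF3 or GTF (via an in-memory gffutils db).

    Requires gene/transcript(mRNA)/exon/CDS features linked by ID/Parent
    (GFF3) or gene_id/transcript_id (GTF). File coordinates are 1-based
    inclusive and converted to 0-based half-open.
    """
    import gffutils

    if dialect not in ("gff3", "gtf"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    with _open_text(path) as fh:
        text = fh.read()
    db = gffutils.create_db(
        text,
        ":memory:",
        from_string=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    # group exon/CDS rows per transcript
    tx: dict[str, dict] = {}
    order: list[str] = []

    def _rec(tid: str, gid: str, chrom: str, strand: str) -> dict:
        if strand not in ("+", "-"):
            raise ValueError(f"unknown strand symbol {strand!r} for transcript {tid!r}")
        if tid not in tx:
            tx[tid] = {"gene": gid, "chrom": chrom, "strand": strand, "exons": [], "cds": []}
            order.append(tid)
        return tx[tid]

    if dialect == "gff3":
        for t in db.features_of_type(("mRNA", "transcript")):
            gid = t.attributes.get("Parent", [t.id])[0]
            _rec(t.id, gid, t.seqid, t.strand)
        for ftype, key in (("exon", "exons"), ("CDS", "cds")):
            for f in db.features_of_type(ftype):
                for parent in f.attributes.get("Parent", []):
                    if parent in tx:
                        rec = tx[parent]
                    else:
                        rec = _rec(parent, parent, f.seqid, f.strand)
                    rec[key].append((f.start - 1, f.end))
    else:
        for ftype, key in (("exon", "exons"), ("CDS", "cds")):
            for f in db.features_of_type(ftype):
                tid = f.attributes["transcript_id"][0]
                gid = f.attributes.get("gene_id", [tid])[0]
                rec = _rec(tid, gid, f.seqid, f.strand)
                rec[key].append((f.start - 1, f.end))

    models = []
    for tid in order:
        rec = tx[tid]
        if not rec["exons"]:
            continue
        cds = None
        if rec["cds"]:
            cds = (min(s for s, _ in rec["cds"]), max(e for _, e in rec["cds"]))
        # merge book-ended/duplicate exon rows
        exons = sorted(set(rec["exons"]))
        merged: list[tuple[int, int]] = []
        for s, e in exons:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        models.append(
            TranscriptModel(
                gene_id=rec["gene"],
                transcript_id=tid,
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=merged,
                cds=cds,
            )
        )
    models.sort(key=lambda t: (t.chrom, t.exons[0][0], t.transcript_id))
    return models


def write_gff3(transcripts: Sequence[TranscriptModel], path) -> None:
    """Write transcript models as minimal GFF3 (gene/mRNA/exon/CDS)."""
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        seen_genes = set()
        for t in sorted(transcripts, key=lambda t: (t.chrom, t.exons[0][0])):
            g_start = t.exons[0][0] + 1
            g_end = t.exons[-1][1]
            if t.gene_id not in seen_genes:
                fh.write(
                    f"{t.chrom}\tribostall\tgene\t{g_start}\t{g_end}\t.\t{t.strand}\t.\tID={t.gene_id}\n"
                )
                seen_genes.add(t.gene_id)
            fh.write(
                f"{t.chrom}\tribostall\tmRNA\t{g_start}\t{g_end}\t.\t{t.strand}\t.\t"
                f"ID={t.transcript_id};Parent={t.gene_id}\n"
            )
            for s, e in t.exons:
                fh.write(
                    f"{t.chrom}\tribostall\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\tParent={t.transcript_id}\n"
                )
            for s, e in t.cds_intervals():
                fh.write(
                    f"{t.chrom}\tribostall\tCDS\t{s + 1}\t{e}\t.\t{t.strand}\t0\tParent={t.transcript_id}\n"
                )


def read_bedgraph(path, genome: Genome | None = None, lengths: dict[str, int] | None = None) -> CoverageTrack:
    """Read a bedGraph into per-base arrays; uncovered bases are 0.

    Chromosome lengths come from ``genome`` (or an explicit ``lengths`` map).
    Overlapping intervals and out-of-bounds intervals are errors.
    """
    if lengths is None:
        if genome is None:
            raise ValueError("either genome or lengths is required")
        lengths = genome.lengths
    arrays = {c: np.zeros(n) for c, n in lengths.items()}
    covered = {c: np.zeros(n, dtype=bool) for c, n in lengths.items()}
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            chrom, start, end, value = line.split()[:4]
            s, e, v = int(start), int(end), float(value)
            if chrom not in arrays:
                raise ValueError(f"bedGraph chromosome {chrom!r} not in genome")
            if e > len(arrays[chrom]) or s < 0 or s >= e:
                raise ValueError(f"interval ({s},{e}) out of bounds on {chrom}")
            if v < 0:
                raise ValueError(f"negative bedGraph value {v} on {chrom}:{s}-{e}")
            if covered[chrom][s:e].any():
                raise ValueError(f"overlapping bedGraph intervals on {chrom} near {s}")
            covered[chrom][s:e] = True
            arrays[chrom][s:e] = v
    return CoverageTrack(arrays)


def write_bedgraph(track: CoverageTrack, path, omit_zero: bool = True) -> None:
    """Write a coverage track as bedGraph, merging runs of equal value."""
    with _open_text(path, "wt") as fh:
        for chrom in track.data:
            arr = track.data[chrom]
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if omit_zero and v == 0:
                    continue
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def write_bed(peaks: Sequence, path) -> None:
    """Write peak calls as BED6, sorted by (chrom, start).

    ``peaks`` are objects with chrom/start/end/gene_id/library_id/value and
    optional strand; the BED score is the coverage value capped to 0-1000.
    """
    rows = []
    for p in peaks:
        name = f"{p.gene_id}:{getattr(p, 'library_id', '.')}"
        score = int(min(1000, max(0, round(p.value))))
        strand = getattr(p, "strand", None) or "."
        rows.append((p.chrom, int(p.start), int(p.end), name, score, strand))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with _open_text(path, "wt") as fh:
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")
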