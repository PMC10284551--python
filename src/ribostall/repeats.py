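"""Codon-tract detection, motif scanning with exact p-values, and
peak-tract association.

Tracts are maximal in-frame runs of codons encoding the same amino acid
(polyQ strictly CAG by default, polyS over all six serine codons, polyA
over the four alanine codons). The motif scanner scores a consensus motif
(e.g. five consecutive CAG codons, or five Qs against protein sequence) at
every offset with a pseudocount position-weight model and computes the
p-value of each score EXACTLY by dynamic programming over the discretized
per-position score distributions under a 0-order background — the same
construction FIMO uses — so no asymptotic approximation enters.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .consensus import ConsensusPeak
from .io_formats import TranscriptModel

CODON_SETS: dict[str, dict[bool, frozenset[str]]] = {
    "Q": {True: frozenset({"CAG"}), False: frozenset({"CAG", "CAA"})},
    "S": {
        True: frozenset({"AGC", "AGT", "TCA", "TCC", "TCG", "TCT"}),
        False: frozenset({"AGC", "AGT", "TCA", "TCC", "TCG", "TCT"}),
    },
    "A": {
        True: frozenset({"GCA", "GCC", "GCG", "GCT"}),
        False: frozenset({"GCA", "GCC", "GCG", "GCT"}),
    },
}

DNA_ALPHABET = "ACGT"
PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class RepeatTract:
    """Maximal in-frame run of same-amino-acid codons in a spliced CDS."""

    gene_id: str
    amino_acid: str
    codon_set: frozenset[str]
    start_codon: int  # 0-based codon index
    n_codons: int
    genomic_intervals: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def nt_length(self) -> int:
        return 3 * self.n_codons


def find_codon_tracts(
    cds_seq: str,
    amino_acid: str,
    min_codons: int = 4,
    strict_cag: bool = True,
    gene_id: str = "",
) -> list[RepeatTract]:
    """Maximal runs of target codons of length >= ``min_codons``.

    For glutamine with ``strict_cag`` the codon set is {CAG} only (the
    polyQ-disease repeat); relaxing it admits CAA. Serine and alanine use
    their full codon families.
    """
    seq = cds_seq.upper()
    if len(seq) % 3 != 0:
        raise ValueError(f"CDS length {len(seq)} not divisible by 3")
    if amino_acid not in CODON_SETS:
        raise ValueError(f"unsupported amino acid {amino_acid!r}; one of {sorted(CODON_SETS)}")
    codon_set = CODON_SETS[amino_acid][bool(strict_cag)]
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    tracts = []
    run_start = None
    for i, codon in enumerate(codons + ["___"]):  # sentinel flushes the last run
        if codon in codon_set:
            if run_start is None:
                run_start = i
        else:
            if run_start is not None and i - run_start >= min_codons:
                tracts.append(
                    RepeatTract(
                        gene_id=gene_id,
                        amino_acid=amino_acid,
                        codon_set=codon_set,
                        start_codon=run_start,
                        n_codons=i - run_start,
                    )
                )
            run_start = None
    return tracts


def locate_tracts(
    tracts: list[RepeatTract], transcript: TranscriptModel
) -> list[RepeatTract]:
    """Fill each tract's genomic intervals by projecting through the CDS."""
    for tract in tracts:
        tract.genomic_intervals = transcript.codon_span_to_genomic(
            tract.start_codon, tract.n_codons
        )
    return tracts


@dataclass
class MotifHit:
    sequence_id: str
    offset: int  # 0-based
    score: float  # log2 odds, bits
    p_value: float


def estimate_background(seqs, alphabet: str) -> dict[str, float]:
    """0-order letter frequencies pooled over a sequence collection."""
    counts = Counter()
    for s in seqs:
        counts.update(s.upper())
    unknown = set(counts) - set(alphabet)
    if unknown:
        raise ValueError(f"letters {sorted(unknown)} outside alphabet {alphabet!r}")
    total = sum(counts[a] for a in alphabet)
    if total == 0:
        raise ValueError("cannot estimate background from empty sequences")
    # pseudocount keeps every letter strictly positive
    return {a: (counts[a] + 1) / (total + len(alphabet)) for a in alphabet}


class MotifScanner:
    """Consensus-motif scanner with exact DP p-values.

    The motif model gives the consensus letter probability 1 - epsilon at
    each position, spreading epsilon over the other letters. Scores are
    log2 odds against the 0-order background, discretized at ``resolution``
    bits; the null score distribution is the exact convolution of the
    per-position discretized distributions, so the p-value of a window is
    P(score of a random background window >= observed), with no
    approximation beyond the shared discretization.
    """

    def __init__(
        self,
        motif: str,
        background: dict[str, float],
        epsilon: float = 0.01,
        resolution: float = 1e-3,
    ) -> None:
        if not motif:
            raise ValueError("motif must be non-empty")
        alphabet = sorted(background)
        if any(background[a] <= 0 for a in alphabet):
            raise ValueError("background frequencies must be strictly positive")
        total = sum(background.values())
        if not math.isclose(total, 1.0, rel_tol=1e-6):
            background = {a: background[a] / total for a in alphabet}
        missing = set(motif.upper()) - set(alphabet)
        if missing:
            raise ValueError(
                f"motif letters {sorted(missing)} not in background alphabet {alphabet}"
            )
        self.motif = motif.upper()
        self.alphabet = alphabet
        self.background = background
        self.resolution = resolution
        self._index = {a: i for i, a in enumerate(alphabet)}
        k = len(alphabet)
        # integer score matrix: positions x letters, units of `resolution` bits
        self._int_scores = np.empty((len(self.motif), k), dtype=np.int64)
        for j, c in enumerate(self.motif):
            for a, i in self._index.items():
                p = (1 - epsilon) if a == c else epsilon / (k - 1)
                bits = math.log2(p / background[a])
                self._int_scores[j, i] = round(bits / resolution)
        self._build_null()

    def _build_null(self) -> None:
        lo = int(self._int_scores.min(axis=1).sum())
        hi = int(self._int_scores.max(axis=1).sum())
        bg = np.array([self.background[a] for a in self.alphabet])
        pmf = np.zeros(hi - lo + 1)
        # start with the distribution of the first position, then convolve
        offset = lo  # pmf[i] = P(sum == offset + i)
        cur = np.array([1.0])
        cur_lo = 0
        for j in range(len(self.motif)):
            row = self._int_scores[j]
            new_lo = cur_lo + int(row.min())
            new_hi = cur_lo + cur.size - 1 + int(row.max())
            new = np.zeros(new_hi - new_lo + 1)
            for i, a in enumerate(self.alphabet):
                s = int(row[i])
                start = cur_lo + s - new_lo
                new[start : start + cur.size] += bg[i] * cur
            cur, cur_lo = new, new_lo
        pmf = cur
        self._null_lo = cur_lo
        # survival: P(S >= s) for s = lo..hi
        self._sf = np.cumsum(pmf[::-1])[::-1]

    def pvalue(self, int_score: int) -> float:
        idx = int_score - self._null_lo
        if idx < 0:
            return 1.0
        if idx >= self._sf.size:
            return 0.0
        return float(min(1.0, self._sf[idx]))

    def window_int_score(self, window: str) -> int:
        return int(
            sum(self._int_scores[j, self._index[c]] for j, c in enumerate(window))
        )

    def scan(self, seq: str, sequence_id: str = "seq", p_threshold: float = 1e-4) -> list[MotifHit]:
        seq = seq.upper()
        bad = set(seq) - set(self.alphabet)
        if bad:
            raise ValueError(
                f"sequence letters {sorted(bad)} not in scanner alphabet {self.alphabet}"
            )
        L = len(self.motif)
        n_off = len(seq) - L + 1
        if n_off <= 0:
            return []
        idx = np.fromiter((self._index[c] for c in seq), dtype=np.int64, count=len(seq))
        totals = np.zeros(n_off, dtype=np.int64)
        for j in range(L):
            totals += self._int_scores[j, idx[j : j + n_off]]
        hits = []
        for off in np.flatnonzero(totals >= self._min_hit_score(p_threshold)):
            s_int = int(totals[off])
            p = self.pvalue(s_int)
            if p < p_threshold:
                hits.append(
                    MotifHit(
                        sequence_id=sequence_id,
                        offset=int(off),
                        score=s_int * self.resolution,
                        p_value=p,
                    )
                )
        return hits

    def _min_hit_score(self, p_threshold: float) -> int:
        """Smallest integer score whose survival probability is < threshold."""
        qualifying = np.flatnonzero(self._sf < p_threshold)
        if qualifying.size == 0:
            return int(self._null_lo + self._sf.size)  # unreachable score
        return int(self._null_lo + qualifying[0])


def scan_motif(
    seq: str,
    motif: str,
    background: dict[str, float] | None = None,
    p_threshold: float = 1e-4,
    sequence_id: str = "seq",
    epsilon: float = 0.01,
    resolution: float = 1e-3,
) -> list[MotifHit]:
    """Scan one sequence for a consensus motif (single strand).

    When no background is given, 0-order frequencies are estimated from the
    scanned sequence itself. Hits are offsets whose exact-DP p-value is
    below ``p_threshold``.
    """
    motif_u = motif.upper()
    alphabet = DNA_ALPHABET if set(seq.upper()) | set(motif_u) <= set(DNA_ALPHABET) else PROTEIN_ALPHABET
    if background is None:
        background = estimate_background([seq], alphabet)
    scanner = MotifScanner(motif_u, background, epsilon=epsilon, resolution=resolution)
    return scanner.scan(seq, sequence_id=sequence_id, p_threshold=p_threshold)


def peaks_near_tracts(
    peaks: list[ConsensusPeak],
    tracts: list[RepeatTract],
    window: int = 30,
) -> pd.DataFrame:
    """Associate peaks with tract/motif genomic intervals within a window.

    A (peak, tract-interval) pair is associated when the genomic gap
    between the two intervals is at most ``window`` nt (overlap counts as
    distance 0). Returns one row per pair within the window plus a
    per-gene summary column; genes come from the tract annotation.
    """
    rows = []
    for tract in tracts:
        for chrom, ts, te in tract.genomic_intervals:
            for p in peaks:
                if p.chrom != chrom:
                    continue
                gap = max(ts - p.end, p.start - te, 0)
                # half-open intervals: adjacency ([5,10) then [10,12)) is gap 0
                if gap <= window:
                    rows.append(
                        {
                            "gene_id": tract.gene_id,
                            "peak_chrom": p.chrom,
                            "peak_start": p.start,
                            "peak_end": p.end,
                            "feature_type": f"poly{tract.amino_acid}_tract",
                            "feature_start": ts,
                            "feature_end": te,
                            "distance": gap,
                        }
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "peak_chrom",
            "peak_start",
            "peak_end",
            "feature_type",
            "feature_start",
            "feature_end",
            "distance",
        ],
    )


def associated_genes(association: pd.DataFrame) -> set[str]:
    """Genes with at least one peak within the window of a tract."""
    if association.empty:
        return set()
    return set(association["gene_id"].unique())


def compute_tpm(counts: pd.DataFrame, effective_lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million for a genes x libraries count table.

    TPM_g = 1e6 * (c_g / l_g) / sum_h (c_h / l_h); every library column
    sums to 1e6.
    """
    lengths = effective_lengths.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("effective_lengths missing for some genes")
    if (lengths <= 0).any():
        raise ValueError("effective lengths must be positive")
    rate = counts.div(lengths, axis=0)
    totals = rate.sum(axis=0)
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise ValueError(f"zero total counts in libraries {bad}")
    return rate.div(totals, axis=1) * 1e6


def background_motif_proportion(
    expressed_cds: dict[str, str],
    motif: str,
    p_threshold: float = 1e-4,
    target_genes: set[str] | None = None,
    background: dict[str, float] | None = None,
) -> dict:
    """Fraction of expressed genes whose CDS contains a significant motif hit.

    The 0-order background defaults to letter frequencies pooled over the
    expressed CDS set. When ``target_genes`` is given, the same fraction is
    also reported within that subset (the target-vs-background comparison
    used for enrichment claims).
    """
    if not expressed_cds:
        raise ValueError("expressed gene set is empty")
    if background is None:
        background = estimate_background(expressed_cds.values(), DNA_ALPHABET)
    scanner = MotifScanner(motif, background)
    with_hit = {
        gid
        for gid, seq in expressed_cds.items()
        if scanner.scan(seq, sequence_id=gid, p_threshold=p_threshold)
    }
    result = {
        "n_expressed": len(expressed_cds),
        "n_with_motif": len(with_hit),
        "proportion": len(with_hit) / len(expressed_cds),
        "genes_with_motif": with_hit,
    }
    if target_genes is not None:
        targets = set(target_genes) & set(expressed_cds)
        hits = with_hit & targets
        result.update(
            n_targets=len(targets),
            n_target_with_motif=len(hits),
            target_proportion=len(hits) / len(targets) if targets else float("nan"),
        )
    return result
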