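import itertools
import re

import numpy as np
import pandas as pd
import pytest

from ribostall.consensus import ConsensusPeak
from ribostall.io_formats import TranscriptModel
from ribostall.repeats import (
    CODON_SETS,
    MotifScanner,
    RepeatTract,
    background_motif_proportion,
    compute_tpm,
    estimate_background,
    find_codon_tracts,
    locate_tracts,
    peaks_near_tracts,
    scan_motif,
)

UNIFORM = {a: 0.25 for a in "ACGT"}


def regex_tracts(cds: str, codon_set, min_codons: int):
    """Independent oracle: maximal runs via regex over the codon string."""
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    flags = "".join("1" if c in codon_set else "0" for c in codons)
    return [
        (m.start(), m.end() - m.start())
        for m in re.finditer(r"1+", flags)
        if m.end() - m.start() >= min_codons
    ]


class TestCodonTracts:
    def test_four_cag_boundary(self):
        (t,) = find_codon_tracts("CAGCAGCAGCAG", "Q")
        assert (t.start_codon, t.n_codons) == (0, 4)

    def test_three_codons_below_threshold(self):
        assert find_codon_tracts("CAGCAGCAG", "Q") == []

    def test_strictness_modes(self):
        seq = "CAGCAACAGCAGCAG"
        assert find_codon_tracts(seq, "Q", strict_cag=True) == []
        (t,) = find_codon_tracts(seq, "Q", strict_cag=False)
        assert t.n_codons == 5

    def test_length_not_multiple_of_three_raises(self):
        with pytest.raises(ValueError):
            find_codon_tracts("CAGCA", "Q")

    @pytest.mark.parametrize("amino_acid", ["Q", "S", "A"])
    @pytest.mark.parametrize("strict", [True, False])
    def test_regex_oracle_on_random_cds(self, amino_acid, strict):
        rng = np.random.default_rng(10)
        codon_set = CODON_SETS[amino_acid][strict]
        pool = sorted(codon_set) + ["ATG", "GAA", "TTT", "CCC"]
        for _ in range(250):
            n = int(rng.integers(4, 60))
            # bias toward target codons so runs actually occur
            cds = "".join(rng.choice(pool, size=n, p=_weights(len(pool))))
            got = [
                (t.start_codon, t.n_codons)
                for t in find_codon_tracts(cds, amino_acid, strict_cag=strict)
            ]
            assert got == regex_tracts(cds, codon_set, 4)

    def test_maximality(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            codons = rng.choice(["CAG", "AAA"], size=30, p=[0.6, 0.4])
            cds = "".join(codons)
            for t in find_codon_tracts(cds, "Q"):
                if t.start_codon > 0:
                    assert codons[t.start_codon - 1] != "CAG"
                end = t.start_codon + t.n_codons
                if end < len(codons):
                    assert codons[end] != "CAG"


def _weights(k):
    w = np.ones(k)
    w[: k - 4] = 3.0
    return w / w.sum()


class TestLocateTracts:
    def test_plus_strand_projection(self):
        t = TranscriptModel("g", "t", "c", "+", exons=[(100, 160)], cds=(100, 160))
        (tract,) = locate_tracts(find_codon_tracts("CAG" * 20, "Q", gene_id="g"), t)
        assert tract.genomic_intervals == [("c", 100, 160)]

    def test_minus_strand_projection(self):
        # 10-codon CDS on the minus strand: codon 0 sits at the genomic 3' end
        t = TranscriptModel("g", "t", "c", "-", exons=[(100, 130)], cds=(100, 130))
        tract = RepeatTract("g", "Q", frozenset({"CAG"}), start_codon=0, n_codons=2)
        (loc,) = locate_tracts([tract], t)
        assert loc.genomic_intervals == [("c", 124, 130)]


class TestMotifScan:
    def test_consensus_match_is_extreme(self):
        hits = scan_motif("CAGCAGCAGCAGCAG", "CAG" * 5, background=UNIFORM)
        assert len(hits) == 1 and hits[0].offset == 0
        assert hits[0].p_value <= 0.25**15 * 1.001

    def test_no_hit_on_unrelated_sequence(self):
        assert scan_motif("A" * 15, "CAG" * 5, background=UNIFORM) == []

    def test_alphabet_mismatch_raises(self):
        with pytest.raises(ValueError):
            MotifScanner("CAG", UNIFORM).scan("CAGXCAG")

    def test_protein_motif(self):
        hits = scan_motif("MAAQQQQQAAM", "QQQQQ", p_threshold=1e-3)
        assert [h.offset for h in hits] == [3]

    @pytest.mark.parametrize(
        "motif,background",
        [
            ("CAG", UNIFORM),
            ("CAGCA", UNIFORM),
            ("CAGCAGCA", {"A": 0.4, "C": 0.3, "G": 0.2, "T": 0.1}),
        ],
    )
    def test_exact_dp_matches_enumeration(self, motif, background):
        """DP null distribution equals brute-force enumeration over all 4^L
        windows at the shared score discretization."""
        scanner = MotifScanner(motif, background)
        L = len(motif)
        scored = {}
        for window in itertools.product("ACGT", repeat=L):
            w = "".join(window)
            prob = np.prod([background[c] for c in w])
            s = scanner.window_int_score(w)
            scored[s] = scored.get(s, 0.0) + prob
        for s in scored:
            brute = sum(p for si, p in scored.items() if si >= s)
            assert scanner.pvalue(s) == pytest.approx(brute, rel=1e-9)

    def test_pvalues_monotone_in_score(self):
        scanner = MotifScanner("CAGCAG", UNIFORM)
        scores = sorted(
            scanner.window_int_score("".join(w))
            for w in itertools.product("ACGT", repeat=6)
        )
        ps = [scanner.pvalue(s) for s in scores]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestAssociation:
    def _peak(self, start, end):
        return ConsensusPeak("c", start, end, "g", support=2)

    def _tract(self, start, end):
        return RepeatTract("g", "Q", frozenset({"CAG"}), 0, (end - start) // 3,
                           genomic_intervals=[("c", start, end)])

    def test_gap_arithmetic(self):
        df = peaks_near_tracts([self._peak(100, 101)], [self._tract(110, 125)], window=30)
        assert len(df) == 1 and df.iloc[0]["distance"] == 9

    def test_strict_window_boundary(self):
        df = peaks_near_tracts([self._peak(100, 101)], [self._tract(132, 144)], window=30)
        assert len(df) == 0  # gap 31 > 30

    def test_overlap_distance_zero(self):
        df = peaks_near_tracts([self._peak(110, 115)], [self._tract(110, 125)], window=30)
        assert df.iloc[0]["distance"] == 0


class TestTPM:
    def test_single_gene_normalization(self):
        tpm = compute_tpm(pd.DataFrame({"lib": [7]}, index=["g"]), pd.Series({"g": 100}))
        assert tpm.loc["g", "lib"] == pytest.approx(1e6)

    def test_symmetry(self):
        counts = pd.DataFrame({"lib": [5, 5]}, index=["a", "b"])
        tpm = compute_tpm(counts, pd.Series({"a": 100, "b": 100}))
        assert tpm["lib"].tolist() == pytest.approx([5e5, 5e5])

    def test_length_normalization(self):
        counts = pd.DataFrame({"lib": [10, 10]}, index=["a", "b"])
        tpm = compute_tpm(counts, pd.Series({"a": 100, "b": 200}))
        assert tpm.loc["a", "lib"] == pytest.approx(666666.666667)
        assert tpm.loc["b", "lib"] == pytest.approx(333333.333333)

    def test_columns_sum_to_million(self):
        rng = np.random.default_rng(12)
        counts = pd.DataFrame(
            rng.integers(0, 1000, size=(30, 3)), columns=list("xyz"),
            index=[f"g{i}" for i in range(30)],
        )
        counts.iloc[0] += 1  # avoid an all-zero library
        lengths = pd.Series(rng.integers(200, 3000, size=30).astype(float), index=counts.index)
        tpm = compute_tpm(counts, lengths)
        assert tpm.sum(axis=0).tolist() == pytest.approx([1e6] * 3, rel=1e-9)

    def test_zero_library_raises(self):
        counts = pd.DataFrame({"lib": [0, 0]}, index=["a", "b"])
        with pytest.raises(ValueError):
            compute_tpm(counts, pd.Series({"a": 100, "b": 100}))


class TestBackgroundProportion:
    def test_planted_fraction(self):
        rng = np.random.default_rng(13)
        seqs = {}
        for i in range(10):
            # A/T-only bodies cannot contain any partial CAG match, so the
            # only scorable windows are the planted consensus repeats
            body = "".join(rng.choice(["ATA", "TTT", "AAT", "TAT"], size=60))
            if i < 4:
                body = body[:90] + "CAG" * 5 + body[90:]
            seqs[f"g{i}"] = body
        # verify planting with an independent regex check
        assert sum("CAG" * 5 in s for s in seqs.values()) == 4
        res = background_motif_proportion(seqs, "CAG" * 5)
        assert res["proportion"] == pytest.approx(0.4)
        assert res["genes_with_motif"] == {"g0", "g1", "g2", "g3"}

    def test_no_motif_anywhere(self):
        seqs = {f"g{i}": "AT" * 30 for i in range(5)}
        res = background_motif_proportion(seqs, "CAG" * 5, background=UNIFORM)
        assert res["proportion"] == 0.0

    def test_all_genes_contain_motif(self):
        seqs = {f"g{i}": "GAATTT" * 5 + "CAG" * 5 + "CCAATG" * 5 for i in range(5)}
        res = background_motif_proportion(seqs, "CAG" * 5)
        assert res["proportion"] == 1.0

    def test_target_subset_reported(self):
        seqs = {"a": "CAG" * 10 + "AAATTT" * 5, "b": "AT" * 30, "c": "GC" * 30}
        res = background_motif_proportion(seqs, "CAG" * 5, target_genes={"a", "b"},
                                          background=UNIFORM)
        assert res["n_targets"] == 2 and res["n_target_with_motif"] == 1
        assert res["target_proportion"] == pytest.approx(0.5)


def test_estimate_background_rejects_foreign_letters():
    with pytest.raises(ValueError):
        estimate_background(["ACGZ"], "ACGT")
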