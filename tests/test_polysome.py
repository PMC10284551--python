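import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import comb

from ribostall.polysome import (
    call_polysome_targets,
    calls_to_frame,
    library_correlation,
    log_overlap_significance,
    overlap_significance,
    overlap_significance_counts,
)
from ribostall.synthetic import PolysomeSimConfig, simulate_polysome_counts


def _tidy(control, mutant, n_reps=3):
    """Build a tidy count table from per-gene (input, polysome) count maps."""
    rows = []
    for cond, table in (("control", control), ("mutant", mutant)):
        for gene, (inp, poly) in table.items():
            for rep in range(1, n_reps + 1):
                rows.append((gene, cond, "input", rep, inp[rep - 1]))
                rows.append((gene, cond, "polysome", rep, poly[rep - 1]))
    return pd.DataFrame(rows, columns=["gene", "condition", "fraction", "replicate", "count"])


class TestCaller:
    def test_identical_tables_unchanged(self):
        table = {"a": ([100, 110, 90], [200, 210, 190]), "b": ([50, 55, 45], [20, 25, 15])}
        calls = call_polysome_targets(_tidy(table, table))
        assert all(c.state == "unchanged" for c in calls)
        assert all(c.log2fc == pytest.approx(0.0) for c in calls)

    def test_two_replicates_warns(self):
        table = {"a": ([100, 110], [200, 210])}
        with pytest.warns(UserWarning, match="2 replicates"):
            call_polysome_targets(_tidy(table, table, n_reps=2))

    def test_single_replicate_raises(self):
        rows = pd.DataFrame(
            {
                "gene": ["a"] * 4,
                "condition": ["control", "control", "mutant", "mutant"],
                "fraction": ["input", "polysome"] * 2,
                "replicate": [1, 1, 1, 1],
                "count": [10, 10, 10, 10],
            }
        )
        with pytest.raises(ValueError, match="replicates"):
            call_polysome_targets(rows)

    def test_antisymmetry_under_label_swap(self):
        rng = np.random.default_rng(16)
        genes = {
            f"g{i}": (
                rng.integers(50, 500, 3).tolist(),
                rng.integers(50, 500, 3).tolist(),
            )
            for i in range(20)
        }
        other = {
            g: (rng.integers(50, 500, 3).tolist(), rng.integers(50, 500, 3).tolist())
            for g in genes
        }
        fwd = {c.gene_id: c for c in call_polysome_targets(_tidy(genes, other))}
        rev = {c.gene_id: c for c in call_polysome_targets(_tidy(other, genes))}
        flip = {"low": "high", "high": "low", "unchanged": "unchanged"}
        for g in fwd:
            assert fwd[g].log2fc == pytest.approx(-rev[g].log2fc)
            assert fwd[g].p_value == pytest.approx(rev[g].p_value)
            assert rev[g].state == flip[fwd[g].state]

    def test_null_false_positive_calibration(self):
        cfg = PolysomeSimConfig(n_genes=1000, shifted_frac=0.0, seed=21)
        counts, _ = simulate_polysome_counts(cfg)
        with pytest.warns(UserWarning):
            calls = call_polysome_targets(counts)
        fpr = np.mean([c.p_value < 0.05 for c in calls])
        se = np.sqrt(0.05 * 0.95 / len(calls))
        assert abs(fpr - 0.05) <= 3 * se

    def test_planted_low_genes_recovered(self):
        cfg = PolysomeSimConfig(n_genes=1000, shifted_frac=0.05, log2fc=-3.0, seed=22)
        counts, truth = simulate_polysome_counts(cfg)
        with pytest.warns(UserWarning):
            calls = call_polysome_targets(counts)
        low = {c.gene_id for c in calls if c.state == "low"}
        sens = len(low & truth.shift_genes) / len(truth.shift_genes)
        assert sens >= 0.9

    def test_calls_frame_columns(self):
        table = {"a": ([100, 110, 90], [200, 210, 190])}
        df = calls_to_frame(call_polysome_targets(_tidy(table, table)))
        assert list(df.columns) == ["gene", "log2fc", "p_value", "state"]


class TestCorrelation:
    def test_duplicated_column(self):
        rng = np.random.default_rng(17)
        x = rng.random(50)
        df = pd.DataFrame({"a": x, "b": x})
        assert library_correlation(df).loc["a", "b"] == pytest.approx(1.0)

    def test_negated_column(self):
        rng = np.random.default_rng(18)
        x = rng.random(50)
        df = pd.DataFrame({"a": x, "b": -x})
        assert library_correlation(df).loc["a", "b"] == pytest.approx(-1.0)

    def test_zero_variance_flagged_nan(self):
        df = pd.DataFrame({"a": [1.0, 2, 3], "b": [5.0, 5, 5]})
        r = library_correlation(df)
        assert np.isnan(r.loc["a", "b"])
        assert r.loc["b", "b"] == 1.0

    def test_replicate_libraries_highly_correlated(self):
        """Replicate footprint libraries sharing a strongly structured mean
        profile reproduce the r > 0.9 quality-control behaviour."""
        rng = np.random.default_rng(23)
        # shared positional signal (mean 50) dominating independent NB noise
        mu = 50.0 * rng.lognormal(0.0, 1.0, size=10_000)
        size = 50.0
        libs = {
            f"lib{i}": rng.negative_binomial(size, size / (size + mu)).astype(float)
            for i in range(3)
        }
        r = library_correlation(pd.DataFrame(libs))
        off = r.to_numpy()[~np.eye(3, dtype=bool)]
        assert (off > 0.9).all()


class TestOverlap:
    def test_closed_form_full_overlap(self):
        p = overlap_significance_counts(5, 5, 5, 10)
        assert p == pytest.approx(1 / comb(10, 5), rel=1e-12)  # 1/252

    def test_overlap_zero_is_one(self):
        assert overlap_significance_counts(5, 5, 0, 10) == pytest.approx(1.0)

    def test_set_interface(self):
        a, b = {1, 2, 3, 4, 5}, {1, 2, 3, 4, 5}
        assert overlap_significance(a, b, 10) == pytest.approx(1 / 252)

    def test_exchangeability(self):
        assert overlap_significance_counts(30, 70, 25, 200) == pytest.approx(
            overlap_significance_counts(70, 30, 25, 200), rel=1e-12
        )

    def test_summation_oracle_small_universes(self):
        rng = np.random.default_rng(19)
        for _ in range(50):
            m = int(rng.integers(5, 200))
            na = int(rng.integers(1, m + 1))
            nb = int(rng.integers(1, m + 1))
            k = int(rng.integers(0, min(na, nb) + 1))
            direct = sum(
                comb(na, i, exact=True) * comb(m - na, nb - i, exact=True)
                for i in range(k, min(na, nb) + 1)
                if nb - i <= m - na
            ) / comb(m, nb, exact=True)
            assert overlap_significance_counts(na, nb, k, m) == pytest.approx(direct, rel=1e-9)

    def test_log_space_extreme_p_without_underflow(self):
        # overlaps this deep in the tail give p far below 1e-180
        logs = [
            log_overlap_significance(500, 500, k, 20000) for k in (460, 480, 500)
        ]
        assert logs[0] > logs[1] > logs[2]  # monotone in overlap
        assert logs[-1] < -180 * np.log(10)
        assert np.isfinite(logs).all()

    def test_matches_scipy_logsf(self):
        got = log_overlap_significance(500, 500, 400, 20000)
        ref = stats.hypergeom.logsf(399, 20000, 500, 500)
        assert got == pytest.approx(float(ref), rel=1e-6)

    def test_inconsistent_sizes_raise(self):
        with pytest.raises(ValueError):
            overlap_significance_counts(11, 5, 3, 10)
        with pytest.raises(ValueError):
            overlap_significance_counts(5, 5, 6, 10)
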