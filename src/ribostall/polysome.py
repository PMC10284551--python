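"""Polysome-association target calling, library correlation, and set
overlap statistics.

A gene's translation state is summarized per replicate as the log2 ratio of
its polysome-fraction to input counts (translation efficiency, TE) after
library-size normalization and a 0.5 pseudocount. Targets are genes whose
mutant-vs-control TE shift passes a fold-change threshold with an unpaired
t-test p-value below threshold: "low" for a >= 2-fold decrease in polysome
association, "high" for a >= 2-fold increase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

REQUIRED_COLUMNS = {"gene", "condition", "fraction", "replicate", "count"}


@dataclass
class PolysomeCall:
    gene_id: str
    log2fc: float
    p_value: float
    state: str  # low / high / unchanged


def call_polysome_targets(
    counts: pd.DataFrame,
    p_threshold: float = 0.05,
    fold_threshold: float = 2.0,
    pseudocount: float = 0.5,
) -> list[PolysomeCall]:
    """Classify genes by polysome-association change, mutant vs control.

    ``counts`` is tidy with columns gene, condition (control/mutant),
    fraction (input/polysome), replicate, count. Counts are scaled to the
    mean library depth, TE = log2((polysome + 0.5) / (input + 0.5)) per
    replicate, log2fc = mean TE(mutant) - mean TE(control), and the p-value
    comes from a pooled two-sample two-sided t-test on the replicate TEs.
    """
    missing = REQUIRED_COLUMNS - set(counts.columns)
    if missing:
        raise ValueError(f"count table missing columns {sorted(missing)}")
    if (counts["count"] < 0).any():
        raise ValueError("negative counts")
    libs = counts.groupby(["condition", "fraction", "replicate"])["count"]
    n_reps = counts.groupby(["condition", "fraction"])["replicate"].nunique()
    if (n_reps < 2).any():
        raise ValueError("need >= 2 replicates per condition and fraction")
    if (n_reps == 2).any():
        warnings.warn(
            "only 2 replicates per condition: the t-test has 2 degrees of "
            "freedom and limited power",
            stacklevel=2,
        )
    totals = libs.sum()
    scale = (totals.mean() / totals).rename("scale").reset_index()
    df = counts.merge(scale, on=["condition", "fraction", "replicate"])
    df["norm"] = df["count"] * df["scale"]
    wide = df.pivot_table(
        index=["gene", "condition", "replicate"], columns="fraction", values="norm"
    )
    te = np.log2((wide["polysome"] + pseudocount) / (wide["input"] + pseudocount))
    te = te.unstack("replicate")
    ctrl = te.xs("control", level="condition")
    mut = te.xs("mutant", level="condition")
    genes = ctrl.index.intersection(mut.index)
    ctrl_a = ctrl.loc[genes].to_numpy(dtype=float)
    mut_a = mut.loc[genes].to_numpy(dtype=float)
    log2fc = np.nanmean(mut_a, axis=1) - np.nanmean(ctrl_a, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(mut_a, ctrl_a, axis=1, equal_var=True, nan_policy="omit")
        pvals = np.asarray(res.pvalue, dtype=float)
    # zero variance in both groups: identical -> p=1, separated -> p -> 0
    nan_p = np.isnan(pvals)
    pvals[nan_p & (log2fc == 0)] = 1.0
    pvals[nan_p & (log2fc != 0)] = 0.0
    lfc_cut = float(np.log2(fold_threshold))
    calls = []
    for gene, lfc, p in zip(genes, log2fc, pvals):
        if np.isnan(lfc):
            continue
        if lfc <= -lfc_cut and p < p_threshold:
            state = "low"
        elif lfc >= lfc_cut and p < p_threshold:
            state = "high"
        else:
            state = "unchanged"
        calls.append(PolysomeCall(gene_id=gene, log2fc=float(lfc), p_value=float(p), state=state))
    return calls


def calls_to_frame(calls: list[PolysomeCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"gene": c.gene_id, "log2fc": c.log2fc, "p_value": c.p_value, "state": c.state}
            for c in calls
        ]
    )


def library_correlation(values: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson r between library columns (features x libraries).

    Zero-variance columns yield NaN entries (flagged undefined) rather than
    an error; the diagonal is exactly 1.
    """
    if values.shape[1] < 2:
        raise ValueError("need >= 2 libraries")
    if values.shape[0] < 3:
        raise ValueError("need >= 3 features")
    arr = values.to_numpy(dtype=float)
    sd = arr.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(arr, rowvar=False)
    r[np.ix_(sd == 0, np.arange(len(sd)))] = np.nan
    r[np.ix_(np.arange(len(sd)), np.flatnonzero(sd == 0))] = np.nan
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=values.columns, columns=values.columns)


def overlap_significance(set_a, set_b, universe_size: int) -> float:
    """Upper-tail hypergeometric p-value of the overlap of two gene sets.

    ``set_a``/``set_b`` may be sets (overlap computed) or integers (then the
    observed overlap must be passed as a set intersection elsewhere — use
    :func:`overlap_significance_counts`). Computed in log space, so p-values
    far below the double-precision underflow threshold of the naive product
    are still exact.
    """
    a, b = set(set_a), set(set_b)
    return overlap_significance_counts(len(a), len(b), len(a & b), universe_size)


def overlap_significance_counts(n_a: int, n_b: int, overlap: int, universe_size: int) -> float:
    """P(X >= overlap) with X ~ Hypergeometric(universe, n_a, n_b)."""
    if n_a > universe_size or n_b > universe_size:
        raise ValueError("set sizes exceed the universe")
    if overlap > min(n_a, n_b):
        raise ValueError("overlap exceeds the smaller set")
    return float(np.exp(log_overlap_significance(n_a, n_b, overlap, universe_size)))


def log_overlap_significance(n_a: int, n_b: int, overlap: int, universe_size: int) -> float:
    """Natural-log upper-tail hypergeometric probability, exact in log space."""
    k_min = max(overlap, max(0, n_a + n_b - universe_size))
    k_max = min(n_a, n_b)
    if overlap <= max(0, n_a + n_b - universe_size):
        return 0.0  # P(X >= overlap) = 1
    ks = np.arange(k_min, k_max + 1)

    def logC(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    log_terms = logC(n_a, ks) + logC(universe_size - n_a, n_b - ks) - logC(universe_size, n_b)
    return float(logsumexp(log_terms))
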