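"""Relative abundance of RNA modifications from ribonucleoside MS spectra.

A modified ribonucleoside's signal intensity ai_x is expressed as Abundance
versus Proxy: AvP_x = ai_x / (sum of the four canonical ribonucleotide
intensities cr_i in the same spectrum) x 100. Stage profiles are compared
against a baseline stage with an unpaired t test per modification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

CANONICAL_SPECIES = ("AMP", "CMP", "GMP", "UMP")


@dataclass
class SpectrumIntensities:
    """One spectrum's intensities: PTM species plus the four canonicals."""

    ptm_intensities: dict[str, float]
    canonical_intensities: dict[str, float]

    def __post_init__(self) -> None:
        if len(self.canonical_intensities) != 4:
            raise ValueError("exactly four canonical ribonucleotide intensities required")
        for name, v in {**self.ptm_intensities, **self.canonical_intensities}.items():
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"non-finite or negative intensity for {name!r}")
        if any(v <= 0 for v in self.canonical_intensities.values()):
            raise ValueError("canonical intensities must be strictly positive")


def compute_avp(spectrum: SpectrumIntensities) -> dict[str, float]:
    """AvP_x = ai_x / sum(cr_i) * 100 for every PTM in the spectrum."""
    total = sum(spectrum.canonical_intensities.values())
    if total <= 0:
        raise ValueError("canonical intensity sum must be positive")
    return {name: ai / total * 100.0 for name, ai in spectrum.ptm_intensities.items()}


@dataclass
class StageProfile:
    """Replicate AvP values for one stage (rows: replicates, cols: PTMs)."""

    stage: str
    avp: pd.DataFrame = field(default_factory=pd.DataFrame)

    @classmethod
    def from_spectra(cls, stage: str, spectra: list[SpectrumIntensities]) -> "StageProfile":
        rows = [compute_avp(sp) for sp in spectra]
        return cls(stage=stage, avp=pd.DataFrame(rows))

    @property
    def mean(self) -> pd.Series:
        return self.avp.mean()

    @property
    def sd(self) -> pd.Series:
        return self.avp.std(ddof=1)


def compare_stages(
    profiles: list[StageProfile],
    baseline_stage: str,
    welch: bool = True,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Test each stage's replicate AvPs per PTM against the baseline stage.

    Returns one row per (stage, PTM) with the stage mean/SD, the direction of
    the difference from baseline (-1/0/+1), the two-sided unpaired t-test p
    value (Welch by default) and a significance flag at ``p_threshold``.
    The baseline stage is included, flagged ``is_baseline``.
    """
    by_stage = {p.stage: p for p in profiles}
    if baseline_stage not in by_stage:
        raise ValueError(f"baseline stage {baseline_stage!r} not among profiles")
    base = by_stage[baseline_stage]
    records = []
    for prof in profiles:
        for ptm in prof.avp.columns:
            vals = prof.avp[ptm].dropna().to_numpy()
            rec = {
                "stage": prof.stage,
                "ptm": ptm,
                "n": len(vals),
                "mean_avp": float(np.mean(vals)) if len(vals) else float("nan"),
                "sd_avp": float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan"),
                "is_baseline": prof.stage == baseline_stage,
                "baseline_present": ptm in base.avp.columns,
            }
            if prof.stage == baseline_stage:
                rec.update(direction=0, p_value=float("nan"), significant=False)
            elif not rec["baseline_present"] or len(vals) < 2:
                rec.update(direction=0, p_value=float("nan"), significant=False)
            else:
                ref = base.avp[ptm].dropna().to_numpy()
                if len(ref) < 2:
                    rec.update(direction=0, p_value=float("nan"), significant=False)
                else:
                    t = stats.ttest_ind(vals, ref, equal_var=not welch)
                    diff = float(np.mean(vals) - np.mean(ref))
                    rec.update(
                        direction=int(np.sign(diff)) if diff != 0 else 0,
                        p_value=float(t.pvalue),
                        significant=bool(t.pvalue < p_threshold),
                    )
            records.append(rec)
    return pd.DataFrame.from_records(records)


def render_profile_table(
    records: pd.DataFrame, gradient_max: float = 3.0, n_bins: int = 10
) -> pd.DataFrame:
    """Map mean AvPs onto a cold-hot gradient over [0, gradient_max].

    Values above the gradient maximum are clipped into the top bin; the
    significance flag and direction are carried through unchanged.
    """
    out = records.copy()
    clipped = out["mean_avp"].clip(lower=0.0, upper=gradient_max)
    bins = np.minimum((clipped / gradient_max * n_bins).astype(int), n_bins - 1)
    out["gradient_bin"] = bins
    return out
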