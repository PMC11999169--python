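"""Kinetic curve fitting and quality control for multi-exposure reads.

Each (sample, peptide) series of intensity versus exposure time is reduced
by ordinary least squares to a slope, intercept and R^2. QC then removes
peptides with zero or undetectable signal (low maximum intensity, or a
non-positive slope) and peptides whose signal does not grow linearly with
exposure (low R^2). A peptide enters the comparison only if it passes QC
in every sample, matching the single per-comparison pass count the array
workflow reports. The derived per-sample signal is slope times a reference
exposure (100 ms by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import QCError

DEFAULT_MIN_R2 = 0.90
DEFAULT_REFERENCE_EXPOSURE_MS = 100.0

FIT_COLUMNS = ["peptide_id", "sample_id", "chip_id", "group", "slope", "intercept",
               "r_squared", "max_intensity", "n_exposures", "passed_qc", "fail_reason"]


def fit_kinetics(reads: pd.DataFrame) -> pd.DataFrame:
    """OLS fit of intensity on exposure per (chip, sample, peptide).

    Returns one row per series with slope (intensity/ms), intercept, R^2
    and max intensity. Series with fewer than 3 distinct exposures cannot
    support a linearity judgement and are marked failed (reason
    ``nonlinear``). A zero-variance (constant) series gets R^2 = 0.
    """
    recs = []
    for (chip, sample, group, pep), grp in reads.groupby(
            ["chip_id", "sample_id", "group", "peptide_id"], sort=True):
        x = grp["exposure_ms"].to_numpy(float)
        y = grp["intensity"].to_numpy(float)
        n = len(np.unique(x))
        if n < 3:
            recs.append((pep, sample, chip, group, np.nan, np.nan, np.nan,
                         float(y.max()) if y.size else np.nan, n, False, "nonlinear"))
            continue
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        sst = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - float((resid ** 2).sum()) / sst if sst > 0 else 0.0
        r2 = min(max(r2, 0.0), 1.0)
        recs.append((pep, sample, chip, group, float(slope), float(intercept),
                     r2, float(y.max()), n, True, "none"))
    return pd.DataFrame(recs, columns=FIT_COLUMNS)


def apply_qc(fits: pd.DataFrame, min_signal: float,
             min_r2: float = DEFAULT_MIN_R2) -> pd.DataFrame:
    """Flag each fit against the signal and linearity thresholds.

    undetectable  <=>  max_intensity < min_signal or slope <= 0
    nonlinear     <=>  detectable but r_squared < min_r2

    A flat peptide is undetectable (no increase), not nonlinear. Fits
    already failed upstream (too few exposures) stay failed.
    """
    if not 0 <= min_r2 <= 1:
        raise ValueError("min_r2 must be in [0, 1]")
    out = fits.copy()
    degenerate = out["fail_reason"].eq("nonlinear") & out["slope"].isna()
    # numerically flat slopes (OLS on constant data) count as non-increasing
    undetectable = (~degenerate) & ((out["max_intensity"] < min_signal)
                                    | (out["slope"] <= 1e-12))
    nonlinear = (~degenerate) & (~undetectable) & (out["r_squared"] < min_r2)
    out["fail_reason"] = "none"
    out.loc[undetectable, "fail_reason"] = "undetectable"
    out.loc[nonlinear | degenerate, "fail_reason"] = "nonlinear"
    out["passed_qc"] = out["fail_reason"].eq("none")
    return out


def peptides_passing_all(fits: pd.DataFrame) -> set[str]:
    """Peptides that pass QC in every sample of the comparison."""
    ok = fits.groupby("peptide_id")["passed_qc"].all()
    return set(ok.index[ok])


@dataclass
class PeptideSignalMatrix:
    """QC-passed signals: rows are peptides, columns (chip, sample) wells."""

    values: pd.DataFrame  # index peptide_id, columns MultiIndex (chip_id, sample_id)
    sample_groups: dict[str, str]  # sample_id -> group label
    chip_type: str = ""
    reference_exposure_ms: float = DEFAULT_REFERENCE_EXPOSURE_MS
    qc_thresholds: dict = field(default_factory=dict)

    @property
    def peptides(self) -> list[str]:
        return list(self.values.index)

    @property
    def chips(self) -> list[str]:
        return sorted({c for c, _ in self.values.columns})


def build_signal_matrix(fits: pd.DataFrame,
                        reference_exposure_ms: float = DEFAULT_REFERENCE_EXPOSURE_MS,
                        chip_type: str = "",
                        qc_thresholds: dict | None = None) -> PeptideSignalMatrix:
    """Derive the per-peptide signal matrix from QC-annotated fits.

    signal = slope * reference_exposure_ms, kept only for peptides passing
    QC in all samples. Raises QCError when no peptide survives.
    """
    passing = peptides_passing_all(fits)
    if not passing:
        raise QCError("no peptides passed QC in all samples")
    kept = fits[fits["peptide_id"].isin(passing)].copy()
    kept["signal"] = kept["slope"] * reference_exposure_ms
    wide = kept.pivot_table(index="peptide_id", columns=["chip_id", "sample_id"],
                            values="signal", aggfunc="first", sort=True)
    if wide.isna().any().any():
        missing = wide.isna().stack(future_stack=True)
        bad = sorted({p for (p, *_), v in missing.items() if v})
        warnings.warn(f"peptides missing in some wells dropped: {bad}")
        wide = wide.dropna()
        if wide.empty:
            raise QCError("no peptides passed QC in all samples")
    groups = dict(kept.drop_duplicates("sample_id")[["sample_id", "group"]]
                  .itertuples(index=False))
    return PeptideSignalMatrix(wide, groups, chip_type, reference_exposure_ms,
                               qc_thresholds or {})


def estimate_noise_floor(reads: pd.DataFrame, quantile: float = 0.05) -> float:
    """Crude background estimate: a low quantile of the shortest-exposure
    intensities, used to seed the default min_signal threshold."""
    shortest = reads[reads["exposure_ms"] == reads["exposure_ms"].min()]
    return float(shortest["intensity"].quantile(quantile))
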