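"""Control-variability-derived fold-change threshold and the triple DEG filter.

The significance threshold for |log2FC| is not fixed a priori but derived
from the inherent variability of control samples: for each gene the relative
standard deviation (coefficient of variation, CV = SD/mean) of control FPM is
computed, and the threshold is three times the average CV.  A gene is then
called differentially expressed only if it passes three independent filters:
FDR below the cut in *both* external differential-expression methods, mean
expression of at least `fpm_cut` FPM in at least one sample group, and
|log2FC| at or above the variability-derived threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class CVStats:
    """Per-gene control CVs, their mean, and the derived |log2FC| threshold."""

    per_gene_cv: pd.Series
    mean_cv: float
    threshold_log2fc: float

    def __post_init__(self) -> None:
        if (self.per_gene_cv < 0).any():
            raise ValueError("negative CV")
        # the defining identity: threshold = 3 x mean CV
        assert np.isclose(self.threshold_log2fc, 3.0 * self.mean_cv, rtol=1e-12)


def gene_cv(
    fpm: pd.DataFrame,
    control_samples: list[str],
    min_mean_fpm: float = 1.0,
) -> pd.DataFrame:
    """Per-gene CV of FPM across control samples.

    Uses the n-1 sample standard deviation.  Genes whose control mean FPM is
    below ``min_mean_fpm`` are excluded (0/0 instability at unexpressed
    genes would otherwise dominate the average).

    Returns a DataFrame indexed by gene with columns ``mean_fpm`` and ``cv``.
    """
    missing = [s for s in control_samples if s not in fpm.columns]
    if missing:
        raise ValueError(f"control samples not in FPM matrix: {missing}")
    if len(control_samples) < 2:
        raise ValueError("need at least 2 control samples to estimate CV")
    sub = fpm[list(control_samples)]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    keep = mean >= float(min_mean_fpm)
    keep &= mean > 0
    cv = sd[keep] / mean[keep]
    return pd.DataFrame({"mean_fpm": mean[keep], "cv": cv})


def fc_threshold(cv_table: pd.DataFrame | pd.Series) -> CVStats:
    """Fold-change threshold = 3 x arithmetic mean of per-gene CVs."""
    cv = cv_table["cv"] if isinstance(cv_table, pd.DataFrame) else cv_table
    cv = cv.dropna()
    if len(cv) == 0:
        raise ValueError("empty CV table")
    mean_cv = float(cv.mean())
    return CVStats(per_gene_cv=cv, mean_cv=mean_cv, threshold_log2fc=3.0 * mean_cv)


def filter_deg(
    stats: pd.DataFrame,
    threshold: CVStats | float,
    fdr_cut: float = 0.05,
    fpm_cut: float = 3.0,
) -> pd.DataFrame:
    """Apply the triple DEG filter with a full audit trail.

    ``stats`` must be indexed by gene id with columns ``log2fc``,
    ``fdr_method1``, ``fdr_method2`` and one or more ``mean_fpm_<group>``
    columns.  Returns the input augmented with boolean columns
    ``passes_fdr``, ``passes_fpm``, ``passes_fc`` and ``is_deg``.
    """
    thr = threshold.threshold_log2fc if isinstance(threshold, CVStats) else float(threshold)
    required = {"log2fc", "fdr_method1", "fdr_method2"}
    missing = required - set(stats.columns)
    if missing:
        raise ValueError(f"stats table missing columns: {sorted(missing)}")
    mean_cols = [c for c in stats.columns if c.startswith("mean_fpm_")]
    if not mean_cols:
        raise ValueError("stats table has no mean_fpm_<group> columns")
    for col in ("fdr_method1", "fdr_method2"):
        vals = stats[col].to_numpy(dtype=float)
        ok = np.isnan(vals) | ((vals >= 0) & (vals <= 1))
        if not ok.all():
            raise ValueError(f"{col} outside [0, 1]")

    out = stats.copy()
    out["passes_fdr"] = (out["fdr_method1"] < fdr_cut) & (out["fdr_method2"] < fdr_cut)
    out["passes_fpm"] = (out[mean_cols] >= fpm_cut).any(axis=1)
    out["passes_fc"] = out["log2fc"].abs() >= thr
    # NaN statistics (e.g. no usable paired sets) can never pass
    out.loc[out["log2fc"].isna(), "passes_fc"] = False
    out.loc[out[["fdr_method1", "fdr_method2"]].isna().any(axis=1), "passes_fdr"] = False
    out["is_deg"] = out["passes_fdr"] & out["passes_fpm"] & out["passes_fc"]
    return out
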