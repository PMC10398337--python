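"""Normality-routed correlation of regional dALFF values with a clinical score.

Each region's values are first Shapiro-Wilk tested; non-normal regions are
correlated by Spearman rank, normal ones by Pearson.  Exactly one method is
populated per region (the other is reported as absent), mirroring the usual
clinical-correlation table layout.  No correction across regions is applied
by default, but a Bonferroni-adjusted column is emitted alongside.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["correlate_with_clinical", "report_to_csv"]

REPORT_COLUMNS = [
    "region",
    "normality_p",
    "method",
    "coefficient",
    "p_value",
    "pearson_p",
    "spearman_p",
    "p_bonferroni",
    "flag",
]


def correlate_with_clinical(
    region_values: pd.DataFrame,
    scores: np.ndarray | pd.Series,
    alpha_normality: float = 0.05,
) -> pd.DataFrame:
    """Correlate each region column with the clinical score.

    Parameters
    ----------
    region_values : DataFrame, subjects x regions.
    scores : clinical score per subject, aligned with the rows.
    alpha_normality : Shapiro-Wilk threshold; regions with normality
        p < alpha are routed to Spearman, others to Pearson.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if len(scores) != len(region_values):
        raise ValueError("scores must align with region_values rows")
    if len(scores) < 4:
        raise ValueError("need at least 4 paired observations")
    if not np.isfinite(scores).all():
        raise ValueError("scores contain non-finite values")
    rows = []
    n_regions = region_values.shape[1]
    for region in region_values.columns:
        values = region_values[region].to_numpy(dtype=np.float64)
        flag = ""
        if np.ptp(values) == 0 or np.ptp(scores) == 0:
            rows.append(
                {
                    "region": region,
                    "normality_p": np.nan,
                    "method": "none",
                    "coefficient": np.nan,
                    "p_value": np.nan,
                    "pearson_p": np.nan,
                    "spearman_p": np.nan,
                    "p_bonferroni": np.nan,
                    "flag": "constant input",
                }
            )
            continue
        normality_p = float(stats.shapiro(values).pvalue)
        if normality_p < alpha_normality:
            method = "spearman"
            r, p = stats.spearmanr(values, scores)
        else:
            method = "pearson"
            r, p = stats.pearsonr(values, scores)
        rows.append(
            {
                "region": region,
                "normality_p": normality_p,
                "method": method,
                "coefficient": float(r),
                "p_value": float(p),
                "pearson_p": float(p) if method == "pearson" else np.nan,
                "spearman_p": float(p) if method == "spearman" else np.nan,
                "p_bonferroni": float(min(1.0, p * n_regions)),
                "flag": flag,
            }
        )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def report_to_csv(report: pd.DataFrame, path: str | Path) -> None:
    """Write the report with an en dash for the unused method's cell."""
    out = report.copy()
    for col in ("pearson_p", "spearman_p"):
        out[col] = out[col].map(lambda v: "–" if pd.isna(v) else f"{v:.3f}")
    out.to_csv(path, index=False)
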