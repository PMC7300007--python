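"""Cohort-level association statistics for the checkpoint panel.

Operates on a wide cohort table with one row per sample and, per target
``t``, columns ``{t}_fmol_per_ug`` (protein abundance), ``{t}_status``
(detected / zero_assigned / not_detected) and ``{t}_mrna_rpm``; plus
``tps_percent`` and ``tmb_mut_per_mb``.

Conventions: missing (not-detected) abundances are dropped from
correlations but treated as 0 in exceedance and dual-high statistics; a
zero-assigned abundance is the value 0, not missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationResult",
    "pearson_r2",
    "detection_count",
    "coexpression_count",
    "exceedance_count",
    "dual_high_fraction",
    "correlation_report",
    "abundance_col",
    "status_col",
    "mrna_col",
]


def abundance_col(target: str) -> str:
    return f"{target}_fmol_per_ug"


def status_col(target: str) -> str:
    return f"{target}_status"


def mrna_col(target: str) -> str:
    return f"{target}_mrna_rpm"


@dataclass(frozen=True)
class CorrelationResult:
    """Squared Pearson correlation with its two-sided p-value."""

    r2: float
    p_value: float
    n_pairs: int
    r: float


def pearson_r2(x, y, log10: bool = False) -> CorrelationResult:
    """Squared Pearson correlation over pairwise-complete cases.

    Samples missing either value (NaN) are dropped; zeros are values, not
    missing.  With ``log10=True`` both variables are log10-transformed and
    non-positive pairs are dropped first.  The p-value is two-sided from
    the t distribution with n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    keep = ~(np.isnan(x) | np.isnan(y))
    if log10:
        keep &= (x > 0) & (y > 0)
    x, y = x[keep], y[keep]
    if log10:
        x, y = np.log10(x), np.log10(y)
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    return CorrelationResult(r2=r * r, p_value=float(res.pvalue), n_pairs=n, r=r)


def _require_target(table: pd.DataFrame, target: str) -> None:
    if abundance_col(target) not in table.columns:
        raise KeyError(f"unknown target: {target!r}")


def _abundance_as_zero(table: pd.DataFrame, target: str) -> np.ndarray:
    """Abundance vector with absent (NaN) treated as 0."""
    _require_target(table, target)
    return table[abundance_col(target)].fillna(0.0).to_numpy(float)


def detection_count(table: pd.DataFrame, target: str) -> int:
    """Number of samples in which *target* was detected (abundance > 0).

    Uses the status column when present (zero-assigned samples carry an
    abundance of 0 and do not count as detections); otherwise falls back to
    abundance > 0.
    """
    _require_target(table, target)
    col = status_col(target)
    if col in table.columns:
        return int((table[col] == "detected").sum())
    return int((table[abundance_col(target)].fillna(0.0) > 0).sum())


def coexpression_count(table: pd.DataFrame, target_a: str, target_b: str) -> int:
    """Samples in which both targets have abundance > 0."""
    a = _abundance_as_zero(table, target_a)
    b = _abundance_as_zero(table, target_b)
    return int(((a > 0) & (b > 0)).sum())


def exceedance_count(table: pd.DataFrame, target_a: str, target_b: str) -> int:
    """Samples in which abundance(A) strictly exceeds abundance(B).

    Absent values count as 0, so a sample where only A was detected counts.
    """
    a = _abundance_as_zero(table, target_a)
    b = _abundance_as_zero(table, target_b)
    return int((a > b).sum())


def dual_high_fraction(table: pd.DataFrame, target_a: str, target_b: str) -> float:
    """Fraction of samples with both targets strictly above their cohort mean.

    Cohort means are arithmetic means over all samples with absent-as-zero.
    """
    a = _abundance_as_zero(table, target_a)
    b = _abundance_as_zero(table, target_b)
    return float(((a > a.mean()) & (b > b.mean())).mean())


def cohort_from_quant(quant_long: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Join long-format protein quantification onto per-sample metadata.

    *quant_long* has ``sample_id, protein_id, fmol_per_ug, status`` rows (as
    written by the quantification stage); *metadata* has one row per sample.
    Returns a wide cohort table with ``{t}_fmol_per_ug`` and ``{t}_status``
    columns for every quantified protein, replacing any columns of the same
    name already present in the metadata.
    """
    wide_a = quant_long.pivot(
        index="sample_id", columns="protein_id", values="fmol_per_ug"
    )
    wide_s = quant_long.pivot(index="sample_id", columns="protein_id", values="status")
    wide = pd.concat(
        [wide_a.add_suffix("_fmol_per_ug"), wide_s.add_suffix("_status")], axis=1
    ).reset_index()
    drop = [c for c in wide.columns if c != "sample_id" and c in metadata.columns]
    return metadata.drop(columns=drop).merge(wide, on="sample_id", how="inner")


def correlation_report(
    table: pd.DataFrame,
    targets: list[str],
    against: str = "mrna",
    log10: bool = False,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Per-target protein correlation summary across the cohort.

    ``against`` selects the second variable: ``"mrna"`` (the target's own
    mRNA in RPM), ``"tps"`` (PD-L1 IHC tumor proportion score) or ``"tmb"``
    (mutations/Mb).  Targets with too few complete pairs or zero variance
    are reported with NaN statistics rather than raised.  ``bh_correct``
    adds a Benjamini-Hochberg q-value column (off by default; raw p-values
    are the primary report).
    """
    rows = []
    for t in targets:
        _require_target(table, t)
        x = table[abundance_col(t)].to_numpy(float)
        if against == "mrna":
            y = table[mrna_col(t)].to_numpy(float)
        elif against == "tps":
            y = table["tps_percent"].to_numpy(float)
        elif against == "tmb":
            y = table["tmb_mut_per_mb"].to_numpy(float)
        else:
            raise ValueError(f"unknown comparator: {against!r}")
        try:
            res = pearson_r2(x, y, log10=log10)
            rows.append((t, res.r2, res.p_value, res.n_pairs, detection_count(table, t)))
        except ValueError:
            rows.append((t, np.nan, np.nan, 0, detection_count(table, t)))
    out = pd.DataFrame(
        rows, columns=["target", "r2", "p_value", "n_pairs", "n_detected"]
    )
    if bh_correct:
        ok = out["p_value"].notna()
        q = np.full(len(out), np.nan)
        if ok.any():
            q[ok.to_numpy()] = multipletests(
                out.loc[ok, "p_value"], method="fdr_bh"
            )[1]
        out["q_value"] = q
    return out
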