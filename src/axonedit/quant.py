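"""Per-site editing levels, coverage filtering, and global summaries."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from axonedit.model import CompartmentDesign, SiteBaseCounts, ThresholdConfig

logger = logging.getLogger(__name__)

SITE_KEY = ["transcript_id", "position"]


def editing_level(counts: SiteBaseCounts) -> float:
    """Editing level of one site in one sample: G / (A + G).

    C and T calls are excluded from the denominator. Returns NaN when no
    A or G calls were retained.
    """
    denom = counts.a_count + counts.g_count
    if denom == 0:
        return float("nan")
    return counts.g_count / denom


def add_level_columns(counts: pd.DataFrame) -> pd.DataFrame:
    """Append ``ag_coverage``, ``coverage`` and ``level`` columns."""
    out = counts.copy()
    out["coverage"] = (
        out["a_count"] + out["c_count"] + out["g_count"] + out["t_count"]
    )
    out["ag_coverage"] = out["a_count"] + out["g_count"]
    with np.errstate(invalid="ignore", divide="ignore"):
        out["level"] = np.where(
            out["ag_coverage"] > 0, out["g_count"] / out["ag_coverage"], np.nan
        )
    return out


def coverage_filter(
    counts: pd.DataFrame,
    design: CompartmentDesign,
    thresholds: ThresholdConfig | None = None,
) -> pd.DataFrame:
    """Sites whose total depth is >= min_coverage in every design sample.

    A site missing a row for some design sample is treated as coverage 0
    there (and therefore dropped when ``min_coverage > 0``), with a logged
    warning. Returns a DataFrame with the retained (transcript_id,
    position) pairs.
    """
    thresholds = thresholds or ThresholdConfig()
    samples = list(design.all_samples)
    sub = counts[counts["sample_id"].isin(samples)]
    cov = (
        sub.assign(
            coverage=sub["a_count"] + sub["c_count"] + sub["g_count"] + sub["t_count"]
        )
        .pivot_table(
            index=SITE_KEY, columns="sample_id", values="coverage", fill_value=np.nan
        )
        .reindex(columns=samples)
    )
    n_missing = int(cov.isna().sum().sum())
    if n_missing:
        logger.warning(
            "%d site/sample cells missing from the count table; treated as coverage 0",
            n_missing,
        )
        cov = cov.fillna(0)
    keep = (cov >= thresholds.min_coverage).all(axis=1)
    return cov.index[keep].to_frame(index=False)


def mean_editing(levels: pd.Series | np.ndarray) -> float:
    """Unweighted arithmetic mean of per-site editing levels."""
    arr = np.asarray(levels, dtype=float)
    if arr.size == 0:
        raise ValueError("mean_editing over an empty site set")
    if np.isnan(arr).any():
        raise ValueError("mean_editing requires non-missing levels")
    return float(arr.mean())


def editing_index(g_counts: pd.Series | np.ndarray, ag_coverages: pd.Series | np.ndarray) -> float:
    """Coverage-weighted average editing: sum(G) / sum(A + G).

    This weights per-site levels by their A+G coverage, the conventional
    reading of a 'weighted average of editing levels over all sites'.
    """
    g = np.asarray(g_counts, dtype=float)
    ag = np.asarray(ag_coverages, dtype=float)
    total = ag.sum()
    if total == 0:
        raise ValueError("editing_index with zero total A+G coverage")
    return float(g.sum() / total)


def per_sample_levels(counts: pd.DataFrame, retained_sites: pd.DataFrame) -> pd.DataFrame:
    """Per-sample per-site level table restricted to retained sites."""
    with_levels = add_level_columns(counts)
    merged = with_levels.merge(retained_sites, on=SITE_KEY, how="inner")
    return merged[SITE_KEY + ["sample_id", "g_count", "ag_coverage", "coverage", "level"]]


def per_sample_summary(levels: pd.DataFrame) -> pd.DataFrame:
    """Mean editing and editing index per sample over the retained sites.

    Sites with missing level (zero A+G depth) are dropped per sample with
    a warning; this cannot happen post-filter unless depth is entirely
    C/T calls.
    """
    rows = []
    for sample_id, grp in levels.groupby("sample_id", sort=True):
        ok = grp["ag_coverage"] > 0
        if (~ok).any():
            logger.warning(
                "sample %s: %d retained sites have zero A+G depth; dropped",
                sample_id,
                int((~ok).sum()),
            )
            grp = grp[ok]
        rows.append(
            {
                "sample_id": sample_id,
                "n_sites": len(grp),
                "mean_editing": mean_editing(grp["level"]),
                "editing_index": editing_index(grp["g_count"], grp["ag_coverage"]),
            }
        )
    return pd.DataFrame(rows)
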