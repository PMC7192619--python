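"""Site-by-site differential editing between two compartments.

For every tested site, a two-sample t statistic is computed once and
converted into the two one-tailed p-values (A > B and B > A). Each
one-tailed p-vector is Benjamini-Hochberg adjusted separately and a site
is called in a direction when its adjusted value is <= the FDR level.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from axonedit.model import CompartmentDesign, ThresholdConfig, ValidationError
from axonedit.quant import SITE_KEY, add_level_columns, coverage_filter

CALL_A_HIGHER = "A_higher"
CALL_B_HIGHER = "B_higher"
CALL_NO_CHANGE = "no_change"


def welch_one_tailed(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Welch t-test tail probabilities, row-wise.

    ``a`` and ``b`` are (n_sites, n_replicates) matrices. Returns
    ``(p_a_greater, p_b_greater)``, the upper- and lower-tail
    probabilities of the same statistic with Welch-Satterthwaite degrees
    of freedom.

    Degenerate rows (both groups constant) get p = (0.5, 0.5) when the
    means are equal, else (0, 1) in the favored direction — the
    continuity limit of the test.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    ra, rb = a.shape[1], b.shape[1]
    if ra < 2 or rb < 2:
        raise ValidationError("need >= 2 replicates per group")
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    se2 = va / ra + vb / rb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / ((va / ra) ** 2 / (ra - 1) + (vb / rb) ** 2 / (rb - 1))
    p_a = np.where(np.isfinite(t), stats.t.sf(t, df), np.nan)
    p_b = np.where(np.isfinite(t), stats.t.cdf(t, df), np.nan)
    degenerate = se2 == 0
    if degenerate.any():
        eq = degenerate & (ma == mb)
        gt = degenerate & (ma > mb)
        lt = degenerate & (ma < mb)
        p_a = np.where(eq, 0.5, p_a)
        p_b = np.where(eq, 0.5, p_b)
        p_a = np.where(gt, 0.0, p_a)
        p_b = np.where(gt, 1.0, p_b)
        p_a = np.where(lt, 1.0, p_a)
        p_b = np.where(lt, 0.0, p_b)
    return p_a, p_b


def paired_one_tailed(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized paired (one-sample on differences) t-test tails.

    Columns of ``a`` and ``b`` must correspond to the same animal.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape != b.shape:
        raise ValidationError("paired test needs equal replicate counts")
    n = a.shape[1]
    if n < 2:
        raise ValidationError("need >= 2 pairs")
    d = a - b
    md = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = md / (sd / np.sqrt(n))
    df = n - 1
    p_a = np.where(np.isfinite(t), stats.t.sf(t, df), np.nan)
    p_b = np.where(np.isfinite(t), stats.t.cdf(t, df), np.nan)
    degenerate = sd == 0
    if degenerate.any():
        p_a = np.where(degenerate & (md == 0), 0.5, p_a)
        p_b = np.where(degenerate & (md == 0), 0.5, p_b)
        p_a = np.where(degenerate & (md > 0), 0.0, p_a)
        p_b = np.where(degenerate & (md > 0), 1.0, p_b)
        p_a = np.where(degenerate & (md < 0), 1.0, p_a)
        p_b = np.where(degenerate & (md < 0), 0.0, p_b)
    return p_a, p_b


def one_tailed_t_pair(
    levels_a, levels_b, paired: bool = False
) -> tuple[float, float]:
    """Two one-tailed p-values for a single site (scalar convenience)."""
    fn = paired_one_tailed if paired else welch_one_tailed
    p_a, p_b = fn(np.asarray(levels_a)[None, :], np.asarray(levels_b)[None, :])
    return float(p_a[0]), float(p_b[0])


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Returns adjusted values in the input order: q_i = min over j with
    p_(j) >= p_(i) of p_(j) * m / j, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D p-value vector")
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must be in [0,1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def call_sites(results: pd.DataFrame, thresholds: ThresholdConfig | None = None) -> pd.DataFrame:
    """Adjust the two one-tailed p-vectors separately and call each site.

    ``results`` must carry ``p_a_greater`` and ``p_b_greater`` columns.
    Adds ``q_a_greater``, ``q_b_greater`` and ``call``. A site is
    ``A_higher`` iff q_a_greater <= fdr_level (and symmetrically); with
    complementary one-tailed p-values and fdr_level < 0.5 the two calls
    cannot fire together, which is asserted.
    """
    thresholds = thresholds or ThresholdConfig()
    out = results.copy()
    out["q_a_greater"] = bh_adjust(out["p_a_greater"].to_numpy())
    out["q_b_greater"] = bh_adjust(out["p_b_greater"].to_numpy())
    a_sig = out["q_a_greater"] <= thresholds.fdr_level
    b_sig = out["q_b_greater"] <= thresholds.fdr_level
    if (a_sig & b_sig).any():
        raise RuntimeError("a site was called in both directions; inconsistent p-values")
    out["call"] = np.select(
        [a_sig, b_sig], [CALL_A_HIGHER, CALL_B_HIGHER], default=CALL_NO_CHANGE
    )
    return out


def differential_test(
    counts: pd.DataFrame,
    design: CompartmentDesign,
    thresholds: ThresholdConfig | None = None,
    paired: bool = False,
) -> pd.DataFrame:
    """Full per-site differential analysis on a count table.

    Applies the coverage filter, computes replicate editing levels,
    runs the directional tests, adjusts per tail and calls each site.
    Sites with a missing level in any sample are dropped.
    """
    thresholds = thresholds or ThresholdConfig()
    retained = coverage_filter(counts, design, thresholds)
    levels = add_level_columns(counts).merge(retained, on=SITE_KEY, how="inner")
    wide = levels.pivot_table(index=SITE_KEY, columns="sample_id", values="level")
    a_ids = list(design.compartment_a_samples)
    b_ids = list(design.compartment_b_samples)
    missing_cols = [s for s in a_ids + b_ids if s not in wide.columns]
    if missing_cols:
        raise ValidationError(f"samples absent from count table: {missing_cols}")
    if paired:
        if design.pairing is None:
            raise ValidationError("paired test requires a pairing in the design")
        b_ids = [design.pairing[s] for s in a_ids]
    wide = wide.dropna()
    a = wide[a_ids].to_numpy()
    b = wide[b_ids].to_numpy()
    test = paired_one_tailed if paired else welch_one_tailed
    p_a, p_b = test(a, b)
    res = wide.index.to_frame(index=False)
    res["mean_a"] = a.mean(axis=1)
    res["mean_b"] = b.mean(axis=1)
    res["delta"] = res["mean_a"] - res["mean_b"]
    res["p_a_greater"] = p_a
    res["p_b_greater"] = p_b
    return call_sites(res, thresholds)


def summarize_differential(
    results: pd.DataFrame, histogram_bins: np.ndarray | None = None
) -> dict:
    """Global summary of the per-site calls (call counts, raw direction,
    delta histogram)."""
    if len(results) == 0:
        raise ValueError("no tested sites to summarize")
    if histogram_bins is None:
        histogram_bins = np.round(np.arange(-1.0, 1.0 + 1e-9, 0.05), 10)
    calls = results["call"].value_counts()
    delta = results["delta"].to_numpy()
    hist, edges = np.histogram(delta, bins=histogram_bins)
    n = len(results)
    n_raw_a = int((delta > 0).sum())
    summary = {
        "n_sites_tested": n,
        "n_a_higher_significant": int(calls.get(CALL_A_HIGHER, 0)),
        "n_b_higher_significant": int(calls.get(CALL_B_HIGHER, 0)),
        "n_no_change": int(calls.get(CALL_NO_CHANGE, 0)),
        "n_a_higher_raw": n_raw_a,
        "n_b_higher_raw": int((delta < 0).sum()),
        "n_ties_raw": int((delta == 0).sum()),
        "fraction_a_higher_raw": n_raw_a / n,
        "delta_histogram": {
            "bin_edges": [float(e) for e in edges],
            "counts": [int(c) for c in hist],
        },
    }
    assert (
        summary["n_a_higher_significant"]
        + summary["n_b_higher_significant"]
        + summary["n_no_change"]
        == n
    )
    return summary
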