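"""Amplicon editing-event detection against a sequencing-error null.

Each adenosine position in one replicate ("dataset") is tested with an
exact binomial upper tail at the assumed per-base error rate; the
Benjamini-Hochberg correction is applied across all positions within the
replicate and an event is real when the adjusted p-value is strictly
below the cut-off. Replicates are then averaged per group and each
position is reported with mean +/- SEM editing percentage and the fold
over control.

Two combination rules are exposed and reported side by side: a
per-replicate majority rule (edited in >= k experimental replicates) and
the fold-on-means reporting rule (mean_exp > min_fold * mean_ctl).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from axonedit.model import EditingSite, ThresholdConfig, ValidationError


def binomial_error_p(g_count: int, ag_coverage: int, p0: float) -> float:
    """Upper-tail P(X >= g_count) for X ~ Binomial(ag_coverage, p0).

    Exact survival-function evaluation; no normal approximation.
    """
    if not 0 <= g_count <= ag_coverage:
        raise ValidationError(
            f"need 0 <= g_count <= ag_coverage, got {g_count}/{ag_coverage}"
        )
    if not 0.0 < p0 < 1.0:
        raise ValidationError(f"p0 must be in (0,1), got {p0}")
    # sf(k) = P(X > k), so P(X >= g) = sf(g - 1)
    return float(stats.binom.sf(g_count - 1, ag_coverage, p0))


def detect_in_dataset(
    observations: pd.DataFrame, thresholds: ThresholdConfig | None = None
) -> pd.DataFrame:
    """Per-position binomial p, BH-adjusted p and edited flag for one replicate.

    ``observations`` needs columns ``position``, ``g_count`` and either
    ``ag_coverage`` or ``a_count``. BH runs across all positions of this
    dataset; edited iff adjusted p < detection_adjusted_p (strict).
    """
    from axonedit.differential import bh_adjust

    thresholds = thresholds or ThresholdConfig()
    obs = observations.copy()
    if "ag_coverage" not in obs.columns:
        obs["ag_coverage"] = obs["a_count"] + obs["g_count"]
    if obs["position"].duplicated().any():
        dup = obs.loc[obs["position"].duplicated(), "position"].iloc[0]
        raise ValidationError(f"duplicate position {dup} in dataset")
    g = obs["g_count"].to_numpy()
    n = obs["ag_coverage"].to_numpy()
    if ((g < 0) | (g > n)).any():
        raise ValidationError("g_count outside [0, ag_coverage]")
    p = stats.binom.sf(g - 1, n, thresholds.error_rate_p0)
    q = bh_adjust(p)
    out = obs[["position", "g_count", "ag_coverage"]].copy()
    out["p_value"] = p
    out["q_value"] = q
    out["edited"] = q < thresholds.detection_adjusted_p
    return out


def _percent(df: pd.DataFrame) -> np.ndarray:
    ag = df["ag_coverage"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(ag > 0, 100.0 * df["g_count"].to_numpy() / ag, np.nan)


def summarize_replicates(
    experimental: dict[str, pd.DataFrame],
    control: dict[str, pd.DataFrame],
    thresholds: ThresholdConfig | None = None,
    min_replicates_detected: int = 3,
    min_fold: float = 2.0,
) -> pd.DataFrame:
    """Average replicate groups per position and combine per-replicate calls.

    Editing percentages per replicate are 100*G/(A+G); means and SEMs
    (sample SD over sqrt(n)) are computed per group. Two detected flags
    are emitted: ``detected_by_replicates`` (edited in >=
    ``min_replicates_detected`` experimental replicates) and
    ``detected_by_fold`` (mean_exp strictly > min_fold * mean_ctl, the
    reporting rule used for the printed site partition).
    """
    thresholds = thresholds or ThresholdConfig()
    if not experimental or not control:
        raise ValidationError("need at least one replicate per group")

    ref_positions = None
    per_rep: dict[str, pd.DataFrame] = {}
    for name, df in list(experimental.items()) + list(control.items()):
        det = detect_in_dataset(df, thresholds).sort_values("position")
        if ref_positions is None:
            ref_positions = det["position"].to_numpy()
        elif not np.array_equal(det["position"].to_numpy(), ref_positions):
            raise ValidationError(f"replicate {name} has a different position set")
        per_rep[name] = det

    def _group(names: list[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        pct = np.column_stack([_percent(per_rep[n]) for n in names])
        mean = pct.mean(axis=1)
        n = pct.shape[1]
        sem = pct.std(axis=1, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(len(pct))
        n_edited = np.column_stack(
            [per_rep[n]["edited"].to_numpy() for n in names]
        ).sum(axis=1)
        return mean, sem, n_edited

    mean_exp, sem_exp, n_edited_exp = _group(list(experimental))
    mean_ctl, sem_ctl, n_edited_ctl = _group(list(control))

    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(mean_ctl > 0, mean_exp / mean_ctl, np.nan)

    return pd.DataFrame(
        {
            "position": ref_positions,
            "mean_exp": mean_exp,
            "sem_exp": sem_exp,
            "mean_ctl": mean_ctl,
            "sem_ctl": sem_ctl,
            "n_edited_exp_replicates": n_edited_exp,
            "n_edited_ctl_replicates": n_edited_ctl,
            "fold_vs_control": fold,
            "detected_by_replicates": n_edited_exp >= min_replicates_detected,
            "detected_by_fold": flag_by_fold(mean_exp, mean_ctl, min_fold),
        }
    )


def flag_by_fold(mean_exp, mean_ctl, min_fold: float = 2.0) -> np.ndarray:
    """Reporting rule: experimental mean strictly exceeds min_fold x control.

    Positions where both means are zero are never flagged; a zero control
    mean with a positive experimental mean is flagged (infinite fold).
    """
    mean_exp = np.asarray(mean_exp, dtype=float)
    mean_ctl = np.asarray(mean_ctl, dtype=float)
    return mean_exp > min_fold * mean_ctl


def table1_report(
    results: pd.DataFrame,
    sites: list[EditingSite] | None = None,
    detected_column: str = "detected_by_fold",
) -> pd.DataFrame:
    """Merge detection results with the known-site list, ordered by position.

    ``sites`` positions carry the in vivo editing level; result positions
    absent from the site list are kept and flagged ``putative_novel``.
    """
    out = results.copy().sort_values("position").reset_index(drop=True)
    out["detected"] = out[detected_column]
    # the site list owns these columns in the merged report
    out = out.drop(columns=["in_vivo_percent", "putative_novel"], errors="ignore")
    if sites is not None:
        site_df = pd.DataFrame(
            {
                "position": [s.position for s in sites],
                "in_vivo_percent": [
                    np.nan if s.in_vivo_level is None else 100.0 * s.in_vivo_level
                    for s in sites
                ],
            }
        )
        out = out.merge(site_df, on="position", how="left")
        out["putative_novel"] = ~out["position"].isin(site_df["position"])
    cols = ["position"]
    if sites is not None:
        cols.append("in_vivo_percent")
    cols += [
        "mean_ctl",
        "sem_ctl",
        "mean_exp",
        "sem_exp",
        "fold_vs_control",
        "detected",
    ]
    if sites is not None:
        cols.append("putative_novel")
    extra = [c for c in out.columns if c not in cols]
    return out[cols + extra]
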