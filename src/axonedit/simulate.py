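"""Synthetic count data with the statistical structure the analyses assume.

Two generators are provided: paired-compartment RNA-seq-like counts
(negative-binomial coverage, optional beta overdispersion of replicate
editing levels, 0.1% base-call error floor) and amplicon assay counts
(fixed coverage per replicate, error-only controls). Both emit the same
tabular shapes the readers in :mod:`axonedit.io` accept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from axonedit.io import COUNT_COLUMNS
from axonedit.model import CompartmentDesign, EditingSite, ValidationError


@dataclass
class CompartmentSimSpec:
    """Parameters for simulating paired two-compartment count tables.

    Per-site true levels may be given explicitly (``true_level_a`` /
    ``true_level_b`` arrays of length ``n_sites``) or generated from a
    rule: ``frac_a_higher`` of sites get ``level_a = base + delta`` and
    the rest ``level_b = base + delta``, with ``delta`` drawn uniformly
    from ``delta_range`` and base levels uniform on ``base_level_range``.
    ``overdispersion_rho`` is the beta intra-class correlation of realized
    replicate levels around the true level (0 = binomial sampling only).
    """

    n_sites: int
    n_pairs: int = 4
    true_level_a: np.ndarray | None = None
    true_level_b: np.ndarray | None = None
    frac_a_higher: float = 0.92
    delta_range: tuple[float, float] = (0.05, 0.3)
    base_level_range: tuple[float, float] = (0.0, 0.6)
    coverage_mean: float = 100.0
    coverage_dispersion: float = 5.0
    error_rate: float = 0.001
    overdispersion_rho: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1 or self.n_pairs < 1:
            raise ValidationError("n_sites and n_pairs must be >= 1")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValidationError("error_rate must be in [0,1)")
        if not 0.0 <= self.overdispersion_rho < 1.0:
            raise ValidationError("overdispersion_rho must be in [0,1)")
        if self.coverage_mean <= 0 or self.coverage_dispersion <= 0:
            raise ValidationError("coverage_mean and coverage_dispersion must be > 0")
        if not 0.0 <= self.frac_a_higher <= 1.0:
            raise ValidationError("frac_a_higher must be in [0,1]")
        for arr_name in ("true_level_a", "true_level_b"):
            arr = getattr(self, arr_name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != (self.n_sites,):
                    raise ValidationError(f"{arr_name} must have length n_sites")
                if ((arr < 0) | (arr > 1)).any():
                    raise ValidationError(f"{arr_name} values must be in [0,1]")
                setattr(self, arr_name, arr)


@dataclass
class AssaySimSpec:
    """Parameters for simulating per-replicate amplicon adenosine counts."""

    n_adenosines: int = 126
    edited_positions: dict[int, float] = field(default_factory=dict)
    n_experimental: int = 5
    n_control: int = 5
    coverage_per_replicate: int = 100_000
    error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_adenosines < 1:
            raise ValidationError("n_adenosines must be >= 1")
        if self.n_experimental < 0 or self.n_control < 0:
            raise ValidationError("replicate counts must be >= 0")
        if self.coverage_per_replicate < 1:
            raise ValidationError("coverage_per_replicate must be >= 1")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValidationError("error_rate must be in [0,1)")
        for pos, lvl in self.edited_positions.items():
            if not 1 <= pos <= self.n_adenosines:
                raise ValidationError(f"edited position {pos} outside 1..{self.n_adenosines}")
            if not 0.0 <= lvl <= 1.0:
                raise ValidationError(f"editing fraction at {pos} must be in [0,1]")


def _nb_coverage(rng: np.random.Generator, mean: float, dispersion: float, size) -> np.ndarray:
    """Negative-binomial coverage (mean/dispersion parameterization), floor 1."""
    p = dispersion / (dispersion + mean)
    cov = rng.negative_binomial(dispersion, p, size=size)
    return np.maximum(cov, 1)


def _realized_levels(
    rng: np.random.Generator, true_level: np.ndarray, rho: float, n_rep: int
) -> np.ndarray:
    """Per-replicate realized editing levels, beta around the true level.

    With intra-class correlation ``rho``, the beta concentration is
    ``1/rho - 1``; rho == 0 (or a degenerate true level of exactly 0 or 1)
    yields the true level at every replicate.
    """
    levels = np.broadcast_to(true_level[:, None], (true_level.size, n_rep)).copy()
    if rho > 0:
        kappa = 1.0 / rho - 1.0
        inner = (true_level > 0) & (true_level < 1)
        if inner.any():
            alpha = true_level[inner] * kappa
            beta = (1.0 - true_level[inner]) * kappa
            levels[inner] = rng.beta(alpha[:, None], beta[:, None], size=(inner.sum(), n_rep))
    return levels


def _observed_g_prob(level: np.ndarray, error_rate: float) -> np.ndarray:
    # A true edited base always reads G absent error; an unedited A reads G
    # with the error probability; an edited base misread drops back to A.
    return level * (1.0 - error_rate) + (1.0 - level) * error_rate


def simulate_compartment_counts(
    spec: CompartmentSimSpec,
) -> tuple[list[EditingSite], pd.DataFrame, CompartmentDesign, pd.DataFrame]:
    """Simulate paired two-compartment count tables.

    Returns ``(sites, counts, design, truth)`` where ``counts`` has the
    standard count-table columns (only A and G calls are emitted) and
    ``truth`` records per-site true levels in both compartments.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_sites

    level_a = spec.true_level_a
    level_b = spec.true_level_b
    if level_a is None or level_b is None:
        base = rng.uniform(*spec.base_level_range, size=n)
        delta = rng.uniform(*spec.delta_range, size=n)
        a_higher = rng.random(n) < spec.frac_a_higher
        level_a = np.where(a_higher, base + delta, base)
        level_b = np.where(a_higher, base, base + delta)
        level_a = np.clip(level_a, 0.0, 1.0)
        level_b = np.clip(level_b, 0.0, 1.0)

    sites = [EditingSite(f"tx{i // 100 + 1:04d}", i % 100 + 1) for i in range(n)]
    a_ids = [f"GA_{k + 1}" for k in range(spec.n_pairs)]
    b_ids = [f"GFL_{k + 1}" for k in range(spec.n_pairs)]
    design = CompartmentDesign(
        tuple(a_ids), tuple(b_ids), dict(zip(a_ids, b_ids))
    )

    frames = []
    for level, ids in ((level_a, a_ids), (level_b, b_ids)):
        realized = _realized_levels(rng, level, spec.overdispersion_rho, len(ids))
        coverage = _nb_coverage(
            rng, spec.coverage_mean, spec.coverage_dispersion, (n, len(ids))
        )
        g = rng.binomial(coverage, _observed_g_prob(realized, spec.error_rate))
        for j, sid in enumerate(ids):
            frames.append(
                pd.DataFrame(
                    {
                        "transcript_id": [s.transcript_id for s in sites],
                        "position": [s.position for s in sites],
                        "sample_id": sid,
                        "a_count": coverage[:, j] - g[:, j],
                        "c_count": 0,
                        "g_count": g[:, j],
                        "t_count": 0,
                    }
                )
            )
    counts = pd.concat(frames, ignore_index=True)[COUNT_COLUMNS]
    truth = pd.DataFrame(
        {
            "transcript_id": [s.transcript_id for s in sites],
            "position": [s.position for s in sites],
            "true_level_a": level_a,
            "true_level_b": level_b,
        }
    )
    return sites, counts, design, truth


def simulate_assay_counts(
    spec: AssaySimSpec,
) -> tuple[dict[str, pd.DataFrame], dict[str, pd.DataFrame], pd.DataFrame]:
    """Simulate amplicon assay replicates.

    Returns ``(experimental, control, truth)``; the first two map
    replicate id to a DataFrame with columns ``position, a_count,
    g_count``. Control replicates are error-only (true level 0
    everywhere).
    """
    rng = np.random.default_rng(spec.seed)
    positions = np.arange(1, spec.n_adenosines + 1)
    true_level = np.zeros(spec.n_adenosines)
    for pos, lvl in spec.edited_positions.items():
        true_level[pos - 1] = lvl

    def _replicates(n_rep: int, level: np.ndarray, prefix: str) -> dict[str, pd.DataFrame]:
        out: dict[str, pd.DataFrame] = {}
        p_g = _observed_g_prob(level, spec.error_rate)
        for k in range(n_rep):
            g = rng.binomial(spec.coverage_per_replicate, p_g)
            out[f"{prefix}_{k + 1}"] = pd.DataFrame(
                {
                    "position": positions,
                    "a_count": spec.coverage_per_replicate - g,
                    "g_count": g,
                }
            )
        return out

    experimental = _replicates(spec.n_experimental, true_level, "axoplasm")
    control = _replicates(
        spec.n_control, np.zeros(spec.n_adenosines), "control"
    )
    truth = pd.DataFrame({"position": positions, "true_level": true_level})
    return experimental, control, truth
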