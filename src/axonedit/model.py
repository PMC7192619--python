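"""Core domain types shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass


class ValidationError(ValueError):
    """Raised when an input value violates a documented invariant."""


@dataclass(frozen=True)
class EditingSite:
    """A known editable adenosine on a transcript or amplicon sense strand.

    Coordinates are 1-based and inclusive. ``in_vivo_level``, when present,
    is the previously reported editing fraction at this site (0..1).
    """

    transcript_id: str
    position: int
    ref_base: str = "A"
    in_vivo_level: float | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(
                f"position must be >= 1, got {self.position} "
                f"({self.transcript_id})"
            )
        if self.ref_base != "A":
            raise ValidationError(
                f"ref_base must be 'A', got {self.ref_base!r} at "
                f"{self.transcript_id}:{self.position}"
            )
        if self.in_vivo_level is not None and not 0.0 <= self.in_vivo_level <= 1.0:
            raise ValidationError(
                f"in_vivo_level must be in [0,1], got {self.in_vivo_level} at "
                f"{self.transcript_id}:{self.position}"
            )

    @property
    def key(self) -> tuple[str, int]:
        return (self.transcript_id, self.position)


@dataclass(frozen=True)
class SiteBaseCounts:
    """Quality-filtered base-call counts at one site in one sample."""

    transcript_id: str
    position: int
    sample_id: str
    a_count: int
    c_count: int
    g_count: int
    t_count: int

    def __post_init__(self) -> None:
        for base in "acgt":
            n = getattr(self, f"{base}_count")
            if n < 0:
                raise ValidationError(
                    f"{base}_count must be >= 0, got {n} at "
                    f"{self.transcript_id}:{self.position} ({self.sample_id})"
                )

    @property
    def coverage(self) -> int:
        """Total retained base calls (all four bases)."""
        return self.a_count + self.c_count + self.g_count + self.t_count

    @property
    def ag_coverage(self) -> int:
        return self.a_count + self.g_count


@dataclass(frozen=True)
class QualityFilterConfig:
    """Base- and mapping-quality cut-offs used when counts are produced.

    ``min_mapping_quality`` applies only when counts are derived upstream
    from alignments; it is carried here for provenance.
    """

    min_base_quality: int = 30
    min_mapping_quality: int = 40

    def __post_init__(self) -> None:
        if self.min_base_quality < 0 or self.min_mapping_quality < 0:
            raise ValidationError("quality thresholds must be >= 0")


@dataclass(frozen=True)
class CompartmentDesign:
    """Assignment of sample ids to the two compared compartments.

    ``pairing`` optionally maps each compartment-A sample to its paired
    compartment-B sample (same animal of origin) and must be a bijection.
    """

    compartment_a_samples: tuple[str, ...]
    compartment_b_samples: tuple[str, ...]
    pairing: dict[str, str] | None = None

    def __post_init__(self) -> None:
        a = tuple(self.compartment_a_samples)
        b = tuple(self.compartment_b_samples)
        object.__setattr__(self, "compartment_a_samples", a)
        object.__setattr__(self, "compartment_b_samples", b)
        if not a or not b:
            raise ValidationError("both compartments need at least one sample")
        if len(set(a)) != len(a) or len(set(b)) != len(b):
            raise ValidationError("duplicate sample ids within a compartment")
        if set(a) & set(b):
            raise ValidationError("compartment sample lists must be disjoint")
        if self.pairing is not None:
            if set(self.pairing) != set(a) or set(self.pairing.values()) != set(b):
                raise ValidationError(
                    "pairing must be a bijection between the two sample lists"
                )

    @property
    def all_samples(self) -> tuple[str, ...]:
        return self.compartment_a_samples + self.compartment_b_samples


@dataclass(frozen=True)
class ThresholdConfig:
    """Analysis thresholds; defaults follow the published workflow."""

    min_coverage: int = 20
    fdr_level: float = 0.1
    error_rate_p0: float = 0.001
    detection_adjusted_p: float = 0.001

    def __post_init__(self) -> None:
        if self.min_coverage < 0:
            raise ValidationError("min_coverage must be >= 0")
        for name in ("fdr_level", "error_rate_p0", "detection_adjusted_p"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name} must be in (0,1), got {v}")
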