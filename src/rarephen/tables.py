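"""Core containers for rare-event categorical phenotyping data.

The unit of analysis is one wild-type-vs-knockout comparison on one binary
trait, held as a pair of per-sex 2x2 tables (knockout vs wild-type, abnormal
vs as-expected).  All tests downstream are functions of these counts only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional


class ValidationError(ValueError):
    """Raised when counts or records are internally inconsistent."""


@dataclass(frozen=True)
class TwoByTwo:
    """Event/trial counts for two groups on one trait.

    Group *a* is the knockout (or, for knockout-only sex comparisons, the
    first sex); group *b* is the wild-type (or second sex).
    """

    events_a: int
    total_a: int
    events_b: int
    total_b: int

    def __post_init__(self) -> None:
        for name in ("events_a", "total_a", "events_b", "total_b"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                object.__setattr__(self, name, int(v))
                v = getattr(self, name)
            if v < 0:
                raise ValidationError(f"{name} must be non-negative, got {v}")
        if self.events_a > self.total_a:
            raise ValidationError(
                f"events_a ({self.events_a}) exceeds total_a ({self.total_a})"
            )
        if self.events_b > self.total_b:
            raise ValidationError(
                f"events_b ({self.events_b}) exceeds total_b ({self.total_b})"
            )

    @property
    def total_events(self) -> int:
        return self.events_a + self.events_b

    @property
    def total(self) -> int:
        return self.total_a + self.total_b

    def rate_a(self) -> float:
        return self.events_a / self.total_a if self.total_a else float("nan")

    def rate_b(self) -> float:
        return self.events_b / self.total_b if self.total_b else float("nan")


@dataclass(frozen=True)
class SexStratifiedCounts:
    """The 2x2x2 table (sex x group x outcome) for one data set on one trait.

    Within each sex stratum, group a = knockout, group b = wild-type.
    """

    male: TwoByTwo
    female: TwoByTwo
    line_id: str = ""
    zygosity: str = ""
    trait_id: str = ""

    def __post_init__(self) -> None:
        if self.male.total == 0 and self.female.total == 0:
            raise ValidationError("at least one sex stratum must have animals")

    @property
    def dataset_id(self) -> str:
        return f"{self.line_id}:{self.zygosity}:{self.trait_id}"

    @property
    def family_id(self) -> str:
        """Family for within-family FDR control: gene x zygosity."""
        return f"{self.line_id}:{self.zygosity}"

    def knockout_table(self) -> TwoByTwo:
        """Knockout-only sex comparison: group a = male KO, group b = female KO."""
        return TwoByTwo(
            events_a=self.male.events_a,
            total_a=self.male.total_a,
            events_b=self.female.events_a,
            total_b=self.female.total_a,
        )

    def swap_sexes(self) -> "SexStratifiedCounts":
        return SexStratifiedCounts(
            male=self.female,
            female=self.male,
            line_id=self.line_id,
            zygosity=self.zygosity,
            trait_id=self.trait_id,
        )


@dataclass
class TestResult:
    """Outcome of one hypothesis test."""

    method: str
    p_value: float
    statistic: Optional[float] = None
    df: Optional[int] = None
    converged: bool = True
    warnings: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            # p-values of discrete/penalized tests are strictly positive
            raise ValidationError(
                f"p_value must lie in (0, 1], got {self.p_value!r}"
            )


@dataclass(frozen=True)
class EffectEstimate:
    """Difference in abnormality proportions with confidence bounds."""

    estimate: float
    lower: float
    upper: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if not (self.lower - 1e-12 <= self.estimate <= self.upper + 1e-12):
            raise ValidationError(
                f"estimate {self.estimate} outside [{self.lower}, {self.upper}]"
            )
        if self.lower < -1 - 1e-12 or self.upper > 1 + 1e-12:
            raise ValidationError("bounds must lie within [-1, 1]")
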