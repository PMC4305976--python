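"""Judgment quality gates.

Crowd work needs validity controls proving the contributor at least
attempted the task. Two gates are applied to every judgment: a minimum
number of counted cells (sum of positive and negative clicks), and at
least one click in the lower part of the vertically scrolled image —
evidence that the contributor traversed the whole canvas.

Both boundary comparisons are inclusive (>=): a stated minimum
conventionally admits equality. The experiment's actual threshold and
lower-region boundary are not published; the defaults (20 cells, bottom
half) are documented assumptions, exposed through :class:`GateConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import Canvas, Judgment

MIN_COUNT_GATE = "min_count"
LOWER_REGION_GATE = "lower_region"


@dataclass(frozen=True)
class GateConfig:
    min_total_cells: int = 20
    lower_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.min_total_cells < 1:
            raise ValueError("min_total_cells must be >= 1")
        if not 0.0 < self.lower_fraction < 1.0:
            raise ValueError("lower_fraction must be in (0, 1)")


@dataclass
class ValidationResult:
    passed: bool
    failed_gates: list[str] = field(default_factory=list)
    end_attempts_observed: int = 0

    def __post_init__(self) -> None:
        if self.passed != (not self.failed_gates):
            raise ValueError("passed must be equivalent to failed_gates being empty")


def check_min_count(judgment: Judgment, cfg: GateConfig = GateConfig()) -> bool:
    """True iff the judgment counted at least ``min_total_cells`` cells."""
    return len(judgment.clicks) >= cfg.min_total_cells


def check_lower_region(
    judgment: Judgment, canvas: Canvas, cfg: GateConfig = GateConfig()
) -> bool:
    """True iff at least one click lies in the bottom ``lower_fraction``
    of the canvas (y >= height * (1 - lower_fraction), inclusive)."""
    threshold = canvas.height * (1.0 - cfg.lower_fraction)
    return any(c.point.y >= threshold for c in judgment.clicks)


def validate_judgment(
    judgment: Judgment, canvas: Canvas, cfg: GateConfig = GateConfig()
) -> ValidationResult:
    """Evaluate both gates independently; a judgment failing any gate is
    excluded from aggregation downstream."""
    failed = []
    if not check_min_count(judgment, cfg):
        failed.append(MIN_COUNT_GATE)
    if not check_lower_region(judgment, canvas, cfg):
        failed.append(LOWER_REGION_GATE)
    return ValidationResult(
        passed=not failed,
        failed_gates=failed,
        end_attempts_observed=judgment.end_attempts,
    )
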