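"""Crowd aggregation of per-judgment positivity percentages.

The crowd estimate for an image is a summary of the gate-passing
judgments' positivity percentages — by default their median, the
classical wisdom-of-the-crowd estimator, robust to a minority of wild
judgments. Aggregation operates on per-judgment percentages, not on
pooled click counts: each contributor's count is summarised first, then
the crowd of summaries is aggregated. With an even number of judgments
(the collection default is 10) the median is the midpoint of the
central pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .gates import GateConfig, validate_judgment
from .model import (
    GoldAnnotation,
    Judgment,
    PositivityRecord,
    UndefinedStatisticError,
    judgment_positivity,
)

METHODS = ("median", "mean", "trimmed_mean")


class NoValidJudgmentsError(ValueError):
    """Every judgment of an image failed the quality gates."""


@dataclass(frozen=True)
class AggregationConfig:
    method: str = "median"
    trim_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown aggregation method {self.method!r}; "
                             f"expected one of {METHODS}")
        if not 0.0 <= self.trim_fraction < 0.5:
            raise ValueError("trim_fraction must be in [0, 0.5)")


def aggregate(values: list[float], cfg: AggregationConfig = AggregationConfig()) -> float:
    """Aggregate judgment positivities into the crowd estimate.

    The result always lies within [min, max] of the input.
    """
    if not values:
        raise UndefinedStatisticError("cannot aggregate an empty list of positivities")
    arr = np.asarray(values, dtype=float)
    if cfg.method == "median":
        return float(np.median(arr))
    if cfg.method == "mean":
        return float(np.mean(arr))
    return float(stats.trim_mean(arr, cfg.trim_fraction))


def build_positivity_record(
    image_id: str,
    gold: GoldAnnotation,
    judgments: list[Judgment],
    gates: GateConfig = GateConfig(),
    agg: AggregationConfig = AggregationConfig(),
) -> PositivityRecord:
    """Filter judgments through the quality gates, then aggregate.

    Invalid judgments are excluded (discarded work), never zero-filled.

    Raises
    ------
    NoValidJudgmentsError
        If no judgment passes, listing each judgment's failed gates.
    """
    valid: list[Judgment] = []
    failures: list[str] = []
    for j in judgments:
        result = validate_judgment(j, gold.canvas, gates)
        if result.passed:
            valid.append(j)
        else:
            failures.append(f"{j.worker_id}: {', '.join(result.failed_gates)}")
    if not valid:
        raise NoValidJudgmentsError(
            f"no judgment of image {image_id!r} passed the quality gates "
            f"({len(judgments)} rejected: {'; '.join(failures)})"
        )
    positivities = [judgment_positivity(j) for j in valid]
    return PositivityRecord(
        image_id=image_id,
        gold_positivity=gold.positivity(),
        judgment_positivities=positivities,
        crowd_positivity=aggregate(positivities, agg),
    )
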