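"""Concordance of crowd estimates against the pathologist's gold standard.

Three complementary views are computed over the per-image (gold, crowd)
positivity pairs:

* Spearman rank correlation — does the crowd order images the way the
  pathologist does? Ranks use average-rank tie handling; rho is the
  Pearson correlation of the rank vectors, which reduces to
  ``1 - 6*sum(d^2) / (n*(n^2-1))`` when there are no ties.
* Ordinary least squares of crowd on gold — is there a systematic
  offset? A positive intercept with slope below one is the signature of
  negative-nucleus overestimation (uncounted stromal/lymphocyte nuclei
  clicked as negative).
* 15% positivity cutoff classification — does the crowd put each image
  on the same side of the clinical high/low proliferation threshold?
  The boundary is inclusive: positivity >= cutoff is "above".

The correlation and regression are written from first principles so that
tiny-instance oracles can verify them exactly; p-values for rho are
deliberately not computed (n is typically ~13, too small for the
asymptotic approximation to add information).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import Judgment, PositivityRecord

ABOVE = "above"
BELOW = "below"


class UndefinedCorrelationError(ValueError):
    """Rank correlation is undefined (constant vector or too few points)."""


def _rank_average(values: np.ndarray) -> np.ndarray:
    """Average-rank transform (1-based; ties share the mean of the ranks
    they span)."""
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values), dtype=float)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman(x: list[float], y: list[float]) -> float:
    """Spearman rank correlation with average-rank tie handling."""
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 3:
        raise UndefinedCorrelationError(
            f"rank correlation needs at least 3 pairs, got {len(x)}"
        )
    rx = _rank_average(np.asarray(x, dtype=float))
    ry = _rank_average(np.asarray(y, dtype=float))
    dx = rx - rx.mean()
    dy = ry - ry.mean()
    sx = float(np.sqrt((dx * dx).sum()))
    sy = float(np.sqrt((dy * dy).sum()))
    if sx == 0.0 or sy == 0.0:
        raise UndefinedCorrelationError(
            "rank correlation is undefined for a constant vector"
        )
    return float((dx * dy).sum() / (sx * sy))


def ols_fit(x: list[float], y: list[float]) -> tuple[float, float]:
    """Ordinary least squares of y on x; returns (slope, intercept).

    The default concordance fit regresses crowd (y) on gold (x), so the
    intercept reads as the crowd's offset at zero true positivity.
    """
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 2:
        raise ValueError("regression needs at least 2 points")
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    dx = xa - xa.mean()
    sxx = float((dx * dx).sum())
    if sxx == 0.0:
        raise ValueError("regression is singular: x is constant")
    slope = float((dx * (ya - ya.mean())).sum() / sxx)
    intercept = float(ya.mean() - slope * xa.mean())
    return slope, intercept


def classify_cutoff(p: float, cutoff: float = 15.0) -> str:
    """Dichotomise a positivity percentage at the clinical cutoff
    (boundary inclusive: p >= cutoff is "above")."""
    if not 0.0 <= p <= 100.0:
        raise ValueError(f"positivity must be in [0, 100], got {p}")
    return ABOVE if p >= cutoff else BELOW


def cutoff_confusion(
    gold: list[float], crowd: list[float], cutoff: float = 15.0
) -> tuple[int, int]:
    """Count cutoff disagreements: (false positives, false negatives).

    A false positive is an image below the cutoff by gold but above by
    crowd; a false negative the reverse.
    """
    if len(gold) != len(crowd):
        raise ValueError(f"length mismatch: {len(gold)} vs {len(crowd)}")
    fp = fn = 0
    for g, c in zip(gold, crowd):
        g_above = classify_cutoff(g, cutoff) == ABOVE
        c_above = classify_cutoff(c, cutoff) == ABOVE
        if c_above and not g_above:
            fp += 1
        elif g_above and not c_above:
            fn += 1
    return fp, fn


@dataclass
class CrowdStats:
    """Descriptive statistics of the contributor crowd."""

    n_contributors: int
    n_judgments: int
    mean_units_per_contributor: float
    mean_seconds_per_unit: float | None
    n_countries: int

    def to_dict(self) -> dict:
        return {
            "n_contributors": self.n_contributors,
            "n_judgments": self.n_judgments,
            "mean_units_per_contributor": round(self.mean_units_per_contributor, 2),
            "mean_seconds_per_unit": (
                None if self.mean_seconds_per_unit is None
                else round(self.mean_seconds_per_unit, 1)
            ),
            "n_countries": self.n_countries,
        }


def crowd_summary(judgments: list[Judgment]) -> CrowdStats:
    """Distinct contributors, judgment total, mean units per contributor,
    mean unit duration, and distinct countries."""
    if not judgments:
        raise ValueError("cannot summarise an empty judgment list")
    workers = {j.worker_id for j in judgments}
    countries = {j.country for j in judgments if j.country}
    times = [j.elapsed_seconds for j in judgments if j.elapsed_seconds is not None]
    return CrowdStats(
        n_contributors=len(workers),
        n_judgments=len(judgments),
        mean_units_per_contributor=len(judgments) / len(workers),
        mean_seconds_per_unit=(sum(times) / len(times)) if times else None,
        n_countries=len(countries),
    )


@dataclass
class EvaluationReport:
    """Full concordance report over a set of per-image records."""

    n_images: int
    spearman_rho: float | None
    regression_slope: float
    regression_intercept: float
    cutoff: float
    false_positive_images: int
    false_negative_images: int
    crowd_stats: CrowdStats | None = None
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "n_images": self.n_images,
            "spearman_rho": (None if self.spearman_rho is None
                             else round(self.spearman_rho, 4)),
            "spearman_p_value": "not computed",
            "regression_slope": round(self.regression_slope, 4),
            "regression_intercept": round(self.regression_intercept, 4),
            "cutoff": self.cutoff,
            "false_positive_images": self.false_positive_images,
            "false_negative_images": self.false_negative_images,
            "notes": self.notes,
        }
        if self.crowd_stats is not None:
            d["crowd_stats"] = self.crowd_stats.to_dict()
        return d


def evaluate(
    records: list[PositivityRecord],
    judgments: list[Judgment] | None = None,
    cutoff: float = 15.0,
) -> EvaluationReport:
    """Assemble the concordance report from per-image positivity records.

    With fewer than 3 records the rank correlation is reported as
    unavailable (with a note); regression still requires 2.
    """
    if not records:
        raise ValueError("cannot evaluate an empty record list")
    gold = [r.gold_positivity for r in records]
    crowd = [r.crowd_positivity for r in records]
    notes: list[str] = []
    rho: float | None
    try:
        rho = spearman(gold, crowd)
    except UndefinedCorrelationError as exc:
        rho = None
        notes.append(f"spearman unavailable: {exc}")
    slope, intercept = ols_fit(gold, crowd)
    fp, fn = cutoff_confusion(gold, crowd, cutoff)
    return EvaluationReport(
        n_images=len(records),
        spearman_rho=rho,
        regression_slope=slope,
        regression_intercept=intercept,
        cutoff=cutoff,
        false_positive_images=fp,
        false_negative_images=fn,
        crowd_stats=crowd_summary(judgments) if judgments else None,
        notes=notes,
    )
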