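"""Domain types for crowdsourced immunohistochemistry quantification.

The pipeline operates on point annotations of stained tissue images:
a pathologist's gold standard marks every nucleus as positive (stained),
negative (unstained tumour) or other (stromal cells / lymphocytes that
must not be counted), while crowd contributors submit judgments — click
lists carrying only positive/negative labels, because the task interface
offers no "other" button.

Coordinate convention: 0-based pixels, origin at the top-left corner,
x increasing rightward and y increasing downward (the screen convention
of a web canvas). "Lower part of the image" therefore means large y.
The reference geometry is the rotated-vertical image, 772 x 1044 pixels.

Percentages are carried on the 0-100 scale throughout; conversion to
fractions happens only inside statistical formulas.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class UndefinedStatisticError(ValueError):
    """A ratio statistic was requested for an empty denominator."""


class NucleusClass(enum.Enum):
    """Nucleus category. ``OTHER`` is legal only in gold annotations:
    contributors click only positive/negative nuclei."""

    POSITIVE = "P"
    NEGATIVE = "N"
    OTHER = "O"

    @classmethod
    def from_code(cls, code: str) -> "NucleusClass":
        try:
            return cls(code)
        except ValueError:
            raise ValueError(
                f"unknown nucleus class code {code!r}; expected one of P, N, O"
            ) from None


@dataclass(frozen=True)
class Point:
    """Pixel location, 0-based, origin top-left, y downward."""

    x: float
    y: float

    def distance_to(self, other: "Point") -> float:
        return ((self.x - other.x) ** 2 + (self.y - other.y) ** 2) ** 0.5


@dataclass(frozen=True)
class Canvas:
    """Image geometry in pixels."""

    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError(f"canvas dimensions must be positive, got {self.width}x{self.height}")

    def contains(self, p: Point) -> bool:
        return 0 <= p.x < self.width and 0 <= p.y < self.height


#: Rotated-vertical reference geometry (acquired 1044x772, shown vertical).
DEFAULT_CANVAS = Canvas(width=772, height=1044)


@dataclass
class GoldAnnotation:
    """A pathologist's reference annotation of one image.

    ``nuclei`` is a list of (point, class) pairs; all points must lie
    inside ``canvas``.
    """

    image_id: str
    canvas: Canvas
    nuclei: list[tuple[Point, NucleusClass]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for i, (p, _) in enumerate(self.nuclei):
            if not self.canvas.contains(p):
                raise ValueError(
                    f"nucleus {i} at ({p.x}, {p.y}) outside canvas "
                    f"{self.canvas.width}x{self.canvas.height} of image {self.image_id!r}"
                )

    def count(self, cls: NucleusClass) -> int:
        return sum(1 for _, c in self.nuclei if c is cls)

    @property
    def n_positive(self) -> int:
        return self.count(NucleusClass.POSITIVE)

    @property
    def n_negative(self) -> int:
        return self.count(NucleusClass.NEGATIVE)

    @property
    def n_other(self) -> int:
        return self.count(NucleusClass.OTHER)

    def positivity(self) -> float:
        """Gold positivity percentage; "other" nuclei never contribute."""
        return positivity(self.n_positive, self.n_negative)


@dataclass(frozen=True)
class Click:
    """One contributor click: a point plus a positive/negative label."""

    point: Point
    label: NucleusClass

    def __post_init__(self) -> None:
        if self.label is NucleusClass.OTHER:
            raise ValueError(
                "judgment clicks carry only positive/negative labels; "
                "the task interface has no 'other' category"
            )


@dataclass
class Judgment:
    """One contributor's complete annotation of one image (one task-unit
    result), with the behavioural metadata collected alongside it:
    end_attempts (tries to finish before passing the quality gates) and
    afterthoughts (clicks removed by re-clicking a selected nucleus).
    """

    image_id: str
    worker_id: str
    clicks: list[Click] = field(default_factory=list)
    country: str | None = None
    elapsed_seconds: float | None = None
    end_attempts: int = 0
    afterthoughts: int = 0

    def __post_init__(self) -> None:
        if self.end_attempts < 0:
            raise ValueError("end_attempts must be nonnegative")
        if self.afterthoughts < 0:
            raise ValueError("afterthoughts must be nonnegative")
        if self.elapsed_seconds is not None and self.elapsed_seconds < 0:
            raise ValueError("elapsed_seconds must be nonnegative")
        seen: dict[tuple[float, float], NucleusClass] = {}
        for c in self.clicks:
            key = (c.point.x, c.point.y)
            if key in seen and seen[key] is not c.label:
                raise ValueError(
                    f"conflicting labels at coordinate {key} in judgment "
                    f"({self.worker_id!r}, {self.image_id!r}); an afterthought "
                    "removes the earlier click, it cannot relabel it"
                )
            seen[key] = c.label

    @property
    def n_positive(self) -> int:
        return sum(1 for c in self.clicks if c.label is NucleusClass.POSITIVE)

    @property
    def n_negative(self) -> int:
        return sum(1 for c in self.clicks if c.label is NucleusClass.NEGATIVE)


@dataclass
class PositivityRecord:
    """Per-image summary: gold positivity, the gate-passing judgments'
    positivities, and their crowd aggregate."""

    image_id: str
    gold_positivity: float
    judgment_positivities: list[float]
    crowd_positivity: float

    def __post_init__(self) -> None:
        if self.judgment_positivities:
            lo, hi = min(self.judgment_positivities), max(self.judgment_positivities)
            if not (lo - 1e-9 <= self.crowd_positivity <= hi + 1e-9):
                raise ValueError(
                    f"crowd positivity {self.crowd_positivity} outside the range "
                    f"[{lo}, {hi}] of the judgment positivities"
                )


def positivity(n_positive: int, n_negative: int) -> float:
    """Positivity percentage: 100 * positive / (positive + negative).

    This is the labelling index used clinically for proliferation markers
    such as Ki-67/MIB1. "Other" nuclei are excluded by definition.

    Raises
    ------
    UndefinedStatisticError
        If both counts are zero — the statistic is undefined, never
        silently 0 or NaN.
    """
    if n_positive < 0 or n_negative < 0:
        raise ValueError("nucleus counts must be nonnegative")
    total = n_positive + n_negative
    if total == 0:
        raise UndefinedStatisticError(
            "positivity is undefined for zero counted nuclei"
        )
    return 100.0 * n_positive / total


def judgment_positivity(judgment: Judgment) -> float:
    """Positivity percentage of a single judgment's clicks."""
    if not judgment.clicks:
        raise UndefinedStatisticError(
            f"judgment ({judgment.worker_id!r}, {judgment.image_id!r}) has no "
            "clicks; its positivity is undefined"
        )
    return positivity(judgment.n_positive, judgment.n_negative)
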