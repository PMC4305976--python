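"""Synthetic gold fields and crowd simulation.

Real crowdsourced counting data carry three characteristic error
phenomena: detection misses (a nucleus nobody clicks), wrong-class
counting (stromal cells and lymphocytes — the "other" class — clicked
and labelled negative, which biases positivity downward), and spurious
background clicks. The worker model here is the minimal parametric
family producing all three, plus label confusion and click jitter.

Everything is deterministic for a fixed seed: field generation, worker
behaviour, and the worker-to-image assignment.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .model import (
    Canvas,
    Click,
    DEFAULT_CANVAS,
    GoldAnnotation,
    Judgment,
    NucleusClass,
    Point,
)


class PlacementError(RuntimeError):
    """Requested nucleus field cannot be packed onto the canvas."""


class CapacityError(ValueError):
    """Worker pool cannot supply the requested number of judgments."""


# Country pool for simulated contributor metadata (ISO 3166 alpha-2).
COUNTRIES: tuple[str, ...] = (
    "IN", "ID", "PH", "US", "PK", "BD", "VN", "EG", "RO", "RS",
    "TR", "BR", "MX", "NG", "UA", "PL", "IT", "GB",
)

#: Mean task-unit duration in seconds used for simulated timing metadata
#: (2 min 43 s, a realistic per-image counting time).
MEAN_ELAPSED_SECONDS = 163.0


@dataclass(frozen=True)
class FieldConfig:
    """Specification of one synthetic nucleus field.

    ``min_separation`` is the minimum pairwise centre distance in pixels;
    24 px default keeps ~150 nuclei placeable on the 772x1044 canvas
    while leaving click clusters separable downstream.
    """

    n_positive: int
    n_negative: int
    n_other: int = 0
    canvas: Canvas = DEFAULT_CANVAS
    min_separation: float = 24.0
    seed: int = 0
    image_id: str | None = None

    def __post_init__(self) -> None:
        if min(self.n_positive, self.n_negative, self.n_other) < 0:
            raise ValueError("nucleus counts must be nonnegative")
        if self.min_separation <= 0:
            raise ValueError("min_separation must be positive")


@dataclass(frozen=True)
class WorkerProfile:
    """Parametric error model of one simulated contributor.

    Parameters
    ----------
    s_pos, s_neg
        Probability that a positive / negative nucleus is detected and
        clicked.
    s_other
        Probability that an "other" nucleus (stroma, lymphocyte) is
        wrongly clicked; such clicks are always labelled negative,
        because these cells are morphologically unstained.
    confusion
        Probability that a detected positive/negative nucleus receives
        the flipped label.
    fp_rate
        Expected number of spurious background clicks per image
        (Poisson), placed uniformly on the canvas.
    fp_neg_share
        Probability a spurious click is labelled negative (most
        background resembles unstained material).
    jitter_sd
        Isotropic Gaussian displacement of every click, in pixels,
        clamped to the canvas.
    """

    worker_id: str
    s_pos: float = 0.9
    s_neg: float = 0.9
    s_other: float = 0.2
    confusion: float = 0.02
    fp_rate: float = 2.0
    fp_neg_share: float = 0.7
    jitter_sd: float = 3.0

    def __post_init__(self) -> None:
        for name in ("s_pos", "s_neg", "s_other", "confusion", "fp_neg_share"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0,1], got {v}")
        if self.fp_rate < 0:
            raise ValueError("fp_rate must be nonnegative")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be nonnegative")


def perfect_worker(worker_id: str = "perfect") -> WorkerProfile:
    """Error-free contributor: clicks every positive/negative nucleus
    exactly, never touches "other" nuclei, no spurious clicks or jitter."""
    return WorkerProfile(
        worker_id=worker_id, s_pos=1.0, s_neg=1.0, s_other=0.0,
        confusion=0.0, fp_rate=0.0, jitter_sd=0.0,
    )


@dataclass(frozen=True)
class CrowdConfig:
    """How judgments are collected: ``n_judgments_per_image`` distinct
    workers per image, no worker judging an image twice nor exceeding
    ``max_units_per_worker`` units overall."""

    worker_pool: tuple[WorkerProfile, ...]
    n_judgments_per_image: int = 10
    max_units_per_worker: int = 13
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_judgments_per_image < 1:
            raise ValueError("n_judgments_per_image must be >= 1")
        if self.max_units_per_worker < 1:
            raise ValueError("max_units_per_worker must be >= 1")
        object.__setattr__(self, "worker_pool", tuple(self.worker_pool))


def make_worker_pool(
    n_workers: int,
    seed: int = 0,
    heterogeneity: float = 0.0,
    **overrides: float,
) -> list[WorkerProfile]:
    """Build a pool of workers around the default error profile.

    ``heterogeneity`` perturbs each probability parameter by a truncated
    Gaussian of that standard deviation, making the crowd mildly diverse;
    0 yields identical profiles. Countries cycle through a fixed pool so
    a 28-worker crowd spans 18 countries.
    """
    rng = np.random.default_rng(seed)
    base = {f.name: f.default for f in dataclasses.fields(WorkerProfile)
            if f.name != "worker_id"}
    base.update(overrides)
    pool = []
    for i in range(n_workers):
        params = dict(base)
        if heterogeneity > 0:
            for name in ("s_pos", "s_neg", "s_other", "confusion"):
                params[name] = float(
                    np.clip(params[name] + rng.normal(0, heterogeneity), 0.0, 1.0)
                )
            params["fp_rate"] = float(
                max(0.0, params["fp_rate"] + rng.normal(0, heterogeneity * 10))
            )
        pool.append(WorkerProfile(worker_id=f"w{i:03d}", **params))
    return pool


def worker_country(profile: WorkerProfile, index: int) -> str:
    return COUNTRIES[index % len(COUNTRIES)]


def generate_field(cfg: FieldConfig) -> GoldAnnotation:
    """Place nuclei by random sequential packing with a hard-core
    minimum separation; deterministic for a fixed seed.

    Raises
    ------
    PlacementError
        If a nucleus cannot be placed after bounded retries, naming the
        violated separation constraint.
    """
    rng = np.random.default_rng(cfg.seed)
    total = cfg.n_positive + cfg.n_negative + cfg.n_other
    xs = np.empty(total)
    ys = np.empty(total)
    max_attempts = 500
    for i in range(total):
        for _ in range(max_attempts):
            # integer pixel centres, matching click-recorded annotations
            x = float(rng.integers(0, cfg.canvas.width))
            y = float(rng.integers(0, cfg.canvas.height))
            if i == 0 or np.min(
                np.hypot(xs[:i] - x, ys[:i] - y)
            ) >= cfg.min_separation:
                xs[i], ys[i] = x, y
                break
        else:
            raise PlacementError(
                f"could not place nucleus {i + 1}/{total} with min_separation="
                f"{cfg.min_separation}px on a {cfg.canvas.width}x"
                f"{cfg.canvas.height} canvas after {max_attempts} attempts"
            )
    classes = (
        [NucleusClass.POSITIVE] * cfg.n_positive
        + [NucleusClass.NEGATIVE] * cfg.n_negative
        + [NucleusClass.OTHER] * cfg.n_other
    )
    # shuffle class assignment so spatial position carries no class signal
    order = rng.permutation(total)
    nuclei = [
        (Point(float(xs[i]), float(ys[i])), classes[int(k)])
        for i, k in enumerate(order)
    ]
    image_id = cfg.image_id if cfg.image_id is not None else f"synthetic-{cfg.seed}"
    return GoldAnnotation(image_id=image_id, canvas=cfg.canvas, nuclei=nuclei)


def make_study_fields(
    n_images: int = 13,
    seed: int = 0,
    n_counted: int = 120,
    n_other: int = 30,
    positivity_range: tuple[float, float] = (2.0, 80.0),
) -> list[GoldAnnotation]:
    """Generate a study-sized panel of fields whose gold positivities
    spread evenly across ``positivity_range``.

    ``n_counted`` is the number of countable (positive + negative)
    nuclei per field; ``n_other`` stromal/lymphocyte nuclei are added on
    top. Defaults mirror a 40x high-power field of a stained breast
    specimen: order-100 tumour nuclei with a substantial stromal
    admixture.
    """
    targets = np.linspace(positivity_range[0], positivity_range[1], n_images)
    seeds = np.random.SeedSequence(seed).generate_state(n_images) % (2**31)
    fields = []
    for i, (p, s) in enumerate(zip(targets, seeds)):
        n_pos = int(round(p / 100.0 * n_counted))
        fields.append(generate_field(FieldConfig(
            n_positive=n_pos,
            n_negative=n_counted - n_pos,
            n_other=n_other,
            seed=int(s),
            image_id=f"img{i + 1:02d}",
        )))
    return fields


def _clamp(v: float, lo: float, hi: float) -> float:
    return min(max(v, lo), hi)


def _place_click(
    clicks: dict[tuple[int, int], NucleusClass],
    x: float,
    y: float,
    label: NucleusClass,
    canvas: Canvas,
) -> None:
    """Register an integer-pixel click, nudging deterministically on a
    coordinate collision so no pixel carries conflicting labels."""
    xi = int(round(_clamp(x, 0, canvas.width - 1)))
    yi = int(round(_clamp(y, 0, canvas.height - 1)))
    for dx, dy in ((0, 0), (1, 0), (0, 1), (-1, 0), (0, -1), (1, 1),
                   (-1, -1), (1, -1), (-1, 1), (2, 0), (0, 2)):
        key = (int(_clamp(xi + dx, 0, canvas.width - 1)),
               int(_clamp(yi + dy, 0, canvas.height - 1)))
        if key not in clicks:
            clicks[key] = label
            return
    # all nudge targets occupied (pathologically dense); drop the click


def simulate_judgment(
    gold: GoldAnnotation,
    worker: WorkerProfile,
    seed: int | np.random.Generator = 0,
    country: str | None = None,
) -> Judgment:
    """Simulate one contributor annotating one image.

    Each positive (negative) nucleus is clicked with probability
    ``s_pos`` (``s_neg``) and labelled correctly with probability
    ``1 - confusion``; each "other" nucleus is clicked with probability
    ``s_other`` and always labelled negative. Poisson(``fp_rate``)
    spurious clicks land uniformly on the canvas. Every click is
    displaced by Gaussian jitter, clamped to the canvas, and rounded to
    integer pixels.
    """
    if not gold.nuclei:
        raise ValueError("cannot simulate a judgment of an empty gold annotation")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    canvas = gold.canvas
    clicks: dict[tuple[int, int], NucleusClass] = {}

    for point, cls in gold.nuclei:
        if cls is NucleusClass.OTHER:
            if rng.random() >= worker.s_other:
                continue
            label = NucleusClass.NEGATIVE
        else:
            detect_p = worker.s_pos if cls is NucleusClass.POSITIVE else worker.s_neg
            if rng.random() >= detect_p:
                continue
            label = cls
            if rng.random() < worker.confusion:
                label = (NucleusClass.NEGATIVE if cls is NucleusClass.POSITIVE
                         else NucleusClass.POSITIVE)
        x, y = point.x, point.y
        if worker.jitter_sd > 0:
            x += rng.normal(0, worker.jitter_sd)
            y += rng.normal(0, worker.jitter_sd)
        _place_click(clicks, x, y, label, canvas)

    for _ in range(rng.poisson(worker.fp_rate)):
        label = (NucleusClass.NEGATIVE if rng.random() < worker.fp_neg_share
                 else NucleusClass.POSITIVE)
        _place_click(clicks, rng.uniform(0, canvas.width),
                     rng.uniform(0, canvas.height), label, canvas)

    elapsed = float(max(10.0, rng.lognormal(np.log(MEAN_ELAPSED_SECONDS), 0.4)))
    return Judgment(
        image_id=gold.image_id,
        worker_id=worker.worker_id,
        country=country,
        elapsed_seconds=round(elapsed, 1),
        end_attempts=int(rng.poisson(0.1)),
        afterthoughts=int(rng.poisson(0.3)),
        clicks=[Click(Point(float(x), float(y)), label)
                for (x, y), label in sorted(clicks.items())],
    )


def _assign_workers(
    n_images: int, cfg: CrowdConfig, rng: np.random.Generator
) -> list[list[int]]:
    """Round-robin worker-to-image assignment over a seeded shuffle of
    the pool, honouring the one-judgment-per-image and per-worker unit
    caps."""
    pool_size = len(cfg.worker_pool)
    needed = n_images * cfg.n_judgments_per_image
    if pool_size < cfg.n_judgments_per_image:
        raise CapacityError(
            f"pool of {pool_size} workers cannot supply "
            f"{cfg.n_judgments_per_image} distinct judgments per image"
        )
    if pool_size * cfg.max_units_per_worker < needed:
        raise CapacityError(
            f"pool capacity {pool_size} x {cfg.max_units_per_worker} = "
            f"{pool_size * cfg.max_units_per_worker} judgments is below the "
            f"{needed} required ({n_images} images x "
            f"{cfg.n_judgments_per_image} judgments)"
        )
    order = list(rng.permutation(pool_size))
    units_done = [0] * pool_size
    assignments: list[list[int]] = []
    cursor = 0
    for _ in range(n_images):
        chosen: list[int] = []
        scanned = 0
        while len(chosen) < cfg.n_judgments_per_image:
            if scanned >= pool_size:  # cannot happen given the capacity checks
                raise CapacityError("worker pool exhausted mid-assignment")
            w = order[cursor % pool_size]
            cursor += 1
            scanned += 1
            if w in chosen or units_done[w] >= cfg.max_units_per_worker:
                continue
            chosen.append(w)
            units_done[w] += 1
            scanned = 0
        assignments.append(chosen)
    return assignments


def simulate_crowd(
    golds: list[GoldAnnotation], cfg: CrowdConfig
) -> list[Judgment]:
    """Simulate the full collection run: ``n_judgments_per_image``
    judgments for every image, deterministic for a fixed seed."""
    rng = np.random.default_rng(cfg.seed)
    assignments = _assign_workers(len(golds), cfg, rng)
    seeds = np.random.SeedSequence(cfg.seed).spawn(len(golds))
    judgments: list[Judgment] = []
    for gold, chosen, img_seed in zip(golds, assignments, seeds):
        child = np.random.default_rng(img_seed)
        for w in chosen:
            profile = cfg.worker_pool[w]
            judgments.append(
                simulate_judgment(gold, profile, child,
                                  country=worker_country(profile, w))
            )
    return judgments
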