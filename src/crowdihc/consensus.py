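"""Spatial click consensus: pooled-click aggregation across judgments.

Instead of summarising each judgment into one number, the clicks of all
gate-passing judgments of an image are pooled and clustered spatially:
a cluster of clicks from several contributors marks one crowd-identified
nucleus, its support being the number of distinct judgments that
contributed a click. Keeping only well-supported nuclei suppresses
individual contributors' spurious clicks and stromal-cell mistakes —
the error-reduction idea behind "most selected cells".

Clustering is greedy density clustering: repeatedly seed a cluster at
the pooled click with the most neighbours within ``cluster_radius``
(ties broken by lowest y, then lowest x — coordinate-based, so the
result is invariant to judgment order), absorb at most one click per
judgment (the nearest within the radius), remove them, and recurse.
Deterministic and oracle-checkable on tiny instances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    GoldAnnotation,
    Judgment,
    NucleusClass,
    Point,
    UndefinedStatisticError,
    positivity,
)


@dataclass(frozen=True)
class ConsensusConfig:
    """``min_support=None`` means a majority of the pooled judgments
    (computed at call time); ``match_radius=None`` inherits
    ``cluster_radius``."""

    cluster_radius: float = 15.0
    min_support: int | None = None
    match_radius: float | None = None

    def __post_init__(self) -> None:
        if self.cluster_radius <= 0:
            raise ValueError("cluster_radius must be positive")
        if self.min_support is not None and self.min_support < 1:
            raise ValueError("min_support must be >= 1")
        if self.match_radius is not None and self.match_radius <= 0:
            raise ValueError("match_radius must be positive")

    def effective_match_radius(self) -> float:
        return self.cluster_radius if self.match_radius is None else self.match_radius

    def effective_min_support(self, n_judgments: int) -> int:
        if self.min_support is not None:
            return self.min_support
        return n_judgments // 2 + 1


@dataclass
class ConsensusNucleus:
    """One crowd-identified nucleus: cluster centroid, its support
    (distinct contributing judgments; each judgment contributes at most
    one click, so the label votes sum to the support), and the majority
    label (ties broken toward negative — conservative with respect to
    clinical positivity)."""

    centroid: Point
    support: int
    positive_votes: int
    negative_votes: int

    def __post_init__(self) -> None:
        if self.support < 1:
            raise ValueError("support must be >= 1")
        if self.positive_votes + self.negative_votes != self.support:
            raise ValueError("label votes must sum to the support")

    @property
    def label(self) -> NucleusClass:
        if self.positive_votes > self.negative_votes:
            return NucleusClass.POSITIVE
        return NucleusClass.NEGATIVE


@dataclass
class MatchReport:
    """Consensus-to-gold matching outcome. ``true_positives`` counts
    consensus nuclei matched to a gold positive/negative nucleus;
    consensus nuclei sitting on gold "other" nuclei count as spurious,
    surfacing the stromal-confusion error."""

    true_positives: int
    spurious: int
    missed: int
    label_agreement: float | None


def cluster_clicks(
    judgments: list[Judgment], cfg: ConsensusConfig = ConsensusConfig()
) -> list[ConsensusNucleus]:
    """Cluster the pooled clicks of several judgments of one image."""
    image_ids = {j.image_id for j in judgments}
    if len(image_ids) > 1:
        raise ValueError(f"judgments refer to different images: {sorted(image_ids)}")
    pooled: list[tuple[float, float, int, NucleusClass]] = []
    for ji, j in enumerate(judgments):
        for c in j.clicks:
            pooled.append((c.point.x, c.point.y, ji, c.label))
    if not pooled:
        return []

    xs = np.array([p[0] for p in pooled])
    ys = np.array([p[1] for p in pooled])
    owner = np.array([p[2] for p in pooled])
    labels = [p[3] for p in pooled]
    n = len(pooled)
    # pairwise distances; pooled click counts per image are small (~10^3)
    dist = np.hypot(xs[:, None] - xs[None, :], ys[:, None] - ys[None, :])
    within = dist <= cfg.cluster_radius
    alive = np.ones(n, dtype=bool)
    clusters: list[ConsensusNucleus] = []

    while alive.any():
        counts = (within & alive[None, :]).sum(axis=1)
        counts[~alive] = -1
        best = counts.max()
        # tie-break: lowest y, then lowest x, among maximal-count seeds
        cand = np.flatnonzero(counts == best)
        seed = cand[np.lexsort((xs[cand], ys[cand]))[0]]
        members: list[int] = []
        for ji in np.unique(owner[alive & within[seed]]):
            mask = alive & within[seed] & (owner == ji)
            idx = np.flatnonzero(mask)
            members.append(int(idx[np.argmin(dist[seed, idx])]))
        pos = sum(1 for m in members if labels[m] is NucleusClass.POSITIVE)
        clusters.append(ConsensusNucleus(
            centroid=Point(float(xs[members].mean()), float(ys[members].mean())),
            support=len(members),
            positive_votes=pos,
            negative_votes=len(members) - pos,
        ))
        alive[members] = False
    return clusters


def apply_support_threshold(
    nuclei: list[ConsensusNucleus], min_support: int
) -> list[ConsensusNucleus]:
    """Keep consensus nuclei supported by at least ``min_support``
    distinct judgments."""
    return [n for n in nuclei if n.support >= min_support]


def match_to_gold(
    consensus: list[ConsensusNucleus],
    gold: GoldAnnotation,
    cfg: ConsensusConfig = ConsensusConfig(),
) -> MatchReport:
    """Greedy nearest-pair matching of consensus nuclei to gold
    positive/negative nuclei (ascending distance, each side used once,
    pairs beyond the match radius rejected). Gold "other" nuclei are
    never match targets."""
    targets = [(p, c) for p, c in gold.nuclei if c is not NucleusClass.OTHER]
    radius = cfg.effective_match_radius()
    pairs: list[tuple[float, int, int]] = []
    for ci, cn in enumerate(consensus):
        for gi, (gp, _) in enumerate(targets):
            d = cn.centroid.distance_to(gp)
            if d <= radius:
                pairs.append((d, ci, gi))
    pairs.sort()
    used_c: set[int] = set()
    used_g: set[int] = set()
    agree = 0
    for _, ci, gi in pairs:
        if ci in used_c or gi in used_g:
            continue
        used_c.add(ci)
        used_g.add(gi)
        if consensus[ci].label is targets[gi][1]:
            agree += 1
    matched = len(used_c)
    return MatchReport(
        true_positives=matched,
        spurious=len(consensus) - matched,
        missed=len(targets) - matched,
        label_agreement=(agree / matched) if matched else None,
    )


def consensus_positivity(consensus: list[ConsensusNucleus]) -> float:
    """Positivity percentage over the majority labels of the consensus
    nuclei — the pooled-click alternative to the median of per-judgment
    percentages."""
    if not consensus:
        raise UndefinedStatisticError(
            "consensus positivity is undefined for an empty consensus set"
        )
    pos = sum(1 for n in consensus if n.label is NucleusClass.POSITIVE)
    return positivity(pos, len(consensus) - pos)
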