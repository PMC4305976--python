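"""Spatial click consensus: clustering, support thresholds, gold matching."""

import numpy as np
import pytest

from crowdihc import (
    ConsensusConfig,
    ConsensusNucleus,
    CrowdConfig,
    FieldConfig,
    NucleusClass,
    Point,
    WorkerProfile,
    apply_support_threshold,
    cluster_clicks,
    consensus_positivity,
    generate_field,
    match_to_gold,
    simulate_crowd,
    UndefinedStatisticError,
)
from conftest import make_judgment


def test_perfect_zero_jitter_crowd_recovers_gold_exactly(small_field,
                                                         perfect_crowd):
    clusters = cluster_clicks(perfect_crowd)
    gold_pn = {(p.x, p.y): c for p, c in small_field.nuclei
               if c is not NucleusClass.OTHER}
    assert len(clusters) == len(gold_pn) == 100
    for n in clusters:
        key = (n.centroid.x, n.centroid.y)
        assert n.support == 10
        assert key in gold_pn
        assert n.label is gold_pn[key]
    assert consensus_positivity(clusters) == pytest.approx(
        small_field.positivity())
    report = match_to_gold(clusters, small_field)
    assert (report.true_positives, report.spurious, report.missed) == (100, 0, 0)
    assert report.label_agreement == pytest.approx(1.0)


def test_single_judgment_clusters_are_its_clicks():
    j = make_judgment([(10, 10, "P"), (200, 300, "N"), (400, 100, "P")])
    clusters = cluster_clicks([j])
    assert len(clusters) == 3
    assert all(n.support == 1 for n in clusters)
    assert {(n.centroid.x, n.centroid.y) for n in clusters} == {
        (10.0, 10.0), (200.0, 300.0), (400.0, 100.0)}


def test_two_judgments_shared_nucleus_merges_at_midpoint():
    a = make_judgment([(100, 100, "P")], worker_id="a")
    b = make_judgment([(104, 100, "P")], worker_id="b")
    clusters = cluster_clicks([a, b], ConsensusConfig(cluster_radius=15))
    assert len(clusters) == 1
    n = clusters[0]
    assert n.support == 2
    assert (n.centroid.x, n.centroid.y) == (102.0, 100.0)
    assert (n.positive_votes, n.negative_votes) == (2, 0)


def test_one_click_per_judgment_per_cluster():
    """A single worker's double-click cannot inflate support."""
    doubled = make_judgment([(100, 100, "P"), (103, 100, "P")], worker_id="a")
    other = make_judgment([(101, 101, "P")], worker_id="b")
    clusters = cluster_clicks([doubled, other])
    assert max(n.support for n in clusters) == 2  # not 3


def test_empty_pooled_clicks_give_empty_result():
    assert cluster_clicks([]) == []


def test_clustering_invariant_to_judgment_order():
    rng = np.random.default_rng(0)
    judgments = []
    for w in range(5):
        spec = [(int(rng.integers(0, 700)), int(rng.integers(0, 1000)),
                 "P" if rng.random() < 0.4 else "N") for _ in range(30)]
        judgments.append(make_judgment(spec, worker_id=f"w{w}"))
    forward = cluster_clicks(judgments)
    backward = cluster_clicks(judgments[::-1])
    key = lambda n: (n.centroid.y, n.centroid.x)
    assert sorted([(key(n), n.support) for n in forward]) == \
        sorted([(key(n), n.support) for n in backward])


def test_cluster_rejects_mixed_images():
    a = make_judgment([(1, 1, "P")], image_id="x")
    b = make_judgment([(1, 1, "P")], image_id="y")
    with pytest.raises(ValueError, match="different images"):
        cluster_clicks([a, b])


def _nucleus(x, y, support, pos):
    return ConsensusNucleus(Point(float(x), float(y)), support, pos,
                            support - pos)


def test_support_threshold_filtering_and_monotonicity():
    nuclei = [_nucleus(i * 50, 0, s, s) for i, s in enumerate([1, 3, 5, 10])]
    assert apply_support_threshold(nuclei, 1) == nuclei
    assert apply_support_threshold(nuclei, 4) == nuclei[2:]
    assert apply_support_threshold(nuclei, 11) == []
    prev = nuclei
    for m in range(1, 12):
        cur = apply_support_threshold(nuclei, m)
        assert set(id(n) for n in cur) <= set(id(n) for n in prev)
        prev = cur


def test_match_to_gold_radius_and_other_exclusion(canvas):
    from crowdihc import GoldAnnotation
    gold = GoldAnnotation("im", canvas, [
        (Point(100, 100), NucleusClass.POSITIVE),
        (Point(300, 300), NucleusClass.OTHER),
    ])
    near = [_nucleus(103, 100, 5, 5)]
    rep = match_to_gold(near, gold)
    assert (rep.true_positives, rep.spurious, rep.missed) == (1, 0, 0)
    assert rep.label_agreement == pytest.approx(1.0)

    far = [_nucleus(130, 100, 5, 5)]
    rep = match_to_gold(far, gold)
    assert (rep.true_positives, rep.spurious, rep.missed) == (0, 1, 1)

    # sitting exactly on an "other" nucleus still counts as spurious
    on_other = [_nucleus(300, 300, 5, 0)]
    rep = match_to_gold(on_other, gold)
    assert (rep.true_positives, rep.spurious, rep.missed) == (0, 1, 1)


def test_match_empty_consensus(small_field):
    rep = match_to_gold([], small_field)
    assert rep.true_positives == 0
    assert rep.spurious == 0
    assert rep.missed == 100
    assert rep.label_agreement is None


def test_consensus_positivity_and_tie_rule():
    nuclei = [_nucleus(0, 0, 10, 8),   # positive majority
              _nucleus(50, 0, 10, 2),  # negative majority
              _nucleus(100, 0, 10, 5)]  # 5-5 tie -> negative
    assert [n.label.value for n in nuclei] == ["P", "N", "N"]
    assert consensus_positivity(nuclei) == pytest.approx(100 / 3)
    with pytest.raises(UndefinedStatisticError):
        consensus_positivity([])


def test_consensus_nucleus_vote_invariant():
    with pytest.raises(ValueError, match="sum"):
        ConsensusNucleus(Point(0, 0), support=3, positive_votes=1,
                         negative_votes=1)


def test_majority_consensus_reduces_spurious_versus_individuals():
    """With stromal confusion and spurious clicks present, majority-
    supported consensus yields far fewer spurious nuclei than the pool
    of all individual false clicks."""
    cfg = ConsensusConfig(cluster_radius=15)
    for seed in (1, 2, 3):
        gold = generate_field(FieldConfig(40, 60, 30, seed=seed))
        pool = tuple(
            WorkerProfile(f"w{i}", s_pos=0.9, s_neg=0.9, s_other=0.3,
                          confusion=0.02, fp_rate=3.0, jitter_sd=3.0)
            for i in range(10))
        judgments = simulate_crowd([gold], CrowdConfig(
            worker_pool=pool, n_judgments_per_image=10, seed=seed))
        targets = [p for p, c in gold.nuclei if c is not NucleusClass.OTHER]

        def is_false(click):
            return all(click.point.distance_to(t) > cfg.cluster_radius
                       for t in targets)

        individual_false = sum(
            sum(1 for c in j.clicks if is_false(c)) for j in judgments)
        clusters = cluster_clicks(judgments, cfg)
        kept = apply_support_threshold(clusters, 6)
        rep = match_to_gold(kept, gold, cfg)
        assert individual_false > 0
        assert rep.spurious < individual_false
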