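"""Synthetic field generation and the crowd worker error model."""

import numpy as np
import pytest

from crowdihc import (
    Canvas,
    CapacityError,
    CrowdConfig,
    FieldConfig,
    NucleusClass,
    PlacementError,
    WorkerProfile,
    generate_field,
    judgment_positivity,
    make_study_fields,
    make_worker_pool,
    perfect_worker,
    simulate_crowd,
    simulate_judgment,
)


def test_generate_field_counts_and_separation():
    cfg = FieldConfig(n_positive=10, n_negative=20, n_other=5, seed=1)
    gold = generate_field(cfg)
    assert len(gold.nuclei) == 35
    assert (gold.n_positive, gold.n_negative, gold.n_other) == (10, 20, 5)
    pts = [(p.x, p.y) for p, _ in gold.nuclei]
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            d = np.hypot(pts[i][0] - pts[j][0], pts[i][1] - pts[j][1])
            assert d >= cfg.min_separation
    assert all(gold.canvas.contains(p) for p, _ in gold.nuclei)


def test_generate_field_empty_and_deterministic():
    empty = generate_field(FieldConfig(0, 0, 0, seed=7))
    assert empty.nuclei == []
    a = generate_field(FieldConfig(10, 20, 5, seed=1))
    b = generate_field(FieldConfig(10, 20, 5, seed=1))
    assert a == b
    c = generate_field(FieldConfig(10, 20, 5, seed=2))
    assert a != c


def test_generate_field_infeasible_packing_raises():
    cfg = FieldConfig(n_positive=50, n_negative=50, canvas=Canvas(30, 30),
                      min_separation=20.0, seed=0)
    with pytest.raises(PlacementError, match="min_separation"):
        generate_field(cfg)


def test_worker_profile_validation():
    with pytest.raises(ValueError):
        WorkerProfile("w", s_pos=1.5)
    with pytest.raises(ValueError):
        WorkerProfile("w", fp_rate=-1)


def test_perfect_worker_reproduces_gold_exactly(small_field, perfect_crowd):
    gold_pn = {(p.x, p.y): c for p, c in small_field.nuclei
               if c is not NucleusClass.OTHER}
    for j in perfect_crowd:
        assert {(c.point.x, c.point.y): c.label for c in j.clicks} == gold_pn
        assert judgment_positivity(j) == pytest.approx(small_field.positivity())


def test_blind_worker_clicks_nothing(small_field):
    blind = WorkerProfile("b", s_pos=0, s_neg=0, s_other=0, confusion=0,
                          fp_rate=0)
    j = simulate_judgment(small_field, blind, seed=0)
    assert j.clicks == []


def test_simulate_judgment_requires_nonempty_gold():
    empty = generate_field(FieldConfig(0, 0, 0, seed=0))
    with pytest.raises(ValueError, match="empty gold"):
        simulate_judgment(empty, perfect_worker(), seed=0)


def test_clicks_stay_inside_canvas_under_heavy_jitter(small_field):
    wild = WorkerProfile("w", s_pos=1, s_neg=1, s_other=1, confusion=0,
                         fp_rate=10, jitter_sd=200.0)
    for seed in range(5):
        j = simulate_judgment(small_field, wild, seed=seed)
        assert all(small_field.canvas.contains(c.point) for c in j.clicks)


def test_worker_model_expectation_monte_carlo(small_field):
    """The closed-form mean positivity 100*s_pos*Np / (s_pos*Np +
    s_neg*Nn + s_other*No) matches simulation within 3 standard errors."""
    gold = generate_field(FieldConfig(80, 20, 30, seed=9))
    w = WorkerProfile("w", s_pos=0.8, s_neg=0.8, s_other=0.5, confusion=0.0,
                      fp_rate=0.0, jitter_sd=0.0)
    expected = 100.0 * 0.8 * 80 / (0.8 * 80 + 0.8 * 20 + 0.5 * 30)  # 67.368
    rng = np.random.default_rng(2024)
    vals = np.array([judgment_positivity(simulate_judgment(gold, w, rng))
                     for _ in range(2000)])
    se = vals.std(ddof=1) / np.sqrt(len(vals))
    assert abs(vals.mean() - expected) < 3 * se


def test_thinning_neutrality():
    """Equal detection of positives and negatives (no other-class clicks,
    no spurious clicks) leaves the expected positivity at gold."""
    gold = generate_field(FieldConfig(40, 60, 0, seed=11))
    w = WorkerProfile("w", s_pos=0.7, s_neg=0.7, s_other=0.0, confusion=0.0,
                      fp_rate=0.0, jitter_sd=0.0)
    rng = np.random.default_rng(7)
    vals = np.array([judgment_positivity(simulate_judgment(gold, w, rng))
                     for _ in range(2000)])
    se = vals.std(ddof=1) / np.sqrt(len(vals))
    assert abs(vals.mean() - gold.positivity()) < 3 * se


def test_other_clicks_bias_positivity_downward():
    """Counting stromal/lymphocyte nuclei as negative strictly lowers
    the expected positivity below gold — the reported bias direction."""
    gold = generate_field(FieldConfig(50, 50, 40, seed=13))
    w = WorkerProfile("w", s_pos=1.0, s_neg=1.0, s_other=0.5, confusion=0.0,
                      fp_rate=0.0, jitter_sd=0.0)
    rng = np.random.default_rng(3)
    vals = np.array([judgment_positivity(simulate_judgment(gold, w, rng))
                     for _ in range(500)])
    assert vals.mean() < gold.positivity()
    assert (vals <= gold.positivity()).all()


def test_simulate_crowd_design_and_determinism():
    golds = make_study_fields(n_images=13, seed=5)
    pool = tuple(make_worker_pool(28, seed=6))
    cfg = CrowdConfig(worker_pool=pool, n_judgments_per_image=10,
                      max_units_per_worker=13, seed=7)
    judgments = simulate_crowd(golds, cfg)
    assert len(judgments) == 130
    per_image = {}
    per_worker = {}
    for j in judgments:
        per_image.setdefault(j.image_id, []).append(j.worker_id)
        per_worker[j.worker_id] = per_worker.get(j.worker_id, 0) + 1
    for workers in per_image.values():
        assert len(workers) == 10
        assert len(set(workers)) == 10  # no worker judges an image twice
    assert max(per_worker.values()) <= 13
    assert simulate_crowd(golds, cfg) == judgments


def test_simulate_crowd_single_judgment():
    golds = make_study_fields(n_images=1, seed=1)
    cfg = CrowdConfig(worker_pool=(perfect_worker("solo"),),
                      n_judgments_per_image=1, seed=0)
    out = simulate_crowd(golds, cfg)
    assert len(out) == 1 and out[0].worker_id == "solo"


def test_simulate_crowd_capacity_errors():
    golds = make_study_fields(n_images=2, seed=1)
    # 12 workers x 1 unit each = 12 < 20 required judgments
    pool = tuple(make_worker_pool(12, seed=0))
    with pytest.raises(CapacityError, match="capacity"):
        simulate_crowd(golds, CrowdConfig(worker_pool=pool,
                                          n_judgments_per_image=10,
                                          max_units_per_worker=1, seed=0))
    with pytest.raises(CapacityError, match="distinct"):
        simulate_crowd(golds, CrowdConfig(worker_pool=pool[:5],
                                          n_judgments_per_image=10, seed=0))


def test_study_fields_positivity_spread():
    golds = make_study_fields(n_images=13, seed=0)
    ps = [g.positivity() for g in golds]
    assert len(golds) == 13
    assert ps == sorted(ps)
    assert ps[0] == pytest.approx(2.0, abs=1.0)
    assert ps[-1] == pytest.approx(80.0, abs=1.0)
    assert all(g.n_other > 0 for g in golds)
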