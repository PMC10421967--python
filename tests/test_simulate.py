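import numpy as np
import pytest

from ncoinfer import (
    Genome,
    MarkerModel,
    SimConfig,
    ValidationError,
    e1_grid,
    e2_grid,
    estimate_penetrance,
    simulate_dataset,
    synth_markers,
)
from ncoinfer.kernel import detection_function
from ncoinfer.lengthdist import NBComponent
from helpers import component


def test_density_marker_model_hits_target_spacing():
    g = Genome({"chr1": 10_000_000})
    mm = synth_markers(g, MarkerModel(spacing=1465.0), np.random.default_rng(0))
    gaps = np.diff(mm.get("P1", "chr1"))
    assert abs(gaps.mean() - 1465.0) / 1465.0 < 0.1


def test_clustered_marker_model_matches_mean_and_median():
    g = Genome({"chr1": 10_000_000})
    mm = synth_markers(
        g, MarkerModel(spacing=1465.0, median_spacing=754.0), np.random.default_rng(0)
    )
    gaps = np.diff(mm.get("P1", "chr1"))
    assert abs(gaps.mean() - 1465.0) / 1465.0 < 0.1
    assert abs(np.median(gaps) - 754.0) / 754.0 < 0.1


def test_allele_frequency_marker_model():
    g = Genome({"chr1": 1000})
    rng = np.random.default_rng(1)
    sites = tuple(range(1, 1001))
    # monomorphic sites are never informative
    mono = MarkerModel(sites=sites, freqs=tuple([0.0] * 500 + [1.0] * 500))
    with pytest.raises(ValidationError, match="empty marker set"):
        synth_markers(g, mono, rng)
    # f = 0.5 sites kept with probability 1/2
    half = MarkerModel(sites=sites, freqs=tuple([0.5] * 1000))
    kept = synth_markers(g, half, rng).get("P1", "chr1").size
    assert 400 < kept < 600


def test_simulated_tracts_respect_ground_truth():
    cfg = SimConfig(Genome({"chr1": 500_000}), MarkerModel(spacing=50.0),
                    (component(80.0, 0.25),), (1.0,), 0.6, n_tracts=200)
    res = simulate_dataset(cfg, seed=3)
    assert len(res.dataset.tracts) == 200
    assert res.n_events >= 200
    markers = res.dataset.markers.get("P1", "chr1")
    for tract, (comp_i, start, length) in zip(res.dataset.tracts, res.tract_events):
        lo, hi = start, start + length - 1
        assert all(lo <= pos <= hi for pos in tract.positions)
        inside = markers[(markers >= lo) & (markers <= hi)]
        assert set(tract.positions) <= set(int(v) for v in inside)


def test_simulation_is_deterministic():
    cfg = SimConfig(Genome({"chr1": 300_000}), MarkerModel(spacing=40.0),
                    (component(60.0, 0.25),), (1.0,), 1.0, n_tracts=100)
    a = simulate_dataset(cfg, seed=9)
    b = simulate_dataset(cfg, seed=9)
    assert a.n_events == b.n_events
    assert [t.positions for t in a.dataset.tracts] == [t.positions for t in b.dataset.tracts]


def test_dense_full_penetrance_tracts_equal_events():
    cfg = SimConfig(Genome({"chr1": 100_000}), MarkerModel(spacing=1.0),
                    (component(50.0, 0.25),), (1.0,), 1.0, n_tracts=150)
    res = simulate_dataset(cfg, seed=4)
    assert res.n_events == 150  # every event converts a marker
    for tract, (_, start, length) in zip(res.dataset.tracts, res.tract_events):
        assert tract.span == length  # span equals the true event length


def test_conversion_fraction_matches_penetrance():
    cfg = SimConfig(Genome({"chr1": 500_000}), MarkerModel(spacing=25.0),
                    (component(120.0, 0.25),), (1.0,), 0.5, n_tracts=400)
    res = simulate_dataset(cfg, seed=8)
    pen = estimate_penetrance(res.dataset.tracts, res.dataset.markers)
    se = np.sqrt(0.5 * 0.5 / pen.n_internal_markers)
    assert abs(pen.p - 0.5) < 4 * se


def test_detected_fraction_matches_kernel_prediction():
    """Cross-module: empirical detection rate vs sum_x D(x) f(x)."""
    comp = component(60.0, 0.25)
    cfg = SimConfig(Genome({"chr1": 400_000}), MarkerModel(spacing=100.0),
                    (comp,), (1.0,), 0.5, n_events=20_000)
    res = simulate_dataset(cfg, seed=12)
    from ncoinfer.lengthdist import detection_mass, truncation_point
    d = detection_function(res.dataset.markers, cfg.genome, 0.5,
                           truncation_point(comp))
    predicted = detection_mass(comp, d)
    observed = len(res.dataset.tracts) / res.n_events
    mc_se = np.sqrt(predicted * (1 - predicted) / res.n_events)
    assert abs(observed - predicted) < 3 * mc_se


def test_experiment_grids_have_published_shapes():
    e1 = e1_grid()
    assert len(e1) == 63  # 3 means x 7 variances x 3 penetrances
    assert {c.components[0].mean for c in e1} == {100.0, 300.0, 1000.0}
    assert all(c.n_tracts == 1000 for c in e1)
    ks = {round(c.components[0].variance / c.components[0].mean ** 2, 6) for c in e1}
    assert len(ks) == 7  # variance parameterised as mean^2 * k

    e2 = e2_grid()
    assert len(e2) == 147  # 7 x 7 variance pairs x 3 penetrances
    assert all(c.tracts_per_component == (1000, 1000) for c in e2)
    assert all({cc.mean for cc in c.components} == {100.0, 1000.0} for c in e2)


def test_stopping_rules_are_exclusive():
    g = Genome({"chr1": 1000})
    mm = MarkerModel(spacing=10.0)
    comp = (component(10.0, 0.25),)
    with pytest.raises(ValidationError, match="stopping rule"):
        SimConfig(g, mm, comp, (1.0,), 1.0, n_tracts=10, n_events=10)
    with pytest.raises(ValidationError, match="penetrance"):
        SimConfig(g, mm, comp, (1.0,), 1.5, n_tracts=10)


def test_undetectable_mixture_raises_after_event_cap():
    g = Genome({"chr1": 10_000})
    cfg = SimConfig(g, MarkerModel(positions=(5000,)),
                    (NBComponent(2.0, 1.0),), (1.0,), 1e-9, n_tracts=10)
    with pytest.raises(ValidationError, match="undetectable"):
        import ncoinfer.simulate as sim
        res = sim.synth_markers(g, cfg.marker_model, np.random.default_rng(0))
        sim.simulate_events(res, g, cfg.components, np.array([1.0]), 1e-9,
                            np.random.default_rng(0), n_tracts=10, max_events=50_000)
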