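import numpy as np
import pytest

from racert.race_algebra import equality_catalog
from racert.rt_io import write_rt_table
from racert.synthetic_observer import (
    FEATURE_DIMS,
    ResponseModel,
    ResponseSpec,
    RTMapping,
    SceneSpec,
    default_mapping,
    generate_dataset,
    generate_scene,
    inject_contamination,
    sample_race_rts,
    sample_rts,
    sample_trial,
    scenario_preset,
)

CAT = equality_catalog()


def test_presets_declare_expected_neurons():
    nc = scenario_preset("no_conjunction")
    assert set(nc.neurons) == {"C", "M", "O"}
    v1 = scenario_preset("v1_like")
    assert set(v1.neurons) == {"C", "M", "O", "CO", "MO"}  # CM scarce, CMO absent
    cmo = scenario_preset("cmo_present")
    assert "CMO" in cmo.neurons
    with pytest.raises(ValueError):
        scenario_preset("extrastriate")


def test_nontrivial_response_lists():
    v1 = scenario_preset("v1_like")
    # CO singleton drives C and O cells plus the CO cell (fully released)
    # and the MO cell through its orientation overlap
    assert len(v1.nontrivial_specs("CO")) == 4
    # CMO singleton drives every neuron type present
    assert len(v1.nontrivial_specs("CMO")) == 5
    nc = scenario_preset("no_conjunction")
    assert len(nc.nontrivial_specs("CO")) == 2
    assert len(nc.nontrivial_specs("C")) == 1
    # conjunction release ordering: full > partial on average
    full = v1.neurons["CO"][FEATURE_DIMS["CO"]]
    partial = v1.neurons["CO"][frozenset({"color"})]
    assert full.median > partial.median


def test_point_mass_responses_reproduce_deterministic_race():
    """With zero response variability the generator reduces to the
    deterministic race model: rt = floor + gain/max(levels)."""
    neurons = {
        "C": {FEATURE_DIMS["C"]: ResponseSpec(20.0, 0.0)},
        "O": {FEATURE_DIMS["O"]: ResponseSpec(25.0, 0.0)},
    }
    model = ResponseModel("custom", neurons, {})
    mapping = RTMapping(gain=6.0, floor=0.3)
    rng = np.random.default_rng(0)
    assert sample_trial(model, mapping, "C", rng) == pytest.approx(0.3 + 6.0 / 20.0)
    assert sample_trial(model, mapping, "CO", rng) == pytest.approx(0.3 + 6.0 / 25.0)
    # min(RT_C, RT_O) equals RT_CO exactly in the deterministic limit
    rt_c = sample_trial(model, mapping, "C", rng)
    rt_o = sample_trial(model, mapping, "O", rng)
    assert min(rt_c, rt_o) == pytest.approx(0.3 + 6.0 / 25.0)


def test_rts_exceed_floor_and_decrease_with_response_strength():
    v1 = scenario_preset("v1_like")
    mapping = default_mapping(v1)
    rng = np.random.default_rng(1)
    rts = sample_rts(v1, mapping, "CMO", 5000, rng)
    assert np.all(rts > mapping.floor)
    weak = sample_rts(v1, mapping, "C", 5000, rng)
    strong = sample_rts(v1, mapping, "C", 5000, rng, response_scale=1.5)
    assert strong.mean() < weak.mean()


def test_calibrated_single_feature_mean():
    for name in ("no_conjunction", "v1_like"):
        model = scenario_preset(name)
        mapping = default_mapping(model)
        rng = np.random.default_rng(2)
        pooled = np.concatenate([
            sample_rts(model, mapping, t, 20000, rng) for t in ("C", "M", "O")
        ])
        assert pooled.mean() == pytest.approx(0.6, abs=0.01)


def test_dataset_reproducibility_and_structure(tmp_path):
    model = scenario_preset("v1_like")
    a = generate_dataset(model, n_per_type=60, observers=3, seed=11)
    b = generate_dataset(model, n_per_type=60, observers=3, seed=11)
    fa, fb = tmp_path / "a.csv", tmp_path / "b.csv"
    write_rt_table(a, fa)
    write_rt_table(b, fb)
    assert fa.read_bytes() == fb.read_bytes()
    assert len(a) == 60 * 7 * 3
    per = a.df.groupby(["observer_id", "singleton", "scene_color"]).size()
    assert set(per) == {30}
    assert a.df.correct.all()
    assert (a.df.rt_seconds > 0.3).all()
    c = generate_dataset(model, n_per_type=60, observers=3, seed=12)
    assert not a.df.equals(c.df)


def test_facilitation_inequalities_under_v1_like(v1_like_model):
    """Conjunction cells make the double-feature singleton faster than the
    race of its single-feature components."""
    mapping = default_mapping(v1_like_model)
    rng = np.random.default_rng(3)
    n = 30_000
    for pair, parts in [("CO", ("C", "O")), ("MO", ("M", "O"))]:
        rt_pair = sample_rts(v1_like_model, mapping, pair, n, rng)
        rt_race = sample_race_rts(v1_like_model, mapping, parts, n, rng)
        assert rt_pair.mean() < rt_race.mean() - 0.02


def test_no_conjunction_satisfies_double_feature_race(no_conjunction_model):
    from scipy.stats import ks_2samp

    mapping = default_mapping(no_conjunction_model)
    rng = np.random.default_rng(4)
    n = 20_000
    rt_co = sample_rts(no_conjunction_model, mapping, "CO", n, rng)
    race = sample_race_rts(no_conjunction_model, mapping, ("C", "O"), n, rng)
    dkw = np.sqrt(np.log(2 / 0.05) / 2) * 2 / np.sqrt(n)
    assert ks_2samp(rt_co, race).statistic < dkw


def test_contamination_counts_and_identity():
    model = scenario_preset("no_conjunction")
    ds = generate_dataset(model, n_per_type=100, observers=1, seed=5)
    assert inject_contamination(ds) is ds
    rng = np.random.default_rng(6)
    cont = inject_contamination(ds, fast_guess_rate=0.05, error_rate=0.1,
                                slow_outlier_rate=0.02, rng=rng)
    extra = len(cont) - len(ds)
    assert extra == 7 * (5 + 10 + 2)
    assert (cont.df.rt_seconds[~cont.df.correct.astype(bool)] > 0).all()
    with pytest.raises(ValueError):
        inject_contamination(ds, fast_guess_rate=1.5)


def test_scene_geometry():
    spec = SceneSpec()
    rng = np.random.default_rng(7)
    scene = generate_scene(spec, "CO", rng)
    items = scene["items"]
    assert len(items) == 660 == spec.n_items
    sing = items.loc[scene["singleton_index"]]
    bg = items.drop(index=scene["singleton_index"])
    assert bg["color"].nunique() == 1 and bg["orientation"].nunique() == 1
    assert sing["color"] != bg["color"].iloc[0]
    assert sing["orientation"] != bg["orientation"].iloc[0]
    assert sing["motion"] == bg["motion"].iloc[0]
    # singleton sits near the requested eccentricity
    ecc = np.hypot(sing["x_deg"], sing["y_deg"])
    assert abs(ecc - spec.eccentricity_deg) < 2.5
    # determinism
    s2 = generate_scene(spec, "CO", np.random.default_rng(7))
    assert s2["items"].equals(items)
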