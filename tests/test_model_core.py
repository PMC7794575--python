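"""Unit tests for the pool/process model and the tracer integrator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from soilntrace.model_core import (
    NAT_ABUNDANCE_ATOM_PCT,
    POOLS,
    PROCESS_IDS,
    PROCESS_TOPOLOGY,
    ExperimentDesign,
    IsotopePool,
    ModelStructure,
    Parameter,
    ParameterSet,
    ProcessSpec,
    TracerObservationSet,
    default_structure,
    derivatives,
    initial_state_from_design,
    predict_dataset,
    predict_observables,
    process_rate,
    simulate,
)

from conftest import NA_FRAC, make_state, single_process


# -- kinetics ----------------------------------------------------------------


@pytest.mark.parametrize(
    "order,params,substrate,expected",
    [
        ("zero", {"k": 2.0}, 5.0, 2.0),
        ("zero", {"k": 2.0}, 0.0, 0.0),  # substrate limit clips zero order
        ("first", {"k": 0.1}, 20.0, 2.0),
        ("first", {"k": 0.0}, 20.0, 0.0),
        ("michaelis_menten", {"vmax": 10.0, "km": 20.0}, 20.0, 5.0),  # half saturation
        ("michaelis_menten", {"vmax": 10.0, "km": 20.0}, 0.0, 0.0),
    ],
)
def test_process_rate_kinetic_forms(order, params, substrate, expected):
    assert process_rate(order, params, substrate) == pytest.approx(expected)


def test_process_rate_contract_violations():
    with pytest.raises(ValueError):
        process_rate("first", {"k": 0.1}, -1.0)
    with pytest.raises(ValueError):
        process_rate("first", {"k": -0.1}, 1.0)
    with pytest.raises(ValueError):
        process_rate("cubic", {"k": 0.1}, 1.0)


# -- pool and state invariants ----------------------------------------------


def test_isotope_pool_bounds():
    p = IsotopePool(10.0, 0.098063)
    assert p.n15 == pytest.approx(0.98063)
    assert p.ape == pytest.approx(9.44, abs=1e-10)
    with pytest.raises(ValueError):
        IsotopePool(-1.0, 0.1)
    with pytest.raises(ValueError):
        IsotopePool(1.0, 1.5)


def test_process_spec_topology_fixed():
    spec = ProcessSpec("O_NH4", "first")
    assert (spec.source_pool, spec.sink_pool) == ("nh4", "no3")
    assert PROCESS_TOPOLOGY["D_NO3"] == ("no3", "nh4")
    assert PROCESS_TOPOLOGY["I_NO3"] == ("no3", "n_rec")
    assert PROCESS_TOPOLOGY["A_NH4"] == ("nh4", "nh4_ads")
    with pytest.raises(ValueError):
        ProcessSpec("X_NH4", "first")


# -- derivatives -------------------------------------------------------------


def test_derivatives_all_inactive_zero():
    model = ModelStructure(
        [ProcessSpec(pid, "first", active=False) for pid in PROCESS_IDS]
    )
    d = derivatives(make_state(), model, ParameterSet({}))
    assert all(v == (0.0, 0.0) for v in d.values())


def test_derivatives_single_flux_bookkeeping():
    model, pset = single_process("O_NH4", "first", k=0.5)
    state = make_state(nh4=20.0, nh4_frac=0.10)
    d = derivatives(state, model, pset)
    assert d["nh4"][0] == pytest.approx(-10.0)
    assert d["no3"][0] == pytest.approx(10.0)
    assert d["nh4"][1] == pytest.approx(-1.0)  # 15N routed at source enrichment
    assert d["no3"][1] == pytest.approx(1.0)
    assert d["n_lab"] == (0.0, 0.0)


@pytest.mark.parametrize("seed", range(5))
def test_derivatives_sums_vanish_random_configurations(seed):
    """Internal transfers only: total-N and 15N derivative sums are zero.

    Oracle: directly summing the per-process flux list must give zero by
    pairing, independent of the bookkeeping path."""
    rng = np.random.default_rng(seed)
    orders = rng.choice(["zero", "first", "michaelis_menten"], size=len(PROCESS_IDS))
    active = rng.random(len(PROCESS_IDS)) > 0.3
    model = ModelStructure(
        [ProcessSpec(pid, o, active=a) for pid, o, a in zip(PROCESS_IDS, orders, active)]
    )
    values = {}
    for spec in model.active:
        if spec.kinetic_order == "michaelis_menten":
            values[f"{spec.process_id}.vmax"] = rng.uniform(0.1, 5)
            values[f"{spec.process_id}.km"] = rng.uniform(1, 50)
        else:
            values[f"{spec.process_id}.k"] = rng.uniform(0.01, 2)
    pset = model.default_parameters(values=values, fit_n_lab=False)
    state = make_state(nh4=rng.uniform(1, 30), no3=rng.uniform(1, 30),
                       nh4_frac=rng.uniform(0.004, 0.1))
    d = derivatives(state, model, pset)
    assert abs(sum(v[0] for v in d.values())) < 1e-12
    assert abs(sum(v[1] for v in d.values())) < 1e-12


def test_derivatives_unknown_process_rejected():
    with pytest.raises(ValueError):
        derivatives(make_state(), [ProcessSpec("nonsense", "first")], ParameterSet({}))


# -- simulate: closed forms and properties -----------------------------------


def test_simulate_first_order_matches_exponential():
    model, pset = single_process("O_NH4", "first", k=0.5)
    state = make_state(nh4=20.0, no3=5.0)
    traj = simulate(model, pset, state, [0.5, 1.0, 2.0])
    expected_nh4 = 20.0 * np.exp(-0.5 * traj.times)
    assert np.allclose(traj.totals[:, 0], expected_nh4, rtol=1e-6)
    assert traj.totals[-1, 1] == pytest.approx(5.0 + 20.0 - 20.0 * np.exp(-1.0), rel=1e-6)


def test_simulate_zero_order_linear_before_exhaustion():
    model, pset = single_process("M_Nrec", "zero", k=3.0)
    state = make_state(nh4=2.0, n_rec=800.0)
    traj = simulate(model, pset, state, [0.5, 1.0, 2.0])
    assert np.allclose(traj.totals[:, 0], 2.0 + 3.0 * traj.times, atol=1e-8)


def test_simulate_empty_model_constant():
    model = ModelStructure([])
    state = make_state()
    traj = simulate(model, ParameterSet({}), state, [0.0, 1.0, 2.0])
    assert np.allclose(traj.totals, np.tile(state.totals(), (3, 1)))
    assert np.allclose(traj.n15, np.tile(state.n15(), (3, 1)))


def test_simulate_michaelis_menten_limits():
    """km -> 0 recovers the zero-order solution at rate vmax; km -> inf at
    fixed vmax/km recovers first order with k = vmax/km."""
    state = make_state(nh4=20.0)
    times = [0.5, 1.0, 2.0]

    mm_lo, p_lo = single_process("O_NH4", "michaelis_menten", vmax=3.0, km=1e-7)
    z, pz = single_process("O_NH4", "zero", k=3.0)
    t_mm = simulate(mm_lo, p_lo, state, times)
    t_z = simulate(z, pz, state, times)
    assert np.allclose(t_mm.totals, t_z.totals, rtol=1e-5)

    k = 0.5
    km = 1e6
    mm_hi, p_hi = single_process("O_NH4", "michaelis_menten", vmax=k * km, km=km)
    f, pf = single_process("O_NH4", "first", k=k)
    t_mm = simulate(mm_hi, p_hi, state, times)
    t_f = simulate(f, pf, state, times)
    assert np.allclose(t_mm.totals, t_f.totals, rtol=1e-4)


def test_simulate_step_halving_convergence():
    model = default_structure()
    pset = model.default_parameters(
        values={f"{s.process_id}.k": v for s, v in zip(model.active, np.linspace(0.05, 1.0, 10))},
        fit_n_lab=False,
    )
    state = make_state(nh4=22.0, no3=33.0, nh4_frac=0.08)
    t1 = simulate(model, pset, state, [2.0], dt=0.001)
    t2 = simulate(model, pset, state, [2.0], dt=0.0005)
    rel = np.abs(t1.totals - t2.totals) / np.maximum(np.abs(t2.totals), 1e-12)
    assert rel.max() < 1e-6


def test_simulate_substrate_exhaustion_keeps_pools_nonnegative():
    # zero-order sink far faster than the supply: source must stop at 0
    model, pset = single_process("O_NH4", "zero", k=100.0)
    state = make_state(nh4=5.0, no3=1.0)
    traj = simulate(model, pset, state, [0.5, 1.0, 2.0])
    assert (traj.totals >= 0.0).all()
    assert traj.totals[-1, 0] == pytest.approx(0.0, abs=1e-9)
    assert traj.totals[-1, 1] == pytest.approx(6.0, rel=1e-9)  # all NH4 moved to NO3


@given(st.integers(0, 1000))
@settings(max_examples=25, deadline=None)
def test_conservation_property(seed):
    """Closed system: both total N and total 15N are conserved along any
    trajectory of the full ten-process model."""
    rng = np.random.default_rng(seed)
    model = default_structure()
    values = {}
    for spec in model.active:
        hi = 3.0 if spec.kinetic_order == "zero" else 1.5
        values[f"{spec.process_id}.k"] = rng.uniform(0, hi)
    pset = model.default_parameters(values=values, fit_n_lab=False)
    state = make_state(nh4=rng.uniform(5, 30), no3=rng.uniform(5, 30),
                       nh4_frac=rng.uniform(0.004, 0.1))
    traj = simulate(model, pset, state, np.linspace(0.1, 2.0, 5))
    tot0, n15_0 = state.totals().sum(), state.n15().sum()
    assert np.abs(traj.totals.sum(axis=1) / tot0 - 1).max() < 1e-6
    assert np.abs(traj.n15.sum(axis=1) / n15_0 - 1).max() < 1e-6


@given(st.integers(0, 1000))
@settings(max_examples=15, deadline=None)
def test_enrichment_bounded_by_initial_range(seed):
    """Mixing cannot create enrichment: every pool's atom fraction stays
    within the [min, max] envelope of the initial pool fractions."""
    rng = np.random.default_rng(seed)
    model = default_structure()
    values = {f"{s.process_id}.k": rng.uniform(0.01, 0.8) for s in model.active}
    pset = model.default_parameters(values=values, fit_n_lab=False)
    state = make_state(nh4=20.0, no3=20.0, nh4_frac=rng.uniform(0.01, 0.1),
                       no3_frac=rng.uniform(0.004, 0.1), nh4_ads=1.0)
    f0 = [state.pool(p).frac15 for p in POOLS]
    traj = simulate(model, pset, state, np.linspace(0.1, 2.0, 5))
    f = traj.frac15()
    assert f.min() >= min(f0) - 1e-9
    assert f.max() <= max(f0) + 1e-9


# -- design -> initial state -------------------------------------------------


def test_initial_state_mixing_arithmetic():
    design = ExperimentDesign(soil_nh4=2.46, soil_no3=13.60)
    state = initial_state_from_design(design, "NH4_labelled")
    assert state.nh4.total_n == pytest.approx(22.46)
    # amendment APE diluted by the unlabelled soil background
    assert state.nh4.ape == pytest.approx(20 * 9.44 / 22.46, abs=1e-4)
    # the unlabelled species sits at natural abundance
    assert state.no3.ape == pytest.approx(0.0, abs=1e-12)
    assert state.no3.frac15 == pytest.approx(NA_FRAC)
    assert state.n_rec.frac15 == pytest.approx(NA_FRAC)
    assert state.nh4_ads.total_n == 0.0


def test_initial_state_no3_labelled_treatment():
    design = ExperimentDesign(soil_nh4=2.35, soil_no3=3.02)
    state = initial_state_from_design(design, "NO3_labelled")
    assert state.no3.ape == pytest.approx(20 * 9.75 / 23.02, abs=1e-4)
    assert state.nh4.ape == pytest.approx(0.0, abs=1e-12)


def test_initial_state_zero_amendment_is_background():
    design = ExperimentDesign(amendment_nh4=0.0, amendment_no3=0.0)
    state = initial_state_from_design(design, "NH4_labelled")
    assert state.nh4.total_n == pytest.approx(design.soil_nh4)
    assert state.nh4.frac15 == pytest.approx(NA_FRAC)
    assert state.no3.frac15 == pytest.approx(NA_FRAC)


def test_initial_state_closes_tn_balance():
    design = ExperimentDesign(soil_tn_g_kg=0.9, n_lab_init=50.0)
    state = initial_state_from_design(design, "NH4_labelled")
    organic = state.n_lab.total_n + state.n_rec.total_n
    assert organic + design.soil_nh4 + design.soil_no3 == pytest.approx(900.0)


# -- observables -------------------------------------------------------------


def test_predict_observables_units_and_count(design):
    model, pset = single_process("O_NH4", "first", k=0.2)
    preds = predict_dataset(model, pset, design)
    assert len(preds) == 16  # 2 treatments x 4 times x 2 pools
    # a pool at natural abundance has zero atom% excess
    no3_t0 = preds[(preds["treatment"] == "NH4_labelled") & (preds["pool"] == "NO3")]
    assert no3_t0["ape_mean"].iloc[0] < 0.6  # only slightly raised by O_NH4 influx


def test_ape_unit_conversion_identity():
    p = IsotopePool(1.0, 0.098063)
    assert p.ape == pytest.approx(9.44, abs=1e-6)


def test_predict_observables_requires_sampling_times(design):
    model, pset = single_process("O_NH4", "first", k=0.2)
    state = initial_state_from_design(design, "NH4_labelled")
    traj = simulate(model, pset, state, [0.5])  # lacks the design times
    with pytest.raises(KeyError):
        predict_observables(traj, design, "NH4_labelled")


# -- observation set validation ----------------------------------------------


def _obs_frame():
    import pandas as pd

    rows = []
    for tr in ("NH4_labelled", "NO3_labelled"):
        for t in (0.5, 12.0, 24.0, 48.0):
            for pool in ("NH4", "NO3"):
                rows.append(
                    dict(treatment=tr, time_h=t, pool=pool, conc_mean=10.0,
                         conc_sd=0.5, ape_mean=1.0, ape_sd=0.05)
                )
    return pd.DataFrame(rows)


def test_observation_set_roundtrip_and_keys():
    frame = _obs_frame()
    obs = TracerObservationSet(frame)
    assert len(obs) == 16
    dup = frame.copy()
    dup.loc[len(dup)] = dup.iloc[3]
    with pytest.raises(ValueError, match="duplicate"):
        TracerObservationSet(dup)


def test_observation_set_rejects_bad_rows():
    bad = _obs_frame()
    bad.loc[0, "conc_mean"] = -1.0
    with pytest.raises(ValueError, match="row 1"):
        TracerObservationSet(bad)
    bad = _obs_frame()
    bad.loc[2, "pool"] = "N2O"
    with pytest.raises(ValueError, match="row 3"):
        TracerObservationSet(bad)


def test_observation_set_flags_small_negative_ape():
    frame = _obs_frame()
    frame.loc[5, "ape_mean"] = -0.1  # within measurement-noise tolerance
    obs = TracerObservationSet(frame)
    assert obs.flagged_negative_ape == [5]
    frame.loc[5, "ape_mean"] = -2.0
    with pytest.raises(ValueError):
        TracerObservationSet(frame)


def test_design_validation():
    with pytest.raises(ValueError):
        ExperimentDesign(sampling_times_h=(12.0, 0.5))
    with pytest.raises(ValueError):
        ExperimentDesign(replicates=0)
    with pytest.raises(ValueError):
        ExperimentDesign(enrichment_nh4=0.0)
    with pytest.raises(ValueError):
        ExperimentDesign(soil_nh4=float("nan"))
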