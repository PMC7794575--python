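"""Synthetic tracer datasets and soil cohorts from known ground truth.

Two generators make every other module testable without any download:

* :func:`generate_tracer_dataset` simulates both labelling treatments of the
  paired 15NH4NO3 / NH415NO3 incubation design (20 mg N kg^-1 amendments of
  each inorganic species at 9.44 / 9.75 atom% excess, sampling at
  0.5/12/24/48 h, 3 replicates) at known parameters and draws replicate
  measurements with Gaussian noise (truncated at the physical bounds),
  emitting per-record replicate means and sds — the shape real IRMS data
  arrive in.

* :func:`generate_cohort` draws a two-land-use cohort (11 forestland,
  8 cropland soils) whose soil properties are Gaussian around the study-area
  group means and whose true 48-h average gross rates are centred on the
  reported group means.  Rate targets are drawn lognormally (mean-exact,
  strictly positive); within-group couplings tie NH4+ immobilization
  positively and autotrophic nitrification negatively to SOC, so
  cohort-level correlation signs match the field contrast.  True rate
  parameters are back-solved so each soil's 48-h average rates match its
  drawn targets (to a 2% tolerance; targets beyond the substrate-supply
  ceiling of the closed incubation are capped, with both target and achieved
  rates stored).

Dispersions: the study reports group means +/- standard errors; per-soil
sds here are SE * sqrt(n), cross-checked against the reported ranges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .inference import GrossRates, average_rates
from .model_core import (
    DEFAULT_DT,
    PROCESS_IDS as _PROCESS_IDS,
    ExperimentDesign,
    ModelStructure,
    Parameter,
    ParameterSet,
    ProcessSpec,
    TracerObservationSet,
    initial_state_from_design,
    predict_dataset,
    simulate,
)
from .indices import derive_indices

__all__ = [
    "NoiseModel",
    "SoilTruth",
    "GROUP_STATS",
    "generate_tracer_dataset",
    "generate_cohort",
    "cohort_to_frame",
    "back_solve_parameters",
    "land_use_truth",
    "recovery_structure",
    "design_for",
    "toy_runoff_events",
]

_MAX_REDRAWS = 100


@dataclass(frozen=True)
class NoiseModel:
    """Replicate-level measurement error: relative sd of concentration
    readings and absolute sd of atom%-excess readings.  (The study reports no
    instrument error model; these defaults are stated assumptions.)"""

    conc_cv: float = 0.03
    ape_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.conc_cv < 0 or self.ape_sd < 0:
            raise ValueError("noise parameters must be >= 0")


#: per-land-use generator centres: (mean, per-soil sd).  Soil properties and
#: the six reported rate aggregates come from the study's group summaries
#: (sd = SE * sqrt(n), n = 11 forestland / 8 cropland); O_Nrec, I_NO3 and
#: D_NO3 centres are small values consistent with "negligible" heterotrophic
#: nitrification and DNRA, identical across land uses.
GROUP_STATS: dict[str, dict] = {
    "forestland": {
        "n": 11,
        "ph": (7.85, 0.199),
        "soc": (22.91, 4.544),  # g kg^-1
        "tn": (1.45, 0.431),  # g kg^-1
        "nh4": (2.35, 0.232),  # mg N kg^-1
        "no3": (3.02, 0.265),
        "M_N": (3.95, 1.691),  # mg N kg^-1 day^-1
        "I_NH4": (6.67, 2.454),
        "O_NH4": (1.99, 1.857),
        "O_Nrec": (0.01, 0.005),
        "I_NO3": (0.5, 0.30),
        "D_NO3": (0.1, 0.08),
    },
    "cropland": {
        "n": 8,
        "ph": (7.83, 0.085),
        "soc": (8.90, 3.422),
        "tn": (0.90, 0.198),
        "nh4": (2.46, 0.509),
        "no3": (13.60, 1.442),
        "M_N": (4.84, 1.952),
        "I_NH4": (0.34, 0.283),
        "O_NH4": (14.54, 4.695),
        "O_Nrec": (0.01, 0.005),
        "I_NO3": (0.5, 0.30),
        "D_NO3": (0.1, 0.08),
    },
}

#: within-group correlation between SOC and the coupled rates.
_SOC_RATE_RHO = {"I_NH4": 0.6, "O_NH4": -0.6}


@dataclass
class SoilTruth:
    """Ground truth for one synthetic soil: properties, kinetic structure and
    parameters, and the implied true 48-h average gross rates."""

    land_use: str
    ph: float
    soc: float  # g kg^-1
    tn: float  # g kg^-1
    cn: float  # recomputed as soc/tn, never drawn independently
    nh4: float  # mg N kg^-1
    no3: float
    structure: ModelStructure
    parameters: ParameterSet | None
    rates: GrossRates  # drawn target rates
    sample_id: str = ""
    #: rates actually achieved by the back-solved parameters; differs from
    #: ``rates`` only when a drawn target exceeded the 48-h substrate-supply
    #: ceiling of the amended incubation and was capped.
    rates_achieved: GrossRates | None = None

    def __post_init__(self) -> None:
        for name in ("ph", "soc", "tn", "cn", "nh4", "no3"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if abs(self.cn - self.soc / self.tn) > 0.01 * self.cn:
            raise ValueError("C/N inconsistent with SOC/TN beyond 1%")


def design_for(truth: SoilTruth, **overrides) -> ExperimentDesign:
    """The incubation design for one soil: defaults plus that soil's measured
    inorganic N and TN backgrounds."""
    kwargs = {
        "soil_nh4": truth.nh4,
        "soil_no3": truth.no3,
        "soil_tn_g_kg": truth.tn,
        "n_lab_init": 0.0,
    }
    kwargs.update(overrides)
    return ExperimentDesign(**kwargs)


# --------------------------------------------------------------------------
# Rate -> parameter back-solving
# --------------------------------------------------------------------------


def _average_rate(
    structure: ModelStructure,
    params: ParameterSet,
    design: ExperimentDesign,
    process_id: str,
    horizon_d: float,
    dt: float,
) -> float:
    state0 = initial_state_from_design(design, "NH4_labelled")
    traj = simulate(structure, params, state0, [horizon_d], dt=dt)
    return float(traj.flux_integrals[-1][traj.process_ids.index(process_id)] / horizon_d)


def back_solve_parameters(
    structure: ModelStructure,
    targets: Mapping[str, float],
    design: ExperimentDesign,
    params0: ParameterSet | None = None,
    horizon_h: float = 48.0,
    dt: float = 0.01,
    max_sweeps: int = 12,
    rtol: float = 1e-5,
    k_max: float = 50.0,
    on_unreachable: str = "raise",
) -> ParameterSet:
    """Solve rate parameters so each targeted process attains its requested
    48-h average rate.

    Deterministic Gauss-Seidel over processes: each sweep root-finds (Brent)
    the 1-D map k -> average rate of that process with all other parameters
    held, iterated until every achieved rate matches its target to ``rtol``.
    Zero-order processes whose substrate never exhausts are exact in one
    assignment (average rate = k).  Only single-parameter kinetics (zero /
    first order) are back-solved; Michaelis-Menten processes must be given
    fixed parameters via ``params0``.

    A closed amended incubation caps every consuming process at its substrate
    supply: a first-order rate constant beyond ``k_max`` (day^-1) cannot raise
    the 48-h average further in any practically distinguishable way.  When a
    target exceeds that ceiling, ``on_unreachable='raise'`` (default) errors;
    ``'cap'`` pins the rate constant at ``k_max`` and achieves the
    supply-limited maximum instead (callers can compare achieved vs target).
    """
    if on_unreachable not in ("raise", "cap"):
        raise ValueError("on_unreachable must be 'raise' or 'cap'")
    params = params0 if params0 is not None else structure.default_parameters(fit_n_lab=False)
    horizon_d = horizon_h / 24.0
    for pid, target in targets.items():
        spec = structure.spec(pid)
        if target < 0:
            raise ValueError(f"negative target rate for {pid}")
        if spec.kinetic_order == "michaelis_menten":
            raise ValueError(
                f"{pid}: Michaelis-Menten processes cannot be back-solved from "
                f"a single average-rate target"
            )

    def set_k(p: ParameterSet, pid: str, k: float) -> ParameterSet:
        name = f"{pid}.k"
        old = p[name]
        return ParameterSet(
            {**dict(p.items()), name: Parameter(k, old.lower, max(old.upper, k * 2 + 1.0))}
        )

    capped: set[str] = set()
    for sweep in range(max_sweeps):
        capped.clear()
        for pid, target in targets.items():
            spec = structure.spec(pid)
            if target == 0.0:
                params = set_k(params, pid, 0.0)
                continue
            if spec.kinetic_order == "zero":
                params = set_k(params, pid, target)
                continue

            def gap(k: float, pid=pid) -> float:
                trial = set_k(params, pid, k)
                return _average_rate(structure, trial, design, pid, horizon_d, dt) - target

            hi = min(max(target / 10.0, 1e-3), k_max)
            g_hi = gap(hi)
            while g_hi < 0.0 and hi < k_max:
                hi = min(hi * 2.0, k_max)
                g_hi = gap(hi)
            if g_hi < 0.0:
                if on_unreachable == "raise":
                    raise ValueError(
                        f"{pid}: target average rate {target:.4g} is unreachable "
                        f"within the 48-h substrate supply (max "
                        f"{target + g_hi:.4g} at k = {k_max})"
                    )
                capped.add(pid)
                params = set_k(params, pid, k_max)
                continue
            k = brentq(gap, 0.0, hi, xtol=1e-12, rtol=1e-12)
            params = set_k(params, pid, float(k))
        achieved = {
            pid: _average_rate(structure, params, design, pid, horizon_d, dt)
            for pid in targets
        }
        worst = max(
            (
                abs(achieved[pid] - t) / max(abs(t), 1e-9) if t > 0 else abs(achieved[pid])
            )
            for pid, t in targets.items()
            if pid not in capped
        )
        if worst < rtol:
            return params
    raise RuntimeError(
        f"back-solve did not converge in {max_sweeps} sweeps (worst relative "
        f"gap {worst:.3g})"
    )


# --------------------------------------------------------------------------
# Reference truths for the two land uses (reduced, identifiable structure)
# --------------------------------------------------------------------------


def recovery_structure() -> ModelStructure:
    """The reduced five-process structure used for parameter-recovery
    exercises: total mineralization carried by M_Nrec (zero order), NH4+
    immobilization by I_NH4_Nrec (first order), plus first-order O_NH4,
    I_NO3 and D_NO3.  With 4 sampling times x 2 pools x 2 treatments x 2
    observable kinds it is well identified, unlike the full ten-process
    network."""
    return ModelStructure(
        [
            ProcessSpec("M_Nrec", "zero"),
            ProcessSpec("I_NH4_Nrec", "first"),
            ProcessSpec("O_NH4", "first"),
            ProcessSpec("I_NO3", "first"),
            ProcessSpec("D_NO3", "first"),
        ]
    )


def land_use_truth(land_use: str, structure: ModelStructure | None = None) -> SoilTruth:
    """A deterministic reference soil for each land use: properties at the
    group means and true rates at the reported group-mean aggregates
    (M_N / I_NH4 / O_NH4 plus the small NO3--consuming processes), with
    parameters back-solved on the reduced recovery structure."""
    if land_use not in GROUP_STATS:
        raise ValueError(f"unknown land use {land_use!r}")
    g = GROUP_STATS[land_use]
    structure = structure or recovery_structure()
    targets = {
        "M_Nrec": g["M_N"][0],
        "I_NH4_Nrec": g["I_NH4"][0],
        "O_NH4": g["O_NH4"][0],
        "I_NO3": g["I_NO3"][0],
        "D_NO3": g["D_NO3"][0],
    }
    truth = SoilTruth(
        land_use=land_use,
        ph=g["ph"][0],
        soc=g["soc"][0],
        tn=g["tn"][0],
        cn=g["soc"][0] / g["tn"][0],
        nh4=g["nh4"][0],
        no3=g["no3"][0],
        structure=structure,
        parameters=None,
        rates=GrossRates({k: v for k, v in targets.items()}),
        sample_id=f"{land_use}-ref",
    )
    design = design_for(truth)
    truth.parameters = back_solve_parameters(structure, targets, design)
    return truth


# --------------------------------------------------------------------------
# Tracer dataset generation
# --------------------------------------------------------------------------


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lower: float
) -> float:
    if sd == 0.0:
        if mean < lower:
            raise ValueError("noise-free value below physical bound")
        return mean
    for _ in range(_MAX_REDRAWS):
        v = rng.normal(mean, sd)
        if v >= lower:
            return v
    raise RuntimeError(
        f"could not draw a value >= {lower} around {mean} +/- {sd} in "
        f"{_MAX_REDRAWS} attempts"
    )


def generate_tracer_dataset(
    truth: SoilTruth,
    design: ExperimentDesign | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> tuple[TracerObservationSet, dict]:
    """Simulate both treatments at the true parameters and emit noisy
    replicate means +/- sds per (treatment, time, pool) record, plus the
    stored truth (parameters, rates, seed) for round-trip checks.

    Concentration replicates are Gaussian with cv ``noise.conc_cv`` truncated
    at 0; APE replicates Gaussian with sd ``noise.ape_sd`` truncated at
    -natural abundance.  Identical seeds give identical output.
    """
    if truth.parameters is None:
        raise ValueError("truth has no parameters; back-solve them first")
    design = design if design is not None else design_for(truth)
    noise = noise if noise is not None else NoiseModel()
    rng = np.random.default_rng(seed)

    clean = predict_dataset(truth.structure, truth.parameters, design, dt=DEFAULT_DT)
    rows = []
    for _, rec in clean.iterrows():
        conc_true, ape_true = rec["conc_mean"], rec["ape_mean"]
        conc_reps = [
            _truncated_normal(rng, conc_true, noise.conc_cv * conc_true, 0.0)
            for _ in range(design.replicates)
        ]
        ape_reps = [
            _truncated_normal(rng, ape_true, noise.ape_sd, -design.natural_abundance)
            for _ in range(design.replicates)
        ]
        conc_reps = np.asarray(conc_reps)
        ape_reps = np.asarray(ape_reps)

        def _sd(reps: np.ndarray, noiseless: bool) -> float:
            if design.replicates < 2 or noiseless:
                return 0.0
            return float(reps.std(ddof=1))

        rows.append(
            {
                "treatment": rec["treatment"],
                "time_h": rec["time_h"],
                "pool": rec["pool"],
                "conc_mean": float(conc_reps.mean()),
                "conc_sd": _sd(conc_reps, noise.conc_cv == 0.0),
                "ape_mean": float(ape_reps.mean()),
                "ape_sd": _sd(ape_reps, noise.ape_sd == 0.0),
            }
        )
    obs = TracerObservationSet(pd.DataFrame(rows))
    stored_truth = {
        "seed": int(seed),
        "land_use": truth.land_use,
        "parameters": {k: p.value for k, p in truth.parameters.items()},
        "rates": {pid: truth.rates.rate(pid) for pid in _PROCESS_IDS},
        "noise": {"conc_cv": noise.conc_cv, "ape_sd": noise.ape_sd},
    }
    return obs, stored_truth


# --------------------------------------------------------------------------
# Cohort generation
# --------------------------------------------------------------------------


def _lognormal_exact_mean(
    rng_z: float, mean: float, sd: float
) -> float:
    """Value of a lognormal with the requested arithmetic mean and sd,
    evaluated at standard-normal deviate ``rng_z`` (mean-exact, > 0)."""
    cv2 = (sd / mean) ** 2
    sigma2 = math.log1p(cv2)
    mu = math.log(mean) - 0.5 * sigma2
    return math.exp(mu + math.sqrt(sigma2) * rng_z)


def generate_cohort(
    n_forest: int = 11,
    n_crop: int = 8,
    seed: int = 0,
    solve_parameters: bool = True,
) -> list[SoilTruth]:
    """Draw the two-land-use cohort.

    Soil properties: Gaussian around the group centres (redrawn when a draw
    falls at or below zero, at most 100 attempts); C/N recomputed as SOC/TN.
    Rates: lognormal with arithmetic mean equal to the group centre; I_NH4
    couples positively and O_NH4 negatively to the soil's within-group SOC
    z-score.  ``solve_parameters=False`` skips the (slower) rate-to-parameter
    back-solving when only properties/rates are needed, e.g. for cohort
    statistics.
    """
    if n_forest < 2 or n_crop < 2:
        raise ValueError("group sizes must be >= 2")
    rng = np.random.default_rng(seed)
    soils: list[SoilTruth] = []
    for land_use, n in (("forestland", n_forest), ("cropland", n_crop)):
        g = GROUP_STATS[land_use]
        for i in range(n):
            ph = _truncated_normal(rng, *g["ph"], 1e-6)
            soc = _truncated_normal(rng, *g["soc"], 1e-6)
            tn = _truncated_normal(rng, *g["tn"], 1e-6)
            nh4 = _truncated_normal(rng, *g["nh4"], 1e-6)
            no3 = _truncated_normal(rng, *g["no3"], 1e-6)
            z_soc = (soc - g["soc"][0]) / g["soc"][1]

            def rate_draw(key: str) -> float:
                mean, sd = g[key]
                rho = _SOC_RATE_RHO.get(key, 0.0)
                z = rho * z_soc + math.sqrt(1.0 - rho * rho) * rng.standard_normal()
                return _lognormal_exact_mean(z, mean, sd)

            totals = {key: rate_draw(key) for key in ("M_N", "I_NH4", "O_NH4", "O_Nrec", "I_NO3", "D_NO3")}
            # split the aggregates over their component processes (even split)
            targets = {
                "M_Nlab": 0.5 * totals["M_N"],
                "M_Nrec": 0.5 * totals["M_N"],
                "I_NH4_Nlab": 0.5 * totals["I_NH4"],
                "I_NH4_Nrec": 0.5 * totals["I_NH4"],
                "O_NH4": totals["O_NH4"],
                "O_Nrec": totals["O_Nrec"],
                "I_NO3": totals["I_NO3"],
                "D_NO3": totals["D_NO3"],
            }
            truth = SoilTruth(
                land_use=land_use,
                ph=ph,
                soc=soc,
                tn=tn,
                cn=soc / tn,
                nh4=nh4,
                no3=no3,
                structure=_cohort_structure(),
                parameters=None,
                rates=GrossRates(targets),
                sample_id=f"{land_use[:4]}-{i + 1:02d}",
            )
            if solve_parameters:
                design = design_for(truth, n_lab_init=40.0)
                params0 = truth.structure.default_parameters(
                    values={"A_NH4.k": 0.5, "R_NH4.k": 0.5}, fit_n_lab=False
                )
                truth.parameters = back_solve_parameters(
                    truth.structure, targets, design, params0=params0,
                    on_unreachable="cap", max_sweeps=30, rtol=0.02,
                )
                truth.rates_achieved = average_rates(
                    truth.structure, [truth.parameters], design, dt=0.01
                )
            soils.append(truth)
    return soils


def _cohort_structure() -> ModelStructure:
    """Full ten-process default structure used for cohort truths; the NH4+
    adsorption/release pair runs at fixed small rate constants (it is not a
    reported aggregate)."""
    from .model_core import default_structure

    return default_structure()


def cohort_to_frame(soils: Sequence[SoilTruth]) -> pd.DataFrame:
    """Tidy cohort table: one row per soil with land use, properties, true
    rates (component processes plus M_N / I_NH4 totals) and derived indices."""
    rows = []
    for s in soils:
        row = {
            "sample_id": s.sample_id,
            "land_use": s.land_use,
            "ph": s.ph,
            "soc_g_kg": s.soc,
            "tn_g_kg": s.tn,
            "cn": s.cn,
            "nh4_mg_kg": s.nh4,
            "no3_mg_kg": s.no3,
        }
        for pid in _PROCESS_IDS:
            row[pid] = s.rates.rate(pid)
        row["M_N"] = s.rates.m_n
        row["I_NH4"] = s.rates.i_nh4
        idx = derive_indices(s.rates, nh4_conc=s.nh4, no3_conc=s.no3)
        row.update(idx.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def toy_runoff_events(seed: int = 0, land_use: str = "cropland") -> pd.DataFrame:
    """A small synthetic runoff-event table (monsoon-weighted) in the events
    CSV layout, for exercising the flux module end to end."""
    rng = np.random.default_rng(seed)
    n_events = 7 if land_use == "cropland" else 6
    pathway_cycle = (
        ["interflow", "overland"] if land_use == "cropland" else ["whole-catchment"]
    )
    conc_scale = 12.0 if land_use == "cropland" else 0.4
    rows = []
    for i in range(n_events):
        month = int(rng.integers(5, 10))
        day = int(rng.integers(1, 28))
        rows.append(
            {
                "date": f"2016-{month:02d}-{day:02d}",
                "pathway": pathway_cycle[i % len(pathway_cycle)],
                "c_mg_per_L": round(float(rng.gamma(4.0, conc_scale / 4.0)), 3),
                "q_mm": round(float(rng.gamma(2.0, 15.0)), 2),
            }
        )
    return pd.DataFrame(rows)
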