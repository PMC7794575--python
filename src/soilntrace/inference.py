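"""Parameter estimation for the tracer model.

The fitting targets are the replicate means +/- standard deviations of
NH4+/NO3- concentration and 15N atom% excess from both labelling treatments,
fitted jointly with one shared parameter set per soil.  The misfit

    J(theta) = sum_records [ (predicted - mean) / sd ]^2

over both observable kinds is interpreted as -2 log likelihood up to an
additive constant (independent Gaussians with known sds), which makes the
Metropolis acceptance rule ``min(1, exp(-(J' - J)/2))`` and the model-choice
score ``AIC = J_best + 2 p`` a coherent triple.  The prior is the uniform box
defined by the parameter bounds: proposals outside it are rejected.

Random-walk Metropolis with per-parameter Gaussian proposals; the proposal
scale is adapted toward a 20-45% acceptance rate during burn-in only and
frozen afterwards, preserving detailed balance for the retained draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model_core import (
    DEFAULT_DT,
    NAT_ABUNDANCE_ATOM_PCT,
    ExperimentDesign,
    ModelStructure,
    ParameterSet,
    PROCESS_IDS,
    TracerObservationSet,
    SimulationError,
    _encode,
    _integrate,
    initial_state_from_design,
    _state_vector,
)

__all__ = [
    "CONC_SD_FLOOR_ABS",
    "CONC_SD_FLOOR_REL",
    "APE_SD_FLOOR",
    "TracerMisfit",
    "misfit",
    "MCMCResult",
    "metropolis_sample",
    "compute_aic",
    "ModelSelection",
    "select_model",
    "GrossRates",
    "average_rates",
    "TracerFit",
    "fit_tracer_model",
]

#: sd floors guarding against infinite weights from zero replicate variance.
CONC_SD_FLOOR_ABS = 0.05  # mg N kg^-1
CONC_SD_FLOOR_REL = 0.02  # fraction of the mean
APE_SD_FLOOR = 0.02  # atom% excess

#: default integration step used inside the misfit during fitting (days).
#: Coarser than the reporting grid; RK4 keeps the induced error orders of
#: magnitude below measurement noise at these rate scales.
FIT_DT = 0.01


# --------------------------------------------------------------------------
# Misfit
# --------------------------------------------------------------------------


class TracerMisfit:
    """Callable weighted sum-of-squares misfit J(theta) for one soil.

    Precompiles the observation table and process encoding so repeated
    evaluation inside the sampler is cheap.  ``theta`` follows the order of
    ``params_template.names``.
    """

    def __init__(
        self,
        model: ModelStructure,
        params_template: ParameterSet,
        design: ExperimentDesign,
        observations: TracerObservationSet,
        dt: float = FIT_DT,
        apply_sd_floors: bool = True,
    ):
        if len(observations) == 0:
            raise ValueError("observations must be non-empty")
        self.model = model
        self.template = params_template
        self.design = design
        self.observations = observations
        self.dt = float(dt)

        names = list(params_template.names)
        self.param_names = tuple(names)
        self._bounds = params_template.bounds()

        # kernel encoding at template values; theta is written into pa/pb
        src, dst, kin, pa, pb, ids = _encode(model, params_template)
        self._src, self._dst, self._kin = src, dst, kin
        self._pa0, self._pb0 = pa.copy(), pb.copy()
        self._ids = ids
        # map theta index -> (array, process position)
        pa_map: list[tuple[int, int]] = []
        pb_map: list[tuple[int, int]] = []
        self._n_lab_idx = -1
        for j, name in enumerate(names):
            if name == "init.n_lab":
                self._n_lab_idx = j
                continue
            pid, pname = name.rsplit(".", 1)
            pos = ids.index(pid)
            if pname in ("k", "vmax"):
                pa_map.append((j, pos))
            elif pname == "km":
                pb_map.append((j, pos))
            else:  # pragma: no cover - template construction guards this
                raise ValueError(f"unrecognized parameter name {name!r}")
        self._pa_map = pa_map
        self._pb_map = pb_map

        # per-treatment observation arrays and initial-state templates
        na_frac = design.natural_abundance / 100.0
        self._na_frac = na_frac
        self._tn_mg = design.soil_tn_g_kg * 1000.0
        self._times_d = np.asarray(design.sampling_times_d)
        self._treat_data = []
        n_terms = 0
        for treatment in observations.treatments:
            sub = observations.subset(treatment)
            t_idx = []
            pool_col = []
            for _, row in sub.iterrows():
                match = np.flatnonzero(
                    np.isclose(self._times_d * 24.0, row["time_h"], rtol=0, atol=1e-9)
                )
                if match.size == 0:
                    raise ValueError(
                        f"observation time {row['time_h']} h is not a design "
                        f"sampling time"
                    )
                t_idx.append(int(match[0]))
                pool_col.append(0 if row["pool"] == "NH4" else 1)
            conc_mean = sub["conc_mean"].to_numpy(float)
            ape_mean = sub["ape_mean"].to_numpy(float)
            conc_sd = sub["conc_sd"].to_numpy(float)
            ape_sd = sub["ape_sd"].to_numpy(float)
            if apply_sd_floors:
                conc_floor = np.maximum(CONC_SD_FLOOR_ABS, CONC_SD_FLOOR_REL * conc_mean)
                conc_sd = np.where(np.isnan(conc_sd), conc_floor, np.maximum(conc_sd, conc_floor))
                ape_sd = np.where(np.isnan(ape_sd), APE_SD_FLOOR, np.maximum(ape_sd, APE_SD_FLOOR))
            else:
                if np.isnan(conc_sd).any() or np.isnan(ape_sd).any():
                    raise ValueError("missing sds require apply_sd_floors=True")
                if (conc_sd <= 0).any() or (ape_sd <= 0).any():
                    raise ValueError("sds must be > 0 when floors are disabled")
            y0 = _state_vector(initial_state_from_design(design, treatment))
            self._treat_data.append(
                {
                    "t_idx": np.asarray(t_idx),
                    "pool": np.asarray(pool_col),
                    "conc_mean": conc_mean,
                    "conc_sd": conc_sd,
                    "ape_mean": ape_mean,
                    "ape_sd": ape_sd,
                    "y0": y0,
                }
            )
            n_terms += int(np.isfinite(conc_mean).sum() + np.isfinite(ape_mean).sum())
        self.n_obs = n_terms
        self.n_params = len(names)

    # -- evaluation -----------------------------------------------------------

    def bounds(self) -> np.ndarray:
        return self._bounds.copy()

    def initial_vector(self) -> np.ndarray:
        return self.template.vector()

    def _predict(self, theta: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
        """Per-treatment (totals, n15) arrays at the sampling times, pools
        NH4 (col 0) and NO3 (col 1)."""
        pa = self._pa0.copy()
        pb = self._pb0.copy()
        for j, pos in self._pa_map:
            pa[pos] = theta[j]
        for j, pos in self._pb_map:
            pb[pos] = theta[j]
        out = []
        for data in self._treat_data:
            y = data["y0"].copy()
            if self._n_lab_idx >= 0:
                n_lab = theta[self._n_lab_idx]
                n_rec = self._tn_mg - n_lab - self.design.soil_nh4 - self.design.soil_no3
                if n_rec < 0:
                    raise SimulationError(
                        "initial n_lab exceeds the soil TN balance"
                    )
                y[2] = n_lab
                y[3] = n_rec
                y[7] = n_lab * self._na_frac
                y[8] = n_rec * self._na_frac
            flux_acc = np.zeros(len(self._ids))
            totals = np.empty((self._times_d.size, 2))
            n15 = np.empty((self._times_d.size, 2))
            t_now = 0.0
            for i, t in enumerate(self._times_d):
                fail = _integrate(
                    y, self._src, self._dst, self._kin, pa, pb, t_now, t, self.dt, flux_acc
                )
                if fail >= 0.0:
                    raise SimulationError(
                        f"integrator failure near t = {fail:.6g} d at "
                        f"theta = {np.array2string(theta, precision=4)}"
                    )
                t_now = t
                totals[i] = y[:2]
                n15[i] = y[5:7]
            out.append((totals, n15))
        return out

    def __call__(self, theta: Sequence[float]) -> float:
        theta = np.asarray(theta, dtype=float)
        preds = self._predict(theta)
        na = self.design.natural_abundance
        j_total = 0.0
        for data, (totals, n15) in zip(self._treat_data, preds):
            ti, pc = data["t_idx"], data["pool"]
            conc_pred = totals[ti, pc]
            with np.errstate(divide="ignore", invalid="ignore"):
                frac = np.where(totals[ti, pc] > 1e-300, n15[ti, pc] / totals[ti, pc], 0.0)
            ape_pred = frac * 100.0 - na
            r1 = (conc_pred - data["conc_mean"]) / data["conc_sd"]
            r2 = (ape_pred - data["ape_mean"]) / data["ape_sd"]
            j_total += float(np.nansum(r1 * r1) + np.nansum(r2 * r2))
        return j_total


def misfit(
    params: ParameterSet,
    model: ModelStructure,
    design: ExperimentDesign,
    observations: TracerObservationSet,
    dt: float = FIT_DT,
    apply_sd_floors: bool = True,
) -> float:
    """One-shot weighted sum-of-squares misfit (see :class:`TracerMisfit`)."""
    fn = TracerMisfit(model, params, design, observations, dt=dt, apply_sd_floors=apply_sd_floors)
    return fn(params.vector())


# --------------------------------------------------------------------------
# Metropolis sampler
# --------------------------------------------------------------------------


@dataclass
class MCMCResult:
    """One random-walk Metropolis chain on a misfit surface."""

    chain: np.ndarray  # (n_iter, p) all stored draws
    misfit_trace: np.ndarray  # (n_iter,)
    acceptance_rate: float  # post-burn-in fraction
    burn_in: int  # index of the first retained draw
    best_params: np.ndarray
    best_misfit: float
    param_names: tuple[str, ...]
    rng_seed: int
    n_obs: int | None = None
    n_params: int | None = None
    aic: float | None = None
    proposal_scale_final: np.ndarray | None = None

    def posterior(self) -> np.ndarray:
        """Post-burn-in draws, (n_kept, p)."""
        return self.chain[self.burn_in :]

    def posterior_summary(self) -> pd.DataFrame:
        post = self.posterior()
        return pd.DataFrame(
            {
                "parameter": list(self.param_names),
                "mean": post.mean(axis=0),
                "sd": post.std(axis=0, ddof=1),
                "q2.5": np.percentile(post, 2.5, axis=0),
                "q97.5": np.percentile(post, 97.5, axis=0),
            }
        )


def metropolis_sample(
    misfit_fn: Callable[[np.ndarray], float],
    bounds: np.ndarray,
    init: Sequence[float],
    n_iter: int,
    proposal_scale: float | Sequence[float] = 0.05,
    seed: int = 0,
    burn_in_frac: float = 0.5,
    adapt: bool = True,
    adapt_interval: int = 200,
    target_acceptance: tuple[float, float] = (0.20, 0.45),
    param_names: Sequence[str] | None = None,
) -> MCMCResult:
    """Random-walk Metropolis on a misfit treated as -2 log likelihood.

    A candidate theta' is accepted with probability
    ``min(1, exp(-(J' - J)/2))``; proposals outside the bounding box are
    rejected outright (uniform box prior).  Proposal standard deviations are
    ``proposal_scale * (upper - lower)`` per coordinate and are adapted only
    during burn-in.  Identical seeds give bit-identical chains.
    """
    bounds = np.asarray(bounds, dtype=float)
    if bounds.ndim != 2 or bounds.shape[1] != 2:
        raise ValueError("bounds must be an (n, 2) array")
    lo, hi = bounds[:, 0], bounds[:, 1]
    if not np.all(np.isfinite(lo)) or not np.all(np.isfinite(hi)):
        raise ValueError("bounds must be finite for proposal scaling")
    width = hi - lo
    if np.any(width <= 0):
        raise ValueError("zero-width bounds on a free parameter")
    theta = np.asarray(init, dtype=float).copy()
    if theta.shape != lo.shape:
        raise ValueError("init length does not match bounds")
    if np.any(theta < lo) or np.any(theta > hi):
        raise ValueError("init must lie within bounds")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    scale = np.broadcast_to(np.asarray(proposal_scale, dtype=float), lo.shape).copy()
    if np.any(scale <= 0):
        raise ValueError("proposal_scale must be > 0")

    rng = np.random.default_rng(seed)
    p = theta.size
    burn_in = int(round(burn_in_frac * n_iter))
    chain = np.empty((n_iter, p))
    trace = np.empty(n_iter)

    j_cur = float(misfit_fn(theta))
    best_theta, best_j = theta.copy(), j_cur
    accepted_post = 0
    accepted_window = 0
    step_sd = scale * width

    for it in range(n_iter):
        prop = theta + rng.normal(0.0, 1.0, size=p) * step_sd
        in_box = np.all(prop >= lo) and np.all(prop <= hi)
        accepted = False
        if in_box:
            j_prop = float(misfit_fn(prop))
            if j_prop <= j_cur:
                accepted = True  # downhill moves always accepted
            elif rng.random() < math.exp(-0.5 * (j_prop - j_cur)):
                accepted = True
            if accepted:
                theta, j_cur = prop, j_prop
                if j_prop < best_j:
                    best_theta, best_j = prop.copy(), j_prop
        chain[it] = theta
        trace[it] = j_cur
        if accepted:
            accepted_window += 1
            if it >= burn_in:
                accepted_post += 1
        if adapt and it < burn_in and (it + 1) % adapt_interval == 0:
            rate = accepted_window / adapt_interval
            if rate < target_acceptance[0]:
                scale *= 0.7
            elif rate > target_acceptance[1]:
                scale *= 1.4
            # keep steps meaningful: a collapsing scale cannot rescue a chain
            # trapped in a poor mode, it only freezes it there
            np.clip(scale, 1e-5, 0.5, out=scale)
            step_sd = scale * width
            accepted_window = 0
        elif (it + 1) % adapt_interval == 0:
            accepted_window = 0

    n_post = max(n_iter - burn_in, 1)
    names = tuple(param_names) if param_names is not None else tuple(
        f"theta{i}" for i in range(p)
    )
    return MCMCResult(
        chain=chain,
        misfit_trace=trace,
        acceptance_rate=accepted_post / n_post,
        burn_in=burn_in,
        best_params=best_theta,
        best_misfit=best_j,
        param_names=names,
        rng_seed=int(seed) if np.isscalar(seed) else -1,
        proposal_scale_final=scale,
    )


# --------------------------------------------------------------------------
# AIC & model selection
# --------------------------------------------------------------------------


def compute_aic(
    best_misfit: float, n_obs: int, n_params: int, corrected: bool = False
) -> float:
    """AIC = J_best + 2 p, with J on the -2 log-likelihood scale.  Smaller is
    better.  ``corrected=True`` gives the small-sample AICc variant."""
    if n_params < 1:
        raise ValueError("n_params must be >= 1")
    if n_obs <= n_params:
        raise ValueError("AIC requires n_obs > n_params")
    aic = best_misfit + 2.0 * n_params
    if corrected:
        aic += 2.0 * n_params * (n_params + 1) / (n_obs - n_params - 1)
    return aic


@dataclass
class ModelSelection:
    ranked: list  # TracerFit, ascending AIC
    table: pd.DataFrame

    @property
    def best(self):
        return self.ranked[0]


def select_model(candidates: Sequence["TracerFit"]) -> ModelSelection:
    """Rank candidate fits (of the same observation set) by AIC, ties broken
    by fewer parameters, then stable input order."""
    if len(candidates) < 2:
        raise ValueError("model selection needs at least 2 candidates")
    fps = {c.obs_fingerprint for c in candidates}
    if len(fps) != 1:
        raise ValueError("candidates were fitted to different observation sets")
    order = sorted(
        range(len(candidates)),
        key=lambda i: (candidates[i].aic, candidates[i].n_params, i),
    )
    ranked = [candidates[i] for i in order]
    table = pd.DataFrame(
        {
            "rank": np.arange(1, len(ranked) + 1),
            "label": [c.label for c in ranked],
            "aic": [c.aic for c in ranked],
            "best_misfit": [c.best_misfit for c in ranked],
            "n_params": [c.n_params for c in ranked],
        }
    )
    return ModelSelection(ranked=ranked, table=table)


# --------------------------------------------------------------------------
# Average gross rates over the analysis horizon
# --------------------------------------------------------------------------


class GrossRates:
    """48-h average gross transformation rates (mg N kg^-1 day^-1) with
    posterior sds, plus the derived totals M_N = M_Nlab + M_Nrec and
    I_NH4 = I_NH4_Nlab + I_NH4_Nrec (exact component sums)."""

    def __init__(self, mean: Mapping[str, float], sd: Mapping[str, float] | None = None):
        self._mean = {pid: float(mean.get(pid, 0.0)) for pid in PROCESS_IDS}
        sd = sd or {}
        self._sd = {pid: float(sd.get(pid, 0.0)) for pid in PROCESS_IDS}
        self._total_sd: dict[str, float] = {}
        for pid, v in self._mean.items():
            if v < -1e-12:
                raise ValueError(f"negative rate for {pid}")

    @classmethod
    def from_draws(cls, draws: pd.DataFrame) -> "GrossRates":
        """``draws``: one row per posterior draw, one column per process id."""
        mean = draws.mean(axis=0).to_dict()
        sd = draws.std(axis=0, ddof=1).to_dict() if len(draws) > 1 else {}
        obj = cls(mean, sd)
        for label, parts in (("M_N", ("M_Nlab", "M_Nrec")), ("I_NH4", ("I_NH4_Nlab", "I_NH4_Nrec"))):
            cols = [c for c in parts if c in draws.columns]
            if cols and len(draws) > 1:
                obj._total_sd[label] = float(draws[cols].sum(axis=1).std(ddof=1))
        return obj

    def rate(self, process_id: str) -> float:
        return self._mean[process_id]

    def sd(self, process_id: str) -> float:
        return self._sd[process_id]

    @property
    def m_n(self) -> float:
        return self._mean["M_Nlab"] + self._mean["M_Nrec"]

    @property
    def m_n_sd(self) -> float:
        return self._total_sd.get(
            "M_N", math.hypot(self._sd["M_Nlab"], self._sd["M_Nrec"])
        )

    @property
    def i_nh4(self) -> float:
        return self._mean["I_NH4_Nlab"] + self._mean["I_NH4_Nrec"]

    @property
    def i_nh4_sd(self) -> float:
        return self._total_sd.get(
            "I_NH4", math.hypot(self._sd["I_NH4_Nlab"], self._sd["I_NH4_Nrec"])
        )

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"process": pid, "rate": self._mean[pid], "sd": self._sd[pid]}
            for pid in PROCESS_IDS
        ]
        rows.append({"process": "M_N", "rate": self.m_n, "sd": self.m_n_sd})
        rows.append({"process": "I_NH4", "rate": self.i_nh4, "sd": self.i_nh4_sd})
        return pd.DataFrame(rows)

    def __repr__(self) -> str:  # pragma: no cover
        return f"GrossRates(M_N={self.m_n:.3g}, I_NH4={self.i_nh4:.3g}, O_NH4={self.rate('O_NH4'):.3g})"


def average_rates(
    model: ModelStructure,
    posterior_draws: Sequence[ParameterSet],
    design: ExperimentDesign,
    horizon_h: float = 48.0,
    dt: float = DEFAULT_DT,
) -> GrossRates:
    """Average gross rate of every process over [0, horizon]:
    (1/T) * integral of the flux along the trajectory, trapezoidal on the
    integration grid, evaluated at each posterior draw; reported value is the
    posterior mean, uncertainty the posterior sd over draws.

    The trajectory of pool *totals* is identical in both treatments (equal
    amendments), so rates are computed once per draw from the NH4-labelled
    initial state.
    """
    if horizon_h <= 0:
        raise ValueError("horizon must be > 0")
    draws = list(posterior_draws)
    if not draws:
        raise ValueError("posterior draws must be non-empty")
    from .model_core import simulate  # local import to avoid cycle confusion

    horizon_d = horizon_h / 24.0
    rows = []
    for params in draws:
        n_lab = (
            params.value("init.n_lab") if "init.n_lab" in params else design.n_lab_init
        )
        state0 = initial_state_from_design(replace(design, n_lab_init=n_lab), "NH4_labelled")
        traj = simulate(model, params, state0, [horizon_d], dt=dt)
        avg = traj.flux_integrals[-1] / horizon_d
        rows.append({pid: float(a) for pid, a in zip(traj.process_ids, avg)})
    frame = pd.DataFrame(rows)
    for pid in PROCESS_IDS:
        if pid not in frame.columns:
            frame[pid] = 0.0
    return GrossRates.from_draws(frame[list(PROCESS_IDS)])


# --------------------------------------------------------------------------
# High-level fit
# --------------------------------------------------------------------------


@dataclass
class TracerFit:
    """A multi-chain Metropolis fit of one soil's tracer data."""

    model: ModelStructure
    design: ExperimentDesign
    misfit_fn: TracerMisfit
    chains: list[MCMCResult]
    kept_chains: list[int]
    param_names: tuple[str, ...]
    best_params: np.ndarray
    best_misfit: float
    n_obs: int
    n_params: int
    aic: float
    seed: int
    obs_fingerprint: str
    label: str = "model"

    def posterior(self) -> np.ndarray:
        """Post-burn-in draws pooled over converged chains, (n_kept, p)."""
        return np.vstack([self.chains[i].posterior() for i in self.kept_chains])

    def posterior_summary(self) -> pd.DataFrame:
        post = self.posterior()
        return pd.DataFrame(
            {
                "parameter": list(self.param_names),
                "mean": post.mean(axis=0),
                "sd": post.std(axis=0, ddof=1),
                "q2.5": np.percentile(post, 2.5, axis=0),
                "q97.5": np.percentile(post, 97.5, axis=0),
            }
        )

    @property
    def acceptance_rates(self) -> list[float]:
        return [c.acceptance_rate for c in self.chains]

    def posterior_parameter_sets(self, n_draws: int = 100) -> list[ParameterSet]:
        """Evenly thinned posterior draws as ParameterSet objects."""
        post = self.posterior()
        idx = np.unique(np.linspace(0, len(post) - 1, min(n_draws, len(post))).astype(int))
        return [self.misfit_fn.template.with_vector(post[i]) for i in idx]

    def gross_rates(
        self, n_draws: int = 100, horizon_h: float = 48.0, dt: float = DEFAULT_DT
    ) -> GrossRates:
        return average_rates(
            self.model, self.posterior_parameter_sets(n_draws), self.design,
            horizon_h=horizon_h, dt=dt,
        )

    def rate_draws(
        self, n_draws: int = 100, horizon_h: float = 48.0, dt: float = DEFAULT_DT
    ) -> pd.DataFrame:
        """Per-draw 48-h average rates (one row per thinned posterior draw),
        including the M_N and I_NH4 totals — the basis for posterior rate
        intervals."""
        from .model_core import simulate

        horizon_d = horizon_h / 24.0
        rows = []
        for params in self.posterior_parameter_sets(n_draws):
            n_lab = (
                params.value("init.n_lab") if "init.n_lab" in params else self.design.n_lab_init
            )
            state0 = initial_state_from_design(
                replace(self.design, n_lab_init=n_lab), "NH4_labelled"
            )
            traj = simulate(self.model, params, state0, [horizon_d], dt=dt)
            avg = traj.flux_integrals[-1] / horizon_d
            row = {pid: 0.0 for pid in PROCESS_IDS}
            row.update({pid: float(a) for pid, a in zip(traj.process_ids, avg)})
            rows.append(row)
        frame = pd.DataFrame(rows)
        frame["M_N"] = frame["M_Nlab"] + frame["M_Nrec"]
        frame["I_NH4"] = frame["I_NH4_Nlab"] + frame["I_NH4_Nrec"]
        return frame


def fit_tracer_model(
    model: ModelStructure,
    params_template: ParameterSet,
    design: ExperimentDesign,
    observations: TracerObservationSet,
    n_chains: int = 3,
    n_iter: int = 30000,
    proposal_scale: float = 0.05,
    seed: int = 0,
    dt: float = FIT_DT,
    burn_in_frac: float = 0.5,
    polish: bool = False,
    pre_optimize: bool = True,
    chain_filter_margin: float = 20.0,
    label: str = "model",
) -> TracerFit:
    """Fit both labelling treatments jointly with one shared parameter set.

    Runs ``n_chains`` independent Metropolis chains from overdispersed random
    starts (seeds derived deterministically from ``seed``), pools post-burn-in
    draws, and computes AIC from the best misfit found.

    ``pre_optimize`` runs a short bounded Nelder-Mead descent from each random
    start before sampling, so chains begin near a mode rather than high on the
    misfit surface.  Chains whose post-burn-in median misfit exceeds the best
    chain's median by more than ``chain_filter_margin`` (on the -2 log
    likelihood scale) are flagged unconverged — trapped in a clearly inferior
    mode — and excluded from the pooled posterior (all chains remain
    inspectable on the result).  ``polish=True`` additionally refines the best
    draw before the AIC is computed, useful for model comparison at low noise
    where the misfit minimum is sharp.
    """
    from scipy.optimize import minimize

    fn = TracerMisfit(model, params_template, design, observations, dt=dt)
    bounds = fn.bounds()
    lo, hi = bounds[:, 0], bounds[:, 1]
    chains: list[MCMCResult] = []
    for c in range(n_chains):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), c]))
        init = lo + (0.1 + 0.8 * rng.random(lo.size)) * (hi - lo)
        if pre_optimize:
            r = minimize(
                fn,
                init,
                method="Nelder-Mead",
                bounds=list(zip(lo, hi)),
                options={"maxiter": 200 * lo.size, "xatol": 1e-6, "fatol": 1e-6},
            )
            init = np.clip(np.asarray(r.x), lo, hi)
        chain_seed = np.random.SeedSequence([int(seed), c, 1])
        res = metropolis_sample(
            fn,
            bounds,
            init,
            n_iter=n_iter,
            proposal_scale=proposal_scale,
            seed=chain_seed,
            burn_in_frac=burn_in_frac,
            param_names=fn.param_names,
        )
        res.rng_seed = int(seed)
        chains.append(res)

    medians = [float(np.median(c.misfit_trace[c.burn_in :])) for c in chains]
    best_median = min(medians)
    kept = [i for i, m in enumerate(medians) if m <= best_median + chain_filter_margin]

    best = min(chains, key=lambda c: c.best_misfit)
    best_theta, best_j = best.best_params.copy(), best.best_misfit
    if polish:
        eps = 1e-12 * (hi - lo)
        r = minimize(
            fn,
            np.clip(best_theta, lo + eps, hi - eps),
            method="Nelder-Mead",
            bounds=list(zip(lo, hi)),
            options={"maxiter": 400 * lo.size, "xatol": 1e-8, "fatol": 1e-10},
        )
        if r.fun < best_j:
            best_theta, best_j = np.asarray(r.x), float(r.fun)

    aic = compute_aic(best_j, fn.n_obs, fn.n_params)
    for c in chains:
        c.n_obs, c.n_params, c.aic = fn.n_obs, fn.n_params, aic
    return TracerFit(
        model=model,
        design=design,
        misfit_fn=fn,
        chains=chains,
        kept_chains=kept,
        param_names=fn.param_names,
        best_params=best_theta,
        best_misfit=best_j,
        n_obs=fn.n_obs,
        n_params=fn.n_params,
        aic=aic,
        seed=int(seed),
        obs_fingerprint=observations.fingerprint(),
        label=label,
    )
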