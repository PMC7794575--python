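"""Five-pool soil nitrogen tracer model.

The model tracks five nitrogen pools — NH4+, NO3-, labile organic N,
recalcitrant organic N and exchange-site-adsorbed NH4+ — each carried as a
(total N, 15N atom fraction) pair, and ten simultaneously occurring
transformation processes connecting them:

========  ===========  ===========  =================================
process   source       sink         meaning
========  ===========  ===========  =================================
M_Nlab    n_lab        nh4          mineralization of labile organic N
M_Nrec    n_rec        nh4          mineralization of recalcitrant organic N
I_NH4_Nlab  nh4        n_lab        NH4+ immobilization into labile organic N
I_NH4_Nrec  nh4        n_rec        NH4+ immobilization into recalcitrant organic N
A_NH4     nh4          nh4_ads      NH4+ adsorption on cation exchange sites
R_NH4     nh4_ads      nh4          release of adsorbed NH4+
O_NH4     nh4          no3          autotrophic nitrification
O_Nrec    n_rec        no3          heterotrophic nitrification
D_NO3     no3          nh4          dissimilatory NO3- reduction to NH4+ (DNRA)
I_NO3     no3          n_rec        NO3- immobilization into recalcitrant organic N
========  ===========  ===========  =================================

Each process runs with zero-order, first-order or Michaelis-Menten kinetics
on its source ("substrate") pool, and every flux carries the instantaneous
15N atom fraction of its source pool (pool-dilution assumption; no isotopic
fractionation).  Integration is fixed-step classical 4th-order Runge-Kutta
with per-step clipping of outgoing fluxes so no pool can be driven negative
within a step; this implements the physical substrate limit of zero-order
kinetics and keeps the scheme deterministic and exactly mass-conserving.

Internal time unit is days; rate constants are day^-1 (first order) or
mg N kg^-1 day^-1 (zero order / vmax).  Sampling times supplied in hours are
converted on read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numba
import numpy as np
import pandas as pd

__all__ = [
    "NAT_ABUNDANCE_ATOM_PCT",
    "POOLS",
    "PROCESS_TOPOLOGY",
    "PROCESS_IDS",
    "KINETIC_ORDERS",
    "IsotopePool",
    "SoilState",
    "ProcessSpec",
    "Parameter",
    "ParameterSet",
    "ModelStructure",
    "ExperimentDesign",
    "TracerObservationSet",
    "Trajectory",
    "SimulationError",
    "process_rate",
    "derivatives",
    "simulate",
    "initial_state_from_design",
    "predict_observables",
    "predict_dataset",
    "default_structure",
]

# --------------------------------------------------------------------------
# Constants and topology
# --------------------------------------------------------------------------

#: 15N atom percent of atmospheric N2, the baseline for "atom% excess".
NAT_ABUNDANCE_ATOM_PCT = 0.3663

HOURS_PER_DAY = 24.0

POOLS = ("nh4", "no3", "n_lab", "n_rec", "nh4_ads")
_POOL_INDEX = {name: i for i, name in enumerate(POOLS)}

#: process_id -> (source pool, sink pool); fixed by the model topology.
PROCESS_TOPOLOGY: dict[str, tuple[str, str]] = {
    "M_Nlab": ("n_lab", "nh4"),
    "M_Nrec": ("n_rec", "nh4"),
    "I_NH4_Nlab": ("nh4", "n_lab"),
    "I_NH4_Nrec": ("nh4", "n_rec"),
    "A_NH4": ("nh4", "nh4_ads"),
    "R_NH4": ("nh4_ads", "nh4"),
    "O_NH4": ("nh4", "no3"),
    "O_Nrec": ("n_rec", "no3"),
    "D_NO3": ("no3", "nh4"),
    "I_NO3": ("no3", "n_rec"),
}
PROCESS_IDS = tuple(PROCESS_TOPOLOGY)

KINETIC_ORDERS = ("zero", "first", "michaelis_menten")
_KINETIC_CODE = {"zero": 0, "first": 1, "michaelis_menten": 2}

TREATMENTS = ("NH4_labelled", "NO3_labelled")
OBS_POOLS = ("NH4", "NO3")

#: default per-step integration step, days.
DEFAULT_DT = 0.001


class SimulationError(RuntimeError):
    """Raised when the fixed-step integrator fails (non-finite state or
    a pool driven more than numerically-negligibly negative)."""


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class IsotopePool:
    """One nitrogen pool: total N (mg N kg^-1 dry soil) and its absolute
    15N atom fraction (0..1, *not* excess)."""

    total_n: float
    frac15: float

    def __post_init__(self) -> None:
        if not (self.total_n >= 0.0):
            raise ValueError(f"total_n must be >= 0, got {self.total_n}")
        if not (0.0 <= self.frac15 <= 1.0):
            raise ValueError(f"frac15 must lie in [0, 1], got {self.frac15}")

    @property
    def n15(self) -> float:
        """15N amount, mg N kg^-1."""
        return self.total_n * self.frac15

    @property
    def ape(self) -> float:
        """Atom percent excess relative to natural abundance."""
        return self.frac15 * 100.0 - NAT_ABUNDANCE_ATOM_PCT


@dataclass(frozen=True)
class SoilState:
    """State of all five pools at one time point (time in days since label
    addition)."""

    time: float
    nh4: IsotopePool
    no3: IsotopePool
    n_lab: IsotopePool
    n_rec: IsotopePool
    nh4_ads: IsotopePool

    def __post_init__(self) -> None:
        if not (self.time >= 0.0):
            raise ValueError(f"time must be >= 0, got {self.time}")

    def pool(self, name: str) -> IsotopePool:
        if name not in _POOL_INDEX:
            raise KeyError(f"unknown pool {name!r}; expected one of {POOLS}")
        return getattr(self, name)

    def totals(self) -> np.ndarray:
        return np.array([self.pool(p).total_n for p in POOLS])

    def n15(self) -> np.ndarray:
        return np.array([self.pool(p).n15 for p in POOLS])

    @property
    def total_n(self) -> float:
        """Sum of total N over all pools."""
        return float(self.totals().sum())

    @property
    def total_n15(self) -> float:
        return float(self.n15().sum())


@dataclass(frozen=True)
class ProcessSpec:
    """One transformation process: its identity (which fixes source and sink
    pool), kinetic order and active flag.  An inactive process contributes
    zero flux."""

    process_id: str
    kinetic_order: str = "first"
    active: bool = True

    def __post_init__(self) -> None:
        if self.process_id not in PROCESS_TOPOLOGY:
            raise ValueError(
                f"unknown process id {self.process_id!r}; expected one of {PROCESS_IDS}"
            )
        if self.kinetic_order not in KINETIC_ORDERS:
            raise ValueError(
                f"unknown kinetic order {self.kinetic_order!r}; "
                f"expected one of {KINETIC_ORDERS}"
            )

    @property
    def source_pool(self) -> str:
        return PROCESS_TOPOLOGY[self.process_id][0]

    @property
    def sink_pool(self) -> str:
        return PROCESS_TOPOLOGY[self.process_id][1]

    @property
    def param_names(self) -> tuple[str, ...]:
        if self.kinetic_order == "michaelis_menten":
            return (f"{self.process_id}.vmax", f"{self.process_id}.km")
        return (f"{self.process_id}.k",)


@dataclass(frozen=True)
class Parameter:
    """A nonnegative kinetic (or initial-condition) parameter with box bounds."""

    value: float
    lower: float = 0.0
    upper: float = math.inf

    def __post_init__(self) -> None:
        if self.value < 0.0 or self.lower < 0.0:
            raise ValueError("parameters must be nonnegative")
        if not (self.lower <= self.value <= self.upper):
            raise ValueError(
                f"parameter value {self.value} outside bounds "
                f"[{self.lower}, {self.upper}]"
            )


class ParameterSet:
    """Named parameters for a model structure.

    Keys follow ``"<process_id>.k"``, ``"<process_id>.vmax"``,
    ``"<process_id>.km"`` plus the optional initial-condition parameter
    ``"init.n_lab"`` (initial labile organic N, mg N kg^-1).
    """

    def __init__(self, params: Mapping[str, Parameter]):
        self._params: dict[str, Parameter] = dict(params)

    # -- mapping-ish interface ------------------------------------------------
    def __getitem__(self, name: str) -> Parameter:
        return self._params[name]

    def __contains__(self, name: str) -> bool:
        return name in self._params

    def __len__(self) -> int:
        return len(self._params)

    def __iter__(self):
        return iter(self._params)

    def items(self):
        return self._params.items()

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self._params)

    def value(self, name: str, default: float | None = None) -> float:
        if name in self._params:
            return self._params[name].value
        if default is None:
            raise KeyError(name)
        return default

    # -- vector interface for samplers ---------------------------------------
    def vector(self) -> np.ndarray:
        return np.array([p.value for p in self._params.values()])

    def bounds(self) -> np.ndarray:
        """(n, 2) array of [lower, upper]."""
        return np.array([[p.lower, p.upper] for p in self._params.values()])

    def with_vector(self, theta: Sequence[float]) -> "ParameterSet":
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (len(self._params),):
            raise ValueError("vector length does not match parameter count")
        return ParameterSet(
            {
                name: replace(p, value=float(v))
                for (name, p), v in zip(self._params.items(), theta)
            }
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        body = ", ".join(f"{k}={p.value:.4g}" for k, p in self._params.items())
        return f"ParameterSet({body})"


class ModelStructure:
    """An ordered collection of :class:`ProcessSpec` defining which processes
    run and with which kinetics."""

    def __init__(self, processes: Iterable[ProcessSpec]):
        procs = list(processes)
        seen: set[str] = set()
        for p in procs:
            if p.process_id in seen:
                raise ValueError(f"duplicate process {p.process_id!r}")
            seen.add(p.process_id)
        self.processes: tuple[ProcessSpec, ...] = tuple(procs)

    @property
    def active(self) -> tuple[ProcessSpec, ...]:
        return tuple(p for p in self.processes if p.active)

    def spec(self, process_id: str) -> ProcessSpec:
        for p in self.processes:
            if p.process_id == process_id:
                return p
        raise KeyError(process_id)

    def param_names(self, fit_n_lab: bool = True) -> tuple[str, ...]:
        names: list[str] = []
        for p in self.active:
            names.extend(p.param_names)
        if fit_n_lab:
            names.append("init.n_lab")
        return tuple(names)

    def default_parameters(
        self,
        values: Mapping[str, float] | None = None,
        bounds: Mapping[str, tuple[float, float]] | None = None,
        fit_n_lab: bool = True,
    ) -> ParameterSet:
        """Build a ParameterSet for the active processes with sensible default
        bounds (first-order k in [0, 10] d^-1, zero-order k and vmax in
        [0, 50] mg N kg^-1 d^-1, km in [0, 1000] mg N kg^-1, initial n_lab in
        [0, 200] mg N kg^-1)."""
        values = dict(values or {})
        bounds = dict(bounds or {})
        defaults: dict[str, Parameter] = {}

        def make(name: str, default_value: float, default_bounds: tuple[float, float]):
            lo, hi = bounds.get(name, default_bounds)
            defaults[name] = Parameter(values.get(name, default_value), lo, hi)

        for p in self.active:
            if p.kinetic_order == "zero":
                make(f"{p.process_id}.k", 1.0, (0.0, 50.0))
            elif p.kinetic_order == "first":
                make(f"{p.process_id}.k", 0.1, (0.0, 10.0))
            else:
                make(f"{p.process_id}.vmax", 5.0, (0.0, 50.0))
                make(f"{p.process_id}.km", 10.0, (0.0, 1000.0))
        if fit_n_lab:
            make("init.n_lab", 50.0, (0.0, 200.0))
        return ParameterSet(defaults)

    def __iter__(self):
        return iter(self.processes)

    def __len__(self) -> int:
        return len(self.processes)


def default_structure() -> ModelStructure:
    """The default kinetic assignment used by fixtures: mineralization of the
    labile pool first-order, of the recalcitrant pool zero-order, heterotrophic
    nitrification zero-order, everything else first-order.  All overridable in
    config — the kinetic order per process is exactly what AIC selection is for.
    """
    orders = {
        "M_Nlab": "first",
        "M_Nrec": "zero",
        "I_NH4_Nlab": "first",
        "I_NH4_Nrec": "first",
        "A_NH4": "first",
        "R_NH4": "first",
        "O_NH4": "first",
        "O_Nrec": "zero",
        "D_NO3": "first",
        "I_NO3": "first",
    }
    return ModelStructure(
        ProcessSpec(pid, kinetic_order=orders[pid]) for pid in PROCESS_IDS
    )


@dataclass(frozen=True)
class ExperimentDesign:
    """The paired-labelling incubation design.

    Two treatments receive the same inorganic amendments (NH4+ and NO3-, each
    ``amendment_* = 20`` mg N kg^-1 by default); in ``NH4_labelled`` the NH4+
    amendment carries ``enrichment_nh4`` atom% excess, in ``NO3_labelled`` the
    NO3- amendment carries ``enrichment_no3``.  Destructive sampling at
    ``sampling_times_h`` (hours), ``replicates`` flasks per treatment x time.
    Soil background values are in mg N kg^-1 (inorganic N) and g kg^-1 (TN).
    """

    amendment_nh4: float = 20.0
    amendment_no3: float = 20.0
    enrichment_nh4: float = 9.44  # atom% excess of the 15NH4NO3 label
    enrichment_no3: float = 9.75  # atom% excess of the NH415NO3 label
    sampling_times_h: tuple[float, ...] = (0.5, 12.0, 24.0, 48.0)
    replicates: int = 3
    natural_abundance: float = NAT_ABUNDANCE_ATOM_PCT
    soil_nh4: float = 2.46
    soil_no3: float = 13.60
    soil_tn_g_kg: float = 0.90
    n_lab_init: float = 50.0
    nh4_ads_init: float = 0.0

    def __post_init__(self) -> None:
        for name in ("amendment_nh4", "amendment_no3"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("enrichment_nh4", "enrichment_no3"):
            e = getattr(self, name)
            if not (0.0 < e <= 100.0 - self.natural_abundance):
                raise ValueError(
                    f"{name} must lie in (0, {100.0 - self.natural_abundance}]"
                )
        times = self.sampling_times_h
        if any(t <= 0 for t in times) or any(
            b <= a for a, b in zip(times, times[1:])
        ):
            raise ValueError("sampling times must be strictly increasing and > 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for name in ("soil_nh4", "soil_no3", "soil_tn_g_kg"):
            v = getattr(self, name)
            if v is None or not np.isfinite(v) or v < 0:
                raise ValueError(f"missing or invalid soil background value {name}")

    @property
    def sampling_times_d(self) -> tuple[float, ...]:
        return tuple(t / HOURS_PER_DAY for t in self.sampling_times_h)


class TracerObservationSet:
    """Treatment x time x pool replicate means +/- sds of NH4+/NO3-
    concentration (mg N kg^-1) and 15N atom% excess.

    Backed by a tidy DataFrame with columns
    ``treatment, time_h, pool, conc_mean, conc_sd, ape_mean, ape_sd``
    and a unique (treatment, time_h, pool) key.
    """

    COLUMNS = ("treatment", "time_h", "pool", "conc_mean", "conc_sd", "ape_mean", "ape_sd")
    #: small negatives tolerated on APE means (measurement noise), flagged.
    APE_TOLERANCE = 0.5

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"observation table missing columns {missing}")
        df = frame.loc[:, list(self.COLUMNS)].reset_index(drop=True).copy()
        for i, row in df.iterrows():
            rowno = i + 1
            if row["treatment"] not in TREATMENTS:
                raise ValueError(
                    f"row {rowno}: unknown treatment {row['treatment']!r}"
                )
            if row["pool"] not in OBS_POOLS:
                raise ValueError(f"row {rowno}: unknown pool {row['pool']!r}")
            if row["time_h"] <= 0:
                raise ValueError(f"row {rowno}: time_h must be > 0")
            if row["conc_mean"] < 0:
                raise ValueError(f"row {rowno}: negative concentration")
            for c in ("conc_sd", "ape_sd"):
                if pd.notna(row[c]) and row[c] < 0:
                    raise ValueError(f"row {rowno}: negative {c}")
            if pd.notna(row["ape_mean"]) and row["ape_mean"] < -self.APE_TOLERANCE:
                raise ValueError(
                    f"row {rowno}: ape_mean {row['ape_mean']} below "
                    f"-{self.APE_TOLERANCE} tolerance"
                )
        dup = df.duplicated(subset=["treatment", "time_h", "pool"])
        if dup.any():
            rowno = int(dup.idxmax()) + 1
            raise ValueError(
                f"row {rowno}: duplicate (treatment, time_h, pool) key"
            )
        self.frame = df
        # flag (not reject) small negative APE means
        self.flagged_negative_ape = df.index[
            df["ape_mean"].notna() & (df["ape_mean"] < 0)
        ].tolist()

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def treatments(self) -> tuple[str, ...]:
        return tuple(t for t in TREATMENTS if t in set(self.frame["treatment"]))

    def subset(self, treatment: str) -> pd.DataFrame:
        return self.frame[self.frame["treatment"] == treatment]

    def fingerprint(self) -> str:
        """Stable content hash, used to refuse cross-dataset model comparison."""
        import hashlib

        canon = self.frame.sort_values(["treatment", "time_h", "pool"]).to_csv(
            index=False, float_format="%.12g"
        )
        return hashlib.sha256(canon.encode()).hexdigest()


# --------------------------------------------------------------------------
# Kinetics
# --------------------------------------------------------------------------


def process_rate(kinetic_order: str, params: Mapping[str, float], substrate: float) -> float:
    """Instantaneous flux (mg N kg^-1 day^-1) for one process.

    zero-order: k (0 if the substrate is exhausted); first-order: k*S;
    Michaelis-Menten: vmax*S/(km+S).
    """
    if substrate < 0:
        raise ValueError(f"substrate must be >= 0, got {substrate}")
    if kinetic_order not in KINETIC_ORDERS:
        raise ValueError(f"unknown kinetic order {kinetic_order!r}")
    if kinetic_order == "zero":
        k = params["k"]
        if k < 0:
            raise ValueError("k must be >= 0")
        return 0.0 if substrate == 0.0 else k
    if kinetic_order == "first":
        k = params["k"]
        if k < 0:
            raise ValueError("k must be >= 0")
        return k * substrate
    vmax, km = params["vmax"], params["km"]
    if vmax < 0 or km < 0:
        raise ValueError("vmax and km must be >= 0")
    if substrate == 0.0:
        return 0.0
    return vmax * substrate / (km + substrate)


def _params_for(spec: ProcessSpec, params: ParameterSet) -> dict[str, float]:
    if spec.kinetic_order == "michaelis_menten":
        return {
            "vmax": params.value(f"{spec.process_id}.vmax"),
            "km": params.value(f"{spec.process_id}.km"),
        }
    return {"k": params.value(f"{spec.process_id}.k")}


def derivatives(
    state: SoilState, model: ModelStructure | Iterable[ProcessSpec], params: ParameterSet
) -> dict[str, tuple[float, float]]:
    """Instantaneous time derivative of every pool's (total N, 15N amount).

    Pure-Python reference implementation of the flux bookkeeping: each active
    process removes F from its source and adds F to its sink, and its 15N flux
    is F times the source pool's atom fraction.  Total-N and 15N derivative
    sums are both exactly zero (internal transfers only).
    """
    procs = model.active if isinstance(model, ModelStructure) else [
        p for p in model if p.active
    ]
    d = {p: [0.0, 0.0] for p in POOLS}
    for spec in procs:
        src, dst = spec.source_pool, spec.sink_pool
        pool = state.pool(src)
        flux = process_rate(spec.kinetic_order, _params_for(spec, params), pool.total_n)
        f15 = flux * pool.frac15
        d[src][0] -= flux
        d[dst][0] += flux
        d[src][1] -= f15
        d[dst][1] += f15
    return {k: (v[0], v[1]) for k, v in d.items()}


# --------------------------------------------------------------------------
# Numba integration kernel
#
# State vector y has 10 entries: totals of the 5 pools, then their 15N
# amounts, in POOLS order.  Processes are encoded as parallel arrays:
# src/dst pool indices, kinetic code (0 zero, 1 first, 2 MM), pa (k or vmax),
# pb (km, unused otherwise).
# --------------------------------------------------------------------------


@numba.njit(cache=True)
def _raw_fluxes(y, src, kin, pa, pb, h, out):  # pragma: no cover - jitted
    n = src.shape[0]
    for p in range(n):
        s = y[src[p]]
        if s <= 0.0:
            out[p] = 0.0
        elif kin[p] == 0:
            out[p] = pa[p]
        elif kin[p] == 1:
            out[p] = pa[p] * s
        else:
            out[p] = pa[p] * s / (pb[p] + s)
    # clip: total outflow from a pool over a full step h may not exceed stock
    for pool in range(5):
        tot = 0.0
        for p in range(n):
            if src[p] == pool:
                tot += out[p]
        if tot > 0.0:
            avail = y[pool]
            if avail < tot * h:
                scale = avail / (tot * h) if avail > 0.0 else 0.0
                for p in range(n):
                    if src[p] == pool:
                        out[p] *= scale


@numba.njit(cache=True)
def _deriv(y, src, dst, kin, pa, pb, h, dy, fl):  # pragma: no cover - jitted
    _raw_fluxes(y, src, kin, pa, pb, h, fl)
    for i in range(10):
        dy[i] = 0.0
    for p in range(src.shape[0]):
        f = fl[p]
        sp = src[p]
        dp = dst[p]
        tot = y[sp]
        if tot > 1e-300:
            r = y[5 + sp] / tot
            if r < 0.0:
                r = 0.0
            elif r > 1.0:
                r = 1.0
        else:
            r = 0.0
        f15 = f * r
        dy[sp] -= f
        dy[dp] += f
        dy[5 + sp] -= f15
        dy[5 + dp] += f15


@numba.njit(cache=True)
def _integrate(y, src, dst, kin, pa, pb, t0, t1, dt, flux_acc):  # pragma: no cover
    """Advance y from t0 to t1 in substeps <= dt; accumulate per-process
    trapezoidal flux integrals into flux_acc.  Returns the time of failure
    or -1.0 on success."""
    span = t1 - t0
    if span <= 0.0:
        return -1.0
    nsub = int(np.ceil(span / dt))
    if nsub < 1:
        nsub = 1
    h = span / nsub
    nproc = src.shape[0]
    k1 = np.empty(10)
    k2 = np.empty(10)
    k3 = np.empty(10)
    k4 = np.empty(10)
    fl0 = np.empty(nproc)
    fl = np.empty(nproc)
    ytmp = np.empty(10)
    for step in range(nsub):
        _deriv(y, src, dst, kin, pa, pb, h, k1, fl0)
        for i in range(10):
            ytmp[i] = y[i] + 0.5 * h * k1[i]
        _deriv(ytmp, src, dst, kin, pa, pb, h, k2, fl)
        for i in range(10):
            ytmp[i] = y[i] + 0.5 * h * k2[i]
        _deriv(ytmp, src, dst, kin, pa, pb, h, k3, fl)
        for i in range(10):
            ytmp[i] = y[i] + h * k3[i]
        _deriv(ytmp, src, dst, kin, pa, pb, h, k4, fl)
        for i in range(10):
            y[i] += (h / 6.0) * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
        for i in range(10):
            if not np.isfinite(y[i]):
                return t0 + (step + 1) * h
            if y[i] < 0.0:
                if y[i] < -1e-6:
                    return t0 + (step + 1) * h
                y[i] = 0.0  # numerical dust at substrate exhaustion
        _raw_fluxes(y, src, kin, pa, pb, h, fl)
        for p in range(nproc):
            flux_acc[p] += 0.5 * h * (fl0[p] + fl[p])
    return -1.0


def _encode(
    model: ModelStructure, params: ParameterSet
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, tuple[str, ...]]:
    """Encode active processes as kernel arrays."""
    src, dst, kin, pa, pb, ids = [], [], [], [], [], []
    for spec in model.active:
        src.append(_POOL_INDEX[spec.source_pool])
        dst.append(_POOL_INDEX[spec.sink_pool])
        kin.append(_KINETIC_CODE[spec.kinetic_order])
        if spec.kinetic_order == "michaelis_menten":
            pa.append(params.value(f"{spec.process_id}.vmax"))
            pb.append(params.value(f"{spec.process_id}.km"))
        else:
            pa.append(params.value(f"{spec.process_id}.k"))
            pb.append(0.0)
        ids.append(spec.process_id)
    return (
        np.asarray(src, dtype=np.int64),
        np.asarray(dst, dtype=np.int64),
        np.asarray(kin, dtype=np.int64),
        np.asarray(pa, dtype=np.float64),
        np.asarray(pb, dtype=np.float64),
        tuple(ids),
    )


# --------------------------------------------------------------------------
# Trajectory & simulate
# --------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Simulation output at requested times.

    ``totals`` and ``n15`` are (n_times, 5) arrays in POOLS order;
    ``flux_integrals`` is (n_times, n_active) with the cumulative
    time-integral of each active process flux from t=0 (trapezoid on the
    integration grid), used for 48-h average gross rates.
    """

    times: np.ndarray  # days
    totals: np.ndarray
    n15: np.ndarray
    process_ids: tuple[str, ...]
    flux_integrals: np.ndarray

    def frac15(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(self.totals > 1e-300, self.n15 / np.maximum(self.totals, 1e-300), 0.0)
        return f

    def state_at(self, index: int) -> SoilState:
        f = self.frac15()[index]
        pools = {
            name: IsotopePool(float(self.totals[index, j]), float(min(max(f[j], 0.0), 1.0)))
            for j, name in enumerate(POOLS)
        }
        return SoilState(time=float(self.times[index]), **pools)

    def index_of(self, time_d: float) -> int:
        hit = np.flatnonzero(np.isclose(self.times, time_d, rtol=0.0, atol=1e-9))
        if hit.size == 0:
            raise KeyError(f"time {time_d} d not in trajectory")
        return int(hit[0])

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: time_d, pool, total_n, frac15, ape."""
        f = self.frac15()
        rows = []
        for i, t in enumerate(self.times):
            for j, pool in enumerate(POOLS):
                rows.append(
                    {
                        "time_d": float(t),
                        "pool": pool,
                        "total_n": float(self.totals[i, j]),
                        "frac15": float(f[i, j]),
                        "ape": float(f[i, j] * 100.0 - NAT_ABUNDANCE_ATOM_PCT),
                    }
                )
        return pd.DataFrame(rows)


def _state_vector(state: SoilState) -> np.ndarray:
    y = np.empty(10)
    y[:5] = state.totals()
    y[5:] = state.n15()
    return y


def simulate(
    model: ModelStructure,
    params: ParameterSet,
    initial_state: SoilState,
    output_times: Sequence[float],
    dt: float = DEFAULT_DT,
) -> Trajectory:
    """Integrate the coupled 14N+15N dynamics and return the state at each
    requested time (days).  Deterministic; pools never (more than
    numerically-negligibly) negative; raises :class:`SimulationError` naming
    the failing time on integrator breakdown.
    """
    out_t = np.asarray(sorted(float(t) for t in output_times), dtype=float)
    if out_t.size and out_t[0] < 0:
        raise ValueError("output times must be >= 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    src, dst, kin, pa, pb, ids = _encode(model, params)
    y = _state_vector(initial_state)
    flux_acc = np.zeros(len(ids))
    t_now = float(initial_state.time)

    totals = np.empty((out_t.size, 5))
    n15 = np.empty((out_t.size, 5))
    flux_int = np.empty((out_t.size, len(ids)))
    for i, t in enumerate(out_t):
        if t < t_now - 1e-12:
            raise ValueError("output times precede the initial state time")
        if t > t_now + 1e-15 and len(ids) > 0:
            fail = _integrate(y, src, dst, kin, pa, pb, t_now, t, dt, flux_acc)
            if fail >= 0.0:
                raise SimulationError(
                    f"integrator failure near t = {fail:.6g} d "
                    f"(non-finite or negative pool)"
                )
        t_now = t
        totals[i] = y[:5]
        n15[i] = y[5:]
        flux_int[i] = flux_acc
    return Trajectory(out_t, totals, n15, ids, flux_int)


# --------------------------------------------------------------------------
# Design -> initial state, trajectory -> observables
# --------------------------------------------------------------------------


def _mix_frac15(
    soil_amount: float, soil_frac: float, amendment: float, amendment_frac: float
) -> float:
    total = soil_amount + amendment
    if total <= 0.0:
        return soil_frac
    return (soil_amount * soil_frac + amendment * amendment_frac) / total


def initial_state_from_design(design: ExperimentDesign, treatment: str) -> SoilState:
    """State immediately after label addition.

    Inorganic pool totals are soil background + amendment; their atom
    fractions are the amount-weighted mixture of natural-abundance soil N and
    the (labelled or unlabelled) amendment.  Organic pools start at natural
    abundance; adsorbed NH4+ starts at ``design.nh4_ads_init`` (default 0);
    recalcitrant organic N closes the TN balance.
    """
    if treatment not in TREATMENTS:
        raise ValueError(f"unknown treatment {treatment!r}; expected one of {TREATMENTS}")
    na_frac = design.natural_abundance / 100.0
    if treatment == "NH4_labelled":
        nh4_amend_frac = (design.natural_abundance + design.enrichment_nh4) / 100.0
        no3_amend_frac = na_frac
    else:
        nh4_amend_frac = na_frac
        no3_amend_frac = (design.natural_abundance + design.enrichment_no3) / 100.0

    nh4_total = design.soil_nh4 + design.amendment_nh4
    no3_total = design.soil_no3 + design.amendment_no3
    nh4 = IsotopePool(
        nh4_total, _mix_frac15(design.soil_nh4, na_frac, design.amendment_nh4, nh4_amend_frac)
    )
    no3 = IsotopePool(
        no3_total, _mix_frac15(design.soil_no3, na_frac, design.amendment_no3, no3_amend_frac)
    )
    n_lab = IsotopePool(design.n_lab_init, na_frac)
    tn_mg = design.soil_tn_g_kg * 1000.0
    n_rec_total = tn_mg - design.n_lab_init - design.soil_nh4 - design.soil_no3
    if n_rec_total < 0:
        raise ValueError(
            "initial n_lab + inorganic N exceeds total N; lower n_lab_init"
        )
    n_rec = IsotopePool(n_rec_total, na_frac)
    nh4_ads = IsotopePool(design.nh4_ads_init, na_frac)
    return SoilState(0.0, nh4=nh4, no3=no3, n_lab=n_lab, n_rec=n_rec, nh4_ads=nh4_ads)


def predict_observables(
    trajectory: Trajectory, design: ExperimentDesign, treatment: str
) -> pd.DataFrame:
    """Noise-free predicted observables for one treatment at the design's
    sampling times: NH4+/NO3- concentration and atom% excess.  sd columns are
    NaN (predictions carry no replicate scatter)."""
    rows = []
    f = trajectory.frac15()
    for t_h, t_d in zip(design.sampling_times_h, design.sampling_times_d):
        i = trajectory.index_of(t_d)  # KeyError if the trajectory lacks the time
        for pool_label, j in (("NH4", 0), ("NO3", 1)):
            rows.append(
                {
                    "treatment": treatment,
                    "time_h": float(t_h),
                    "pool": pool_label,
                    "conc_mean": float(trajectory.totals[i, j]),
                    "conc_sd": np.nan,
                    "ape_mean": float(f[i, j] * 100.0 - design.natural_abundance),
                    "ape_sd": np.nan,
                }
            )
    return pd.DataFrame(rows)


def predict_dataset(
    model: ModelStructure,
    params: ParameterSet,
    design: ExperimentDesign,
    treatments: Sequence[str] = TREATMENTS,
    dt: float = DEFAULT_DT,
) -> pd.DataFrame:
    """Noise-free predictions for all treatments (one simulate per treatment;
    the initial n_lab comes from ``params["init.n_lab"]`` when present, else
    from the design)."""
    frames = []
    n_lab = params.value("init.n_lab", design.n_lab_init) if "init.n_lab" in params else design.n_lab_init
    design_used = replace(design, n_lab_init=n_lab)
    for tr in treatments:
        state0 = initial_state_from_design(design_used, tr)
        traj = simulate(model, params, state0, design.sampling_times_d, dt=dt)
        frames.append(predict_observables(traj, design_used, tr))
    return pd.concat(frames, ignore_index=True)
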