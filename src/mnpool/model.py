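"""Two-compartment conductance-based motoneuron pool.

Each motoneuron is reduced to two coupled cylinders: a soma carrying the
spike-generating conductances (Na, fast K, slow K) and a dendrite carrying
the leak, an optional Ca conductance and the excitatory/inhibitory synaptic
inputs.  Membrane voltage follows the standard conductance-based convention

    C dv/dt = I_ext - sum_k g_k (v - E_k)

with all voltages expressed in mV *relative to rest* (E_leak = 0).  The
spike-generating gates m, h, n, q follow first-order kinetics whose rate
constants are switched by a brief pulse triggered when the somatic voltage
crosses a firing threshold, producing a stereotyped action-potential
conductance episode and a slow-K-mediated after-hyperpolarisation.  The
firing threshold is the product of rheobase and input resistance, which
makes rheobase the exact firing boundary for steady somatic current.

Internal units: mV, ms, nA, uS, nF (capacitance fields are reported in pF).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np

__all__ = [
    "MotoneuronGeometry",
    "GatingScheme",
    "MotoneuronParameters",
    "PassiveDerived",
    "MotoneuronState",
    "DriveSample",
    "PoolSpec",
    "InvalidSpecError",
    "build_pool",
    "derive_passive",
    "input_resistance_from_geometry",
    "advance_state",
    "SingleUnitIntegrator",
    "default_pool_spec",
    "load_pool_spec",
    "save_pool_spec",
    "S_TYPE_GATING",
]

SCHEMA_VERSION = 1

#: re-detection guard after a threshold crossing (ms); the pulse-conductance
#: episode provides the dynamics-driven refractory, this only suppresses
#: numerical double-crossings at coarse dt.
SPIKE_REDETECT_GUARD_MS = 2.0


class InvalidSpecError(ValueError):
    """Raised for inconsistent pool / parameter specifications."""


class NumericalError(RuntimeError):
    """Raised when integration encounters non-finite state."""


@dataclass(frozen=True)
class MotoneuronGeometry:
    """Cylinder dimensions of the two compartments (µm)."""

    soma_length_um: float
    soma_diameter_um: float
    dendrite_length_um: float
    dendrite_diameter_um: float

    def __post_init__(self):
        for name in ("soma_length_um", "soma_diameter_um",
                     "dendrite_length_um", "dendrite_diameter_um"):
            if getattr(self, name) <= 0:
                raise InvalidSpecError(f"{name} must be strictly positive")

    @property
    def soma_area_cm2(self) -> float:
        return math.pi * self.soma_diameter_um * self.soma_length_um * 1e-8

    @property
    def dendrite_area_cm2(self) -> float:
        return math.pi * self.dendrite_diameter_um * self.dendrite_length_um * 1e-8


@dataclass(frozen=True)
class GatingScheme:
    """Pulse-switched first-order gate kinetics (rates in 1/ms).

    During the `pulse_ms` episode after a threshold crossing the activation
    gates (m, n, q) relax toward 1 at their alpha rate and the inactivation
    gate h relaxes toward 0 at its beta rate; outside the pulse the gates
    relax back (m, n, q toward 0 at beta; h toward 1 at alpha).  The
    dendritic Ca activation p decays at beta_p and is inert while g_Ca = 0.
    """

    pulse_ms: float = 0.6
    alpha_m: float = 22.0
    beta_m: float = 13.0
    alpha_h: float = 0.5
    beta_h: float = 4.0
    alpha_n: float = 1.5
    beta_n: float = 0.1
    alpha_q: float = 8.0
    beta_q: float = 0.02
    beta_p: float = 0.008


S_TYPE_GATING = GatingScheme()


@dataclass(frozen=True)
class MotoneuronParameters:
    """Full parameter set of one motoneuron.

    Conductances are absolute per compartment (µS); reversal potentials are
    mV relative to rest; `g_excit`/`g_inhib` scale the dimensionless common
    excitatory / inhibitory inputs into dendritic conductances (µS per a.u.).
    """

    geometry: MotoneuronGeometry
    specific_capacitance_uF_cm2: float = 1.0
    axial_resistivity_ohm_cm: float = 70.0
    g_leak_soma_uS: float = 0.19
    g_leak_dendrite_uS: float = 0.60
    g_na_uS: float = 0.75
    g_kfast_uS: float = 0.23
    g_kslow_uS: float = 1.2
    g_ca_uS: float = 0.0
    e_leak_mV: float = 0.0
    e_na_mV: float = 120.0
    e_kfast_mV: float = -10.0
    e_kslow_mV: float = -25.0
    e_ca_mV: float = 140.0
    e_excit_mV: float = 70.0
    e_inhib_mV: float = -16.0
    g_excit_uS: float = 0.6
    g_inhib_uS: float = 3.0
    rheobase_nA: float = 3.5
    input_resistance_Mohm: float = 1.9
    gating: GatingScheme = field(default=S_TYPE_GATING)

    def __post_init__(self):
        for name in ("g_leak_soma_uS", "g_leak_dendrite_uS", "g_na_uS",
                     "g_kfast_uS", "g_kslow_uS", "g_ca_uS",
                     "g_excit_uS", "g_inhib_uS"):
            if getattr(self, name) < 0:
                raise InvalidSpecError(f"{name} must be non-negative")
        if not (self.e_na_mV > self.e_leak_mV):
            raise InvalidSpecError("E_Na must exceed E_leak")
        if not (self.e_kfast_mV < self.e_leak_mV):
            raise InvalidSpecError("E_Kfast must be below E_leak")
        if not (self.e_inhib_mV < self.e_excit_mV):
            raise InvalidSpecError("E_inhib must be below E_excit")
        if self.rheobase_nA <= 0:
            raise InvalidSpecError("rheobase must be positive")
        if self.input_resistance_Mohm <= 0:
            raise InvalidSpecError("input resistance must be positive")


@dataclass(frozen=True)
class PassiveDerived:
    """Geometry-derived passive quantities of one motoneuron."""

    c_soma_pF: float
    c_dendrite_pF: float
    g_coupling_uS: float
    v_threshold_mV: float  # rheobase x input resistance, relative to rest

    def __post_init__(self):
        if self.c_soma_pF <= 0 or self.c_dendrite_pF <= 0:
            raise InvalidSpecError("compartment capacitances must be positive")
        if self.g_coupling_uS <= 0:
            raise InvalidSpecError("coupling conductance must be positive")


@dataclass
class MotoneuronState:
    """Dynamic state: compartment voltages (mV rel. rest) and gates."""

    v_soma: float = 0.0
    v_dendrite: float = 0.0
    m: float = 0.0
    h: float = 1.0
    n: float = 0.0
    q: float = 0.0
    p: float = 0.0

    def validate(self) -> None:
        for g in ("m", "h", "n", "q", "p"):
            if not 0.0 <= getattr(self, g) <= 1.0:
                raise InvalidSpecError(f"gating value {g} outside [0, 1]")
        if not (math.isfinite(self.v_soma) and math.isfinite(self.v_dendrite)):
            raise NumericalError("non-finite compartment voltage")


@dataclass(frozen=True)
class DriveSample:
    """Instantaneous drive: common excitation, inhibition, additive noise.

    `noise` adds to `exc`; the summed excitatory input is floored at zero so
    the synaptic conductance stays non-negative.  `i_soma_nA` is an optional
    intracellular-injection analogue used for rheobase-style protocols.
    """

    exc: float = 0.0
    inh: float = 0.0
    noise: float = 0.0
    i_soma_nA: float = 0.0

    def __post_init__(self):
        if self.exc < 0 or self.inh < 0:
            raise InvalidSpecError("exc and inh drives must be non-negative")


@dataclass(frozen=True)
class PoolSpec:
    """Endpoint parameter sets to interpolate across a size-graded pool."""

    n_units: int
    smallest: MotoneuronParameters
    largest: MotoneuronParameters

    def __post_init__(self):
        if self.n_units < 1:
            raise InvalidSpecError("n_units must be >= 1")
        if self.largest.geometry.soma_area_cm2 < self.smallest.geometry.soma_area_cm2:
            raise InvalidSpecError(
                "largest endpoint has smaller soma area than smallest endpoint")


# ---------------------------------------------------------------------------
# passive derivations

def derive_passive(params: MotoneuronParameters) -> PassiveDerived:
    """Capacitances, coupling conductance and firing threshold.

    Compartment capacitance is specific capacitance times lateral cylinder
    area pi*d*l.  The coupling conductance is the reciprocal of the summed
    half-cylinder axial resistances, R_half = Ra*(l/2)/(pi*(d/2)^2).
    """
    geo = params.geometry
    cm = params.specific_capacitance_uF_cm2
    c_soma_pF = cm * geo.soma_area_cm2 * 1e6  # µF -> pF with area in cm²
    c_dend_pF = cm * geo.dendrite_area_cm2 * 1e6

    ra = params.axial_resistivity_ohm_cm

    def half_axial_ohm(length_um: float, diameter_um: float) -> float:
        length_cm = length_um * 1e-4
        radius_cm = diameter_um * 1e-4 / 2.0
        cross_cm2 = math.pi * radius_cm ** 2
        if cross_cm2 <= 0:
            raise InvalidSpecError("zero-area geometry")
        return ra * (length_cm / 2.0) / cross_cm2

    r_total = (half_axial_ohm(geo.soma_length_um, geo.soma_diameter_um)
               + half_axial_ohm(geo.dendrite_length_um, geo.dendrite_diameter_um))
    g_coupling_uS = 1e6 / r_total

    v_th = params.rheobase_nA * params.input_resistance_Mohm  # nA*MΩ = mV
    return PassiveDerived(c_soma_pF, c_dend_pF, g_coupling_uS, v_th)


def input_resistance_from_geometry(params: MotoneuronParameters) -> float:
    """Somatic input resistance (MΩ) of the passive two-compartment network.

    At rest the active conductances are shut (m = n = q = 0), so the soma
    sees its leak in parallel with the coupling conductance in series with
    the dendritic leak.
    """
    passive = derive_passive(replace(params, rheobase_nA=1.0,
                                     input_resistance_Mohm=1.0))
    g_c = passive.g_coupling_uS
    g_ld = params.g_leak_dendrite_uS
    g_path = g_c * g_ld / (g_c + g_ld) if (g_c + g_ld) > 0 else 0.0
    return 1.0 / (params.g_leak_soma_uS + g_path)


# ---------------------------------------------------------------------------
# pool construction

_INTERP_FIELDS = (
    "specific_capacitance_uF_cm2", "axial_resistivity_ohm_cm",
    "g_leak_soma_uS", "g_leak_dendrite_uS",
    "g_na_uS", "g_kfast_uS", "g_kslow_uS", "g_ca_uS",
    "e_leak_mV", "e_na_mV", "e_kfast_mV", "e_kslow_mV", "e_ca_mV",
    "e_excit_mV", "e_inhib_mV", "g_excit_uS", "g_inhib_uS",
    "rheobase_nA", "input_resistance_Mohm",
)
_GEOM_FIELDS = ("soma_length_um", "soma_diameter_um",
                "dendrite_length_um", "dendrite_diameter_um")


def build_pool(spec: PoolSpec) -> list[MotoneuronParameters]:
    """Linearly interpolate every parameter from smallest to largest.

    Unit i (1-based) gets f_i = f_small + (i-1)/(n-1) * (f_large - f_small);
    a single-unit pool returns the smallest endpoint.  Ordering is smallest
    to largest, so derived soma capacitance is non-decreasing.
    """
    n = spec.n_units
    out: list[MotoneuronParameters] = []
    for i in range(n):
        w = 0.0 if n == 1 else i / (n - 1)
        geo = MotoneuronGeometry(**{
            f: (1 - w) * getattr(spec.smallest.geometry, f)
               + w * getattr(spec.largest.geometry, f)
            for f in _GEOM_FIELDS})
        fields = {
            f: (1 - w) * getattr(spec.smallest, f) + w * getattr(spec.largest, f)
            for f in _INTERP_FIELDS}
        out.append(MotoneuronParameters(geometry=geo,
                                        gating=spec.smallest.gating, **fields))
    return out


# ---------------------------------------------------------------------------
# single-step dynamics (reference implementation; the production integrator
# in _integrator.py runs the same mathematics inside a numba kernel)

def _gate_stage_values(state: MotoneuronState, gating: GatingScheme,
                       pulse_active: bool, dt: float):
    """Closed-form gate values at t+dt (rates are piecewise constant)."""
    def toward(x0, target, rate, dt):
        return target + (x0 - target) * math.exp(-rate * dt)

    if pulse_active:
        m = toward(state.m, 1.0, gating.alpha_m, dt)
        h = toward(state.h, 0.0, gating.beta_h, dt)
        n = toward(state.n, 1.0, gating.alpha_n, dt)
        q = toward(state.q, 1.0, gating.alpha_q, dt)
    else:
        m = toward(state.m, 0.0, gating.beta_m, dt)
        h = toward(state.h, 1.0, gating.alpha_h, dt)
        n = toward(state.n, 0.0, gating.beta_n, dt)
        q = toward(state.q, 0.0, gating.beta_q, dt)
    p = state.p * math.exp(-gating.beta_p * dt)
    return m, h, n, q, p


def _voltage_derivs(v_s, v_d, gates, params: MotoneuronParameters,
                    passive: PassiveDerived, drive: DriveSample):
    m, h, n, q, p = gates
    g_c = passive.g_coupling_uS
    c_s = passive.c_soma_pF * 1e-3  # nF
    c_d = passive.c_dendrite_pF * 1e-3
    exc_eff = max(drive.exc + drive.noise, 0.0)
    i_s = (drive.i_soma_nA
           - g_c * (v_s - v_d)
           - params.g_leak_soma_uS * (v_s - params.e_leak_mV)
           - params.g_na_uS * m ** 3 * h * (v_s - params.e_na_mV)
           - params.g_kfast_uS * n ** 4 * (v_s - params.e_kfast_mV)
           - params.g_kslow_uS * q ** 2 * (v_s - params.e_kslow_mV))
    i_d = (-g_c * (v_d - v_s)
           - params.g_leak_dendrite_uS * (v_d - params.e_leak_mV)
           - params.g_ca_uS * p * (v_d - params.e_ca_mV)
           - exc_eff * params.g_excit_uS * (v_d - params.e_excit_mV)
           - drive.inh * params.g_inhib_uS * (v_d - params.e_inhib_mV))
    return i_s / c_s, i_d / c_d


def advance_state(state: MotoneuronState, params: MotoneuronParameters,
                  drive: DriveSample, dt_ms: float,
                  passive: PassiveDerived | None = None,
                  pulse_active: bool = False,
                  step_index: int | None = None,
                  ) -> tuple[MotoneuronState, bool]:
    """One RK4 step of the soma/dendrite equations.

    The gate ODEs are linear with piecewise-constant rates, so gate values at
    the RK4 stage times are computed in closed form (exact); only the two
    voltages are advanced by RK4.  Returns the new state and a spike flag
    raised iff v_soma crosses threshold upward during the step.  Gate outputs
    are clipped to [0, 1].
    """
    if dt_ms <= 0:
        raise InvalidSpecError("dt must be positive")
    if not all(map(math.isfinite, (state.v_soma, state.v_dendrite, drive.exc,
                                   drive.inh, drive.noise, drive.i_soma_nA))):
        where = "" if step_index is None else f" at step {step_index}"
        raise NumericalError(f"non-finite state or drive{where}")
    if passive is None:
        passive = derive_passive(params)
    gating = params.gating

    g0 = (state.m, state.h, state.n, state.q, state.p)
    g_half = _gate_stage_values(state, gating, pulse_active, dt_ms / 2.0)
    g_full = _gate_stage_values(state, gating, pulse_active, dt_ms)

    v_s, v_d = state.v_soma, state.v_dendrite
    k1s, k1d = _voltage_derivs(v_s, v_d, g0, params, passive, drive)
    k2s, k2d = _voltage_derivs(v_s + dt_ms / 2 * k1s, v_d + dt_ms / 2 * k1d,
                               g_half, params, passive, drive)
    k3s, k3d = _voltage_derivs(v_s + dt_ms / 2 * k2s, v_d + dt_ms / 2 * k2d,
                               g_half, params, passive, drive)
    k4s, k4d = _voltage_derivs(v_s + dt_ms * k3s, v_d + dt_ms * k3d,
                               g_full, params, passive, drive)
    v_s_new = v_s + dt_ms / 6.0 * (k1s + 2 * k2s + 2 * k3s + k4s)
    v_d_new = v_d + dt_ms / 6.0 * (k1d + 2 * k2d + 2 * k3d + k4d)
    if not (math.isfinite(v_s_new) and math.isfinite(v_d_new)):
        where = "" if step_index is None else f" at step {step_index}"
        raise NumericalError(f"integration diverged{where}")

    clip = lambda x: min(1.0, max(0.0, x))
    new = MotoneuronState(v_s_new, v_d_new, *(clip(x) for x in g_full))
    spiked = v_s < passive.v_threshold_mV <= v_s_new
    return new, spiked


class SingleUnitIntegrator:
    """Convenience wrapper handling pulse-episode and re-detection bookkeeping
    around :func:`advance_state` for single-unit protocols and tests."""

    def __init__(self, params: MotoneuronParameters, dt_ms: float = 0.05):
        self.params = params
        self.passive = derive_passive(params)
        self.dt_ms = dt_ms
        self.state = MotoneuronState()
        self.t_ms = 0.0
        self._pulse_end = -1.0
        self._last_spike = -math.inf
        self.spike_times_ms: list[float] = []

    def step(self, drive: DriveSample) -> bool:
        pulse_on = self.t_ms < self._pulse_end
        self.state, crossed = advance_state(
            self.state, self.params, drive, self.dt_ms,
            passive=self.passive, pulse_active=pulse_on)
        self.t_ms += self.dt_ms
        spiked = (crossed
                  and self.t_ms - self._last_spike >= SPIKE_REDETECT_GUARD_MS)
        if spiked:
            self._last_spike = self.t_ms
            self._pulse_end = self.t_ms + self.params.gating.pulse_ms
            self.spike_times_ms.append(self.t_ms)
        return spiked

    def run(self, duration_ms: float, drive: DriveSample) -> list[float]:
        n = int(round(duration_ms / self.dt_ms))
        for _ in range(n):
            self.step(drive)
        return self.spike_times_ms


# ---------------------------------------------------------------------------
# default S-type endpoint sets

def _endpoint(soma_um: float, dend_d_um: float, dend_l_um: float,
              rheobase_nA: float,
              rm_soma_kohm_cm2: float = 1.0,
              rm_dend_kohm_cm2: float = 12.0,
              g_na_mS_cm2: float = 4.0,
              g_kf_mS_cm2: float = 1.2,
              g_ks_mS_cm2: float = 6.4,
              g_excit_uS: float = 0.6,
              g_inhib_uS: float = 3.0) -> MotoneuronParameters:
    geo = MotoneuronGeometry(soma_um, soma_um, dend_l_um, dend_d_um)
    a_s, a_d = geo.soma_area_cm2, geo.dendrite_area_cm2
    params = MotoneuronParameters(
        geometry=geo,
        g_leak_soma_uS=a_s / rm_soma_kohm_cm2 * 1e3,   # cm²/(kΩcm²) -> mS -> µS
        g_leak_dendrite_uS=a_d / rm_dend_kohm_cm2 * 1e3,
        g_na_uS=g_na_mS_cm2 * a_s * 1e3,
        g_kfast_uS=g_kf_mS_cm2 * a_s * 1e3,
        g_kslow_uS=g_ks_mS_cm2 * a_s * 1e3,
        g_excit_uS=g_excit_uS,
        g_inhib_uS=g_inhib_uS,
        rheobase_nA=rheobase_nA,
    )
    return replace(params,
                   input_resistance_Mohm=input_resistance_from_geometry(params))


def default_pool_spec(n_units: int = 20) -> PoolSpec:
    """Default S-type pool endpoints (cat lumbar literature values).

    Soma diameter = length runs 77.5 -> 82.5 µm, giving soma capacitances of
    roughly 189 -> 214 pF at 1 µF/cm²; dendritic cylinder 41.5x5500 ->
    62.5x6800 µm; rheobase 3.5 -> 6.5 nA.  Override via a JSON parameter
    file (:func:`load_pool_spec`) to reproduce supplementary-anchored sets.
    """
    return PoolSpec(
        n_units=n_units,
        smallest=_endpoint(77.5, 41.5, 5500.0, 3.5, g_excit_uS=0.97),
        largest=_endpoint(82.5, 62.5, 6800.0, 6.5, g_excit_uS=1.25),
    )


# ---------------------------------------------------------------------------
# JSON parameter files

def _params_to_dict(p: MotoneuronParameters) -> dict:
    d = asdict(p)
    d["geometry"] = asdict(p.geometry)
    d["gating"] = asdict(p.gating)
    return d


def _params_from_dict(d: dict) -> MotoneuronParameters:
    d = dict(d)
    geo = MotoneuronGeometry(**d.pop("geometry"))
    gating = GatingScheme(**d.pop("gating")) if "gating" in d else S_TYPE_GATING
    return MotoneuronParameters(geometry=geo, gating=gating, **d)


def save_pool_spec(spec: PoolSpec, path) -> None:
    """Write endpoint sets as unit-annotated JSON (schema versioned)."""
    payload = {
        "schema_version": SCHEMA_VERSION,
        "units": {"voltage": "mV (relative to rest)", "conductance": "uS",
                  "capacitance": "pF", "current": "nA", "time": "ms",
                  "geometry": "um", "resistance": "Mohm"},
        "n_units": spec.n_units,
        "smallest": _params_to_dict(spec.smallest),
        "largest": _params_to_dict(spec.largest),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_pool_spec(path) -> PoolSpec:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("schema_version") != SCHEMA_VERSION:
        raise InvalidSpecError(
            f"unsupported parameter-file schema: {payload.get('schema_version')}")
    return PoolSpec(n_units=int(payload["n_units"]),
                    smallest=_params_from_dict(payload["smallest"]),
                    largest=_params_from_dict(payload["largest"]))
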