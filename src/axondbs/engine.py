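"""Simulation engine: implicit cable integration, spike detection,
threshold searches and conduction-block classification.

The voltage/gating system is advanced by the numba kernel in ``_kernel``;
this module prepares the per-compartment coefficient arrays, manages
resting-state settling, and exposes the scientific operations: running a
fiber under extracellular and/or intracellular drive, bisection searches
for activation (and block) thresholds, and block classification of
intrinsically driven fibers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import _kernel
from .bursts import InjectionSchedule
from .channels import allocate_channels
from .fiber import (KIND_FLUT, KIND_MYSA, KIND_NODE, KIND_STIN,
                    FiberGeometry, NodalConductances, load_parameter_table,
                    resting_gates)
from .field import FieldModel, StimulusProgram, step_average_current
from .population import FiberPose, fiber_distance_profile

__all__ = [
    "SimulationConfig",
    "SpikeTrain",
    "SimResult",
    "run_fiber",
    "detect_spikes",
    "intracellular_rheobase",
    "is_activated",
    "find_activation_current",
    "find_block_threshold",
    "detect_conduction_block",
]

# Conductance standing in for the absent myelin at nodes: the periaxonal
# space there opens directly to the extracellular medium.
_G_CLAMP_US = 1.0e9

ONSET_EXCLUSION_MS = 100.0  # kHz-onset transient excluded from block calls


@dataclass(frozen=True)
class SimulationConfig:
    """Integration and detection settings.

    ``dt_ms`` of 0.02 is the workhorse step; 0.002 reproduces fine-step
    runs. ``variant`` selects deterministic or stochastic nodal gating;
    ``n_na`` is the per-node fast Na+ channel count of the stochastic
    variant.
    """

    dt_ms: float = 0.02
    epoch_ms: float = 1000.0
    settle_ms: float = 20.0
    spike_threshold_mv: float = -20.0
    refractory_ms: float = 1.0
    variant: str = "deterministic"
    n_na: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.dt_ms <= 0 or self.epoch_ms < self.dt_ms:
            raise ValueError("need dt > 0 and epoch >= dt")
        if self.variant not in ("deterministic", "stochastic"):
            raise ValueError("variant must be deterministic or stochastic")
        if self.variant == "stochastic" and not self.n_na:
            raise ValueError("stochastic variant needs n_na")


@dataclass
class SpikeTrain:
    fiber_id: int
    spike_times_ms: np.ndarray
    recording_node: int
    epoch_ms: float

    def __len__(self):
        return self.spike_times_ms.size


@dataclass
class SimResult:
    t_ms: np.ndarray
    v_mv: np.ndarray            # (n_rec, n_steps+1) transmembrane traces
    record_nodes: list[int]
    config: SimulationConfig

    def spike_train(self, which: int = 0, fiber_id: int = 0) -> SpikeTrain:
        cfg = self.config
        times = detect_spikes(self.v_mv[which], cfg.dt_ms,
                              cfg.spike_threshold_mv, cfg.refractory_ms)
        return SpikeTrain(fiber_id, times, self.record_nodes[which],
                          cfg.epoch_ms)


def detect_spikes(v_trace: np.ndarray, dt_ms: float,
                  threshold_mv: float = -20.0,
                  refractory_ms: float = 1.0) -> np.ndarray:
    """Upward threshold crossings separated by at least the refractory time."""
    v = np.asarray(v_trace)
    up = np.flatnonzero((v[:-1] < threshold_mv) & (v[1:] >= threshold_mv))
    if up.size == 0:
        return np.empty(0)
    times = (up + 1) * dt_ms
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= refractory_ms:
            kept.append(t)
    return np.asarray(kept)


# --------------------------------------------------------------------------
# coefficient assembly (cached per geometry + dt)
# --------------------------------------------------------------------------

_coef_cache: dict = {}
_settle_cache: dict = {}


def _geom_key(geom: FiberGeometry) -> tuple:
    return (geom.diameter_um, geom.n_nodes)


def _coefficients(geom: FiberGeometry, dt: float):
    key = (_geom_key(geom), dt)
    if key in _coef_cache:
        return _coef_cache[key]
    table = geom.params or load_parameter_table()
    g = table["global"]
    cond = NodalConductances.from_table(table)

    kind = geom.kind
    L = geom.length_um
    d_ax = geom.axon_diameter_um
    sp = geom.periaxonal_space_um
    n = geom.n_compartments

    area_ax = np.pi * d_ax * L                       # axolemma area, um2
    area_my = np.pi * geom.diameter_um * L           # myelin sheath area

    c_ax = g["c_axolemma_uf_cm2"] * 1e-5             # nF/um2
    a_cax_dt = area_ax * c_ax / dt

    gpas_density = np.zeros(n)
    gpas_density[kind == KIND_MYSA] = g["g_pas_mysa_s_cm2"]
    gpas_density[kind == KIND_FLUT] = g["g_pas_flut_s_cm2"]
    gpas_density[kind == KIND_STIN] = g["g_pas_stin_s_cm2"]
    g_pas_abs = gpas_density * 0.01 * area_ax        # uS
    b_pas_abs = g_pas_abs * g["e_pas_mv"]

    nl2 = 2.0 * geom.n_myelin_lamellae               # membranes per sheath
    c_my = g["myelin_c_per_lamella_uf_cm2"] / nl2 * 1e-5
    g_my = g["myelin_g_per_lamella_s_cm2"] / nl2 * 0.01
    amy_cmy_dt = area_my * c_my / dt
    g_my_abs = area_my * g_my
    node_mask = kind == KIND_NODE
    amy_cmy_dt[node_mask] = 0.0
    g_my_abs[node_mask] = _G_CLAMP_US

    rho = g["rho_axial_ohm_cm"] * 1.0e4              # ohm-um
    a_cross = np.pi * d_ax ** 2 / 4.0
    half_r_intra = rho * 0.5 * L / a_cross           # ohm
    a_peri = np.pi * ((d_ax / 2 + sp) ** 2 - (d_ax / 2) ** 2)
    half_r_peri = rho * 0.5 * L / a_peri
    ga = 1.0e6 / (half_r_intra[:-1] + half_r_intra[1:])   # uS
    gp = 1.0e6 / (half_r_peri[:-1] + half_r_peri[1:])

    node_comp = geom.node_compartments.astype(np.int64)
    area_node = geom.node_area_um2
    coef = dict(
        a_cax_dt=a_cax_dt, g_pas_abs=g_pas_abs, b_pas_abs=b_pas_abs,
        amy_cmy_dt=amy_cmy_dt, g_my_abs=g_my_abs, ga=ga, gp=gp,
        node_comp=node_comp,
        gnaf_abs=cond.gnaf_max * 0.01 * area_node,
        gnap_abs=cond.gnap_max * 0.01 * area_node,
        gks_abs=cond.gks_max * 0.01 * area_node,
        glk_abs=cond.glk * 0.01 * area_node,
        e_na=cond.e_na, e_k=cond.e_k, e_lk=cond.e_lk,
        v_rest=table["global"]["v_rest_mv"],
    )
    _coef_cache[key] = coef
    return coef


def _initial_state(geom: FiberGeometry, coef: dict):
    n = geom.n_compartments
    nn = geom.n_nodes
    g0 = resting_gates(coef["v_rest"])
    vi = np.full(n, coef["v_rest"])
    w = np.zeros(n)
    gates = (np.full(nn, g0["naf_m"]), np.full(nn, g0["naf_h"]),
             np.full(nn, g0["nap_p"]), np.full(nn, g0["ks_s"]))
    return vi, w, gates


def _settled_state(geom: FiberGeometry, config: SimulationConfig):
    """Deterministic resting state after the settle period (cached)."""
    key = (_geom_key(geom), config.dt_ms, round(config.settle_ms, 6))
    if key in _settle_cache:
        vi, w, gates = _settle_cache[key]
        return vi.copy(), w.copy(), tuple(x.copy() for x in gates)
    coef = _coefficients(geom, config.dt_ms)
    vi, w, gates = _initial_state(geom, coef)
    n_steps = int(round(config.settle_ms / config.dt_ms))
    if n_steps > 0:
        _run_kernel(geom, coef, config, vi, w, gates,
                    stim=np.zeros(n_steps), inj=np.zeros(n_steps),
                    phi_unit=np.zeros(geom.n_compartments),
                    inj_comp=0, rec_comp=np.array([0], dtype=np.int64),
                    stochastic=False, pop=None)
    _settle_cache[key] = (vi.copy(), w.copy(),
                          tuple(x.copy() for x in gates))
    return vi, w, gates


def _run_kernel(geom, coef, config, vi, w, gates, *, stim, inj, phi_unit,
                inj_comp, rec_comp, stochastic, pop):
    gm, gh, gpg, gs = gates
    n_steps = stim.size
    v_rec = np.empty((rec_comp.size, n_steps + 1))
    if stochastic:
        na_states = pop.na_states
        k_states = pop.k_states
        gamma_na = pop.gamma_na_ps * 1e-6  # pS -> uS
        gamma_k = pop.gamma_k_ps * 1e-6
    else:
        na_states = np.zeros((1, 8), dtype=np.int64)
        k_states = np.zeros((1, 2), dtype=np.int64)
        gamma_na = gamma_k = 0.0
    _kernel.integrate(
        coef["a_cax_dt"], coef["g_pas_abs"], coef["b_pas_abs"],
        coef["amy_cmy_dt"], coef["g_my_abs"], coef["ga"], coef["gp"],
        coef["node_comp"],
        coef["gnaf_abs"], coef["gnap_abs"], coef["gks_abs"], coef["glk_abs"],
        coef["e_na"], coef["e_k"], coef["e_lk"],
        vi, w, gm, gh, gpg, gs,
        1 if stochastic else 0, na_states, k_states, gamma_na, gamma_k,
        int(config.seed) & 0x7FFFFFFF,
        phi_unit, stim, inj, inj_comp, config.dt_ms, rec_comp, v_rec)
    return v_rec


def _injection_array(schedule: InjectionSchedule | None, geom, config,
                     n_steps: int) -> tuple[np.ndarray, int]:
    inj = np.zeros(n_steps)
    if schedule is None or schedule.spike_times_ms.size == 0:
        return inj, 0
    amp = schedule.pulse_amplitude_na
    if amp is None:
        amp = 2.0 * intracellular_rheobase(geom, config)
    amps = np.broadcast_to(np.asarray(amp, dtype=float),
                           schedule.spike_times_ms.shape)
    dt = config.dt_ms
    wdt = schedule.pulse_width_ms
    for t0, amp in zip(schedule.spike_times_ms, amps):
        t1 = t0 + wdt
        k0 = max(int(math.floor(t0 / dt)), 0)
        k1 = min(int(math.ceil(t1 / dt)), n_steps)
        for k in range(k0, k1):
            lo, hi = k * dt, (k + 1) * dt
            overlap = max(0.0, min(hi, t1) - max(lo, t0))
            inj[k] += amp * overlap / dt
    node_comp = geom.node_compartments
    return inj, int(node_comp[schedule.injection_node])


def run_fiber(geom: FiberGeometry,
              config: SimulationConfig = SimulationConfig(),
              *,
              pose: FiberPose | None = None,
              field_model: FieldModel | None = None,
              program: StimulusProgram | None = None,
              phi_unit_mv_per_ma: np.ndarray | None = None,
              injection: InjectionSchedule | None = None,
              record_nodes: Sequence[int] = (-1,)) -> SimResult:
    """Simulate one fiber for ``config.epoch_ms`` after a settle period.

    Extracellular drive comes either from a (pose, field_model, program)
    triple or from a precomputed per-compartment unit potential profile
    plus ``program``. ``record_nodes`` are node indices (negative from the
    distal end) whose transmembrane potential is recorded.
    """
    coef = _coefficients(geom, config.dt_ms)
    n_steps = int(round(config.epoch_ms / config.dt_ms))

    if program is not None:
        if phi_unit_mv_per_ma is None:
            if pose is None:
                raise ValueError("extracellular drive needs a pose or a "
                                 "unit potential profile")
            field_model = field_model or FieldModel()
            r = fiber_distance_profile(pose, geom)
            rho_ohm_m = field_model.resistivity_ohm_cm * 0.01
            # phi[V] = rho * I[A] / (4 pi r[m]); in mV per mA with r in mm
            # the metre->millimetre conversion leaves a factor 1000.
            phi_unit_mv_per_ma = 1.0e3 * rho_ohm_m / (4.0 * np.pi * r)
        stim = step_average_current(program, config.dt_ms, n_steps)
    else:
        phi_unit_mv_per_ma = np.zeros(geom.n_compartments)
        stim = np.zeros(n_steps)
    phi_unit_mv_per_ma = np.ascontiguousarray(phi_unit_mv_per_ma, dtype=float)

    inj, inj_comp = _injection_array(injection, geom, config, n_steps)

    vi, w, gates = _settled_state(geom, config)
    stochastic = config.variant == "stochastic"
    pop = None
    if stochastic:
        pop = allocate_channels(config.n_na, geom=geom)

    node_comp = geom.node_compartments
    rec_nodes = [int(node_comp[i]) for i in record_nodes]
    rec_comp = np.asarray(rec_nodes, dtype=np.int64)

    v_rec = _run_kernel(geom, coef, config, vi, w, gates,
                        stim=stim, inj=inj, phi_unit=phi_unit_mv_per_ma,
                        inj_comp=inj_comp, rec_comp=rec_comp,
                        stochastic=stochastic, pop=pop)
    t = np.arange(n_steps + 1) * config.dt_ms
    return SimResult(t, v_rec, list(record_nodes), config)


# --------------------------------------------------------------------------
# threshold searches
# --------------------------------------------------------------------------

_rheobase_cache: dict = {}


def intracellular_rheobase(geom: FiberGeometry,
                           config: SimulationConfig,
                           pulse_width_ms: float = 0.1) -> float:
    """Minimal intracellular pulse current (nA) at the proximal node that
    elicits a spike propagating to the distal node. Bisection to 2%."""
    key = (_geom_key(geom), config.dt_ms, pulse_width_ms)
    if key in _rheobase_cache:
        return _rheobase_cache[key]
    epoch = 2.0 + geom.total_length_um * 1e-4 / 2.0  # generous travel time
    cfg = replace(config, epoch_ms=epoch, variant="deterministic", n_na=None)

    def fires(amp: float) -> bool:
        sched = InjectionSchedule(np.array([0.2]), amp, pulse_width_ms)
        res = run_fiber(geom, cfg, injection=sched, record_nodes=(-1,))
        return len(res.spike_train()) > 0

    lo, hi = 0.0, 1.0
    for _ in range(20):
        if fires(hi):
            break
        lo, hi = hi, hi * 2.0
    else:
        raise RuntimeError("no intracellular threshold bracket found")
    while (hi - lo) / hi > 0.02:
        mid = 0.5 * (lo + hi)
        lo, hi = (lo, mid) if fires(mid) else (mid, hi)
    _rheobase_cache[key] = hi
    return hi


def is_activated(geom: FiberGeometry, pose: FiberPose,
                 program: StimulusProgram, amplitude_ma: float,
                 config: SimulationConfig,
                 field_model: FieldModel | None = None,
                 test_ms: float = 100.0,
                 follow_fraction: float = 0.9) -> bool:
    """Does a test train at this amplitude drive the fiber one-for-one?

    'Activated' means at least ``follow_fraction`` of the pulses in a
    ``test_ms`` train are answered by a spike propagating to the distal
    recording node.
    """
    cfg = replace(config, epoch_ms=test_ms)
    prog = program.with_amplitude(amplitude_ma)
    res = run_fiber(geom, cfg, pose=pose, field_model=field_model,
                    program=prog, record_nodes=(-1,))
    n_pulses = int(np.floor(test_ms / prog.period_ms))
    n_pulses = max(n_pulses, 1)
    return len(res.spike_train()) >= follow_fraction * n_pulses


def find_activation_current(geom: FiberGeometry, pose: FiberPose,
                            program: StimulusProgram,
                            config: SimulationConfig,
                            field_model: FieldModel | None = None,
                            bracket: tuple[float, float] = (0.01, 50.0),
                            rel_tol: float = 0.01,
                            test_ms: float = 100.0) -> float:
    """Bisection for the minimal amplitude (mA) that activates the fiber.

    The upper edge is found by doubling from the lower bracket edge, since
    far suprathreshold kHz-range amplitudes can block rather than activate
    and a fixed upper bracket need not itself be 'activated'.
    """
    lo, hi_max = bracket
    if is_activated(geom, pose, program, lo, config, field_model, test_ms):
        return lo
    hi = lo
    while True:
        hi *= 2.0
        if hi > hi_max:
            raise RuntimeError(f"no activating amplitude below {hi_max} mA")
        if is_activated(geom, pose, program, hi, config, field_model,
                        test_ms):
            break
        lo = hi
    while (hi - lo) / hi > rel_tol:
        mid = 0.5 * (lo + hi)
        if is_activated(geom, pose, program, mid, config, field_model,
                        test_ms):
            hi = mid
        else:
            lo = mid
    return hi


def detect_conduction_block(intended_times_ms: np.ndarray,
                            distal_train: SpikeTrain,
                            window_ms: tuple[float, float] | None = None,
                            partial_fraction: float = 0.5) -> str:
    """Classify propagation of intrinsic drive: blocked / partial / conducting.

    The analysis window excludes the onset transient (first 100 ms by
    default), during which even fibers headed for block emit spikes.
    """
    intended = np.asarray(intended_times_ms)
    if intended.size == 0:
        raise ValueError("block classification needs intrinsic drive")
    if window_ms is None:
        window_ms = (ONSET_EXCLUSION_MS, distal_train.epoch_ms)
    lo, hi = window_ms
    n_int = int(np.sum((intended >= lo) & (intended < hi)))
    got = distal_train.spike_times_ms
    n_got = int(np.sum((got >= lo) & (got < hi)))
    if n_int == 0:
        return "conducting"
    if n_got == 0:
        return "blocked"
    if n_got < partial_fraction * n_int:
        return "partial"
    return "conducting"


def find_block_threshold(geom: FiberGeometry, pose: FiberPose,
                         program: StimulusProgram,
                         config: SimulationConfig,
                         injection: InjectionSchedule,
                         field_model: FieldModel | None = None,
                         bracket: tuple[float, float] = (0.05, 100.0),
                         rel_tol: float = 0.02,
                         window_ms: tuple[float, float] | None = None,
                         ) -> float:
    """Minimal stimulus amplitude (mA) that blocks conduction of the
    intrinsic drive past the electrode.

    The upper edge is found by doubling from the lower bracket edge: far
    above block threshold, strong stimuli can excite distant nodes and
    re-establish distal activity, so a fixed upper bracket need not itself
    be 'blocked'.
    """

    def blocked(amp: float) -> bool:
        prog = program.with_amplitude(amp)
        res = run_fiber(geom, config, pose=pose, field_model=field_model,
                        program=prog, injection=injection,
                        record_nodes=(-1,))
        status = detect_conduction_block(injection.spike_times_ms,
                                         res.spike_train(), window_ms)
        return status == "blocked"

    lo, hi_max = bracket
    if blocked(lo):
        return lo
    hi = lo
    while True:
        hi *= 2.0
        if hi > hi_max:
            raise RuntimeError(f"no blocking amplitude below {hi_max} mA")
        if blocked(hi):
            break
        lo = hi
    while (hi - lo) / hi > rel_tol:
        mid = 0.5 * (lo + hi)
        if blocked(mid):
            hi = mid
        else:
            lo = mid
    return hi
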