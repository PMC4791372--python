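"""Compartmental geometry and nodal membrane dynamics of a myelinated axon.

The fiber is a double-cable model of a mammalian myelinated axon (the MRG
motor-axon model): explicit nodes of Ranvier carrying fast Na+, persistent
Na+, slow K+ and leak conductances, flanked by passive myelin attachment
(MYSA), main paranode (FLUT) and internodal (STIN) sections. Each section
has an axolemma (inner membrane) and, outside it, a periaxonal space under
the myelin sheath, giving two coupled longitudinal cables.

Units throughout: lengths um, potentials mV, time ms, conductances uS,
capacitances nF, currents nA.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal

import numpy as np

__all__ = [
    "KIND_NODE",
    "KIND_MYSA",
    "KIND_FLUT",
    "KIND_STIN",
    "FiberGeometry",
    "NodalConductances",
    "MembraneState",
    "UnsupportedDiameterError",
    "load_parameter_table",
    "build_fiber",
    "gating_rates",
    "steady_state_gates",
    "resting_gates",
    "membrane_current",
]

# Compartment kind codes (stable integers, used by the integration kernel).
KIND_NODE = 0
KIND_MYSA = 1  # paranode_attach
KIND_FLUT = 2  # paranode_main
KIND_STIN = 3  # internode

_KIND_NAMES = {KIND_NODE: "node", KIND_MYSA: "paranode_attach",
               KIND_FLUT: "paranode_main", KIND_STIN: "internode"}

# Conversion factors to the package unit system.
_S_CM2_TO_US_UM2 = 0.01      # 1 S/cm2 = 0.01 uS/um2
_UF_CM2_TO_NF_UM2 = 1.0e-5   # 1 uF/cm2 = 1e-5 nF/um2
_OHM_CM_TO_OHM_UM = 1.0e4


class UnsupportedDiameterError(ValueError):
    """Raised when no parameter row exists for the requested fiber diameter."""


def load_parameter_table() -> dict:
    """Load the versioned fiber parameter table shipped with the package."""
    with resources.files("axondbs.data").joinpath(
            "mrg_fiber_parameters.json").open() as fh:
        return json.load(fh)


@dataclass(frozen=True)
class NodalConductances:
    """Maximal conductance densities and reversal potentials at the node.

    Densities are in S/cm2, potentials in mV, capacitance in uF/cm2. The
    same values are used for deterministic and stochastic channel variants;
    stochastic variants divide the nodal maxima into integer channels.
    """

    gnaf_max: float = 3.0
    gnap_max: float = 0.01
    gks_max: float = 0.08
    glk: float = 0.007
    e_na: float = 50.0
    e_k: float = -90.0
    e_lk: float = -90.0
    c_m: float = 2.0
    temperature_c: float = 36.0

    def __post_init__(self):
        for name in ("gnaf_max", "gnap_max", "gks_max", "glk"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("e_na", "e_k", "e_lk"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @classmethod
    def from_table(cls, table: dict | None = None) -> "NodalConductances":
        table = table or load_parameter_table()
        node = table["node"]
        return cls(
            gnaf_max=node["gnaf_max_s_cm2"],
            gnap_max=node["gnap_max_s_cm2"],
            gks_max=node["gks_max_s_cm2"],
            glk=node["glk_s_cm2"],
            e_na=node["e_na_mv"],
            e_k=node["e_k_mv"],
            e_lk=node["e_lk_mv"],
            c_m=node["c_m_uf_cm2"],
            temperature_c=table["global"]["temperature_c"],
        )


@dataclass
class FiberGeometry:
    """Compartmentalized axon: nodes, paranodes and internodes in sequence.

    Arrays are ordered proximal -> distal. ``kind`` holds the compartment
    kind codes; ``position_um`` is the axial center of each compartment and
    is strictly increasing. Nodes are at indices ``node_compartments``.
    """

    diameter_um: float
    n_nodes: int
    internode_spacing_um: float
    kind: np.ndarray               # (n_comp,) int8 kind codes
    length_um: np.ndarray          # (n_comp,) compartment length
    axon_diameter_um: np.ndarray   # (n_comp,) inner (axolemma) diameter
    position_um: np.ndarray        # (n_comp,) axial center position
    periaxonal_space_um: np.ndarray  # (n_comp,) periaxonal gap width
    n_myelin_lamellae: int
    electrode_node_index: int      # node aligned nearest the electrode
    params: dict = field(repr=False, default_factory=dict)

    @property
    def n_compartments(self) -> int:
        return self.kind.size

    @property
    def node_compartments(self) -> np.ndarray:
        return np.flatnonzero(self.kind == KIND_NODE)

    @property
    def total_length_um(self) -> float:
        return (self.n_nodes - 1) * self.internode_spacing_um

    @property
    def node_area_um2(self) -> float:
        """Membrane area of one node of Ranvier (cylinder, pi*d*L)."""
        i = int(self.node_compartments[0])
        return math.pi * self.axon_diameter_um[i] * self.length_um[i]

    def kind_names(self) -> list[str]:
        return [_KIND_NAMES[int(k)] for k in self.kind]


# How many nodes from the distal end the electrode-aligned node sits.
ELECTRODE_NODE_FROM_DISTAL = 40


def build_fiber(diameter_um: float = 5.7, n_nodes: int = 81,
                table: dict | None = None) -> FiberGeometry:
    """Build the compartment sequence for a fiber of the given diameter.

    The repeating unit between consecutive nodes is
    node - MYSA - FLUT - 6x STIN - FLUT - MYSA - node, with dimensions from
    the parameter table row for ``diameter_um``. Total length is
    ``(n_nodes - 1) * internode_spacing``.
    """
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    table = table or load_parameter_table()
    key = f"{float(diameter_um):g}"
    rows = {f"{float(k):g}": v for k, v in table["diameters"].items()}
    if key not in rows:
        raise UnsupportedDiameterError(
            f"no parameter row for fiber diameter {diameter_um} um; "
            f"supported: {sorted(rows)}")
    row = rows[key]
    g = table["global"]

    deltax = row["internode_spacing_um"]
    node_l = g["node_length_um"]
    mysa_l = g["mysa_length_um"]
    flut_l = row["flut_length_um"]
    n_stin = g["n_stin_per_internode"]
    stin_l = (deltax - node_l - 2 * mysa_l - 2 * flut_l) / n_stin
    if stin_l <= 0:
        raise ValueError("inconsistent section lengths in parameter table")

    kinds, lengths, diams, spaces = [], [], [], []

    def add(kind, length, diam, space):
        kinds.append(kind)
        lengths.append(length)
        diams.append(diam)
        spaces.append(space)

    node_d = row["node_diameter_um"]
    mysa_d = row["mysa_diameter_um"]
    axon_d = row["axon_diameter_um"]
    sp = g
    for i in range(n_nodes):
        add(KIND_NODE, node_l, node_d, sp["periaxonal_space_node_um"])
        if i < n_nodes - 1:
            add(KIND_MYSA, mysa_l, mysa_d, sp["periaxonal_space_mysa_um"])
            add(KIND_FLUT, flut_l, axon_d, sp["periaxonal_space_flut_um"])
            for _ in range(n_stin):
                add(KIND_STIN, stin_l, axon_d, sp["periaxonal_space_stin_um"])
            add(KIND_FLUT, flut_l, axon_d, sp["periaxonal_space_flut_um"])
            add(KIND_MYSA, mysa_l, mysa_d, sp["periaxonal_space_mysa_um"])

    lengths = np.asarray(lengths)
    edges = np.concatenate([[0.0], np.cumsum(lengths)])
    positions = 0.5 * (edges[:-1] + edges[1:])

    return FiberGeometry(
        diameter_um=float(diameter_um),
        n_nodes=n_nodes,
        internode_spacing_um=deltax,
        kind=np.asarray(kinds, dtype=np.int8),
        length_um=lengths,
        axon_diameter_um=np.asarray(diams),
        position_um=positions,
        periaxonal_space_um=np.asarray(spaces),
        n_myelin_lamellae=int(row["n_myelin_lamellae"]),
        electrode_node_index=max(n_nodes - 1 - ELECTRODE_NODE_FROM_DISTAL, 0),
        params=table,
    )


# ---------------------------------------------------------------------------
# Nodal gating kinetics (AXNODE scheme; rates in 1/ms, voltages in mV).
# Q10 corrections referenced to the published measurement temperatures.
# ---------------------------------------------------------------------------

_CELSIUS = 36.0
_Q10_MP = 2.2 ** ((_CELSIUS - 20.0) / 10.0)   # fast/persistent Na activation
_Q10_H = 2.9 ** ((_CELSIUS - 20.0) / 10.0)    # fast Na inactivation
_Q10_S = 3.0 ** ((_CELSIUS - 36.0) / 10.0)    # slow K (already at 36 C)

GateName = Literal["naf_m", "naf_h", "nap_p", "ks_s"]
GATE_NAMES: tuple[str, ...] = ("naf_m", "naf_h", "nap_p", "ks_s")


def _vtrap(num_coeff: float, x: np.ndarray, scale: float) -> np.ndarray:
    """Evaluate a*x / (1 - exp(-x/s)) with the removable singularity at 0."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-7
    out[~small] = num_coeff * x[~small] / (1.0 - np.exp(-x[~small] / scale))
    out[small] = num_coeff * scale  # limit of x/(1-exp(-x/s)) is s
    return out


def gating_rates(v, channel: GateName):
    """Forward/backward rate constants (alpha, beta) in 1/ms at potential v.

    Rate expressions are those of the adopted axon model's nodal channels,
    temperature-corrected to 36 C. ``v`` may be scalar or array.
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("membrane potential must be finite")
    if channel == "naf_m":
        alpha = _Q10_MP * _vtrap(6.57, v + 20.4, 10.3)
        beta = _Q10_MP * _vtrap(0.304, -(v + 25.7), 9.16)
    elif channel == "naf_h":
        alpha = _Q10_H * _vtrap(0.34, -(v + 114.0), 11.0)
        beta = _Q10_H * 12.6 / (1.0 + np.exp(-(v + 31.8) / 13.4))
    elif channel == "nap_p":
        alpha = _Q10_MP * _vtrap(0.0353, v + 27.0, 10.2)
        beta = _Q10_MP * _vtrap(0.000883, -(v + 34.0), 10.0)
    elif channel == "ks_s":
        alpha = _Q10_S * 0.3 / (1.0 + np.exp((v + 53.0) / -5.0))
        beta = _Q10_S * 0.03 / (1.0 + np.exp((v + 90.0) / -1.0))
    else:
        raise ValueError(f"unknown channel {channel!r}")
    if v.ndim == 0:
        return float(alpha), float(beta)
    return alpha, beta


def steady_state_gates(v: float) -> dict[str, float]:
    """Steady-state open fraction x_inf = alpha/(alpha+beta) for each gate."""
    out = {}
    for name in GATE_NAMES:
        a, b = gating_rates(float(v), name)
        out[name] = a / (a + b)
    return out


def resting_gates(v_rest: float = -80.0) -> dict[str, float]:
    """Gate initialization values: steady state at the resting potential."""
    return steady_state_gates(v_rest)


@dataclass
class MembraneState:
    """Per-compartment potentials and per-node gating state.

    ``v`` is the transmembrane (axolemma) potential of every compartment;
    ``v_periaxonal`` the potential of the periaxonal space relative to the
    distant extracellular ground. ``gates`` maps gate name -> per-node
    fraction in [0, 1].
    """

    v: np.ndarray
    v_periaxonal: np.ndarray
    gates: dict[str, np.ndarray]
    t: float = 0.0

    def validate(self):
        for name, x in self.gates.items():
            if np.any((x < 0) | (x > 1)):
                raise ValueError(f"gate {name} outside [0, 1]")

    @classmethod
    def at_rest(cls, geom: FiberGeometry, v_rest: float = -80.0):
        n = geom.n_compartments
        nn = geom.n_nodes
        g0 = resting_gates(v_rest)
        return cls(
            v=np.full(n, v_rest),
            v_periaxonal=np.zeros(n),
            gates={k: np.full(nn, val) for k, val in g0.items()},
            t=0.0,
        )


def membrane_current(state: MembraneState, geom: FiberGeometry,
                     cond: NodalConductances | None = None,
                     table: dict | None = None) -> np.ndarray:
    """Ionic (non-capacitive) membrane current density per compartment.

    Returns mA/cm2, positive outward. Nodes carry
    gNaf*m^3*h*(v-E_Na) + gNap*p^3*(v-E_Na) + gKs*s*(v-E_K) + gLk*(v-E_L);
    paranode/internode compartments carry only the passive axolemma leak
    (myelin current is part of the cable system, not of this density).
    """
    cond = cond or NodalConductances.from_table(table)
    table = table or load_parameter_table()
    state.validate()
    g = table["global"]
    v = state.v
    out = np.empty_like(v)

    gpas = {KIND_MYSA: g["g_pas_mysa_s_cm2"],
            KIND_FLUT: g["g_pas_flut_s_cm2"],
            KIND_STIN: g["g_pas_stin_s_cm2"]}
    for kind, gp in gpas.items():
        m = geom.kind == kind
        out[m] = gp * (v[m] - g["e_pas_mv"])

    nodes = geom.node_compartments
    vn = v[nodes]
    m, h = state.gates["naf_m"], state.gates["naf_h"]
    p, s = state.gates["nap_p"], state.gates["ks_s"]
    out[nodes] = (cond.gnaf_max * m ** 3 * h * (vn - cond.e_na)
                  + cond.gnap_max * p ** 3 * (vn - cond.e_na)
                  + cond.gks_max * s * (vn - cond.e_k)
                  + cond.glk * (vn - cond.e_lk))
    return out
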