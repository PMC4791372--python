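"""Markov-scheme stochastic gating for nodal fast Na+ and slow K+ channels.

Fast Na+ channels follow the canonical 8-state m3h topology (four m closed
states x available/inactivated h), slow K+ channels the 2-state closed/open
scheme of the s gate; transition rates are the deterministic alpha/beta
functions, so the deterministic model is the exact large-N limit. The
persistent Na+ conductance stays deterministic in every variant.

Per-node channel counts are configurable; nodal maximal conductances are
held equal to the deterministic model by setting the single-channel
conductance to (nodal maximum) / (channel count).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fiber import FiberGeometry, NodalConductances, gating_rates

__all__ = [
    "NA_KA_RATIO",
    "ChannelPopulation",
    "allocate_channels",
    "channels_per_node_from_density",
    "markov_step",
    "na_open_fraction",
    "k_open_fraction",
]

# Published K+:Na+ channel count ratio, N_K = N_Na * 18/60.
NA_KA_RATIO = 18.0 / 60.0

N_NA_STATES = 8  # (m_count 0..3) x (h in {inactivated, available})
N_K_STATES = 2   # closed, open


@dataclass
class ChannelPopulation:
    """Integer Markov-state occupancies for one node (or a batch of nodes).

    ``na_states`` has shape (..., 8): index 4*h + m_count, h=1 available.
    ``k_states`` has shape (..., 2): index 1 = open. Single-channel
    conductances are in pS.
    """

    n_na: int
    n_k: int
    gamma_na_ps: float
    gamma_k_ps: float
    na_states: np.ndarray
    k_states: np.ndarray

    def check_conservation(self):
        if not np.all(self.na_states.sum(axis=-1) == self.n_na):
            raise ValueError("Na channel count not conserved")
        if not np.all(self.k_states.sum(axis=-1) == self.n_k):
            raise ValueError("K channel count not conserved")
        if np.any(self.na_states < 0) or np.any(self.k_states < 0):
            raise ValueError("negative state occupancy")


def channels_per_node_from_density(density_per_um2: float,
                                   node_area_um2: float) -> int:
    """Channels per node from a membrane density and the nodal area."""
    if density_per_um2 <= 0 or node_area_um2 <= 0:
        raise ValueError("density and area must be positive")
    return int(round(density_per_um2 * node_area_um2))


def allocate_channels(n_na: int, geom: FiberGeometry | None = None,
                      cond: NodalConductances | None = None,
                      n_nodes: int | None = None,
                      v_init: float = -80.0,
                      rng: np.random.Generator | None = None,
                      ) -> ChannelPopulation:
    """Allocate per-node channel populations for ``n_na`` fast Na+ channels.

    K+ count follows the linear rule N_K = round(N_Na * 18/60). If a fiber
    geometry is given, single-channel conductances are chosen so the nodal
    maxima equal the deterministic model's. States are initialized at the
    steady state for ``v_init`` (deterministically rounded, or multinomially
    sampled when ``rng`` is passed).
    """
    if n_na < 1:
        raise ValueError("n_na must be >= 1")
    n_k = int(round(n_na * NA_KA_RATIO))
    cond = cond or NodalConductances()

    if geom is not None:
        area = geom.node_area_um2
        n_nodes = n_nodes or geom.n_nodes
    else:
        area = 1.0e8 / 12000.0 / 5.97  # placeholder; only ratios matter
        n_nodes = n_nodes or 1
    # nodal max conductance in pS: density S/cm2 * area um2 * 1e4 pS/(S/cm2*um2)
    gna_max_ps = cond.gnaf_max * area * 1.0e4
    gk_max_ps = cond.gks_max * area * 1.0e4

    pna = _na_state_distribution(v_init)
    pk = _k_state_distribution(v_init)
    shape_na = (n_nodes, N_NA_STATES)
    shape_k = (n_nodes, N_K_STATES)
    if rng is None:
        na = _largest_remainder(pna, n_na, n_nodes)
        k = _largest_remainder(pk, n_k, n_nodes)
    else:
        na = rng.multinomial(n_na, pna, size=n_nodes)
        k = rng.multinomial(n_k, pk, size=n_nodes)
    na = na.reshape(shape_na).astype(np.int64)
    k = k.reshape(shape_k).astype(np.int64)

    return ChannelPopulation(
        n_na=n_na, n_k=max(n_k, 1),
        gamma_na_ps=gna_max_ps / n_na,
        gamma_k_ps=gk_max_ps / max(n_k, 1),
        na_states=na, k_states=k,
    )


def _largest_remainder(p: np.ndarray, n: int, n_nodes: int) -> np.ndarray:
    """Deterministic integer apportionment of n channels to states p."""
    raw = p * n
    base = np.floor(raw).astype(np.int64)
    rem = n - base.sum()
    order = np.argsort(raw - base)[::-1]
    base[order[:rem]] += 1
    return np.tile(base, (n_nodes, 1))


def _na_state_distribution(v: float) -> np.ndarray:
    am, bm = gating_rates(v, "naf_m")
    ah, bh = gating_rates(v, "naf_h")
    m = am / (am + bm)
    h = ah / (ah + bh)
    from math import comb
    p = np.empty(N_NA_STATES)
    for hi in (0, 1):
        ph = h if hi == 1 else 1.0 - h
        for mi in range(4):
            p[4 * hi + mi] = ph * comb(3, mi) * m ** mi * (1 - m) ** (3 - mi)
    return p / p.sum()


def _k_state_distribution(v: float) -> np.ndarray:
    a, b = gating_rates(v, "ks_s")
    s = a / (a + b)
    return np.array([1.0 - s, s])


def na_open_fraction(pop: ChannelPopulation) -> np.ndarray:
    """Fraction of Na channels in the conducting state (m3, available)."""
    return pop.na_states[..., 7] / pop.n_na


def k_open_fraction(pop: ChannelPopulation) -> np.ndarray:
    return pop.k_states[..., 1] / pop.n_k


def markov_step(pop: ChannelPopulation, v: float, dt: float,
                rng: np.random.Generator, max_substeps: int = 10000,
                ) -> ChannelPopulation:
    """Advance all channel populations one time step at fixed potential.

    Transitions are sampled with competing-risk binomials: each state's
    total exit probability over a substep is 1 - exp(-R*dt_sub) and leavers
    are split multinomially among destinations in proportion to rates. Time
    steps with fast rates are automatically subdivided so that the largest
    single-transition probability stays below ~0.5 per substep, which keeps
    the one-jump-per-substep approximation accurate. Channel totals are
    conserved exactly. Raises if the required subdivision exceeds
    ``max_substeps``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    am, bm = gating_rates(v, "naf_m")
    ah, bh = gating_rates(v, "naf_h")
    as_, bs = gating_rates(v, "ks_s")

    max_rate = max(3 * am, 3 * bm, ah, bh, as_, bs)
    n_sub = max(1, int(np.ceil(max_rate * dt / 0.5)))
    if n_sub > max_substeps:
        raise ValueError(
            f"dt too large for rates at v={v:.1f} mV ({n_sub} substeps needed)")
    h = dt / n_sub

    na = pop.na_states.copy()
    k = pop.k_states.copy()
    for _ in range(n_sub):
        na = _na_substep(na, am, bm, ah, bh, h, rng)
        k = _k_substep(k, as_, bs, h, rng)

    out = ChannelPopulation(pop.n_na, pop.n_k, pop.gamma_na_ps,
                            pop.gamma_k_ps, na, k)
    out.check_conservation()
    return out


def _na_substep(states, am, bm, ah, bh, h, rng):
    flat = states.reshape(-1, N_NA_STATES)
    new = flat.copy()
    for idx in range(N_NA_STATES):
        hi, mi = divmod(idx, 4)
        rates, dests = [], []
        if mi < 3:
            rates.append((3 - mi) * am)
            dests.append(4 * hi + mi + 1)
        if mi > 0:
            rates.append(mi * bm)
            dests.append(4 * hi + mi - 1)
        rates.append(ah if hi == 0 else bh)
        dests.append(4 * (1 - hi) + mi)
        total = sum(rates)
        if total <= 0:
            continue
        p_leave = -np.expm1(-total * h)
        n_leave = rng.binomial(flat[:, idx], p_leave)
        remaining = n_leave.copy()
        rem_rate = total
        for r, d in zip(rates[:-1], dests[:-1]):
            moved = rng.binomial(remaining, r / rem_rate)
            new[:, d] += moved
            remaining -= moved
            rem_rate -= r
        new[:, dests[-1]] += remaining
        new[:, idx] -= n_leave
    return new.reshape(states.shape)


def _k_substep(states, a, b, h, rng):
    flat = states.reshape(-1, N_K_STATES)
    opened = rng.binomial(flat[:, 0], -np.expm1(-a * h))
    closed = rng.binomial(flat[:, 1], -np.expm1(-b * h))
    new = flat.copy()
    new[:, 0] += closed - opened
    new[:, 1] += opened - closed
    return new.reshape(states.shape)
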