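"""Stiff-spring compatibility mode: subunits as bead-spring composites.

Instead of rigid-body integration, every bead and site is a point particle
of mass ``m`` and all particle pairs within a subunit are connected by
harmonic springs of constant ``spring_K`` (in k_b*T/sigma^2), which holds
each composite effectively rigid.  Inter-subunit interactions reuse the WCA
and cosine-site pair kernels.  This mode reproduces the same physics as the
rigid integrator at considerably higher cost and is intended for small
systems and cross-checks; the rigid mode is the default everywhere else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .engine import SimulationState, NEIGHBOR_SKIN
from .params import ModelParameters

__all__ = ["FlexibleState", "from_rigid_state", "step_langevin_flexible",
           "shape_deviation"]


@dataclass
class FlexibleState:
    params: ModelParameters
    pos: np.ndarray          # (P, 3) all beads and sites
    vel: np.ndarray
    sub_id: np.ndarray       # (P,)
    ptype: np.ndarray        # (P,) particle codes (0 bead, 1..6 sites)
    immobile: np.ndarray     # (P,) bool
    spring_i: np.ndarray     # bond list (intra-subunit, all pairs)
    spring_j: np.ndarray
    spring_r0: np.ndarray
    time: float = 0.0

    @property
    def n_particles(self) -> int:
        return len(self.pos)


def from_rigid_state(state: SimulationState) -> FlexibleState:
    """Expand a rigid state into the bead-spring representation."""
    pos, sub, ptype = state.particle_positions()
    npart = len(pos)
    per = 35
    immobile = np.repeat(state.immobile[~state.culled]
                         if state.culled.any() else state.immobile, per)
    si, sj = [], []
    for s in range(npart // per):
        base = s * per
        for i in range(per):
            for j in range(i + 1, per):
                si.append(base + i)
                sj.append(base + j)
    si = np.array(si, np.int64)
    sj = np.array(sj, np.int64)
    r0 = np.linalg.norm(pos[si] - pos[sj], axis=1)
    return FlexibleState(
        params=state.params, pos=pos.copy(), vel=np.zeros_like(pos),
        sub_id=sub.copy(), ptype=ptype.copy(), immobile=immobile,
        spring_i=si, spring_j=sj, spring_r0=r0, time=state.time)


def step_langevin_flexible(state: FlexibleState, n_steps: int,
                           rng_seed=None, *, rng=None) -> FlexibleState:
    """BAOAB Langevin dynamics on the bead-spring system (in place)."""
    p = state.params
    dt = p.timestep
    kT = p.kT
    gamma = p.damping
    m = p.mass
    kspring = p.spring_K * kT / p.sigma ** 2
    rng = rng or np.random.default_rng(rng_seed)
    mobile = ~state.immobile
    mob = mobile[:, None]
    rlist = 2.0 ** (1.0 / 6.0) * p.sigma + NEIGHBOR_SKIN
    a_vals = np.array([p.A_intra, p.A_vertical, p.A_lateral]) * kT
    if gamma > 0:
        c1 = math.exp(-gamma * dt)
        c2 = math.sqrt((1 - c1 * c1) * kT / m)

    cap = max(64, 60 * state.n_particles)
    pi = np.empty(cap, np.int64)
    pj = np.empty(cap, np.int64)
    pk = np.empty(cap, np.int8)
    npairs = 0
    ref = None

    def forces():
        nonlocal npairs, ref, pi, pj, pk, cap
        if ref is None or np.abs(state.pos - ref).max() > 0.5 * NEIGHBOR_SKIN:
            while True:
                npairs = _kernels.build_pairs(
                    state.pos, state.sub_id, state.ptype, _kernels.SITE_KIND,
                    rlist, pi, pj, pk)
                if npairs <= cap:
                    break
                cap = int(1.3 * npairs) + 64
                pi = np.empty(cap, np.int64)
                pj = np.empty(cap, np.int64)
                pk = np.empty(cap, np.int8)
            ref = state.pos.copy()
        f = np.zeros_like(state.pos)
        contacts = np.zeros(int(state.sub_id.max()) + 1, np.int64)
        _kernels.pair_forces(state.pos, pi, pj, pk, npairs, state.sub_id,
                             p.epsilon, p.sigma, p.site_cutoff * p.sigma,
                             a_vals, f, contacts)
        _kernels.spring_forces(state.pos, state.spring_i, state.spring_j,
                               state.spring_r0, kspring, f)
        return f

    f = forces()
    for _ in range(n_steps):
        state.vel += np.where(mob, 0.5 * dt * f / m, 0.0)
        state.pos += np.where(mob, 0.5 * dt * state.vel, 0.0)
        if gamma > 0:
            state.vel = np.where(mob, c1 * state.vel
                                 + c2 * rng.standard_normal(state.pos.shape),
                                 state.vel)
        state.pos += np.where(mob, 0.5 * dt * state.vel, 0.0)
        f = forces()
        state.vel += np.where(mob, 0.5 * dt * f / m, 0.0)
        state.time += dt
    return state


def shape_deviation(state: FlexibleState) -> float:
    """Largest relative deviation of intra-subunit distances from template."""
    d = np.linalg.norm(state.pos[state.spring_i] - state.pos[state.spring_j],
                       axis=1)
    return float(np.abs(d / state.spring_r0 - 1.0).max())
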