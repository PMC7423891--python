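"""Rigid-subunit Langevin dynamics for the wedge microtubule model.

Each tubulin monomer is integrated as one rigid body (6 degrees of freedom):
its 27 beads and 8 attractive sites move with the body frame.  Pair
interactions are the cut-and-shifted (WCA) Lennard-Jones repulsion between
beads of different subunits and a short-range cosine well between
label-matched attractive sites.  The thermostat is a BAOAB-split Langevin
integrator: exact Ornstein-Uhlenbeck updates act on the linear momentum and
on the body-frame angular momentum (rotational friction equals the
translational ``damping``), and free rotations use a symplectic
principal-axis splitting.  Energy minimization uses FIRE on the same rigid
degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernels
from .params import ModelParameters
from . import geometry

__all__ = [
    "EngineError", "EngineInstability", "MinimizationError", "NeighborListOverflow",
    "TemplateSet", "SimulationState", "Trajectory", "MinimizeInfo",
    "pair_energy_wca", "site_energy", "compute_forces", "minimize",
    "step_langevin", "run_depolymerization", "build_protofilament_chain",
]

# body type codes
ALPHA_UNC, ALPHA_COMP, BETA = 0, 1, 2
# site type codes (see _kernels)
S_A_TOP, S_B_BOT, S_B_TOP, S_A_BOT, S_L_LEFT, S_L_RIGHT = 1, 2, 3, 4, 5, 6

NEIGHBOR_SKIN = 0.45


class EngineError(RuntimeError):
    pass


class EngineInstability(EngineError):
    """A subunit moved more than sigma in a single step."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class MinimizationError(EngineError):
    pass


class NeighborListOverflow(EngineError):
    pass


# ---------------------------------------------------------------------------
# quaternion utilities (scalar-first convention, vectorized over bodies)

def quat_mul(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    w1, x1, y1, z1 = a[..., 0], a[..., 1], a[..., 2], a[..., 3]
    w2, x2, y2, z2 = b[..., 0], b[..., 1], b[..., 2], b[..., 3]
    return np.stack([
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
    ], axis=-1)


def quat_to_mat(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q[..., 0], q[..., 1], q[..., 2], q[..., 3]
    m = np.empty(q.shape[:-1] + (3, 3))
    m[..., 0, 0] = 1 - 2 * (y * y + z * z)
    m[..., 0, 1] = 2 * (x * y - w * z)
    m[..., 0, 2] = 2 * (x * z + w * y)
    m[..., 1, 0] = 2 * (x * y + w * z)
    m[..., 1, 1] = 1 - 2 * (x * x + z * z)
    m[..., 1, 2] = 2 * (y * z - w * x)
    m[..., 2, 0] = 2 * (x * z - w * y)
    m[..., 2, 1] = 2 * (y * z + w * x)
    m[..., 2, 2] = 1 - 2 * (x * x + y * y)
    return m


def quat_from_mat(m: np.ndarray) -> np.ndarray:
    # Shepperd's method, single matrix
    t = np.trace(m)
    if t > 0:
        s = math.sqrt(t + 1.0) * 2
        return np.array([0.25 * s, (m[2, 1] - m[1, 2]) / s,
                         (m[0, 2] - m[2, 0]) / s, (m[1, 0] - m[0, 1]) / s])
    i = int(np.argmax(np.diag(m)))
    j, k = (i + 1) % 3, (i + 2) % 3
    s = math.sqrt(m[i, i] - m[j, j] - m[k, k] + 1.0) * 2
    q = np.empty(4)
    q[0] = (m[k, j] - m[j, k]) / s
    q[1 + i] = 0.25 * s
    q[1 + j] = (m[j, i] + m[i, j]) / s
    q[1 + k] = (m[k, i] + m[i, k]) / s
    return q


def quat_from_rotvec(v: np.ndarray) -> np.ndarray:
    """World-frame rotation vectors -> unit quaternions (vectorized)."""
    angle = np.linalg.norm(v, axis=-1, keepdims=True)
    half = 0.5 * angle
    small = angle[..., 0] < 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        axis = np.where(small[..., None], 0.0, v / np.where(angle == 0, 1.0, angle))
    q = np.concatenate([np.cos(half), np.sin(half) * axis], axis=-1)
    q[small] = (1.0, 0.0, 0.0, 0.0)
    return q


def quat_about_z(angle: float) -> np.ndarray:
    return np.array([math.cos(angle / 2), 0.0, 0.0, math.sin(angle / 2)])


def _normalize(q: np.ndarray) -> np.ndarray:
    return q / np.linalg.norm(q, axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# templates

@dataclass
class TemplateSet:
    """Per-body-type rigid template data in the principal (center-of-mass) frame."""

    params: ModelParameters
    local: np.ndarray        # (3, 35, 3) bead+site coords, principal frame
    ptype: np.ndarray        # (35,) particle codes shared by all types? no: (3,35)
    mass: float              # total subunit mass (27 beads)
    inertia: np.ndarray      # (3, 3) principal moments per body type
    q0: np.ndarray           # (3, 4) principal->geometric-local rotation
    grid_origin: np.ndarray  # (3, 3) geometric grid center in principal frame
    r_max: float             # largest particle radius, for displacement bounds

    N_BEADS = 27
    N_SITES = 8
    N_PARTICLES = 35

    @classmethod
    def build(cls, params: ModelParameters) -> "TemplateSet":
        tpl_unc = geometry.build_wedge_template(False, params)
        tpl_comp = geometry.build_wedge_template(True, params)
        m = params.mass
        local = np.empty((3, 35, 3))
        inertia = np.empty((3, 3))
        q0 = np.empty((3, 4))
        grid_origin = np.empty((3, 3))
        ptype = np.empty((3, 35), dtype=np.int8)
        site_codes = {
            ALPHA_UNC: [S_A_TOP, S_A_TOP, S_A_BOT, S_A_BOT,
                        S_L_LEFT, S_L_LEFT, S_L_RIGHT, S_L_RIGHT],
            ALPHA_COMP: [S_A_TOP, S_A_TOP, S_A_BOT, S_A_BOT,
                         S_L_LEFT, S_L_LEFT, S_L_RIGHT, S_L_RIGHT],
            BETA: [S_B_TOP, S_B_TOP, S_B_BOT, S_B_BOT,
                   S_L_LEFT, S_L_LEFT, S_L_RIGHT, S_L_RIGHT],
        }
        for bt, tpl in ((ALPHA_UNC, tpl_unc), (ALPHA_COMP, tpl_comp), (BETA, tpl_unc)):
            coords = np.vstack([tpl.beads, tpl.sites])
            com = tpl.beads.mean(axis=0)  # beads carry the mass; sites are massless
            centered = coords - com
            bead_c = centered[:27]
            it = m * (np.eye(3) * (bead_c ** 2).sum() - bead_c.T @ bead_c)
            w, ev = np.linalg.eigh(it)
            if np.linalg.det(ev) < 0:
                ev[:, 0] = -ev[:, 0]
            local[bt] = centered @ ev
            inertia[bt] = w
            q0[bt] = quat_from_mat(ev)
            grid_origin[bt] = (0.0 - com) @ ev
            ptype[bt, :27] = 0
            ptype[bt, 27:] = site_codes[bt]
        r_max = float(np.linalg.norm(local.reshape(-1, 3), axis=1).max())
        return cls(params=params, local=local, ptype=ptype, mass=27.0 * m,
                   inertia=inertia, q0=q0, grid_origin=grid_origin, r_max=r_max)

    def place(self, body_type: np.ndarray, r_place: np.ndarray, q_place: np.ndarray):
        """Map geometric placement poses to center-of-mass poses.

        ``r_place``/``q_place`` give the pose of the geometric grid frame; the
        returned ``(pos, quat)`` are the center-of-mass position and the
        principal-frame orientation used by the integrator.
        """
        q0 = self.q0[body_type]
        quat = _normalize(quat_mul(q_place, q0))
        # the grid origin sits at +grid_origin in the principal frame, so
        # com_world = r_place - R(quat) @ grid_origin
        rmat = quat_to_mat(quat)
        pos = r_place - np.einsum("nij,nj->ni", rmat, self.grid_origin[body_type])
        return pos, quat


# ---------------------------------------------------------------------------
# state

@dataclass
class SimulationState:
    """Poses, velocities and metadata of every rigid subunit."""

    params: ModelParameters
    templates: TemplateSet
    body_type: np.ndarray          # (N,) int8
    pos: np.ndarray                # (N, 3) center of mass
    quat: np.ndarray               # (N, 4) principal-frame orientation
    vel: np.ndarray                # (N, 3)
    angmom: np.ndarray             # (N, 3) body-frame angular momentum
    immobile: np.ndarray           # (N,) bool, tethered subunits
    culled: np.ndarray             # (N,) bool, removed from interactions
    time: float = 0.0
    meta: dict = field(default_factory=dict)
    config: object = None          # LatticeConfiguration, if built from one
    reference: dict = field(default_factory=dict)

    _pcache: dict = field(default_factory=dict, repr=False)

    @property
    def n_subunits(self) -> int:
        return len(self.body_type)

    def copy(self) -> "SimulationState":
        return SimulationState(
            params=self.params, templates=self.templates,
            body_type=self.body_type.copy(), pos=self.pos.copy(),
            quat=self.quat.copy(), vel=self.vel.copy(),
            angmom=self.angmom.copy(), immobile=self.immobile.copy(),
            culled=self.culled.copy(), time=self.time,
            meta={k: np.array(v) for k, v in self.meta.items()},
            config=self.config, reference=dict(self.reference))

    # -- particle bookkeeping -------------------------------------------------
    def _particles(self):
        """Static per-particle arrays for the current culled set."""
        key = int(self.culled.sum())
        cache = self._pcache
        if cache.get("key") != key:
            active = np.flatnonzero(~self.culled)
            npart = len(active) * TemplateSet.N_PARTICLES
            sub_of = np.repeat(active, TemplateSet.N_PARTICLES).astype(np.int64)
            ptype = self.templates.ptype[self.body_type[active]].reshape(-1).copy()
            local = self.templates.local[self.body_type[active]]
            cache.update(key=key, active=active, sub_of=sub_of,
                         ptype=ptype, local=local, npart=npart)
        return cache

    def particle_positions(self, rmat: np.ndarray | None = None
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World positions of beads+sites of non-culled subunits.

        Returns ``(positions, subunit_index, particle_type)``.  ``rmat`` may
        supply precomputed per-subunit rotation matrices (all subunits).
        """
        pc = self._particles()
        active = pc["active"]
        rot = quat_to_mat(self.quat[active]) if rmat is None else rmat[active]
        local = pc["local"]
        # explicit expansion (fixed evaluation order, no BLAS dispatch)
        l0 = local[:, :, 0]
        l1 = local[:, :, 1]
        l2 = local[:, :, 2]
        world = np.empty_like(local)
        for i in range(3):
            world[:, :, i] = (l0 * rot[:, None, i, 0]
                              + l1 * rot[:, None, i, 1]
                              + l2 * rot[:, None, i, 2]
                              + self.pos[active, None, i])
        return world.reshape(-1, 3), pc["sub_of"], pc["ptype"]

    def grid_center_positions(self) -> np.ndarray:
        """World positions of the geometric grid centers of all subunits."""
        rmat = quat_to_mat(self.quat)
        origin = self.templates.grid_origin[self.body_type]
        return self.pos + np.einsum("nij,nj->ni", rmat, origin)

    def site_positions(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World positions of all sites (including culled subunits)."""
        rmat = quat_to_mat(self.quat)
        local = self.templates.local[self.body_type][:, 27:, :]
        world = self.pos[:, None, :] + np.einsum("nij,npj->npi", rmat, local)
        codes = self.templates.ptype[self.body_type][:, 27:]
        subs = np.repeat(np.arange(self.n_subunits), TemplateSet.N_SITES)
        return world.reshape(-1, 3), subs, codes.reshape(-1)

    def kinetic_energy(self) -> tuple[float, float]:
        mobile = ~self.immobile & ~self.culled
        m = self.templates.mass
        ke_t = 0.5 * m * float((self.vel[mobile] ** 2).sum())
        inertia = self.templates.inertia[self.body_type[mobile]]
        ke_r = 0.5 * float((self.angmom[mobile] ** 2 / inertia).sum())
        return ke_t, ke_r

    def kinetic_temperature(self) -> float:
        mobile = int((~self.immobile & ~self.culled).sum())
        if mobile == 0:
            return 0.0
        ke_t, ke_r = self.kinetic_energy()
        return 2.0 * (ke_t + ke_r) / (6.0 * mobile * self.params.boltzmann)


# ---------------------------------------------------------------------------
# potentials (scalar API, used directly in tests and by the kernels' contract)

def pair_energy_wca(r, params: ModelParameters | None = None):
    """Cut-and-shifted LJ (WCA) bead repulsion: 4e[(s/r)^12-(s/r)^6]+e, r<2^(1/6)s."""
    params = params or ModelParameters()
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    s6 = (params.sigma / r) ** 6
    e = 4.0 * params.epsilon * (s6 * s6 - s6) + params.epsilon
    return np.where(r < 2.0 ** (1.0 / 6.0) * params.sigma, e, 0.0)[()]


def site_energy(r, A, params: ModelParameters | None = None):
    """Cosine attraction well: -A[1 + cos(pi r / r_c)] for r < r_c, else 0."""
    params = params or ModelParameters()
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or A < 0:
        raise ValueError("r and A must be non-negative")
    rc = params.site_cutoff * params.sigma
    e = -A * (1.0 + np.cos(np.pi * r / rc))
    return np.where(r < rc, e, 0.0)[()]


# ---------------------------------------------------------------------------
# force field driver

class _ForceField:
    """Owns the neighbor list and evaluates total forces/torques."""

    def __init__(self, state: SimulationState):
        self.params = state.params
        p = self.params
        self.rlist = 2.0 ** (1.0 / 6.0) * p.sigma + NEIGHBOR_SKIN
        self.a_vals = np.array([p.A_intra, p.A_vertical, p.A_lateral]) * p.kT
        self._cap = 0
        self._ref_pos = None
        self._ref_quat = None
        self.n_rebuilds = 0

    def _needs_rebuild(self, state) -> bool:
        if self._ref_pos is None or len(self._ref_pos) != state.n_subunits:
            return True
        dr = np.linalg.norm(state.pos - self._ref_pos, axis=1)
        dq = np.linalg.norm(state.quat - self._ref_quat, axis=1)
        bound = dr + 2.0 * dq * state.templates.r_max
        return bool(bound.max() > 0.5 * NEIGHBOR_SKIN)

    def _rebuild(self, state, ppos, sub_of, ptype):
        n = len(ppos)
        if self._cap == 0:
            self._cap = max(64, 40 * n)
            self._alloc()
        for _ in range(4):
            npairs = _kernels.build_pairs(
                ppos, sub_of, ptype, _kernels.SITE_KIND, self.rlist,
                self.pi, self.pj, self.pkind)
            if npairs <= self._cap:
                self.npairs = npairs
                break
            self._cap = int(1.3 * npairs) + 64
            self._alloc()
        else:
            raise NeighborListOverflow(
                f"neighbor list did not fit after retries (needed {npairs})")
        self._ref_pos = state.pos.copy()
        self._ref_quat = state.quat.copy()
        self.n_rebuilds += 1

    def _alloc(self):
        self.pi = np.empty(self._cap, np.int64)
        self.pj = np.empty(self._cap, np.int64)
        self.pkind = np.empty(self._cap, np.int8)

    def evaluate(self, state: SimulationState, rmat: np.ndarray | None = None):
        """Returns (force, torque, potential_energy, contacts) per subunit."""
        p = self.params
        ppos, sub_of, ptype = state.particle_positions(rmat=rmat)
        if self._needs_rebuild(state):
            self._rebuild(state, ppos, sub_of, ptype)
        fpart = np.zeros_like(ppos)
        contacts = np.zeros(state.n_subunits, np.int64)
        energy = _kernels.pair_forces(
            ppos, self.pi, self.pj, self.pkind, self.npairs, sub_of,
            p.epsilon, p.sigma, p.site_cutoff * p.sigma, self.a_vals,
            fpart, contacts)
        fsub = np.zeros((state.n_subunits, 3))
        tsub = np.zeros((state.n_subunits, 3))
        _kernels.reduce_rigid(fpart, ppos, sub_of, state.pos, fsub, tsub)
        return fsub, tsub, float(energy), contacts


def compute_forces(state: SimulationState):
    """Forces and world-frame torques per subunit plus the potential energy.

    Immobile subunits accumulate forces like any other (they are simply not
    moved by the integrator).
    """
    ff = _ForceField(state)
    f, t, e, _ = ff.evaluate(state)
    return f, t, e


# ---------------------------------------------------------------------------
# minimization (FIRE on rigid degrees of freedom)

@dataclass
class MinimizeInfo:
    converged: bool
    n_iter: int
    max_force: float
    energy: float


def minimize(state: SimulationState, force_tol: float = 1e-4,
             max_iter: int = 20000, *, max_move: float = 0.05,
             copy: bool = True) -> tuple[SimulationState, MinimizeInfo]:
    """FIRE energy minimization; returns the relaxed state and diagnostics.

    Converged when both the largest subunit force and the largest torque
    (per unit sigma lever) fall below ``force_tol``.  Tethered subunits stay
    fixed.  Non-convergence is reported in the returned info, never silent.
    """
    if copy:
        state = state.copy()
    ff = _ForceField(state)
    n = state.n_subunits
    mobile = (~state.immobile & ~state.culled)[:, None]
    v = np.zeros((n, 3))
    w = np.zeros((n, 3))
    r_max = state.templates.r_max
    # rotational "FIRE inertia": torques act with lever ~r_max, so scaling by
    # r_max^2 balances rotational and translational relaxation timescales
    i_fire = r_max * r_max
    dt0 = 0.02
    dt = dt0
    dt_max = 25 * dt0
    alpha0, alpha = 0.1, 0.1
    n_pos = 0
    energy = math.nan
    fmax = math.inf
    for it in range(1, max_iter + 1):
        f, t, energy, _ = ff.evaluate(state)
        f = np.where(mobile, f, 0.0)
        t = np.where(mobile, t, 0.0)
        fmax = max(np.abs(f).max(initial=0.0), np.abs(t).max(initial=0.0) / r_max)
        if fmax < force_tol:
            state.vel[:] = 0.0
            state.angmom[:] = 0.0
            return state, MinimizeInfo(True, it, float(fmax), energy)
        tr = t / i_fire
        power = float((f * v).sum() + (t * w).sum())
        if power > 0:
            n_pos += 1
            fnorm = math.sqrt((f ** 2).sum() + (tr * t).sum())
            vnorm = math.sqrt((v ** 2).sum() + i_fire * (w ** 2).sum())
            if fnorm > 0:
                mix = alpha * vnorm / fnorm
                v = (1 - alpha) * v + mix * f
                w = (1 - alpha) * w + mix * tr
            if n_pos > 5:
                dt = min(dt * 1.1, dt_max)
                alpha *= 0.99
        else:
            v[:] = 0.0
            w[:] = 0.0
            alpha = alpha0
            dt *= 0.5
            n_pos = 0
        v += dt * f
        w += dt * tr
        step = max(np.abs(v).max(initial=0.0),
                   np.abs(w).max(initial=0.0) * r_max) * dt
        if step > max_move:  # clamp velocities, not just the step
            scale = max_move / step
            v *= scale
            w *= scale
        state.pos += dt * v
        state.quat[:] = _normalize(quat_mul(quat_from_rotvec(dt * w), state.quat))
    state.vel[:] = 0.0
    state.angmom[:] = 0.0
    return state, MinimizeInfo(False, max_iter, float(fmax), energy)


# ---------------------------------------------------------------------------
# Langevin dynamics (BAOAB with symplectic free-rotor splitting)

_ROT_SEQ = ((2, 0.5), (1, 0.5), (0, 1.0), (1, 0.5), (2, 0.5))


def _free_rotor(quat, angmom, inertia, dt):
    """Symplectic free rotation (numba kernel): in-place update of unit
    quaternions and body-frame angular momenta; immobile bodies have zero
    angular momentum and are unchanged."""
    _kernels.free_rotor(quat, angmom, inertia, dt)


def step_langevin(state: SimulationState, n_steps: int,
                  rng_seed: Optional[int] = None, *,
                  rng: Optional[np.random.Generator] = None,
                  forcefield: Optional[_ForceField] = None,
                  callback=None, callback_every: int = 0) -> SimulationState:
    """Advance the state ``n_steps`` Langevin steps in place.

    With ``temperature == 0`` and ``damping == 0`` this reduces to NVE
    velocity-Verlet with the symplectic free-rotor update.  A displacement
    larger than sigma in one step aborts with diagnostics.
    """
    p = state.params
    dt = p.timestep
    kT = p.kT
    gamma = p.damping
    m = state.templates.mass
    rng = rng or np.random.default_rng(rng_seed)
    ff = forcefield or _ForceField(state)
    n = state.n_subunits
    mobf = (~state.immobile & ~state.culled).astype(float)[:, None]
    inertia = state.templates.inertia[state.body_type]
    if gamma > 0:
        c1 = math.exp(-gamma * dt)
        c2t = math.sqrt((1 - c1 * c1) * kT / m) * mobf
        c2r = np.sqrt((1 - c1 * c1) * kT * inertia) * mobf
    kick_t = (0.5 * dt / m) * mobf
    kick_r = 0.5 * dt * mobf
    rmat = quat_to_mat(state.quat)
    f, t, _, _ = ff.evaluate(state, rmat=rmat)
    tb = (rmat * t[:, :, None]).sum(axis=1)
    for step in range(n_steps):
        state.vel += kick_t * f
        state.angmom += kick_r * tb
        # A (dt/2); immobile bodies carry zero momenta and stay put
        state.pos += 0.5 * dt * state.vel
        _free_rotor(state.quat, state.angmom, inertia, 0.5 * dt)
        # O (exact Ornstein-Uhlenbeck)
        if gamma > 0:
            state.vel *= c1
            state.vel += c2t * rng.standard_normal((n, 3))
            state.angmom *= c1
            state.angmom += c2r * rng.standard_normal((n, 3))
        # A (dt/2)
        state.pos += 0.5 * dt * state.vel
        _free_rotor(state.quat, state.angmom, inertia, 0.5 * dt)
        state.quat = _normalize(state.quat)
        vmax = float(np.abs(state.vel).max(initial=0.0))
        if not np.isfinite(vmax) or vmax * dt > p.sigma:
            raise EngineInstability(
                f"displacement exceeded sigma in one step at t={state.time:.3f}",
                {"step": step, "vmax": vmax, "time": state.time})
        rmat = quat_to_mat(state.quat)
        f, t, _, _ = ff.evaluate(state, rmat=rmat)
        tb = (rmat * t[:, :, None]).sum(axis=1)
        state.vel += kick_t * f
        state.angmom += kick_r * tb
        state.time += dt
        if callback is not None and callback_every and (step + 1) % callback_every == 0:
            callback(state, ff)
    return state


def total_energy(state: SimulationState) -> float:
    ke_t, ke_r = state.kinetic_energy()
    _, _, pe = compute_forces(state)
    return ke_t + ke_r + pe


# ---------------------------------------------------------------------------
# builders and the depolymerization driver

def build_protofilament_chain(n_dimers: int, params: ModelParameters,
                              compressed: bool = True,
                              seed_curl: float = 0.0) -> SimulationState:
    """A free chain of dimers (no lateral neighbours, no tether).

    ``seed_curl`` pre-bends the chain by that angle (radians) per dimer about
    the vertical-site anchor line, in the outward direction favoured by the
    compressed wedge; 0 builds the straight vertical chain.  Pre-bent chains
    are useful as minimization seeds because the straight configuration sits
    in a long, nearly flat valley of the bending mode.
    """
    templates = TemplateSet.build(params)
    a = geometry.SUBUNIT_REPEAT * params.sigma
    n = 2 * n_dimers
    body_type = np.empty(n, np.int8)
    body_type[0::2] = ALPHA_COMP if compressed else ALPHA_UNC
    body_type[1::2] = BETA
    r_place = np.zeros((n, 3))
    r_place[:, 2] = a * np.arange(n)
    q_place = np.tile([1.0, 0, 0, 0], (n, 1))
    if seed_curl != 0.0:
        drop = geometry.VSITE_PIVOT_OFFSET * math.tan(geometry.hinge_angle(params)) \
            if compressed else 0.0
        vx = geometry.VSITE_X * params.sigma
        anchor_top = np.array([vx, 0.0, a / 2.0 - drop])
        anchor_bot = np.array([vx, 0.0, -a / 2.0])
        c_seed, s_seed = math.cos(seed_curl), math.sin(seed_curl)
        rd = np.array([[c_seed, 0, s_seed], [0, 1, 0], [-s_seed, 0, c_seed]])
        q_rd = np.array([math.cos(seed_curl / 2), 0.0, math.sin(seed_curl / 2), 0.0])
        c = np.zeros(3)
        rot = np.eye(3)
        q = np.array([1.0, 0.0, 0.0, 0.0])
        for i in range(n):
            r_place[i] = c
            q_place[i] = q
            if i % 2 == 0:  # bend at the intra-dimer junction
                c = c + rot @ (anchor_top - rd @ anchor_bot)
                rot = rot @ rd
                q = quat_mul(q, q_rd)
            else:
                c = c + rot @ np.array([0.0, 0.0, a])
    pos, quat = templates.place(body_type, r_place, q_place)
    meta = {
        "row": np.repeat(np.arange(n_dimers), 2),
        "pf": np.zeros(n, np.int64),
        "monomer": np.tile([0, 1], n_dimers),
        "dimer_id": np.repeat(np.arange(n_dimers), 2),
    }
    return SimulationState(
        params=params, templates=templates, body_type=body_type,
        pos=pos, quat=quat, vel=np.zeros((n, 3)), angmom=np.zeros((n, 3)),
        immobile=np.zeros(n, bool), culled=np.zeros(n, bool), meta=meta)


@dataclass
class Trajectory:
    """Recorded subunit poses at a fixed cadence plus run metadata."""

    times: np.ndarray            # (T,) in tau
    pos: np.ndarray              # (T, N, 3) float32 center-of-mass positions
    quat: np.ndarray             # (T, N, 4) float32
    culled: np.ndarray           # (T, N) bool
    config: object               # LatticeConfiguration
    params: ModelParameters
    seed: Optional[int]
    reference: dict              # initial relaxed poses {"pos", "quat"}
    templates: TemplateSet
    meta: dict

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def frame_state(self, i: int) -> SimulationState:
        n = self.pos.shape[1]
        return SimulationState(
            params=self.params, templates=self.templates,
            body_type=self.meta["body_type"],
            pos=self.pos[i].astype(float), quat=self.quat[i].astype(float),
            vel=np.zeros((n, 3)), angmom=np.zeros((n, 3)),
            immobile=self.meta["immobile"], culled=self.culled[i].copy(),
            time=float(self.times[i]), meta=self.meta, config=self.config,
            reference=self.reference)

    def validate(self) -> None:
        dt = np.diff(self.times)
        if len(dt) and (dt <= 0).any():
            raise ValueError("snapshot times must be strictly increasing")
        if len(dt) > 1 and not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("snapshot cadence must be constant")


def run_depolymerization(config, params: ModelParameters, duration_tau: float,
                         snapshot_cadence: float, seed: Optional[int] = None, *,
                         minimize_first: bool = True, minimize_tol: float = 5e-4,
                         cull: bool = True, cull_after_steps: int = 1000,
                         cull_distance: float = 5.0) -> Trajectory:
    """Build, tether, relax, and thermally evolve a microtubule.

    Snapshots of all subunit poses are recorded every ``snapshot_cadence`` tau.
    Subunits that have lost every attractive contact and drifted more than
    ``cull_distance`` sigma beyond the lattice surface for ``cull_after_steps``
    steps are culled from the interaction list (bookkeeping/performance only;
    length measurements are connectivity-based and unaffected).
    """
    from .lattice import build_microtubule

    state = build_microtubule(config, params)
    relax_info = None
    if minimize_first:
        # pre-relaxation before thermalizing: residual forces far below kT/sigma
        # are irrelevant once the thermostat is on, so convergence to the
        # minimizer tolerance is not required here
        state, relax_info = minimize(state, force_tol=minimize_tol,
                                     max_iter=4000, copy=False)
    state.reference = {"pos": state.pos.copy(), "quat": state.quat.copy()}
    rng = np.random.default_rng(seed)
    ff = _ForceField(state)
    dt = params.timestep
    steps_per_snap = max(1, int(round(snapshot_cadence / dt)))
    n_snaps = int(round(duration_tau / (steps_per_snap * dt)))
    surface_r = geometry.CENTER_RADIUS * params.sigma + state.templates.r_max
    top_z = state.pos[:, 2].max()
    drift_steps = np.zeros(state.n_subunits, np.int64)

    times = [state.time]
    poses = [state.pos.astype(np.float32).copy()]
    quats = [state.quat.astype(np.float32).copy()]
    culls = [state.culled.copy()]
    for _ in range(n_snaps):
        state = step_langevin(state, steps_per_snap, rng=rng, forcefield=ff)
        if cull:
            _, _, _, contacts = ff.evaluate(state)
            radial = np.linalg.norm(state.pos[:, :2], axis=1)
            adrift = ((contacts == 0)
                      & ((radial > surface_r + cull_distance)
                         | (state.pos[:, 2] > top_z + cull_distance))
                      & ~state.immobile & ~state.culled)
            drift_steps[adrift] += steps_per_snap
            drift_steps[~adrift] = 0
            newly = drift_steps > cull_after_steps
            if newly.any():
                state.culled |= newly
                state.vel[newly] = 0.0
                state.angmom[newly] = 0.0
                ff = _ForceField(state)
        times.append(state.time)
        poses.append(state.pos.astype(np.float32).copy())
        quats.append(state.quat.astype(np.float32).copy())
        culls.append(state.culled.copy())

    meta = {k: np.array(v) for k, v in state.meta.items()}
    meta["body_type"] = state.body_type
    meta["immobile"] = state.immobile
    if relax_info is not None:
        meta["relaxation_max_force"] = relax_info.max_force
    traj = Trajectory(
        times=np.array(times), pos=np.array(poses), quat=np.array(quats),
        culled=np.array(culls), config=config, params=params, seed=seed,
        reference=state.reference, templates=state.templates, meta=meta)
    traj.validate()
    return traj
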