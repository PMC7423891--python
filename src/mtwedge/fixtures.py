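"""Deterministic small systems and synthetic data for tests and demos.

Everything is generated programmatically: lattice snapshots (intact, peeled
horn), piecewise length traces with known rates and interruptions,
composition grids (checkerboard, block, a 21-dimer island spanning
6 rows x 11 protofilaments), and noiseless/noisy points for fit-recovery
checks.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from . import geometry
from .engine import (SimulationState, quat_from_mat, quat_mul, _normalize)
from .kinetics import LengthTrace
from .lattice import LatticeConfiguration, build_microtubule, sample_composition
from .params import ModelParameters

__all__ = ["make_fixture", "peel_protofilament", "linear_trace",
           "piecewise_trace", "exponential_rate_points"]


def linear_trace(rate_um_s: float = 0.24, duration_s: float = 120.0,
                 dt_s: float = 5.0, length0_um: float = 40.0) -> LengthTrace:
    """Steady loss at a constant rate (um/s)."""
    t = np.arange(0.0, duration_s + dt_s / 2, dt_s)
    return LengthTrace(times=t, length_um=length0_um - rate_um_s * t,
                       source="synthetic")


def piecewise_trace(segments, dt_s: float = 1.0,
                    length0_um: float = 40.0) -> LengthTrace:
    """Piecewise-linear trace; ``segments`` is [(duration_s, rate_um_s), ...]."""
    times = [0.0]
    lengths = [length0_um]
    for dur, rate in segments:
        n = int(round(dur / dt_s))
        for _ in range(n):
            times.append(times[-1] + dt_s)
            lengths.append(lengths[-1] - rate * dt_s)
    return LengthTrace(times=np.array(times), length_um=np.array(lengths),
                       source="synthetic")


def exponential_rate_points(a: float = 0.60, b: float = 0.060,
                            x=(20, 30, 40, 50, 60, 80, 100),
                            noise_frac: float = 0.0,
                            rng: Optional[np.random.Generator] = None):
    """Rate-vs-composition points on a*exp(-b*x), optionally with
    multiplicative Gaussian noise of the given fractional amplitude."""
    x = np.asarray(x, float)
    y = a * np.exp(-b * x)
    if noise_frac > 0:
        rng = rng or np.random.default_rng(0)
        y = y * (1.0 + noise_frac * rng.standard_normal(len(x)))
    return x, np.clip(y, 1e-9, None)


def peel_protofilament(state: SimulationState, pf: int, from_row: int,
                       curl_per_dimer: Optional[float] = None) -> SimulationState:
    """Curl one protofilament outward from ``from_row`` upward (a single horn).

    The peeled dimers rotate progressively about the vertical-site hinge of
    the junction below ``from_row``, so they stay vertically bonded to the
    lattice while their lateral bonds are broken.
    """
    state = state.copy()
    p = state.params
    cfg = state.config
    curl = curl_per_dimer if curl_per_dimer is not None else geometry.hinge_angle(p)
    a = geometry.SUBUNIT_REPEAT * p.sigma
    phi = 2.0 * math.pi * pf / cfg.n_pf
    vx = geometry.VSITE_X * p.sigma
    rc = geometry.CENTER_RADIUS * p.sigma
    rows = state.meta["row"]
    pfs = state.meta["pf"]
    monos = state.meta["monomer"]

    cphi, sphi = math.cos(phi), math.sin(phi)
    Rz = np.array([[cphi, -sphi, 0], [sphi, cphi, 0], [0, 0, 1]])

    def roty(t):
        c, s = math.cos(t), math.sin(t)
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])

    # forward kinematics in world frame starting from the built pose of the
    # base alpha-subunit (pre-compaction included)
    sel = (pfs == pf) & (rows >= from_row)
    base = np.flatnonzero((pfs == pf) & (rows == from_row) & (monos == 0))[0]
    c = state.grid_center_positions()[base].copy()
    R = Rz.copy()
    drop = geometry.VSITE_PIVOT_OFFSET * math.tan(geometry.hinge_angle(p)) \
        * p.sigma
    anchor_top = np.array([vx, 0.0, a / 2.0 - drop])
    anchor_bot = np.array([vx, 0.0, -a / 2.0])
    rd = roty(curl)
    poses = {}
    for idx in range(2 * (cfg.n_rows - from_row)):
        poses[(from_row + idx // 2, idx % 2)] = (c.copy(), R.copy())
        if idx % 2 == 0:  # intra junction: bend
            c = c + R @ (anchor_top - rd @ anchor_bot)
            R = R @ rd
        else:
            c = c + R @ np.array([0.0, 0.0, a])
    tset = state.templates
    for i in np.flatnonzero(sel):
        world_c, world_R = poses[(int(rows[i]), int(monos[i]))]
        bt = state.body_type[i]
        q_place = quat_from_mat(world_R)
        pos, quat = tset.place(np.array([bt]), world_c[None], q_place[None])
        state.pos[i] = pos[0]
        state.quat[i] = quat[0]
    return state


def _island_21_grid(n_rows: int = 8, n_pf: int = 13) -> np.ndarray:
    """A connected 21-dimer island spanning 6 rows and 11 protofilaments,
    the scale of the largest islands found at 20% uncompressed."""
    grid = np.zeros((n_rows, n_pf), np.uint8)
    grid[1, 0:11] = 1                 # 11 dimers across the base row
    grid[2:7, 0] = 1                  # 5 up the left edge
    grid[2:7, 10] = 1                 # 5 up the right edge
    assert grid.sum() == 21
    return grid


def make_fixture(name: str, params: Optional[ModelParameters] = None):
    """Deterministic named fixtures; raises KeyError for unknown names."""
    params = params or ModelParameters()
    if name == "intact_8row":
        cfg = sample_composition(8, 0.4, seed=2024)
        state = build_microtubule(cfg, params)
        state.reference = {"pos": state.pos.copy(), "quat": state.quat.copy()}
        return state
    if name == "peeled_pf":
        cfg = LatticeConfiguration.uniform(20, 0.0)
        state = build_microtubule(cfg, params)
        state.reference = {"pos": state.pos.copy(), "quat": state.quat.copy()}
        # double the hinge curl so even the base dimer clearly leaves the wall
        return peel_protofilament(state, pf=4, from_row=5,
                                  curl_per_dimer=2 * geometry.hinge_angle(params))
    if name == "steady_loss_trace":
        return linear_trace()
    if name == "piecewise_trace":
        return piecewise_trace([(30, 0.24), (20, 0.0), (30, 0.24)])
    if name == "interrupted_trace":
        # three near-zero stretches of 5/8/12 s separated by steady loss
        return piecewise_trace([(20, 0.2), (5, 0.0), (15, 0.2), (8, 0.0),
                                (15, 0.2), (12, 0.0), (15, 0.2)], dt_s=0.5)
    if name == "checkerboard_grid":
        grid = np.indices((8, 13)).sum(axis=0) % 2
        return LatticeConfiguration(n_rows=8, n_pf=13,
                                    composition=grid.astype(np.uint8))
    if name == "block_grid":
        grid = np.zeros((12, 13), np.uint8)
        grid[4:8, :] = 1
        return LatticeConfiguration(n_rows=12, n_pf=13, composition=grid)
    if name == "island_21dimer":
        return LatticeConfiguration(n_rows=8, n_pf=13,
                                    composition=_island_21_grid())
    raise KeyError(f"unknown fixture: {name!r}")
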