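"""Depolymerization kinetics: length traces, instantaneous loss rates,
interruption statistics, end-morphology measures, and composition-dependence
fits.

The microtubule length is connectivity-based: a dimer row counts as intact
when all of its dimers sit within one bead diameter of their (relaxed)
lattice sites and remain laterally bonded; the highest contiguous block of
intact rows defines the depolymerization front.  Times convert from tau to
seconds via ``tau_per_second`` and lengths to micrometres via ``nm_per_row``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from . import geometry
from .engine import SimulationState, Trajectory

__all__ = [
    "LengthTrace", "RateSeries", "InterruptionRecord", "InterruptionAnalysis",
    "RateCurve", "LinearFit", "ExponentialFit",
    "length_trace", "instantaneous_rate", "detect_interruptions",
    "percent_time_interrupted_curve", "exposed_protofilament_lengths",
    "local_uncompressed_count", "rate_vs_composition", "calibrate_time",
    "intact_row_count",
]


# ---------------------------------------------------------------------------
# containers

@dataclass
class LengthTrace:
    """Time series of intact microtubule length.

    ``times`` in seconds, ``length`` in micrometres; ``delta_um`` is the net
    length lost since the start.
    """

    times: np.ndarray
    length_um: np.ndarray
    source: str = "simulation"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.length_um = np.asarray(self.length_um, float)
        if len(self.times) != len(self.length_um):
            raise ValueError("times and length must have equal length")
        if len(self.times) > 1 and (np.diff(self.times) <= 0).any():
            raise ValueError("times must be strictly increasing")

    @property
    def delta_um(self) -> np.ndarray:
        return self.length_um[0] - self.length_um

    @property
    def total_loss_um(self) -> float:
        return float(self.delta_um[-1])

    @property
    def duration_s(self) -> float:
        return float(self.times[-1] - self.times[0])

    def mean_loss_rate(self) -> float:
        """Net loss divided by elapsed time, in um/s."""
        if self.duration_s == 0:
            raise ValueError("trace has zero duration")
        return self.total_loss_um / self.duration_s


@dataclass
class RateSeries:
    """Instantaneous loss rate (um/s, positive = shrinking)."""

    times: np.ndarray
    rate: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.rate = np.asarray(self.rate, float)


@dataclass(frozen=True)
class InterruptionRecord:
    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("interruption must have positive duration")


@dataclass
class InterruptionAnalysis:
    records: list
    percent_time_interrupted: float
    interruptions_per_um: Optional[float]
    mean_duration_s: float
    rate_threshold: float
    min_duration: float


@dataclass
class RateCurve:
    """Mean loss rate vs composition (percent uncompressed)."""

    composition_percent: np.ndarray
    mean_rate: np.ndarray
    sem: np.ndarray
    n_replicates: np.ndarray

    def __post_init__(self):
        for name in ("composition_percent", "mean_rate", "sem", "n_replicates"):
            setattr(self, name, np.asarray(getattr(self, name), float))
        if (self.mean_rate < 0).any() or (self.sem < 0).any():
            raise ValueError("rates and SEMs must be non-negative")

    @classmethod
    def from_traces(cls, groups: dict) -> "RateCurve":
        """``groups`` maps composition (%) -> iterable of LengthTrace."""
        comps, means, sems, ns = [], [], [], []
        for comp in sorted(groups):
            rates = np.array([tr.mean_loss_rate() for tr in groups[comp]])
            comps.append(comp)
            means.append(rates.mean())
            sems.append(rates.std(ddof=1) / np.sqrt(len(rates))
                        if len(rates) > 1 else 0.0)
            ns.append(len(rates))
        return cls(np.array(comps), np.array(means), np.array(sems), np.array(ns))


class LinearFit(NamedTuple):
    slope: float
    intercept: float
    r_squared: float
    x_intercept: float


class ExponentialFit(NamedTuple):
    plateau: float      # um/s, mean of low-composition rates
    prefactor: float    # a in a*exp(-b*x)
    decay: float        # b, per percent
    crossing: float     # x where a*exp(-b*x) == plateau (slowdown onset)


class LocalComposition(NamedTuple):
    count: int
    rows_used: int
    partial: bool


# ---------------------------------------------------------------------------
# lattice connectivity helpers

def _lateral_partner_index(config) -> tuple[np.ndarray, np.ndarray]:
    """Subunit-level lateral contacts (right-face -> partner's left face).

    For protofilament k < n_pf-1 the partner of subunit (r, k, mono) is
    (r, k, mono) on k+1; across the seam the accumulated 3-monomer shift
    makes the partner the subunit three monomer rows higher on protofilament
    zero.  Returns (subunit_index, partner_index) arrays.
    """
    n_pf = config.n_pf
    n_rows = config.n_rows
    idx = np.arange(2 * n_rows * n_pf).reshape(n_pf, n_rows, 2)
    me, partner = [], []
    for k in range(n_pf):
        kp = (k + 1) % n_pf
        for r in range(n_rows):
            for mono in (0, 1):
                if k < n_pf - 1:
                    me.append(idx[k, r, mono])
                    partner.append(idx[kp, r, mono])
                else:
                    mshift = 2 * r + mono + 3  # 3-monomer seam shift
                    rp, monop = divmod(mshift, 2)
                    if rp < n_rows:
                        me.append(idx[k, r, mono])
                        partner.append(idx[kp, rp, monop])
    return np.array(me), np.array(partner)


def _site_world(traj: Trajectory, frame: int) -> np.ndarray:
    from .engine import quat_to_mat
    quat = traj.quat[frame].astype(float)
    local = traj.templates.local[traj.meta["body_type"]][:, 27:, :]
    rmat = quat_to_mat(quat)
    return traj.pos[frame].astype(float)[:, None, :] + np.einsum(
        "nij,npj->npi", rmat, local)


def dimer_lattice_status(traj: Trajectory, frame: int, *,
                         tol_sigma: float = 1.0,
                         _cache: dict | None = None) -> np.ndarray:
    """Boolean (n_rows, n_pf) grid: dimer still part of the intact wall.

    A dimer qualifies when both subunits sit within ``tol_sigma`` of their
    relaxed lattice positions and at least one of its lateral site pairs is
    engaged (distance below the attraction cutoff).  Tethered rows always
    qualify.
    """
    p = traj.params
    cfg = traj.config
    cache = _cache if _cache is not None else {}
    if "lat" not in cache:
        cache["lat"] = _lateral_partner_index(cfg)
        cache["order"] = np.lexsort(
            (traj.meta["monomer"], traj.meta["row"], traj.meta["pf"]))
    me, partner = cache["lat"]
    order = cache["order"]  # map flat (pf, row, mono) -> storage index

    disp = np.linalg.norm(traj.pos[frame].astype(float)
                          - traj.reference["pos"], axis=1)
    in_place = disp <= tol_sigma * p.sigma

    sites = _site_world(traj, frame)
    right = sites[:, 6:8, :]
    left = sites[:, 4:6, :]
    gme, gpa = order[me], order[partner]
    d = np.linalg.norm(right[gme] - left[gpa], axis=2)
    bonded_pair = (d < p.site_cutoff * p.sigma).any(axis=1)
    sub_bonded = np.zeros(traj.pos.shape[1], bool)
    sub_bonded[gme] |= bonded_pair
    sub_bonded[gpa] |= bonded_pair

    rows, pfs, mono = traj.meta["row"], traj.meta["pf"], traj.meta["monomer"]
    present = np.zeros((cfg.n_rows, cfg.n_pf, 2), bool)
    present[rows, pfs, mono] = in_place | traj.meta["immobile"]
    lat = np.zeros((cfg.n_rows, cfg.n_pf, 2), bool)
    lat[rows, pfs, mono] = sub_bonded | traj.meta["immobile"]
    return present.all(axis=2) & lat.any(axis=2)


def intact_row_count(traj: Trajectory, frame: int, *,
                     tol_sigma: float = 1.0,
                     _cache: dict | None = None) -> int:
    """Number of contiguous intact dimer rows from the minus end.

    A row is intact when all of its dimers are part of the intact wall
    (see :func:`dimer_lattice_status`); the highest such contiguous block
    defines the depolymerization front.
    """
    ok = dimer_lattice_status(traj, frame, tol_sigma=tol_sigma, _cache=_cache)
    row_ok = ok.all(axis=1)
    bad = np.flatnonzero(~row_ok)
    return int(bad[0]) if len(bad) else traj.config.n_rows


def length_trace(traj: Trajectory, *, tol_sigma: float = 1.0) -> LengthTrace:
    """Intact length (um) vs time (s) of a depolymerization trajectory."""
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    p = traj.params
    cache: dict = {}
    rows = np.array([intact_row_count(traj, i, tol_sigma=tol_sigma, _cache=cache)
                     for i in range(traj.n_frames)])
    times = traj.times / p.tau_per_second
    length_um = rows * p.nm_per_row / 1000.0
    return LengthTrace(times=times, length_um=length_um, source="simulation",
                       meta={"rows": rows, "seed": traj.seed,
                             "frac_uncompressed": traj.config.frac_uncompressed})


# ---------------------------------------------------------------------------
# rates and interruptions

def instantaneous_rate(trace: LengthTrace, window: float) -> RateSeries:
    """Centered finite-difference loss rate over a time window (seconds).

    Positive values are shrinkage; transient re-attachment can yield negative
    samples, which are retained.
    """
    dt = np.diff(trace.times)
    if len(dt) == 0:
        raise ValueError("trace too short")
    step = float(np.median(dt))
    half = max(1, int(round(window / 2.0 / step)))
    if window < 2 * step - 1e-12:
        raise ValueError("window must span at least 2 sample intervals")
    if 2 * half >= len(trace.times):
        raise ValueError("window longer than the trace")
    t = trace.times
    L = trace.length_um
    idx = np.arange(half, len(t) - half)
    rate = -(L[idx + half] - L[idx - half]) / (t[idx + half] - t[idx - half])
    return RateSeries(times=t[idx], rate=rate)


def detect_interruptions(rate: RateSeries, rate_threshold: float = 0.024,
                         min_duration: float = 10.0, *,
                         total_loss_um: Optional[float] = None) -> InterruptionAnalysis:
    """Maximal near-zero-rate intervals (|rate| < threshold, >= min_duration).

    The default threshold is 10% of the plateau depolymerization rate
    (0.024 um/s) and the default minimum duration two 5-second sampling
    intervals; both are configurable and echoed in the result.
    """
    if rate_threshold <= 0 or min_duration <= 0:
        raise ValueError("thresholds must be positive")
    quiet = np.abs(rate.rate) < rate_threshold
    records = []
    t = rate.times
    i = 0
    n = len(quiet)
    while i < n:
        if quiet[i]:
            j = i
            while j + 1 < n and quiet[j + 1]:
                j += 1
            start, end = t[i], t[j]
            if j > i and end - start >= min_duration:
                records.append(InterruptionRecord(start=float(start), end=float(end)))
            i = j + 1
        else:
            i += 1
    total_time = float(t[-1] - t[0]) if len(t) > 1 else 0.0
    time_interrupted = sum(r.duration for r in records)
    percent = 100.0 * time_interrupted / total_time if total_time else 0.0
    per_um = (len(records) / total_loss_um
              if total_loss_um not in (None, 0) else None)
    mean_dur = (time_interrupted / len(records)) if records else 0.0
    return InterruptionAnalysis(
        records=records, percent_time_interrupted=percent,
        interruptions_per_um=per_um, mean_duration_s=mean_dur,
        rate_threshold=rate_threshold, min_duration=min_duration)


def percent_time_interrupted_curve(groups: dict) -> LinearFit:
    """OLS fit of percent time interrupted vs fractional composition.

    ``groups`` maps fractional uncompressed composition (0-1) to an iterable
    of percent-time-interrupted values; the returned x-intercept estimates
    the onset composition.
    """
    if len(groups) < 3:
        raise ValueError("need at least 3 composition groups")
    x, y = [], []
    for comp, values in groups.items():
        for v in np.atleast_1d(values):
            x.append(float(comp))
            y.append(float(v))
    x = np.array(x)
    y = np.array(y)
    if np.ptp(x) == 0:
        raise ValueError("degenerate composition range")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - (resid ** 2).sum() / ss_tot if ss_tot > 0 else 0.0
    x_int = -intercept / slope if slope != 0 else np.nan
    return LinearFit(float(slope), float(intercept), float(r2), float(x_int))


# ---------------------------------------------------------------------------
# end morphology and local composition

def exposed_protofilament_lengths(state: SimulationState, *,
                                  last_intact_row: Optional[int] = None,
                                  tol_sigma: float = 1.0) -> np.ndarray:
    """Per-protofilament exposed lengths (dimers) above the last intact row.

    Walks each protofilament upward from the depolymerization front while the
    inter-dimer vertical bond stays engaged, counting dimers that protrude
    from the intact wall (displaced from their lattice sites or laterally
    unbonded); dimers still embedded in the wall above the front are skipped,
    so a fully intact column has exposed length zero.
    """
    cfg = state.config
    p = state.params
    traj = _as_single_frame(state)
    cache: dict = {}
    if last_intact_row is None:
        n_intact = intact_row_count(traj, 0, tol_sigma=tol_sigma, _cache=cache)
    else:
        n_intact = last_intact_row
    in_wall = dimer_lattice_status(traj, 0, tol_sigma=tol_sigma, _cache=cache)
    sites = _site_world(traj, 0)
    rows, pfs, mono = (traj.meta["row"], traj.meta["pf"], traj.meta["monomer"])
    idx = np.full((cfg.n_pf, cfg.n_rows, 2), -1, np.int64)
    idx[pfs, rows, mono] = np.arange(len(rows))
    rc = p.site_cutoff * p.sigma
    out = np.zeros(cfg.n_pf, np.int64)
    for k in range(cfg.n_pf):
        length = 0
        for r in range(max(n_intact, 1), cfg.n_rows):
            below_beta = idx[k, r - 1, 1]
            alpha = idx[k, r, 0]
            d = np.linalg.norm(sites[alpha][2:4] - sites[below_beta][0:2], axis=1)
            if not (d < rc).any():
                break
            if not in_wall[r, k]:
                length += 1
        out[k] = length
    return out


def local_uncompressed_count(state: SimulationState, *,
                             last_intact_row: Optional[int] = None,
                             tol_sigma: float = 1.0) -> LocalComposition:
    """Uncompressed dimers in the top three intact rows (the lattice just
    ahead of the depolymerization front; at most 39 dimers)."""
    cfg = state.config
    if last_intact_row is None:
        n_intact = intact_row_count(_as_single_frame(state), 0,
                                    tol_sigma=tol_sigma)
    else:
        n_intact = last_intact_row
    top = n_intact - 1
    lo = max(0, top - 2)
    if top < 0:
        return LocalComposition(0, 0, True)
    window = cfg.composition[lo:top + 1]
    return LocalComposition(int(window.sum()), window.shape[0],
                            window.shape[0] < 3)


def exposed_length_heatmap(traj: Trajectory, *, tol_sigma: float = 1.0) -> np.ndarray:
    """Exposed protofilament lengths per frame: array (n_frames, n_pf).

    The per-frame rows of this matrix are the heat-map columns of the
    end-morphology analysis (horn lengths over time).
    """
    out = np.zeros((traj.n_frames, traj.config.n_pf), np.int64)
    for i in range(traj.n_frames):
        out[i] = exposed_protofilament_lengths(traj.frame_state(i),
                                               tol_sigma=tol_sigma)
    return out


def _as_single_frame(state: SimulationState) -> Trajectory:
    n = state.n_subunits
    meta = {k: np.asarray(v) for k, v in state.meta.items()}
    meta.setdefault("body_type", state.body_type)
    meta.setdefault("immobile", state.immobile)
    reference = state.reference or {"pos": state.pos.copy(),
                                    "quat": state.quat.copy()}
    return Trajectory(
        times=np.array([state.time]), pos=state.pos[None].astype(np.float32),
        quat=state.quat[None].astype(np.float32),
        culled=state.culled[None].copy(), config=state.config,
        params=state.params, seed=None, reference=reference,
        templates=state.templates, meta=meta)


# ---------------------------------------------------------------------------
# composition dependence

def rate_vs_composition(curve: RateCurve, *, plateau_max: float = 10.0,
                        fit_min: float = 20.0) -> ExponentialFit:
    """Plateau + exponential-decay description of loss rate vs composition.

    The plateau is the mean rate over compositions <= ``plateau_max`` %; the
    decay branch ``a*exp(-b*x)`` is least-squares fitted over compositions
    >= ``fit_min`` %; their crossing ``ln(a/plateau)/b`` estimates the
    slowdown onset.
    """
    x = curve.composition_percent
    y = curve.mean_rate
    low = x <= plateau_max
    if not low.any():
        raise ValueError("no compositions at or below plateau_max")
    plateau = float(y[low].mean())
    sel = x >= fit_min
    if sel.sum() < 2:
        raise ValueError("need at least 2 compositions beyond fit_min")
    pos = sel & (y > 0)
    b0, loga0 = np.polyfit(x[pos], np.log(y[pos]), 1)
    p0 = (np.exp(loga0), -b0)
    try:
        (a, b), _ = curve_fit(lambda xx, a, b: a * np.exp(-b * xx),
                              x[sel], y[sel], p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"exponential fit did not converge: {exc}") from exc
    crossing = np.log(a / plateau) / b if plateau > 0 and b != 0 else np.nan
    return ExponentialFit(plateau=plateau, prefactor=float(a), decay=float(b),
                          crossing=float(crossing))


def calibrate_time(sim_rate_um_per_tau: float,
                   reference_rate_um_per_s: float = 0.240) -> float:
    """Tau-per-second conversion matching a simulated loss rate (um/tau) to a
    reference experimental rate (um/s; default the 0% plateau 0.240)."""
    if sim_rate_um_per_tau <= 0 or reference_rate_um_per_s <= 0:
        raise ValueError("rates must be positive")
    return reference_rate_um_per_s / sim_rate_um_per_tau
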