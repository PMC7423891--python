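"""Wedge-shaped tubulin subunit templates and geometric calibration checks.

A tubulin monomer is a rigid composite of 27 beads arranged on a 3x3x3 grid
that fills a truncated wedge prism: three radial layers, three axial layers,
and three tangential positions whose spread grows with radius so that
``n_protofilaments`` wedges tile a closed ring.  Eight massless attractive
sites are attached per subunit: a radially split vertical pair on the top and
bottom faces (stacking bonds along a protofilament) and an axially split
lateral pair on the left and right faces (protofilament-protofilament bonds,
vertically offset to realize the pitch-3 helical lattice).

Hydrolysis is modelled as a shape change only: the compressed alpha-subunit
has its top face sheared downward about a radial pivot line so that the face
normal tilts inward by ``theta``.  Because the binding sites ride the face,
an energy-minimized chain of compressed dimers curls with one ``theta`` turn
per dimer.  The two remaining proportions - the radial anchor of the vertical
site pair and the pivot offset - are calibration constants fixed once so that
the relaxed curl radius is 28 nm (at theta = 15 deg, with 9 nm per dimer row)
and the lattice compacts axially by 2% when fully compressed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as _dc_replace

import numpy as np

from .params import ModelParameters

__all__ = [
    "WedgeTemplate",
    "DimerSpec",
    "build_wedge_template",
    "build_dimer_spec",
    "ring_closure_count",
    "protofilament_equilibrium_radius",
    "axial_compaction",
    "template_to_xyz",
    "SUBUNIT_REPEAT",
    "ROW_REPEAT",
]

# ---------------------------------------------------------------------------
# Template proportions (units of sigma).  BEAD_DX/BEAD_DZ set the 3x3x3 grid,
# CENTER_RADIUS places the subunit centroid on the microtubule cylinder, and
# FACE_MARGIN insets beads from the lateral faces so that beads of laterally
# adjacent wedges sit at the WCA zero-force distance.
BEAD_DX = 0.96
BEAD_DZ = 1.0
CENTER_RADIUS = 4.5
WCA_CUT = 2.0 ** (1.0 / 6.0)
#: Bead inset from the lateral faces; adjacent wedges' beads then sit just
#: outside the WCA range so the in-register ring is an exact force-free minimum.
FACE_MARGIN = 0.60
#: Axial clearance between the facing bead layers of stacked subunits.  Kept
#: above the WCA cutoff so that stacking distances and junction angles are set
#: by the attractive site pairs alone (beads engage only in real collisions),
#: and large enough that hinge rotations up to ~35 degrees clear the bead
#: body sterically.
STACK_GAP = 1.6

#: Axial repeat of one monomer.
SUBUNIT_REPEAT = 2.0 * BEAD_DZ + STACK_GAP
#: Axial repeat of one dimer row (two monomers).
ROW_REPEAT = 2.0 * SUBUNIT_REPEAT

#: Radial half-split of the vertical site pair.  The two sites of a pair sit
#: at VSITE_X +/- VSITE_DX so that the pair transmits the hinge tilt.
VSITE_DX = 0.5
#: Radial anchor (hinge) of the vertical site pair: at the luminal edge of
#: the bead body, so curls pivot about the inner face as in peeling
#: protofilaments.
VSITE_X = -1.44
#: Tilt gain of the vertical binding contact under compression: the site pair
#: reorients by SITE_TILT_GAIN*theta while the bead face tilts by theta (the
#: binding interface follows the conformational change with a lever larger
#: than the rigid face).  This is the calibration knob fixed so the relaxed
#: curl radius of a compressed-dimer chain is 28 nm at theta = 15 deg with
#: 9 nm per dimer row; see the methods note.
SITE_TILT_GAIN = 1.1296
#: Radial distance from the vertical-site anchor to the shear pivot of the
#: compressed site pair.  Calibrated against the relaxed lattice (the hinge
#: drop plus the small additional settling of the strained pair) so that a
#: fully compressed microtubule shortens axially by 2% at theta = 15 deg.
VSITE_PIVOT_OFFSET = 0.388

#: Axial half-split of the lateral site pairs.
LSITE_DZ = 0.45

SITE_LABELS = (
    "vertical_top", "vertical_top",
    "vertical_bottom", "vertical_bottom",
    "lateral_left", "lateral_left",
    "lateral_right", "lateral_right",
)


@dataclass(frozen=True)
class WedgeTemplate:
    """Local-frame layout of one tubulin monomer.

    The local frame has +x pointing radially outward (wide face), +y along the
    lattice circumference toward the "right" neighbour, and +z toward the
    microtubule plus-end.  ``beads`` are the 27 steric centers, ``sites`` the
    8 attractive points, both relative to the grid center of the uncompressed
    body (not the center of mass).
    """

    beads: np.ndarray          # (27, 3)
    sites: np.ndarray          # (8, 3)
    site_labels: tuple         # 8 face tags
    compressed: bool
    interior_angle: float      # radians, 2*pi/n_protofilaments
    theta: float               # compression angle actually applied, degrees
    pitch_offset: float        # lateral rise per protofilament interface

    def __post_init__(self):
        if self.beads.shape != (27, 3):
            raise ValueError("a wedge template requires exactly 27 beads")
        if self.sites.shape != (8, 3):
            raise ValueError("a wedge template requires exactly 8 sites")

    @property
    def subunit_repeat(self) -> float:
        return SUBUNIT_REPEAT

    def with_interior_angle(self, angle: float) -> "WedgeTemplate":
        return _dc_replace(self, interior_angle=angle)

    def top_face_normal(self) -> np.ndarray:
        """Unit normal of the plane fitted through the top bead layer."""
        top = self.beads[18:27]  # grid order: axial layers bottom/middle/top
        centered = top - top.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        n = vt[2]
        return n if n[2] >= 0 else -n


@dataclass(frozen=True)
class DimerSpec:
    """An alpha-beta dimer: only the alpha template may be compressed."""

    alpha: WedgeTemplate
    beta: WedgeTemplate
    state: str  # "uncompressed" | "compressed"

    def __post_init__(self):
        if self.state not in ("uncompressed", "compressed"):
            raise ValueError("state must be 'uncompressed' or 'compressed'")
        if self.beta.compressed:
            raise ValueError("the beta-subunit is always uncompressed")
        if (self.state == "compressed") != self.alpha.compressed:
            raise ValueError("dimer state must match the alpha template")


def _uncompressed_layout(n_pf: int):
    """Bead and site coordinates of the straight wedge, grid-center frame."""
    half_angle = math.pi / n_pf
    tan_half = math.tan(half_angle)
    xs = np.array([-BEAD_DX, 0.0, BEAD_DX])
    zs = np.array([-BEAD_DZ, 0.0, BEAD_DZ])
    beads = np.empty((27, 3))
    i = 0
    for z in zs:
        for x in xs:
            half_width = (CENTER_RADIUS + x) * tan_half
            # inset from the lateral faces; floor keeps exotic ring counts
            # (wide interior angles) from collapsing the tangential spread
            y_edge = max(half_width - FACE_MARGIN, 0.3 * half_width)
            for y in (-y_edge, 0.0, y_edge):
                beads[i] = (x, y, z)
                i += 1
    a = SUBUNIT_REPEAT
    delta = 3.0 * a / n_pf
    w0 = CENTER_RADIUS * tan_half
    sites = np.array([
        (VSITE_X - VSITE_DX, 0.0, a / 2.0),        # vertical_top
        (VSITE_X + VSITE_DX, 0.0, a / 2.0),
        (VSITE_X - VSITE_DX, 0.0, -a / 2.0),       # vertical_bottom
        (VSITE_X + VSITE_DX, 0.0, -a / 2.0),
        (0.0, -w0, -delta / 2.0 - LSITE_DZ),       # lateral_left
        (0.0, -w0, -delta / 2.0 + LSITE_DZ),
        (0.0, w0, delta / 2.0 - LSITE_DZ),         # lateral_right
        (0.0, w0, delta / 2.0 + LSITE_DZ),
    ])
    return beads, sites, delta


def hinge_angle(params: ModelParameters | None = None) -> float:
    """Equilibrium bend (radians) of the compressed vertical hinge.

    The binding-site pair of a compressed subunit reorients by
    ``SITE_TILT_GAIN * theta``; an isolated compressed-dimer chain therefore
    curls by this angle per dimer.
    """
    params = params or ModelParameters()
    return SITE_TILT_GAIN * params.theta_rad


def build_wedge_template(compressed: bool, params: ModelParameters | None = None) -> WedgeTemplate:
    """Build the local-frame template of one monomer.

    With ``compressed=True`` the top face (its bead layer and its vertical
    site pair) is sheared downward about the radial pivot line
    ``x = VSITE_X - VSITE_PIVOT_OFFSET`` so that the top-face normal tilts
    inward by ``params.theta``; the rest of the body is unchanged.
    """
    params = params or ModelParameters()
    params.validate()
    beads, sites, delta = _uncompressed_layout(params.n_protofilaments)
    if compressed and params.theta > 0.0:
        # bead face: shear about the top-inner (luminal) edge by theta
        tan_t = math.tan(params.theta_rad)
        top_beads = beads[:, 2] > BEAD_DZ / 2.0
        beads = beads.copy()
        beads[top_beads, 2] -= (beads[top_beads, 0] - VSITE_X) * tan_t
        # binding contact: shear the top site pair by the amplified tilt
        tan_h = math.tan(hinge_angle(params))
        pivot = VSITE_X - VSITE_PIVOT_OFFSET
        sites = sites.copy()
        sites[0:2, 2] -= (sites[0:2, 0] - pivot) * tan_h
    return WedgeTemplate(
        beads=beads,
        sites=sites,
        site_labels=SITE_LABELS,
        compressed=bool(compressed),
        interior_angle=2.0 * math.pi / params.n_protofilaments,
        theta=params.theta if compressed else 0.0,
        pitch_offset=delta,
    )


def build_dimer_spec(state: str, params: ModelParameters | None = None) -> DimerSpec:
    params = params or ModelParameters()
    return DimerSpec(
        alpha=build_wedge_template(state == "compressed", params),
        beta=build_wedge_template(False, params),
        state=state,
    )


def ring_closure_count(template: WedgeTemplate) -> int:
    """Number of wedges tiling a closed ring, from the interior angle.

    Raises if the interior angle does not evenly divide the full circle
    (relative rounding error above 1e-6 of a turn).
    """
    if template.compressed:
        raise ValueError("ring closure is defined for the uncompressed template")
    n = 2.0 * math.pi / template.interior_angle
    count = int(round(n))
    if count < 3 or abs(n - count) / n > 1e-6:
        raise ValueError(
            f"wedge interior angle does not divide the circle: {n} wedges per turn")
    return count


def _fit_circle_radius(points: np.ndarray) -> float:
    """Algebraic (Kasa) circle fit in the best plane through 3D points.

    Returns the fitted radius in input units, or +inf for straight chains.
    """
    centered = points - points.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-6 * s[0]:  # collinear: a straight chain
        return math.inf
    uv = centered @ vt[:2].T  # in-plane coordinates
    x, y = uv[:, 0], uv[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x * x + y * y
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy, c = sol
    r2 = c + cx * cx + cy * cy
    if r2 <= 0 or not np.isfinite(r2):
        return math.inf
    r = math.sqrt(r2)
    span = max(s[0], 1e-12)
    if r > 1e4 * span:  # numerically straight
        return math.inf
    return r


def protofilament_equilibrium_radius(
    n_dimers: int,
    params: ModelParameters | None = None,
    *,
    force_tol: float = 1e-4,
    max_iter: int = 40000,
) -> float:
    """Relaxed curl radius (nm) of an isolated chain of compressed dimers.

    Builds a free vertical chain of ``n_dimers`` compressed dimers, minimizes
    its energy (no thermostat), fits a circle to the subunit centers, and
    converts the radius to nanometres via ``nm_per_row``.  A straight chain
    (``theta = 0``) returns ``math.inf``.
    """
    from .engine import MinimizationError, build_protofilament_chain, minimize

    params = params or ModelParameters()
    if n_dimers < 5:
        raise ValueError("need at least 5 dimers to measure a curl radius")
    # The bending mode is a long, nearly flat valley, so relax from several
    # uniformly pre-curled seeds and keep the lowest-energy stationary state.
    hinge = hinge_angle(params)
    best = None
    for seed_curl in (0.0, hinge / 2.0, 0.75 * hinge, hinge, 1.25 * hinge):
        state = build_protofilament_chain(
            n_dimers, params, compressed=True, seed_curl=seed_curl)
        state, info = minimize(state, force_tol=force_tol, max_iter=max_iter)
        if not info.converged:
            continue
        if best is None or info.energy < best[1].energy:
            best = (state, info)
    if best is None:
        raise MinimizationError(
            "chain relaxation did not converge from any seed curvature")
    state, _ = best
    r_sigma = _fit_circle_radius(state.pos)
    if math.isinf(r_sigma):
        return math.inf
    return r_sigma * params.nm_per_row / (ROW_REPEAT * params.sigma)


def axial_compaction(
    params: ModelParameters | None = None,
    *,
    n_rows: int = 40,
    tether_rows: int = 2,
    force_tol: float = 5e-4,
    max_iter: int = 20000,
) -> float:
    """Fractional axial shortening of a fully compressed vs uncompressed lattice.

    Both lattices are energy-minimized with the bottom ``tether_rows`` dimer
    rows immobilized.  The axial row spacing is estimated by regressing the
    per-row mean bead-grid height on the row index over interior rows (the
    tethered bottom and the free top rows are excluded), and the compaction is
    ``1 - spacing_compressed / spacing_uncompressed``.
    """
    from .engine import MinimizationError, minimize
    from .lattice import LatticeConfiguration, build_microtubule

    params = params or ModelParameters()
    spacings = []
    for frac in (0.0, 1.0):
        config = LatticeConfiguration.uniform(
            n_rows=n_rows, frac_uncompressed=frac,
            n_pf=params.n_protofilaments, tether_rows=tether_rows)
        state = build_microtubule(config, params)
        # Relax in chunks until the interior row spacing is stationary: the
        # free plus-end keeps creeping outward long after the interior lattice
        # has equilibrated, so global force convergence is not required for
        # the spacing observable.
        spacing = _row_spacing(state, config, tether_rows)
        settled = False
        for _ in range(max(1, max_iter // 4000)):
            state, info = minimize(state, force_tol=force_tol,
                                   max_iter=4000, copy=False)
            new_spacing = _row_spacing(state, config, tether_rows)
            delta, spacing = abs(new_spacing - spacing), new_spacing
            # 1e-4 rows of drift corresponds to 0.01 pp of compaction,
            # far below the calibration resolution
            if info.converged or delta < 1e-4 * ROW_REPEAT:
                settled = True
                break
        if not settled:
            raise MinimizationError(
                f"lattice relaxation (frac={frac}) did not reach a stationary "
                f"row spacing (last change {delta:.2e} sigma)")
        spacings.append(spacing)
    spacing_compressed, spacing_uncompressed = spacings
    return 1.0 - spacing_compressed / spacing_uncompressed


def _row_spacing(state, config, tether_rows: int) -> float:
    """Mean axial dimer-row spacing from interior rows of a relaxed lattice."""
    rows = np.asarray(state.meta["row"])
    z = state.grid_center_positions()[:, 2]
    lo, hi = tether_rows + 1, config.n_rows - 3
    sel_rows = np.arange(lo, hi)
    if len(sel_rows) < 4:
        raise ValueError("lattice too short to estimate an interior row spacing")
    means = np.array([z[rows == r].mean() for r in sel_rows])
    slope = np.polyfit(sel_rows, means, 1)[0]
    return float(slope)


def template_to_xyz(template: WedgeTemplate, comment: str = "") -> str:
    """XYZ-format text for visualization: beads tagged C, sites by face.

    Element tags: ``C`` beads, ``N``/``O`` vertical top/bottom sites,
    ``F``/``P`` lateral left/right sites.
    """
    tags = {"vertical_top": "N", "vertical_bottom": "O",
            "lateral_left": "F", "lateral_right": "P"}
    lines = [str(27 + 8), comment or f"wedge compressed={template.compressed}"]
    for b in template.beads:
        lines.append(f"C {b[0]:.6f} {b[1]:.6f} {b[2]:.6f}")
    for s, lab in zip(template.sites, template.site_labels):
        lines.append(f"{tags[lab]} {s[0]:.6f} {s[1]:.6f} {s[2]:.6f}")
    return "\n".join(lines) + "\n"
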