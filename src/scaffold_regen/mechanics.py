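"""Apparent-modulus homogenization with a 3D frame solver.

Each strut is a two-node frame element with 6 DOF per node (axial, torsion
and bending in two planes, circular cross-section).  Bending uses the
shear-flexible (Timoshenko) formulation by default: the low-porosity designs
have strut slenderness near 3, where neglecting shear deformation
overstiffens the bending-dominated loading directions and visibly distorts
the anisotropy ratio.  ``shear=False`` selects the classical Euler-Bernoulli
element.  The apparent modulus in
a loading direction is obtained from a displacement-controlled compression
test between rigid platens: the specimen faces perpendicular to the load are
tied to the platens in the loading direction (rotations fixed, lateral
translation free), one face is displaced, and

    E_app = (reaction force / footprint area) / (displacement / span).

Multidirectional stiffness is probed by sweeping the loading direction over
the hemisphere in 15 degree increments of the polar and azimuthal angles;
the ratio of the extreme moduli is the anisotropy coefficient (max:min).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import spsolve
from scipy.stats import linregress

from .lattice import Cylinder, Lattice, trim_to_cylinder

__all__ = [
    "SingularityError",
    "WindowError",
    "DirectionSweep",
    "StressStrainCurve",
    "frame_stiffness",
    "frame_solve",
    "apparent_modulus",
    "direction_sweep",
    "design_direction_sweep",
    "anisotropy_coefficient",
    "direction_average_modulus",
    "modulus_from_hysteresis",
    "synthetic_hysteresis_curve",
]

_PLATEN_TOL = 1e-5  # mm, face-detection tolerance


class SingularityError(RuntimeError):
    """The constrained frame system is rank deficient (floating mechanism)."""


class WindowError(ValueError):
    """The requested stress window is not covered by the recorded curve."""


@dataclass
class DirectionSweep:
    """Apparent moduli sampled over the unique loading hemisphere."""

    phi_deg: np.ndarray
    theta_deg: np.ndarray
    moduli: np.ndarray
    increment: float

    def __post_init__(self) -> None:
        self.phi_deg = np.asarray(self.phi_deg, float)
        self.theta_deg = np.asarray(self.theta_deg, float)
        self.moduli = np.asarray(self.moduli, float)
        if not (len(self.phi_deg) == len(self.theta_deg) == len(self.moduli)):
            raise ValueError("sweep arrays must have equal length")
        if self.moduli.size and np.any(self.moduli <= 0):
            raise ValueError("all sweep moduli must be positive")


@dataclass
class StressStrainCurve:
    """Recorded compression curve with an a-priori yield estimate (MPa)."""

    strain: np.ndarray
    stress: np.ndarray
    yield_estimate: float

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, float)
        self.stress = np.asarray(self.stress, float)
        if len(self.strain) != len(self.stress):
            raise ValueError("strain and stress must have equal length")


# ---------------------------------------------------------------------------
# element / assembly
# ---------------------------------------------------------------------------

#: Shear correction factor for a solid circular section.
def _kappa(poisson: float) -> float:
    return 6.0 * (1.0 + poisson) / (7.0 + 6.0 * poisson)


def _local_stiffness(E, G, A, Iy, Iz, J, L, phi_y, phi_z):
    """Batch of 12x12 local frame stiffness matrices.

    ``phi = 12 E I / (G A_s L^2)`` is the shear-flexibility parameter of the
    Timoshenko beam; ``phi = 0`` recovers the Euler-Bernoulli element.
    """
    m = len(L)
    k = np.zeros((m, 12, 12))
    ax = E * A / L
    tr = G * J / L
    cz = 1.0 + phi_z
    cy = 1.0 + phi_y
    bz12, bz6 = 12 * E * Iz / (cz * L**3), 6 * E * Iz / (cz * L**2)
    bz4, bz2 = (4 + phi_z) * E * Iz / (cz * L), (2 - phi_z) * E * Iz / (cz * L)
    by12, by6 = 12 * E * Iy / (cy * L**3), 6 * E * Iy / (cy * L**2)
    by4, by2 = (4 + phi_y) * E * Iy / (cy * L), (2 - phi_y) * E * Iy / (cy * L)

    def put(i, j, v):
        k[:, i, j] = v
        if i != j:
            k[:, j, i] = v

    put(0, 0, ax); put(0, 6, -ax); put(6, 6, ax)
    put(3, 3, tr); put(3, 9, -tr); put(9, 9, tr)
    # bending in local x-y (about z)
    put(1, 1, bz12); put(1, 5, bz6); put(1, 7, -bz12); put(1, 11, bz6)
    put(5, 5, bz4); put(5, 7, -bz6); put(5, 11, bz2)
    put(7, 7, bz12); put(7, 11, -bz6)
    put(11, 11, bz4)
    # bending in local x-z (about y)
    put(2, 2, by12); put(2, 4, -by6); put(2, 8, -by12); put(2, 10, -by6)
    put(4, 4, by4); put(4, 8, by6); put(4, 10, by2)
    put(8, 8, by12); put(8, 10, by6)
    put(10, 10, by4)
    return k


def _direction_cosines(d: np.ndarray) -> np.ndarray:
    """Batch of 3x3 local-axis matrices (rows: local x, y, z in global)."""
    x = d / np.linalg.norm(d, axis=1, keepdims=True)
    ref = np.tile(np.array([0.0, 0.0, 1.0]), (len(x), 1))
    near_z = np.abs(x[:, 2]) > 0.999
    ref[near_z] = [1.0, 0.0, 0.0]
    y = np.cross(ref, x)
    y /= np.linalg.norm(y, axis=1, keepdims=True)
    z = np.cross(x, y)
    return np.stack([x, y, z], axis=1)


def frame_stiffness(lat: Lattice, shear: bool = True):
    """Assemble the global 6*N DOF stiffness matrix (CSR, symmetric PSD).

    ``shear=True`` (default) uses Timoshenko bending terms, which matter for
    the stocky struts of low-porosity designs; ``shear=False`` selects the
    classical Euler-Bernoulli element (and warns when struts are stocky
    enough for the neglected shear deformation to matter).
    """
    E = lat.material.elastic_modulus
    G = lat.material.shear_modulus
    d = lat.strut_vectors()
    L = np.linalg.norm(d, axis=1)
    r = lat.radii
    slender = L / r
    if not shear and np.any(slender < 3):
        warnings.warn(
            f"{int((slender < 3).sum())} struts have slenderness < 3; "
            "Euler-Bernoulli theory neglects their shear deformation",
            stacklevel=2)
    A = np.pi * r**2
    I = np.pi * r**4 / 4.0
    J = 2.0 * I
    if shear:
        phi = 12.0 * E * I / (G * _kappa(lat.material.poisson_ratio)
                              * A * L**2)
    else:
        phi = np.zeros_like(L)
    k_loc = _local_stiffness(E, G, A, I, I, J, L, phi, phi)
    lam = _direction_cosines(d)                     # (m, 3, 3)
    T = np.zeros((len(L), 12, 12))
    for b in range(4):
        T[:, 3 * b:3 * b + 3, 3 * b:3 * b + 3] = lam
    k_glob = np.einsum("mji,mjk,mkl->mil", T, k_loc, T)
    dof = np.concatenate([6 * lat.struts[:, :1] + np.arange(6),
                          6 * lat.struts[:, 1:] + np.arange(6)], axis=1)
    rows = np.repeat(dof, 12, axis=1).ravel()
    cols = np.tile(dof, (1, 12)).ravel()
    n_dof = 6 * lat.n_nodes
    return coo_matrix((k_glob.ravel(), (rows, cols)),
                      shape=(n_dof, n_dof)).tocsr()


def frame_solve(lat: Lattice, constraints: dict[int, float],
                loads: dict[int, float] | None = None,
                shear: bool = True):
    """Solve K u = f with prescribed DOF values.

    ``constraints`` maps global DOF index (6*node + component, components
    ordered ux, uy, uz, rx, ry, rz) to its prescribed value; ``loads`` maps
    free DOF indices to applied forces/moments.  Returns ``(u, reactions)``
    where reactions are reported on the constrained DOFs.
    """
    K = frame_stiffness(lat, shear=shear).tocsc()
    n = K.shape[0]
    f = np.zeros(n)
    if loads:
        for i, v in loads.items():
            f[i] += v
    fixed = np.array(sorted(constraints), dtype=int)
    u = np.zeros(n)
    u[fixed] = [constraints[i] for i in fixed]
    free = np.setdiff1d(np.arange(n), fixed)
    if len(free):
        rhs = f[free] - K[free][:, fixed] @ u[fixed]
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            try:
                u_free = spsolve(K[free][:, free], rhs)
            except Warning as exc:  # MatrixRankWarning
                raise SingularityError(
                    f"free system is rank deficient: {exc}") from exc
        if not np.all(np.isfinite(u_free)):
            raise SingularityError("free system is rank deficient "
                                   "(non-finite displacements)")
        u[free] = u_free
    reactions = np.asarray(K[fixed] @ u - f[fixed]).ravel()
    return u, dict(zip(fixed.tolist(), reactions.tolist()))


# ---------------------------------------------------------------------------
# apparent modulus
# ---------------------------------------------------------------------------

def _rotation_to_z(direction: np.ndarray) -> np.ndarray:
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    theta = np.arccos(np.clip(d[2], -1, 1))
    phi = np.arctan2(d[1], d[0])
    ct, st = np.cos(-theta), np.sin(-theta)
    cp, sp = np.cos(-phi), np.sin(-phi)
    ry = np.array([[ct, 0, st], [0, 1, 0], [-st, 0, ct]])
    rz = np.array([[cp, -sp, 0], [sp, cp, 0], [0, 0, 1]])
    return ry @ rz


def _bridge_subset(lat: Lattice, bottom: np.ndarray, top: np.ndarray):
    """Keep only components connecting both platen faces."""
    ncomp, labels = connected_components(lat.adjacency(), directed=False)
    good = set(labels[bottom]) & set(labels[top])
    if not good:
        raise SingularityError(
            "no strut path connects the loading faces "
            f"({ncomp} floating components)")
    keep_nodes = np.isin(labels, sorted(good))
    if keep_nodes.all():
        return lat
    remap = np.cumsum(keep_nodes) - 1
    keep_struts = keep_nodes[lat.struts].all(axis=1)
    return Lattice(lat.nodes[keep_nodes], remap[lat.struts[keep_struts]],
                   lat.radii[keep_struts], lat.material)


def apparent_modulus(lat: Lattice, direction, span: float | None = None,
                     area: float | None = None, strain: float = 1e-3,
                     shear: bool = True) -> float:
    """Apparent elastic modulus (MPa) for loading along ``direction``.

    For a non-axial direction the lattice is rigidly rotated so the loading
    axis maps onto z before the platen test; the result is therefore
    identical whether the lattice or the load frame is rotated.  ``area``
    defaults to the circular footprint pi/4 * ex * ey of the node bounding
    box (the full specimen cross-section, as in the physical test).
    """
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    if abs(d[2] - 1.0) > 1e-12:
        lat = lat.rotated(_rotation_to_z(d))
    bb = lat.bbox()
    z0, z1 = bb[0, 2], bb[1, 2]
    if span is None:
        span = z1 - z0
    if area is None:
        ex, ey = bb[1, 0] - bb[0, 0], bb[1, 1] - bb[0, 1]
        area = np.pi / 4.0 * ex * ey
    bottom = np.flatnonzero(lat.nodes[:, 2] < z0 + _PLATEN_TOL)
    top = np.flatnonzero(lat.nodes[:, 2] > z1 - _PLATEN_TOL)
    lat = _bridge_subset(lat, bottom, top)
    bb = lat.bbox()
    bottom = np.flatnonzero(lat.nodes[:, 2] < z0 + _PLATEN_TOL)
    top = np.flatnonzero(lat.nodes[:, 2] > z1 - _PLATEN_TOL)
    delta = strain * span
    constraints: dict[int, float] = {}
    for i in bottom:
        constraints[6 * i + 2] = 0.0
        for c in (3, 4, 5):
            constraints[6 * i + c] = 0.0
    for i in top:
        constraints[6 * i + 2] = -delta
        for c in (3, 4, 5):
            constraints[6 * i + c] = 0.0
    # minimal lateral pin to remove in-plane rigid translation
    pin = bottom[np.argmin(lat.nodes[bottom, 0] ** 2
                           + lat.nodes[bottom, 1] ** 2)]
    constraints[6 * pin + 0] = 0.0
    constraints[6 * pin + 1] = 0.0
    _, reactions = frame_solve(lat, constraints, shear=shear)
    force = -sum(reactions[6 * i + 2] for i in top)
    modulus = (force / area) / strain
    if modulus <= 0:
        raise SingularityError("non-positive apparent modulus")
    return float(modulus)


# ---------------------------------------------------------------------------
# direction sweep
# ---------------------------------------------------------------------------

def sweep_grid(increment: float) -> tuple[np.ndarray, np.ndarray]:
    """(phi, theta) sample grid in degrees: unique pole plus 15-deg bands."""
    if 90 % int(increment):
        raise ValueError("increment must divide 90")
    phis, thetas = [0.0], [0.0]
    for theta in np.arange(increment, 90 + 1e-9, increment):
        for phi in np.arange(0, 360, increment):
            phis.append(float(phi))
            thetas.append(float(theta))
    return np.array(phis), np.array(thetas)


def direction_sweep(block: Lattice, increment: float = 15.0,
                    test_diameter: float | None = None,
                    test_height: float | None = None) -> DirectionSweep:
    """Sweep the loading direction over the hemisphere at ``increment``.

    ``block`` must be an untrimmed lattice large enough to contain the test
    cylinder in every orientation (its inscribed sphere must cover the
    cylinder diagonal).  For each direction the block is rotated so the
    direction maps onto z, re-trimmed to the axial test cylinder, and the
    platen test is run.
    """
    bb = block.bbox()
    ext = bb[1] - bb[0]
    s_min = float(ext.min())
    if test_diameter is None or test_height is None:
        a = 0.98 * s_min / np.sqrt(2.0)
        test_diameter = test_diameter or a
        test_height = test_height or a
    diag = np.hypot(test_diameter, test_height)
    if diag > s_min + 1e-9:
        raise ValueError(
            f"test cylinder diagonal {diag:.1f} mm exceeds block inscribed "
            f"sphere {s_min:.1f} mm")
    phis, thetas = sweep_grid(increment)
    moduli = np.empty(len(phis))
    for k, (phi, theta) in enumerate(zip(phis, thetas)):
        t, p = np.radians(theta), np.radians(phi)
        d = np.array([np.sin(t) * np.cos(p), np.sin(t) * np.sin(p),
                      np.cos(t)])
        rot = _rotation_to_z(d)
        rotated = block.rotated(rot)
        c = rotated.bbox().mean(axis=0)
        spec = trim_to_cylinder(rotated, test_diameter, test_height,
                                center=c)
        moduli[k] = apparent_modulus(
            spec, np.array([0.0, 0.0, 1.0]), span=test_height,
            area=np.pi / 4.0 * test_diameter**2)
    return DirectionSweep(phis, thetas, moduli, increment)


def design_direction_sweep(design, radius: float | None = None,
                           seed: int = 0,
                           increment: float = 15.0) -> DirectionSweep:
    """Multidirectional sweep of a scaffold design on its implant cylinder.

    Builds a block lattice large enough to contain the implant cylinder in
    every orientation (the block's inscribed sphere covers the cylinder
    diagonal), solves the strut radius against the nominal porosity when
    not supplied, and sweeps at ``increment`` degrees.
    """
    import numpy as _np

    from .lattice import (generate_cubic, generate_octetruss,
                          generate_stochastic, solve_radius_for_porosity)

    if radius is None:
        radius = solve_radius_for_porosity(design, seed=seed)
    d, h = design.cylinder_diameter, design.cylinder_height
    side = float(_np.ceil(_np.hypot(d, h)))
    if design.generator == "stochastic":
        n = max(10, int(round(design.point_density * side**3)))
        block = generate_stochastic(_np.array([side] * 3), n,
                                    design.target_connectivity, seed=seed,
                                    material=design.material, radius=radius)
    else:
        a = design.unit_cell
        n_cells = int(_np.ceil(side / a))
        gen = (generate_octetruss if design.generator == "octetruss"
               else generate_cubic)
        block = gen(_np.array([n_cells * a] * 3), a, radius, design.material)
    block = block.translated(-block.bbox().mean(axis=0))
    return direction_sweep(block, increment, test_diameter=d, test_height=h)


def anisotropy_coefficient(sweep: DirectionSweep) -> float:
    """max:min ratio of apparent modulus over the sweep (>= 1)."""
    if sweep.moduli.size == 0:
        raise ValueError("empty sweep")
    return float(sweep.moduli.max() / sweep.moduli.min())


def direction_average_modulus(sweep: DirectionSweep) -> float:
    """Solid-angle-weighted hemisphere mean of the swept moduli (MPa)."""
    if sweep.moduli.size == 0:
        raise ValueError("empty sweep")
    inc = sweep.increment
    th = sweep.theta_deg
    lo = np.radians(np.maximum(th - inc / 2.0, 0.0))
    hi = np.radians(np.minimum(th + inc / 2.0, 90.0))
    band = np.cos(lo) - np.cos(hi)        # solid angle of the theta band
    w = np.zeros_like(band)
    for t in np.unique(th):
        sel = th == t
        w[sel] = band[sel] / sel.sum()    # split band weight over phi samples
    return float(np.sum(w * sweep.moduli) / np.sum(w))


# ---------------------------------------------------------------------------
# hysteresis-loop modulus
# ---------------------------------------------------------------------------

def modulus_from_hysteresis(curve: StressStrainCurve,
                            window: tuple[float, float] = (0.2, 0.7)) -> float:
    """Elastic modulus as the OLS slope of the unload-reload hysteresis
    branch restricted to ``window`` (fractions of the estimated yield).

    The initial loading toe (localized plasticity of a porous specimen) is
    excluded: the fit starts at the first sample where the stress reaches
    the top of the window.  A purely monotone recording (no unload) is fit
    on its loading pass inside the window instead.
    """
    lo = window[0] * curve.yield_estimate
    hi = window[1] * curve.yield_estimate
    stress, strain = curve.stress, curve.strain
    if stress.max() < hi - 0.2 * (hi - lo):
        raise WindowError("curve never reaches the top of the window")
    # noise-scaled detection slack from the curve's second differences
    # (zero for piecewise-linear clean recordings)
    if len(stress) >= 4:
        sigma = float(np.median(np.abs(np.diff(stress, 2)))
                      / (0.6745 * np.sqrt(6.0)))
    else:
        sigma = 0.0
    slack = 3.0 * sigma + 1e-12
    # loop start: first sample at the loading peak
    i1 = int(np.flatnonzero(stress >= stress.max() - slack)[0])
    # unload end: the post-peak stress minimum; without a real unload the
    # recording is monotone and its loading pass is fit instead
    i2 = i1 + int(np.argmin(stress[i1:]))
    if i2 == i1 or stress[i2] > lo + 0.2 * (hi - lo):
        s, e = stress[:i1 + 1], strain[:i1 + 1]
        mask = (s >= lo - 1e-12) & (s <= hi + 1e-12)
        if mask.sum() < 2:
            raise WindowError("window not covered by the loading pass")
        return float(linregress(e[mask], s[mask]).slope)
    after = np.flatnonzero(stress[i2:] >= stress.max() - slack)
    i3 = i2 + (after[0] if len(after) else len(stress[i2:]) - 1)
    # fit strictly after the peak sample: the turning point itself lies on
    # the loop, but anything before it is toe
    sel = slice(i1, i3 + 1)
    s, e = stress[sel], strain[sel]
    mask = (s >= lo - 1e-12) & (s <= hi + 1e-12)
    if mask.sum() < 2:
        raise WindowError("fewer than two samples inside the window")
    return float(linregress(e[mask], s[mask]).slope)


def synthetic_hysteresis_curve(modulus: float, yield_strength: float,
                               toe_modulus: float | None = None,
                               n_per_branch: int = 60,
                               noise_sd: float = 0.0,
                               seed: int | None = None) -> StressStrainCurve:
    """Emulate the recorded compression protocol: an initial toe loaded to
    70% of yield at a reduced slope, an unload to 20% and a reload to 70% at
    the true elastic slope."""
    if toe_modulus is None:
        toe_modulus = modulus / 3.0
    s_hi, s_lo = 0.7 * yield_strength, 0.2 * yield_strength
    toe = np.linspace(0.0, s_hi, n_per_branch)
    unload = np.linspace(s_hi, s_lo, n_per_branch)[1:]
    reload_ = np.linspace(s_lo, s_hi, n_per_branch)[1:]
    stress = np.concatenate([toe, unload, reload_])
    e_top = s_hi / toe_modulus
    strain = np.concatenate([
        toe / toe_modulus,
        e_top - (s_hi - unload) / modulus,
        e_top - (s_hi - s_lo) / modulus + (reload_ - s_lo) / modulus,
    ])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        stress = stress + rng.normal(0.0, noise_sd, len(stress))
    return StressStrainCurve(strain, stress, yield_strength)
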