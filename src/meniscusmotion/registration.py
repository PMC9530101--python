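"""Two-stage registration: rigid tibia anchoring, then deformable meniscus fitting.

Stage 1 estimates a 6-DOF rigid transform by minimising the
sum-of-squared-differences (SSD) restricted to the tibial bone mask, so
that every knee position is expressed in a common, tibia-anchored frame
and all subsequent motion is motion *relative to the tibia*.

Stage 2 estimates a dense displacement field u (mm, on the template
grid) between the menisci of two positions by minimising

    J[u] = SSD(T_s, M_s, u) + alpha * curvature(u) + beta * distance(u)

where T_s and M_s are Gaussian-smoothed indicator images of the template
and moving meniscus masks, ``curvature`` penalises the squared Laplacian
of each displacement component (second-order smoothness; affine fields
are free), and ``distance`` scores, point-wise for each template-meniscus
voxel, the Euclidean distance of its warped position to the moving
meniscus (precomputed as a distance transform of the moving
segmentation).  The distance term gives the objective a capture range:
it pulls the meniscus shapes onto each other even when the two masks do
not overlap at all, which pure SSD on compact shapes cannot do.

The optimiser is a matrix-free Gauss-Newton method: the normal equations
are solved by conjugate gradients using only Jacobian-vector products,
with Armijo backtracking, embedded in a coarse-to-fine multilevel
pyramid to avoid local minima.  The solver is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .errors import (
    ConvergenceError,
    DataError,
    DegenerateInputError,
    GeometryMismatchError,
)
from .grids import Grid, LabelMask, Volume, euclidean_distance_map

__all__ = [
    "RigidTransform",
    "DeformationField",
    "ObjectiveWeights",
    "MultilevelSchedule",
    "register_rigid",
    "register_deformable",
    "ssd_term",
    "curvature_term",
    "distance_term",
]


# --------------------------------------------------------------------------
# rigid transforms
# --------------------------------------------------------------------------

def _rot_x(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_y(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rot_z(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def _drot_x(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[0, 0, 0], [0, -s, -c], [0, c, -s]])


def _drot_y(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[-s, 0, c], [0, 0, 0], [-c, 0, -s]])


def _drot_z(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[-s, -c, 0], [c, -s, 0], [0, 0, 0]])


def _euler_to_matrix(angles):
    ax, ay, az = angles
    return _rot_z(az) @ _rot_y(ay) @ _rot_x(ax)


def _matrix_to_euler(R):
    """Inverse of _euler_to_matrix (R = Rz @ Ry @ Rx), angles in (-pi, pi]."""
    ay = np.arcsin(np.clip(-R[2, 0], -1.0, 1.0))
    if np.abs(np.cos(ay)) > 1e-9:
        ax = np.arctan2(R[2, 1], R[2, 2])
        az = np.arctan2(R[1, 0], R[0, 0])
    else:  # gimbal lock; split arbitrarily
        ax = np.arctan2(-R[1, 2], R[1, 1])
        az = 0.0
    return np.array([ax, ay, az])


@dataclass
class RigidTransform:
    """6-DOF rigid map phi(x) = R(x - c) + c + t in world mm.

    ``rotation`` holds Euler angles (radians, R = Rz Ry Rx) and
    ``translation`` the shift t (mm); ``center`` c is the fixed rotation
    center, by convention the tibia-mask centroid.
    """

    rotation: np.ndarray
    translation: np.ndarray
    center: np.ndarray = dc_field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.center = np.asarray(self.center, dtype=float).reshape(3)

    @property
    def parameters(self) -> np.ndarray:
        """(6,) vector: 3 rotation angles then 3 translations."""
        return np.concatenate([self.rotation, self.translation])

    @property
    def matrix(self) -> np.ndarray:
        return _euler_to_matrix(self.rotation)

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        return (xyz - self.center) @ self.matrix.T + self.center + self.translation

    def inverse(self) -> "RigidTransform":
        R = self.matrix
        return RigidTransform(
            rotation=_matrix_to_euler(R.T),
            translation=-R.T @ self.translation,
            center=self.center,
        )

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform x -> self(other(x)), expressed about self.center."""
        Ra, Rb = self.matrix, other.matrix
        R = Ra @ Rb
        # self(other(x)) = Ra Rb (x - cb) + Ra cb - Ra ca + ca + Ra tb + ta
        c = self.center
        shift = (
            self.apply(other.apply(c)) - (R @ (c - c) + c)
        )
        return RigidTransform(rotation=_matrix_to_euler(R), translation=shift, center=c)

    @staticmethod
    def identity(center=None) -> "RigidTransform":
        c = np.zeros(3) if center is None else np.asarray(center, dtype=float)
        return RigidTransform(np.zeros(3), np.zeros(3), c)


# --------------------------------------------------------------------------
# deformation fields
# --------------------------------------------------------------------------

@dataclass
class DeformationField:
    """Dense per-voxel displacement u (mm, world frame) on the template grid.

    ``u`` has shape (3, *grid.shape); component ordering matches world axes.
    """

    u: np.ndarray
    grid: Grid
    trace: Optional[object] = None  # objective trace (pandas DataFrame), optional

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        if self.u.shape != (3,) + tuple(self.grid.shape):
            raise GeometryMismatchError(
                f"field shape {self.u.shape} != (3, *{self.grid.shape})"
            )
        if not np.all(np.isfinite(self.u)):
            raise DataError("deformation field contains non-finite values")

    def sample_at_world(self, xyz: np.ndarray) -> np.ndarray:
        """Trilinear displacement (3, ...) at world points (..., 3)."""
        idx = np.moveaxis(self.grid.world_to_index(xyz), -1, 0)
        return np.stack(
            [
                ndimage.map_coordinates(c, idx, order=1, mode="nearest")
                for c in self.u
            ]
        )

    @staticmethod
    def zero(grid: Grid) -> "DeformationField":
        return DeformationField(np.zeros((3,) + tuple(grid.shape)), grid)


# --------------------------------------------------------------------------
# solver configuration
# --------------------------------------------------------------------------

@dataclass
class ObjectiveWeights:
    """Weights of the deformable objective: alpha (curvature), beta (distance)."""

    alpha: float = 0.1
    beta: float = 0.05

    def __post_init__(self):
        if not self.alpha > 0:
            raise ValueError("alpha must be > 0 for a well-posed problem")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")


@dataclass
class MultilevelSchedule:
    """Coarse-to-fine schedule of the Gauss-Newton solver."""

    n_levels: int = 3
    downsample_factor: float = 2.0
    max_iter_per_level: int = 12
    tol_rel: float = 1e-4
    max_cg_iter: int = 45
    cg_tol: float = 1e-2
    smoothing_sigma: float = 1.0  # voxels, indicator smoothing

    def __post_init__(self):
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")
        if self.downsample_factor <= 1:
            raise ValueError("downsample_factor must be > 1")


# --------------------------------------------------------------------------
# objective terms
# --------------------------------------------------------------------------

def _warp_indices(grid: Grid, u: np.ndarray) -> np.ndarray:
    """Fractional voxel indices of x + u(x) on ``grid`` for a same-grid image.

    For an orthogonal direction matrix D, the index offset of a world
    displacement u is D^T u / spacing.
    """
    D = grid.direction_matrix
    sp = grid.spacing_array
    base = grid.index_grid()
    off = np.einsum("ji,j...->i...", D, u) / sp.reshape(3, 1, 1, 1)
    return base + off


def _check_same_grid(a, b):
    if not a.grid.approx_equal(b.grid):
        raise GeometryMismatchError("inputs must share one voxel grid")


def ssd_term(template_img: Volume, moving_img: Volume, u: DeformationField) -> float:
    """0.5 * sum_x (T(x) - M(x + u(x)))^2 * voxel_volume, trilinear sampling of M."""
    _check_same_grid(template_img, moving_img)
    _check_same_grid(template_img, u)
    idx = _warp_indices(template_img.grid, u.u)
    warped = ndimage.map_coordinates(
        np.asarray(moving_img.data, dtype=float), idx, order=1, mode="constant", cval=0.0
    )
    r = np.asarray(template_img.data, dtype=float) - warped
    return 0.5 * template_img.grid.voxel_volume * float(np.sum(r * r))


def _laplacian(comp: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    """Discrete Laplacian: central second differences on interior nodes.

    Contributions at the two boundary planes of each axis are zero, so
    constant and affine fields incur no penalty and the operator pair
    (L, L^T) below is an exact adjoint pair.
    """
    out = np.zeros_like(comp, dtype=float)
    for ax in range(3):
        h2 = spacing[ax] ** 2
        sl_c = [slice(None)] * 3
        sl_m = [slice(None)] * 3
        sl_p = [slice(None)] * 3
        sl_c[ax] = slice(1, -1)
        sl_m[ax] = slice(0, -2)
        sl_p[ax] = slice(2, None)
        out[tuple(sl_c)] += (
            comp[tuple(sl_p)] - 2.0 * comp[tuple(sl_c)] + comp[tuple(sl_m)]
        ) / h2
    return out


def _laplacian_adjoint(comp: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    """Adjoint of :func:`_laplacian` (scatter form of the same stencil)."""
    out = np.zeros_like(comp, dtype=float)
    for ax in range(3):
        h2 = spacing[ax] ** 2
        sl_c = [slice(None)] * 3
        sl_m = [slice(None)] * 3
        sl_p = [slice(None)] * 3
        sl_c[ax] = slice(1, -1)
        sl_m[ax] = slice(0, -2)
        sl_p[ax] = slice(2, None)
        t = comp[tuple(sl_c)] / h2
        out[tuple(sl_p)] += t
        out[tuple(sl_c)] += -2.0 * t
        out[tuple(sl_m)] += t
    return out


def curvature_term(u: DeformationField) -> float:
    """Curvature (second-order smoothness) functional sum_l int (lap u_l)^2 dx.

    Discretised with spacing-aware central differences times the voxel
    volume; the conventional 1/2 prefactor of the variational form is
    absorbed into the weight alpha.  Zero for any affine field.
    """
    if not np.all(np.isfinite(u.u)):
        raise DataError("non-finite deformation field")
    sp = u.grid.spacing_array
    v = u.grid.voxel_volume
    total = 0.0
    for comp in u.u:
        lap = _laplacian(comp, sp)
        total += float(np.sum(lap * lap))
    return v * total


def distance_term(
    u: DeformationField,
    meniscus_mask,
    distance_map: Volume,
) -> float:
    """Point-wise shape penalty 0.5 * sum_{x in mask} D(x + u(x))^2 * voxel_volume.

    Each meniscus-mask voxel's warped position is scored against the
    Euclidean distance map (mm) of the counterpart meniscus, sampled
    trilinearly (with nearest-edge extension, so distances keep growing
    outside the grid).  The term vanishes exactly when every warped mask
    voxel lands on the counterpart shape and grows quadratically with the
    residual gap — this is what gives the registration a capture range
    even when the two masks do not overlap at all.

    ``meniscus_mask`` may be a binary mask or a smoothed float indicator
    used as a per-voxel weight.
    """
    _check_same_grid(u, distance_map)
    w = meniscus_mask.data.astype(float) if isinstance(meniscus_mask, LabelMask) \
        else np.asarray(meniscus_mask.data, dtype=float)
    if not np.any(w):
        raise DegenerateInputError("meniscus mask is empty")
    _check_same_grid(distance_map, meniscus_mask)
    idx = _warp_indices(u.grid, u.u)
    dw = ndimage.map_coordinates(
        np.asarray(distance_map.data, dtype=float), idx, order=1, mode="nearest"
    )
    return 0.5 * u.grid.voxel_volume * float(np.sum(w * dw * dw))


# --------------------------------------------------------------------------
# stage 1: rigid registration
# --------------------------------------------------------------------------

@dataclass
class RigidOptions:
    n_levels: int = 3
    downsample_factor: float = 2.0
    smoothing_sigma: float = 1.0  # voxels, pre-smoothing at the finest level
    maxiter: int = 80


def _downsample_volume(data: np.ndarray, grid: Grid, factor: float):
    """Gaussian anti-aliased downsampling of an image; returns (data, grid).

    With ``grid_mode=False`` scipy's zoom maps output index i to input
    index i * (n_in - 1) / (n_out - 1); keeping the same origin, the new
    spacing is therefore spacing * (n_in - 1) / (n_out - 1), which keeps
    every coarse voxel center at its exact world position.
    """
    old_shape = np.asarray(grid.shape, dtype=float)
    new_shape = np.array([max(int(round(n / factor)), 8) for n in grid.shape])
    zoom = new_shape / old_shape
    sigma = np.clip(0.5 / zoom, 0.0, None)
    sm = ndimage.gaussian_filter(np.asarray(data, dtype=float), sigma=sigma)
    out = ndimage.zoom(sm, zoom, order=1, mode="nearest", grid_mode=False)
    new_shape = np.asarray(out.shape, dtype=float)
    new_spacing = grid.spacing_array * (old_shape - 1) / (new_shape - 1)
    new_grid = Grid(
        shape=tuple(out.shape),
        spacing=tuple(new_spacing),
        origin=tuple(grid.origin_array),
        direction=grid.direction,
    )
    return out, new_grid


def register_rigid(
    template: Volume,
    moving: Volume,
    tibia_mask: LabelMask,
    opts: Optional[RigidOptions] = None,
) -> RigidTransform:
    """Estimate the 6-DOF rigid map aligning ``moving`` to ``template``.

    The similarity is the SSD restricted to the template tibia mask,

        f(p) = sum_{x in tibia} (T(x) - M(phi_p(x)))^2 * voxel_volume,

    with the rotation parameterised about the tibia-mask centroid.  The
    minimisation runs coarse-to-fine with an analytic gradient (sampled
    image gradient chained through the rigid map) under L-BFGS-B.  The
    returned transform never has a higher masked SSD than the identity.
    """
    opts = opts or RigidOptions()
    if tibia_mask.n_foreground == 0:
        raise DegenerateInputError("tibia mask is empty")
    _check_same_grid(template, tibia_mask)
    if not (np.all(np.isfinite(template.data)) and np.all(np.isfinite(moving.data))):
        raise DataError("non-finite image values")

    center = tibia_mask.foreground_world().mean(axis=0)
    v = template.grid.voxel_volume

    # build pyramid (coarsest first)
    levels = []
    t_data = ndimage.gaussian_filter(np.asarray(template.data, float), opts.smoothing_sigma)
    m_data = ndimage.gaussian_filter(np.asarray(moving.data, float), opts.smoothing_sigma)
    t_grid, m_grid = template.grid, moving.grid
    mask_pts = tibia_mask.foreground_world()
    levels.append((t_data, t_grid, m_data, m_grid, mask_pts))
    for _ in range(opts.n_levels - 1):
        t_data, t_grid = _downsample_volume(t_data, t_grid, opts.downsample_factor)
        m_data, m_grid = _downsample_volume(m_data, m_grid, opts.downsample_factor)
        # subsample the mask point cloud to roughly match the coarser density
        step = max(int(round(opts.downsample_factor ** 3)), 1)
        mask_pts = mask_pts[:: step ** 1] if len(mask_pts) > 5000 else mask_pts
        levels.append((t_data, t_grid, m_data, m_grid, mask_pts))
    levels = levels[::-1]

    def make_objective(t_data, t_grid, m_data, m_grid, pts):
        t_idx = np.moveaxis(t_grid.world_to_index(pts), -1, 0)
        t_vals = ndimage.map_coordinates(t_data, t_idx, order=1, mode="nearest")
        grads = np.gradient(m_data, *m_grid.spacing_array)
        D = m_grid.direction_matrix
        xc = pts - center

        shape_max = np.asarray(m_grid.shape, dtype=float).reshape(3, 1) - 1.0

        def f_and_g(p):
            R = _euler_to_matrix(p[:3])
            warped = xc @ R.T + center + p[3:]
            idx = np.moveaxis(m_grid.world_to_index(warped), -1, 0)
            m_vals = ndimage.map_coordinates(m_data, idx, order=1, mode="constant", cval=0.0)
            # voxels carried outside the moving field of view have no data;
            # score only the in-domain ones, renormalised so that pushing
            # voxels out of view cannot lower the objective
            valid = np.all((idx >= 0.0) & (idx <= shape_max), axis=0)
            n_valid = int(valid.sum())
            if n_valid == 0:
                return np.inf, np.zeros(6)
            scale = len(t_vals) / n_valid
            r = (t_vals - m_vals) * valid
            f = v * scale * float(np.sum(r * r))
            g_axes = np.stack([
                ndimage.map_coordinates(g, idx, order=1, mode="constant", cval=0.0)
                for g in grads
            ], axis=-1)  # gradient wrt (spacing * index) axes
            g_axes *= valid[:, None]
            g_world = g_axes @ D.T  # world-frame gradient of M at warped points
            ax_, ay_, az_ = p[0], p[1], p[2]
            Rz, Ry, Rx = _rot_z(az_), _rot_y(ay_), _rot_x(ax_)
            dRs = [Rz @ Ry @ _drot_x(ax_), Rz @ _drot_y(ay_) @ Rx, _drot_z(az_) @ Ry @ Rx]
            grad = np.empty(6)
            for k in range(3):
                dphi = xc @ dRs[k].T
                grad[k] = -2.0 * v * scale * float(np.sum(r * np.sum(g_world * dphi, axis=1)))
            for k in range(3):
                grad[3 + k] = -2.0 * v * scale * float(np.sum(r * g_world[:, k]))
            return f, grad

        return f_and_g

    p = np.zeros(6)
    for t_data_l, t_grid_l, m_data_l, m_grid_l, pts_l in levels:
        fg = make_objective(t_data_l, t_grid_l, m_data_l, m_grid_l, pts_l)
        res = optimize.minimize(
            fg, p, jac=True, method="L-BFGS-B",
            options={"maxiter": opts.maxiter, "ftol": 1e-12, "gtol": 1e-10},
        )
        p = res.x

    # guarantee: no worse than identity on the full-resolution masked SSD
    fg_fine = make_objective(*levels[-1])
    if fg_fine(p)[0] > fg_fine(np.zeros(6))[0]:
        p = np.zeros(6)
    return RigidTransform(rotation=p[:3], translation=p[3:], center=center)


# --------------------------------------------------------------------------
# stage 2: deformable registration
# --------------------------------------------------------------------------

def _prolong_field(u: np.ndarray, coarse_grid: Grid, fine_grid: Grid) -> np.ndarray:
    """Interpolate a coarse displacement field (mm) onto a finer grid."""
    out = np.empty((3,) + tuple(fine_grid.shape))
    pts = np.moveaxis(fine_grid.world_grid(), 0, -1).reshape(-1, 3)
    idx = np.moveaxis(coarse_grid.world_to_index(pts), -1, 0)
    for k in range(3):
        out[k] = ndimage.map_coordinates(
            u[k], idx, order=1, mode="nearest"
        ).reshape(tuple(fine_grid.shape))
    return out


class _LevelProblem:
    """Gauss-Newton subproblem on one pyramid level.

    ``t_s`` / ``m_s`` are the smoothed template / moving meniscus
    indicators; ``dmap`` is the Euclidean distance map (mm) of the
    *moving* meniscus, so the distance penalty pulls every template-
    meniscus voxel's warped position x + u(x) onto the moving shape —
    the same direction the SSD term drives u.
    """

    def __init__(self, t_s, m_s, dmap, w_dist, grid: Grid, alpha: float, beta: float):
        self.t_s = t_s
        self.m_s = m_s
        self.dmap = dmap
        self.w_dist = w_dist  # binary/fractional template-mask weight
        self.grid = grid
        self.alpha = alpha
        self.beta = beta
        self.v = grid.voxel_volume
        self.sp = grid.spacing_array
        self.D = grid.direction_matrix
        self.base_idx = grid.index_grid()
        self.m_grads = np.gradient(np.asarray(m_s, float), *self.sp)
        self.d_grads = np.gradient(np.asarray(dmap, float), *self.sp)

    def warp(self, u):
        off = np.einsum("ji,j...->i...", self.D, u) / self.sp.reshape(3, 1, 1, 1)
        idx = self.base_idx + off
        warped = ndimage.map_coordinates(self.m_s, idx, order=1, mode="constant", cval=0.0)
        dwarp = ndimage.map_coordinates(self.dmap, idx, order=1, mode="nearest")
        return idx, warped, dwarp

    def objective(self, u, cache=None):
        if cache is None:
            _, warped, dwarp = self.warp(u)
        else:
            warped, dwarp = cache
        ssd = 0.5 * self.v * float(np.sum((self.t_s - warped) ** 2))
        curv = 0.0
        for comp in u:
            lap = _laplacian(comp, self.sp)
            curv += float(np.sum(lap * lap))
        curv *= self.v
        dist = 0.5 * self.v * float(np.sum(self.w_dist * dwarp * dwarp))
        total = ssd + self.alpha * curv + self.beta * dist
        return total, ssd, curv, dist

    def gradient_and_gn(self, u):
        """Return J(u), its gradient, and a matvec for the GN normal matrix."""
        idx, warped, dwarp = self.warp(u)
        total, ssd, curv, dist = self.objective(u, cache=(warped, dwarp))

        def sample_world_grads(grads):
            g_axes = np.stack([
                ndimage.map_coordinates(g, idx, order=1, mode="nearest")
                for g in grads
            ])
            return np.einsum("ij,j...->i...", self.D, g_axes)

        G = sample_world_grads(self.m_grads)   # grad of moving indicator at x+u
        Gd = sample_world_grads(self.d_grads)  # grad of moving distance map at x+u

        r_ssd = warped - self.t_s  # sign: d(ssd)/du = v * r_ssd * G
        grad = np.empty_like(u)
        w_dist = self.beta * self.v * self.w_dist * dwarp
        laps = [_laplacian(comp, self.sp) for comp in u]
        for k in range(3):
            grad[k] = (
                self.v * r_ssd * G[k]
                + w_dist * Gd[k]
                + 2.0 * self.alpha * self.v * _laplacian_adjoint(laps[k], self.sp)
            )

        # GN normal matrix: v * G G^T + beta*v*w * Gd Gd^T + 2*alpha*v * L^T L
        w_gn_dist = self.beta * self.v * self.w_dist

        def matvec(delta):
            gd = np.einsum("k...,k...->...", G, delta)
            gdd = np.einsum("k...,k...->...", Gd, delta)
            out = np.empty_like(delta)
            core = self.v * gd
            core_d = w_gn_dist * gdd
            for k in range(3):
                out[k] = G[k] * core + Gd[k] * core_d \
                    + 2.0 * self.alpha * self.v * _laplacian_adjoint(
                        _laplacian(delta[k], self.sp), self.sp
                    )
            return out

        return total, ssd, curv, dist, grad, matvec

    def cg(self, matvec, b, maxiter, tol):
        """Conjugate gradients on A x = b, x0 = 0; returns the approximate step."""
        x = np.zeros_like(b)
        r = b.copy()
        p = r.copy()
        rs = float(np.sum(r * r))
        b_norm = np.sqrt(rs)
        if b_norm == 0.0:
            return x
        for _ in range(maxiter):
            Ap = matvec(p)
            pAp = float(np.sum(p * Ap))
            if pAp <= 0:
                break
            a = rs / pAp
            x += a * p
            r -= a * Ap
            rs_new = float(np.sum(r * r))
            if np.sqrt(rs_new) <= tol * b_norm:
                break
            p = r + (rs_new / rs) * p
            rs = rs_new
        return x


def register_deformable(
    template_mask: LabelMask,
    moving_mask: LabelMask,
    weights: Optional[ObjectiveWeights] = None,
    schedule: Optional[MultilevelSchedule] = None,
    seed: Optional[int] = None,
) -> DeformationField:
    """Deformable registration of meniscus masks; returns u on the template grid.

    Both masks must already live in the common tibia-anchored frame.  The
    data images are Gaussian-smoothed indicator functions of the masks
    (smoothing gives the SSD a capture range of a few voxels); the
    distance penalty extends that range to arbitrarily separated shapes.
    ``seed`` is accepted for API uniformity only — the solver is
    deterministic.
    """
    weights = weights or ObjectiveWeights()
    schedule = schedule or MultilevelSchedule()
    if template_mask.n_foreground == 0 or moving_mask.n_foreground == 0:
        raise DegenerateInputError("deformable registration needs non-empty masks")
    _check_same_grid(template_mask, moving_mask)

    grid = template_mask.grid
    sig = schedule.smoothing_sigma
    t_s = ndimage.gaussian_filter(template_mask.data.astype(float), sig)
    m_s = ndimage.gaussian_filter(moving_mask.data.astype(float), sig)
    dmap = np.asarray(euclidean_distance_map(moving_mask).data, dtype=float)
    t_f = template_mask.data.astype(float)
    m_f = moving_mask.data.astype(float)

    # pyramid, coarsest last in construction order
    n_levels = schedule.n_levels
    min_dim = min(grid.shape)
    while n_levels > 1 and min_dim / schedule.downsample_factor ** (n_levels - 1) < 8:
        n_levels -= 1
    pyramid = [(t_s, m_s, dmap, t_f, m_f, grid)]
    for _ in range(n_levels - 1):
        g_prev = pyramid[-1][5]
        t_c, g_c = _downsample_volume(pyramid[-1][0], g_prev, schedule.downsample_factor)
        m_c, _ = _downsample_volume(pyramid[-1][1], g_prev, schedule.downsample_factor)
        d_c, _ = _downsample_volume(pyramid[-1][2], g_prev, schedule.downsample_factor)
        tf_c, _ = _downsample_volume(pyramid[-1][3], g_prev, schedule.downsample_factor)
        mf_c, _ = _downsample_volume(pyramid[-1][4], g_prev, schedule.downsample_factor)
        pyramid.append((t_c, m_c, d_c, tf_c, mf_c, g_c))
    pyramid = pyramid[::-1]  # coarse -> fine

    trace_rows = []
    u = np.zeros((3,) + tuple(pyramid[0][5].shape))
    prev_grid = pyramid[0][5]

    for level, (t_l, m_l, d_l, tf_l, mf_l, g_l) in enumerate(pyramid):
        if not g_l.approx_equal(prev_grid):
            u = _prolong_field(u, prev_grid, g_l)
        prev_grid = g_l
        # per-level shape penalty inputs: recompute the distance map and
        # weight from re-binarised masks so that identical masks incur an
        # exactly-zero penalty at every level (a blurred product would not)
        m_bin = mf_l > 0.5
        if m_bin.any():
            d_use = ndimage.distance_transform_edt(~m_bin, sampling=g_l.spacing_array)
        else:  # structure thinner than the coarse voxel: keep the blurred map
            d_use = d_l
        t_bin = tf_l > 0.5
        w_use = t_bin.astype(float) if t_bin.any() else tf_l
        prob = _LevelProblem(t_l, m_l, d_use, w_use, g_l, weights.alpha, weights.beta)

        total, ssd, curv, dist = prob.objective(u)
        if not np.isfinite(total):
            raise ConvergenceError("non-finite objective", trace=trace_rows)
        trace_rows.append(
            dict(level=level, iteration=0, ssd=ssd, curvature=curv,
                 distance=dist, total=total)
        )
        for it in range(1, schedule.max_iter_per_level + 1):
            total, ssd, curv, dist, grad, matvec = prob.gradient_and_gn(u)
            step = prob.cg(matvec, -grad, schedule.max_cg_iter, schedule.cg_tol)
            slope = float(np.sum(grad * step))
            if slope >= 0:  # CG failed to produce a descent direction
                step = -grad
                slope = -float(np.sum(grad * grad))
                if slope == 0.0:
                    break
            # Armijo backtracking, factor 0.5, c = 1e-4
            s, accepted = 1.0, False
            for _ in range(12):
                new_total, n_ssd, n_curv, n_dist = prob.objective(u + s * step)
                if np.isfinite(new_total) and new_total <= total + 1e-4 * s * slope:
                    accepted = True
                    break
                s *= 0.5
            if not accepted:
                break  # stagnation at this level; keep the best iterate
            u = u + s * step
            trace_rows.append(
                dict(level=level, iteration=it, ssd=n_ssd, curvature=n_curv,
                     distance=n_dist, total=new_total)
            )
            if total - new_total <= schedule.tol_rel * max(abs(total), 1e-12):
                break

    trace = pd.DataFrame(trace_rows)
    for _, sub in trace.groupby("level"):
        tot = sub["total"].to_numpy()
        if np.any(np.diff(tot) > 1e-9 * max(1.0, abs(tot[0]))):
            raise ConvergenceError(
                "objective increased across accepted steps", trace=trace_rows
            )
    field = DeformationField(u, prev_grid)
    field.trace = trace
    return field
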