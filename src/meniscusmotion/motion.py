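"""From a dense deformation field to per-segment meniscal motion.

The clinical readout is, per meniscus and per segment (anterior horn AH,
intermediate horn IH, posterior horn PH, plus the whole meniscus), the
mean displacement vector of the template-meniscus voxels, reported as

* ``avg_mm`` — the length of the mean vector,
* ``ml_mm``  — its signed mediolateral projection (+ = lateral),
* ``ap_mm``  — its signed anteroposterior projection (+ = posterior).

The ML/AP axes are derived automatically from a principal component
analysis of the combined meniscus masks: the top-2 eigenvectors of the
voxel-cloud covariance span the plateau plane; the in-plane axis closer
to the MM-to-LM centroid direction is ML (oriented medial -> lateral),
and the in-plane orthogonal is AP (oriented toward patient-posterior).
Segments are thirds of the crescent by arc length along its arch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError, DegeneracyError, GeometryMismatchError, TopologyError
from .grids import Grid, LabelMask
from .registration import DeformationField

__all__ = [
    "MeniscusAxes",
    "SegmentMotion",
    "SegmentLabels",
    "SEGMENT_CODES",
    "crop_field",
    "anatomical_axes",
    "partition_arch",
    "segment_motion",
]

SEGMENT_CODES = {"AH": 1, "IH": 2, "PH": 3}
_POSTERIOR_WORLD = np.array([0.0, -1.0, 0.0])  # RAS: -y is posterior


@dataclass
class MeniscusAxes:
    """Orthonormal anatomical frame: ml (+lateral), ap (+posterior), normal."""

    ml_axis: np.ndarray
    ap_axis: np.ndarray
    plane_normal: np.ndarray

    def __post_init__(self):
        self.ml_axis = np.asarray(self.ml_axis, dtype=float).reshape(3)
        self.ap_axis = np.asarray(self.ap_axis, dtype=float).reshape(3)
        self.plane_normal = np.asarray(self.plane_normal, dtype=float).reshape(3)
        for v in (self.ml_axis, self.ap_axis, self.plane_normal):
            if abs(np.linalg.norm(v) - 1.0) > 1e-10:
                raise ValueError("axes must be unit vectors")
        if (
            abs(self.ml_axis @ self.ap_axis) > 1e-8
            or abs(self.ml_axis @ self.plane_normal) > 1e-8
            or abs(self.ap_axis @ self.plane_normal) > 1e-8
        ):
            raise ValueError("axes must be pairwise orthogonal")


@dataclass
class SegmentMotion:
    """Mean motion of one meniscus segment."""

    meniscus: str  # MM | LM
    segment: str  # AH | IH | PH | whole
    avg_mm: float
    ml_mm: float
    ap_mm: float
    n_voxels: int

    def __post_init__(self):
        if self.n_voxels < 1:
            raise DegenerateInputError("segment with no voxels")
        if self.ml_mm ** 2 + self.ap_mm ** 2 > self.avg_mm ** 2 + 1e-9:
            raise ValueError("in-plane projections exceed the vector length")


@dataclass
class SegmentLabels:
    """Per-voxel segment assignment on the template grid (1=AH, 2=IH, 3=PH)."""

    data: np.ndarray
    grid: Grid

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if tuple(self.data.shape) != tuple(self.grid.shape):
            raise GeometryMismatchError("label shape differs from grid")
        vals = set(np.unique(self.data)) - {0}
        if not vals <= {1, 2, 3}:
            raise ValueError(f"unexpected segment codes {vals}")


def crop_field(u: DeformationField, meniscus: LabelMask) -> Tuple[np.ndarray, np.ndarray]:
    """Restrict the field to template-meniscus voxels.

    Returns ``(voxels, displacements)``: (N, 3) integer indices and the
    (N, 3) displacement vectors (mm), unmodified.
    """
    if not u.grid.approx_equal(meniscus.grid):
        raise GeometryMismatchError("field and mask must share one grid")
    if meniscus.n_foreground == 0:
        raise DegenerateInputError("cannot crop with an empty mask")
    vox = meniscus.foreground_indices()
    disp = u.u[:, meniscus.data].T.copy()
    return vox, disp


def anatomical_axes(mm_mask: LabelMask, lm_mask: LabelMask, laterality: str) -> MeniscusAxes:
    """PCA-derived anatomical frame from the combined meniscus voxel cloud.

    ``laterality`` ('left'/'right') is carried for provenance and sanity
    checking; the medial-to-lateral orientation itself comes from the MM
    and LM centroids, which encode laterality implicitly.
    """
    if mm_mask.n_foreground == 0 or lm_mask.n_foreground == 0:
        raise DegenerateInputError("both meniscus masks must be non-empty")
    if laterality not in ("left", "right"):
        raise ValueError(f"laterality must be 'left' or 'right', got {laterality!r}")
    if not mm_mask.grid.approx_equal(lm_mask.grid):
        raise GeometryMismatchError("meniscus masks must share one grid")

    pts_mm = mm_mask.foreground_world()
    pts_lm = lm_mask.foreground_world()
    pts = np.vstack([pts_mm, pts_lm])
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / len(pts)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if (evals[2] - evals[0]) <= 1e-6 * max(evals[2], 1e-30) or (
        (evals[1] - evals[0]) <= 1e-6 * max(evals[2], 1e-30)
    ):
        raise DegeneracyError("voxel-cloud covariance is (near-)isotropic")

    e1, e2 = evecs[:, 2], evecs[:, 1]  # top-2 principal directions
    d = pts_lm.mean(axis=0) - pts_mm.mean(axis=0)  # medial -> lateral
    if abs(d @ e1) >= abs(d @ e2):
        ml, ap = e1, e2
    else:
        ml, ap = e2, e1
    if ml @ d < 0:
        ml = -ml
    if ap @ _POSTERIOR_WORLD < 0:
        ap = -ap
    elif ap @ _POSTERIOR_WORLD == 0:
        # plateau plane orthogonal to the AP axis would be anatomically
        # implausible; orient by laterality-consistent handedness instead
        normal_guess = np.cross(ml, ap)
        if normal_guess[2] < 0:
            ap = -ap
    normal = np.cross(ml, ap)
    normal /= np.linalg.norm(normal)
    return MeniscusAxes(ml_axis=ml, ap_axis=ap, plane_normal=normal)


def _fit_circle_center(xy: np.ndarray) -> np.ndarray:
    """Least-squares (Kaasa) circle fit; the crescent's center of curvature.

    Parameterising the arch by the angle about this center (rather than
    the area centroid, which sits off-center inside the C) keeps the
    angular coordinate aligned with the annulus geometry, so arc length
    accumulates uniformly along the crescent.  Falls back to the centroid
    for degenerate (collinear) clouds.
    """
    A = np.column_stack([2.0 * xy[:, 0], 2.0 * xy[:, 1], np.ones(len(xy))])
    b = np.sum(xy ** 2, axis=1)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3 or not np.all(np.isfinite(sol)):
        return xy.mean(axis=0)
    center = sol[:2]
    # guard against absurd fits (nearly straight segments)
    if np.linalg.norm(center - xy.mean(axis=0)) > 10.0 * xy.std(axis=0).sum():
        return xy.mean(axis=0)
    return center


def _connected(mask: LabelMask) -> bool:
    _, n = ndimage.label(mask.data, structure=np.ones((3, 3, 3), dtype=int))
    return n == 1


def partition_arch(meniscus: LabelMask, axes: MeniscusAxes) -> SegmentLabels:
    """Split a crescent into AH/IH/PH thirds by arc length along its arch.

    Voxels are projected onto the principal plane and parameterised by
    the polar angle about the crescent's fitted circle center (its
    center of curvature).  The arch must be
    open (an angular gap of at least 10 degrees) and connected.  Arc
    length is accumulated along the angularly ordered centerline (mean
    radius per angular bin); the crescent is cut at 1/3 and 2/3 of the
    total length, and the end whose voxels are more anterior (smaller AP
    coordinate) becomes AH.
    """
    if meniscus.n_foreground == 0:
        raise DegenerateInputError("empty meniscus mask")
    if not _connected(meniscus):
        raise TopologyError("meniscus mask is disconnected")

    pts = meniscus.foreground_world()
    p_ml = pts @ axes.ml_axis
    p_ap = pts @ axes.ap_axis
    xy = np.column_stack([p_ml, p_ap])

    # two passes: the circle fit on the full (thick) voxel cloud has a small
    # bias toward the open side; refitting on the extracted centerline
    # removes it and keeps the angular coordinate aligned with the arch
    c2 = _fit_circle_center(xy)
    for _ in range(2):
        rel = xy - c2
        theta = np.arctan2(rel[:, 1], rel[:, 0])  # (-pi, pi]
        radius = np.linalg.norm(rel, axis=1)

        # locate the angular gap (crescent opening)
        th_sorted = np.sort(theta, kind="stable")
        gaps = np.diff(th_sorted)
        wrap_gap = th_sorted[0] + 2.0 * np.pi - th_sorted[-1]
        all_gaps = np.concatenate([gaps, [wrap_gap]])
        k = int(np.argmax(all_gaps))
        max_gap = all_gaps[k]
        if np.degrees(max_gap) < 10.0:
            raise TopologyError("mask forms a closed annulus (no arch endpoints)")
        gap_end = th_sorted[(k + 1) % len(th_sorted)]  # first angle after the gap

        # angle measured from the start of the arch, in [0, 2*pi)
        t = np.mod(theta - gap_end, 2.0 * np.pi)
        span = t.max()

        # centerline: mean radius in ~2-degree angular bins, lightly smoothed
        nbins = int(np.clip(np.degrees(span) / 2.0, 18, 180))
        edges = np.linspace(0.0, span, nbins + 1)
        which = np.clip(np.digitize(t, edges) - 1, 0, nbins - 1)
        r_bin = np.full(nbins, np.nan)
        for b in range(nbins):
            sel = which == b
            if np.any(sel):
                r_bin[b] = radius[sel].mean()
        good = np.isfinite(r_bin)
        centers = 0.5 * (edges[:-1] + edges[1:])
        r_bin = np.interp(centers, centers[good], r_bin[good])
        if nbins >= 5:  # moving-average smoothing of the centerline radius
            kern = np.ones(3) / 3.0
            r_bin = np.convolve(np.pad(r_bin, 1, mode="edge"), kern, mode="valid")

        # centerline polyline in plane coordinates; refit center on it
        cl = c2 + np.column_stack([r_bin * np.cos(centers + gap_end),
                                   r_bin * np.sin(centers + gap_end)])
        c2 = _fit_circle_center(cl)

    # cumulative arc length of the centerline polyline
    seg_len = np.hypot(np.diff(cl[:, 0]), np.diff(cl[:, 1]))
    arc = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = arc[-1]
    if total <= 0:
        raise TopologyError("degenerate arch (zero length)")

    s = np.interp(t, centers, arc)  # arc-length coordinate of each voxel
    first_cut, second_cut = total / 3.0, 2.0 * total / 3.0
    seg_idx = np.where(s < first_cut, 0, np.where(s < second_cut, 1, 2))

    # orient: the end with the more anterior voxels is the anterior horn
    ap_first = p_ap[seg_idx == 0].mean()
    ap_last = p_ap[seg_idx == 2].mean()
    codes = (1, 2, 3) if ap_first <= ap_last else (3, 2, 1)

    data = np.zeros(tuple(meniscus.grid.shape), dtype=np.uint8)
    vox = meniscus.foreground_indices()
    data[tuple(vox.T)] = np.asarray(codes, dtype=np.uint8)[seg_idx]
    return SegmentLabels(data=data, grid=meniscus.grid)


def segment_motion(
    u: DeformationField,
    labels: SegmentLabels,
    axes: MeniscusAxes,
    meniscus_id: str,
) -> List[SegmentMotion]:
    """Mean per-segment motion (AH, IH, PH, whole) of one meniscus."""
    if not u.grid.approx_equal(labels.grid):
        raise GeometryMismatchError("field and labels must share one grid")
    out = []
    member = labels.data > 0
    if not np.any(member):
        raise DegenerateInputError("segment labels are empty")
    for seg_name, code in list(SEGMENT_CODES.items()) + [("whole", None)]:
        sel = member if code is None else labels.data == code
        n = int(sel.sum())
        if n == 0:
            raise DegenerateInputError(f"segment {seg_name} has no voxels")
        mean = u.u[:, sel].mean(axis=1)
        out.append(
            SegmentMotion(
                meniscus=meniscus_id,
                segment=seg_name,
                avg_mm=float(np.linalg.norm(mean)),
                ml_mm=float(mean @ axes.ml_axis),
                ap_mm=float(mean @ axes.ap_axis),
                n_voxels=n,
            )
        )
    return out
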