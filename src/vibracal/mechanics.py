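"""Substrate displacement and strain analysis from fiducial-bead images.

The substrate deformation produced by the vibrating probe is read off from
1 µm fluorescent beads embedded at the gel surface: a reference frame (probe
positioned but not moving) is compared with a displaced frame.  Bead motion
gives a scattered displacement sample, which is interpolated onto a regular
grid, and the in-plane normal strains are computed by finite differences
(central 3-point stencils in the interior, one-sided 2-point stencils at the
boundary).  The total strain magnitude is ``E = sqrt(E_x**2 + E_y**2)``.

All physical coordinates are in micrometres; image coordinates follow the
usual row/column (y/x) convention with the origin at the top-left pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator, griddata
from skimage.feature import match_template, peak_local_max

__all__ = [
    "GridSpec",
    "DisplacementField",
    "StrainField",
    "BeadSet",
    "track_beads",
    "interpolate_field",
    "finite_difference",
    "displacement_to_strain",
    "summarize_field",
    "disk_footprint",
]


class MechanicsError(ValueError):
    """Raised for invalid geometry or degenerate inputs."""


@dataclass(frozen=True)
class GridSpec:
    """Regular rectangular grid on the substrate plane.

    Parameters
    ----------
    origin : (x0, y0) coordinates of the first node, µm.
    shape : (ny, nx) number of nodes per axis.
    spacing : node spacing h, µm (isotropic).
    """

    origin: tuple[float, float]
    shape: tuple[int, int]
    spacing: float

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise MechanicsError("grid spacing must be positive")
        ny, nx = self.shape
        if ny < 2 or nx < 2:
            raise MechanicsError("grid must have at least 2 nodes per axis")

    @property
    def x(self) -> np.ndarray:
        return self.origin[0] + self.spacing * np.arange(self.shape[1])

    @property
    def y(self) -> np.ndarray:
        return self.origin[1] + self.spacing * np.arange(self.shape[0])

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """Node coordinate arrays (X, Y), each of shape (ny, nx)."""
        return np.meshgrid(self.x, self.y)


@dataclass
class DisplacementField:
    """Gridded displacement components u_x, u_y (µm) on a regular grid.

    Undefined nodes (e.g. outside the convex hull of the tracked beads)
    are NaN in both components.
    """

    grid_x: np.ndarray
    grid_y: np.ndarray
    u_x: np.ndarray
    u_y: np.ndarray
    spacing: float

    def __post_init__(self) -> None:
        self.grid_x = np.asarray(self.grid_x, dtype=float)
        self.grid_y = np.asarray(self.grid_y, dtype=float)
        self.u_x = np.asarray(self.u_x, dtype=float)
        self.u_y = np.asarray(self.u_y, dtype=float)
        expected = (self.grid_y.size, self.grid_x.size)
        if self.u_x.shape != expected or self.u_y.shape != expected:
            raise MechanicsError(
                f"displacement arrays must have shape {expected}, "
                f"got {self.u_x.shape} / {self.u_y.shape}"
            )
        if self.spacing <= 0:
            raise MechanicsError("spacing must be positive")

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u_x, self.u_y)

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.u_x) & np.isfinite(self.u_y)

    def sample(self, points_um: np.ndarray) -> np.ndarray:
        """Bilinear interpolation of (u_x, u_y) at scattered points (n, 2)."""
        pts = np.asarray(points_um, dtype=float)[:, ::-1]  # (y, x) order
        out = np.empty((len(pts), 2))
        for k, comp in enumerate((self.u_x, self.u_y)):
            interp = RegularGridInterpolator(
                (self.grid_y, self.grid_x), comp, bounds_error=False, fill_value=np.nan
            )
            out[:, k] = interp(pts)
        return out


@dataclass
class StrainField:
    """Normal strains E_x = ∂u_x/∂x, E_y = ∂u_y/∂y and total E (dimensionless)."""

    E_x: np.ndarray
    E_y: np.ndarray
    E: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.E_x = np.asarray(self.E_x, dtype=float)
        self.E_y = np.asarray(self.E_y, dtype=float)
        if self.E_x.shape != self.E_y.shape:
            raise MechanicsError("strain components must be congruent")
        self.E = np.hypot(self.E_x, self.E_y)


@dataclass
class BeadSet:
    """Matched bead positions between a reference and a displaced frame (µm)."""

    positions_ref: np.ndarray
    positions_disp: np.ndarray
    match_score: np.ndarray

    def __post_init__(self) -> None:
        self.positions_ref = np.asarray(self.positions_ref, dtype=float)
        self.positions_disp = np.asarray(self.positions_disp, dtype=float)
        self.match_score = np.asarray(self.match_score, dtype=float)
        n = len(self.positions_ref)
        if len(self.positions_disp) != n or len(self.match_score) != n:
            raise MechanicsError("bead arrays must have equal length")
        if n and (self.match_score.min() < 0 or self.match_score.max() > 1 + 1e-9):
            raise MechanicsError("match scores must lie in [0, 1]")

    @property
    def displacements(self) -> np.ndarray:
        return self.positions_disp - self.positions_ref

    def __len__(self) -> int:
        return len(self.positions_ref)


def _parabolic_offset(vals: np.ndarray) -> float:
    """Sub-sample peak offset from three samples around a discrete maximum."""
    denom = vals[0] - 2.0 * vals[1] + vals[2]
    if denom >= -1e-12:  # flat or non-concave: no refinement
        return 0.0
    off = 0.5 * (vals[0] - vals[2]) / denom
    return float(np.clip(off, -0.5, 0.5))


def _localize_spot(image: np.ndarray, r: int, c: int, background: float) -> tuple[float, float]:
    """Sub-pixel spot centre by parabolic fit on log intensity.

    For a Gaussian spot the log intensity is an exact paraboloid, so a
    3-point parabolic fit along each axis recovers the centre to well below
    a tenth of a pixel once the background is removed.
    """
    H, W = image.shape
    if not (1 <= r < H - 1 and 1 <= c < W - 1):
        return float(r), float(c)
    patch = image[r - 1 : r + 2, c - 1 : c + 2] - background
    if patch[1, 1] >= patch.max() and patch.min() > 0:
        lp = np.log(patch)
        return r + _parabolic_offset(lp[:, 1]), c + _parabolic_offset(lp[1, :])
    # blended or clipped spot: fall back to an intensity-weighted centroid,
    # whose residual bias cancels between the two frames
    w = np.clip(patch, 0.0, None)
    total = w.sum()
    if total <= 0:
        return float(r), float(c)
    rr, cc = np.mgrid[-1:2, -1:2]
    return r + float((w * rr).sum() / total), c + float((w * cc).sum() / total)


def track_beads(
    reference_image: np.ndarray,
    displaced_image: np.ndarray,
    window: int = 15,
    search: int = 31,
    min_score: float = 0.5,
    pixel_size: float = 1.0,
    detection_threshold: float | None = None,
    outlier_tol: float | None = 3.0,
) -> BeadSet:
    """Match fiducial beads between a reference and a displaced frame.

    Beads are detected as local intensity maxima in the reference image and
    matched in the displaced image by normalized cross-correlation of a
    ``window``-pixel template over a ``search``-pixel region.  The integer
    correlation match is then refined to sub-pixel precision by a parabolic
    fit on the spot intensity around the matched maximum (and around the
    detected maximum in the reference frame), which stays accurate even when
    the substrate deformation varies across the template.  Matches scoring
    below ``min_score`` are discarded, as are matches whose displacement
    deviates from the median of their nearest matched neighbours by more
    than ``outlier_tol`` pixels (a neighbourhood-consistency filter that
    removes wrong correspondences in strongly deformed regions; set
    ``outlier_tol=None`` to keep every match).

    Returns positions in µm (``pixel_size`` converts from pixels).
    """
    ref = np.asarray(reference_image, dtype=float)
    disp = np.asarray(displaced_image, dtype=float)
    if ref.shape != disp.shape:
        raise MechanicsError("reference and displaced images must be congruent")
    if window % 2 == 0 or search % 2 == 0:
        raise MechanicsError("window and search sizes must be odd")
    if search <= window:
        raise MechanicsError("search region must exceed the template window")

    background = float(np.median(ref))
    if detection_threshold is None:
        detection_threshold = background + 0.3 * (np.percentile(ref, 99.9) - background)
    half_w = window // 2
    half_s = search // 2
    peaks = peak_local_max(
        ref,
        min_distance=max(2, half_w // 2),
        threshold_abs=detection_threshold,
        exclude_border=half_w,
    )
    if len(peaks) == 0:
        raise MechanicsError("no beads detected in the reference image")

    bg_disp = float(np.median(disp))

    def match_peaks(predictions: np.ndarray, half_search: int):
        """One matching pass; predictions are integer (dr, dc) per peak."""
        rows_rc, rows_pos, rows_score = [], [], []
        H, W = ref.shape
        for (r, c), (pr, pc) in zip(peaks, predictions):
            template = ref[r - half_w : r + half_w + 1, c - half_w : c + half_w + 1]
            rc, cc = r + int(pr), c + int(pc)
            half = half_w + half_search
            r0, r1 = max(0, rc - half), min(H, rc + half + 1)
            c0, c1 = max(0, cc - half), min(W, cc + half + 1)
            region = disp[r0:r1, c0:c1]
            if region.shape[0] < window or region.shape[1] < window:
                continue
            ncc = match_template(region, template, pad_input=False)
            ij = np.unravel_index(np.argmax(ncc), ncc.shape)
            score = float(ncc[ij])
            if score < min_score:
                continue
            mr, mc = r0 + ij[0] + half_w, c0 + ij[1] + half_w
            # snap to the nearest intensity maximum of the displaced spot, then
            # localize both spots to sub-pixel precision on the intensities
            if 1 <= mr < H - 1 and 1 <= mc < W - 1:
                patch = disp[mr - 1 : mr + 2, mc - 1 : mc + 2]
                dr2, dc2 = np.unravel_index(np.argmax(patch), patch.shape)
                mr, mc = mr + dr2 - 1, mc + dc2 - 1
            ref_r, ref_c = _localize_spot(ref, r, c, background)
            disp_r, disp_c = _localize_spot(disp, mr, mc, bg_disp)
            rows_rc.append((r, c))
            rows_pos.append((ref_c, ref_r, disp_c, disp_r))
            rows_score.append(min(1.0, max(0.0, score)))
        return np.asarray(rows_rc), np.asarray(rows_pos), np.asarray(rows_score)

    def consistency_filter(pos: np.ndarray, scores_arr: np.ndarray):
        if outlier_tol is None or len(pos) < 6:
            return pos, scores_arr
        from scipy.spatial import cKDTree

        p_ref, p_disp = pos[:, :2], pos[:, 2:]
        vec = p_disp - p_ref
        tree = cKDTree(p_ref)
        k = min(6, len(p_ref))  # self + up to 5 neighbours
        _, idx = tree.query(p_ref, k=k)
        neigh_median = np.median(vec[idx[:, 1:]], axis=1)
        keep = np.linalg.norm(vec - neigh_median, axis=1) <= outlier_tol
        if keep.any():
            return pos[keep], scores_arr[keep]
        return pos, scores_arr

    # pass 1: zero-prediction search over the full search window
    zero = np.zeros((len(peaks), 2), dtype=int)
    rc1, pos1, score1 = match_peaks(zero, half_s - half_w)
    if len(pos1) == 0:
        raise MechanicsError("no bead matches above min_score")
    pos1, score1 = consistency_filter(pos1, score1)

    # pass 2: re-search every detected bead around the displacement
    # predicted from first-pass inliers (predictor-corrector refinement)
    if len(pos1) >= 4:
        from scipy.interpolate import NearestNDInterpolator
        from scipy.interpolate import griddata as _griddata

        vec1 = pos1[:, 2:] - pos1[:, :2]  # (dx, dy)
        query = peaks[:, ::-1].astype(float)  # (x, y) per peak
        pred = _griddata(pos1[:, :2], vec1, query, method="linear")
        nearest = NearestNDInterpolator(pos1[:, :2], vec1)(query)
        pred = np.where(np.isfinite(pred), pred, nearest)
        pred_rc = np.round(pred[:, ::-1]).astype(int)  # back to (dr, dc)
        # the tight second-pass search is itself the consistency constraint,
        # so steep-but-real displacements are not filtered away here
        rc2, pos2, score2 = match_peaks(pred_rc, max(4, half_w // 2))
        if len(pos2):
            pos1, score1 = pos2, score2

    return BeadSet(
        positions_ref=pos1[:, :2] * pixel_size,
        positions_disp=pos1[:, 2:] * pixel_size,
        match_score=score1,
    )


def interpolate_field(beads: BeadSet, grid: GridSpec) -> DisplacementField:
    """Piecewise-linear interpolation of bead displacements onto a grid.

    Linear interpolation is exact on affine displacement fields, which gives
    a clean analytic oracle.  Grid nodes outside the convex hull of the bead
    positions are NaN.
    """
    if len(beads) < 4:
        raise MechanicsError("need at least 4 beads to interpolate a field")
    pts = beads.positions_ref
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise MechanicsError("bead positions are collinear; field is degenerate")
    X, Y = grid.mesh()
    disp = beads.displacements
    u_x = griddata(pts, disp[:, 0], (X, Y), method="linear")
    u_y = griddata(pts, disp[:, 1], (X, Y), method="linear")
    return DisplacementField(
        grid_x=grid.x, grid_y=grid.y, u_x=u_x, u_y=u_y, spacing=grid.spacing
    )


def finite_difference(values: np.ndarray, spacing: float, axis: int = -1) -> np.ndarray:
    """Derivative estimates along one axis of a sampled function.

    Interior nodes use the central 3-point stencil ``(v[i+1] - v[i-1]) / 2h``;
    the two boundary nodes use one-sided 2-point stencils ``(v[1] - v[0]) / h``
    and ``(v[n-1] - v[n-2]) / h``.
    """
    v = np.asarray(values, dtype=float)
    if v.shape[axis] < 3:
        raise MechanicsError("finite differences need at least 3 samples")
    if spacing <= 0:
        raise MechanicsError("spacing must be positive")
    return np.gradient(v, spacing, axis=axis, edge_order=1)


def displacement_to_strain(field: DisplacementField) -> StrainField:
    """Normal strain components from a gridded displacement field.

    ``E_x = ∂u_x/∂x`` and ``E_y = ∂u_y/∂y`` are evaluated with
    :func:`finite_difference` along grid rows and columns; the total strain is
    their Euclidean magnitude.  NaN (undefined) nodes propagate into the
    stencils that touch them.
    """
    ny, nx = field.u_x.shape
    if ny < 3 or nx < 3:
        raise MechanicsError("strain computation needs at least a 3x3 grid")
    E_x = finite_difference(field.u_x, field.spacing, axis=1)
    E_y = finite_difference(field.u_y, field.spacing, axis=0)
    return StrainField(E_x=E_x, E_y=E_y)


def disk_footprint(grid: GridSpec, center_um: tuple[float, float], radius_um: float) -> np.ndarray:
    """Boolean node mask of a circular cell footprint on ``grid``."""
    X, Y = grid.mesh()
    return (X - center_um[0]) ** 2 + (Y - center_um[1]) ** 2 <= radius_um**2


def summarize_field(
    field: DisplacementField,
    strain: StrainField | None = None,
    cell_footprint: np.ndarray | None = None,
) -> dict:
    """Maxima of |u| (and strain) over defined nodes, optionally in a footprint.

    Returns a dict with ``max_displacement_um``, its node location, and, when
    a strain field is given, ``max_strain`` (restricted to ``cell_footprint``
    if provided, matching how the peak strain at the cell position is read
    off a strain map).
    """
    defined = field.defined
    if cell_footprint is not None:
        if cell_footprint.shape != field.u_x.shape:
            raise MechanicsError("footprint mask must be congruent with the grid")
        restricted = defined & cell_footprint
    else:
        restricted = defined
    if not restricted.any():
        raise MechanicsError("no defined nodes in the requested footprint")

    mag = np.where(restricted, field.magnitude, -np.inf)
    i, j = np.unravel_index(np.argmax(mag), mag.shape)
    summary = {
        "max_displacement_um": float(mag[i, j]),
        "max_displacement_location_um": [float(field.grid_x[j]), float(field.grid_y[i])],
    }
    if strain is not None:
        E = np.where(np.isfinite(strain.E) & restricted, strain.E, -np.inf)
        if np.isfinite(E).any() and E.max() > -np.inf:
            k, l = np.unravel_index(np.argmax(E), E.shape)
            summary["max_strain"] = float(E[k, l])
            summary["max_strain_location_um"] = [
                float(field.grid_x[l]),
                float(field.grid_y[k]),
            ]
        else:
            raise MechanicsError("no defined strain nodes in the requested footprint")
    return summary
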