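"""Synthetic data emulating the substrate-vibration FRET experiment.

No public image data accompanies the experiment this package analyses, so
every input the pipeline consumes is generated here with known ground truth:

* a damped-sinusoid probe-tip vibration trace (the stimulus is a triggered,
  collision-driven oscillation of ~140 Hz and ~70 µm amplitude);
* an analytic substrate displacement field that rises to its maximum
  (~13–14 µm) a little beyond the probe edge (~13 µm away, where the cell
  sits) and then decays exponentially, becoming negligible at the far cell
  edge, together with fiducial-bead image pairs rendered from it;
* two-channel (ECFP donor / YPet acceptor) movies of disk-shaped cell
  phantoms whose emission ratio rises cell-wide (global), only near the
  probe (local), or stays below threshold (none);
* multinomially sampled cohorts of such movies.

All generators are bit-reproducible for a fixed seed.  Distances are µm,
times seconds, intensities detector counts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .imaging import ChannelStack
from .mechanics import BeadSet, DisplacementField, GridSpec

__all__ = [
    "EquipmentModel",
    "SubstrateFieldModel",
    "CellPhantom",
    "ResponseModel",
    "AcquisitionModel",
    "ProbeTrace",
    "ImageSpec",
    "generate_probe_trace",
    "dominant_frequency",
    "generate_displacement_field",
    "generate_bead_images",
    "generate_fret_movie",
    "draw_classes",
    "generate_cohort",
    "default_cell_phantom",
]

CLASSES = ("global", "local", "none")


class SyntheticError(ValueError):
    """Raised for invalid generator parameters."""


# --------------------------------------------------------------------------
# Probe vibration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EquipmentModel:
    """Parametric model of the probe-tip oscillation.

    The vibration is a damped sinusoid
    ``a(t) = amplitude * exp(-t / damping_time) * sin(2 pi frequency t)``;
    ``damping_time=None`` disables the decay envelope (sustained vibration).
    ``amplitude`` is the zero-to-peak tip excursion in µm.
    """

    frequency: float = 140.0
    amplitude: float = 70.0
    damping_time: float | None = None
    duration: float = 0.5
    sampling_rate: float = 10_000.0

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise SyntheticError("frequency must be positive")
        if self.amplitude < 0:
            raise SyntheticError("amplitude must be non-negative")
        if self.duration <= 0:
            raise SyntheticError("duration must be positive")
        if self.sampling_rate <= 2.0 * self.frequency:
            raise SyntheticError("sampling_rate must exceed the Nyquist rate")
        if self.damping_time is not None and self.damping_time <= 0:
            raise SyntheticError("damping_time must be positive (or None)")


@dataclass
class ProbeTrace:
    """Sampled probe-tip displacement trace."""

    time_s: np.ndarray
    displacement_um: np.ndarray

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"time_s": self.time_s, "displacement_um": self.displacement_um}
        ).to_csv(path, index=False)


def generate_probe_trace(model: EquipmentModel, seed: int = 0, jitter: float = 0.0) -> ProbeTrace:
    """Damped-sinusoid probe-tip displacement trace.

    Deterministic for fixed inputs; ``jitter`` (fraction of amplitude) adds
    optional seeded Gaussian measurement noise and is off by default.
    """
    n = int(round(model.duration * model.sampling_rate))
    t = np.arange(n) / model.sampling_rate
    a = model.amplitude * np.sin(2.0 * np.pi * model.frequency * t)
    if model.damping_time is not None:
        a = a * np.exp(-t / model.damping_time)
    if jitter > 0:
        rng = np.random.default_rng(seed)
        a = a + jitter * model.amplitude * rng.standard_normal(n)
    return ProbeTrace(time_s=t, displacement_um=a)


def dominant_frequency(trace: ProbeTrace) -> float:
    """Frequency (Hz) of the magnitude-spectrum peak of a trace."""
    x = trace.displacement_um - trace.displacement_um.mean()
    n = len(x)
    if n < 4:
        raise SyntheticError("trace too short for spectral analysis")
    dt = float(trace.time_s[1] - trace.time_s[0])
    spectrum = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(n, d=dt)
    return float(freqs[np.argmax(spectrum)])


# --------------------------------------------------------------------------
# Substrate displacement field
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SubstrateFieldModel:
    """Phenomenological in-plane substrate displacement around the probe.

    The displacement magnitude depends only on ``d``, the distance from the
    probe edge: it starts at ``edge_value * peak_displacement`` at the edge,
    rises smoothly to ``peak_displacement`` at ``d = peak_offset``, and then
    decays as ``exp(-(d - peak_offset) / decay_length)``.  The direction is a
    fixed unit vector; the default points from the probe toward the cell
    (-y), the dominant displacement direction at the cell position, which
    also reproduces the ~30-40% peak normal strain a cell experiences.
    This is a descriptive profile of the measured deformation, not a
    mechanical gel model.
    """

    probe_position: tuple[float, float] = (96.0, 196.5)
    probe_radius: float = 25.0
    peak_displacement: float = 13.5
    peak_offset: float = 13.0
    decay_length: float = 30.0
    direction: tuple[float, float] = (0.0, -1.0)
    edge_value: float = 0.5

    def __post_init__(self) -> None:
        if self.peak_displacement < 0:
            raise SyntheticError("peak_displacement must be non-negative")
        if self.decay_length <= 0 or self.peak_offset <= 0 or self.probe_radius <= 0:
            raise SyntheticError("lengths must be positive")
        if not 0.0 <= self.edge_value < 1.0:
            raise SyntheticError("edge_value must lie in [0, 1)")
        if not math.isclose(math.hypot(*self.direction), 1.0, rel_tol=1e-9):
            raise SyntheticError("direction must be a unit vector")

    # -- radial profile g(d) and its derivative ---------------------------
    def profile(self, d: np.ndarray) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        p, L, g0 = self.peak_offset, self.decay_length, self.edge_value
        rise = g0 + (1.0 - g0) * np.sin(0.5 * np.pi * np.clip(d, 0.0, p) / p) ** 2
        tail = np.exp(-np.clip(d - p, 0.0, None) / L)
        return np.where(d <= p, rise, tail)

    def profile_derivative(self, d: np.ndarray) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        p, L, g0 = self.peak_offset, self.decay_length, self.edge_value
        rise = (1.0 - g0) * (0.5 * np.pi / p) * np.sin(np.pi * np.clip(d, 0.0, p) / p)
        tail = -np.exp(-np.clip(d - p, 0.0, None) / L) / L
        out = np.where(d <= p, rise, tail)
        return np.where(d <= 0.0, 0.0, out)

    def displacement(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Closed-form u_x, u_y at coordinates (µm)."""
        d = self._edge_distance(x, y)
        mag = self.peak_displacement * self.profile(d)
        return mag * self.direction[0], mag * self.direction[1]

    def gradient(self, x: np.ndarray, y: np.ndarray) -> dict[str, np.ndarray]:
        """Closed-form spatial gradient of u (keys dux_dx, dux_dy, duy_dx, duy_dy)."""
        cx, cy = self.probe_position
        rx, ry = np.asarray(x, dtype=float) - cx, np.asarray(y, dtype=float) - cy
        rho = np.hypot(rx, ry)
        with np.errstate(invalid="ignore", divide="ignore"):
            ddx = np.where(rho > 0, rx / rho, 0.0)
            ddy = np.where(rho > 0, ry / rho, 0.0)
        dmag = self.peak_displacement * self.profile_derivative(rho - self.probe_radius)
        ex, ey = self.direction
        return {
            "dux_dx": ex * dmag * ddx,
            "dux_dy": ex * dmag * ddy,
            "duy_dx": ey * dmag * ddx,
            "duy_dy": ey * dmag * ddy,
        }

    def _edge_distance(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        cx, cy = self.probe_position
        return np.hypot(np.asarray(x, dtype=float) - cx, np.asarray(y, dtype=float) - cy) - self.probe_radius


def generate_displacement_field(
    model: SubstrateFieldModel, grid: GridSpec
) -> tuple[DisplacementField, dict[str, np.ndarray]]:
    """Sample the analytic displacement field (and its gradient) on a grid.

    Returns the gridded :class:`~vibracal.mechanics.DisplacementField` plus
    the closed-form gradient sampled at the same nodes, which serves as the
    independent oracle for the finite-difference strain computation.
    """
    if grid.spacing > model.decay_length / 2.0:
        raise SyntheticError(
            "grid spacing too coarse to resolve the decay length "
            f"({grid.spacing} > {model.decay_length / 2.0})"
        )
    X, Y = grid.mesh()
    u_x, u_y = model.displacement(X, Y)
    field = DisplacementField(
        grid_x=grid.x, grid_y=grid.y, u_x=u_x, u_y=u_y, spacing=grid.spacing
    )
    return field, model.gradient(X, Y)


# --------------------------------------------------------------------------
# Bead images
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ImageSpec:
    """Pixel raster for rendered images: (H, W) shape and µm/pixel size."""

    shape: tuple[int, int] = (96, 96)
    pixel_size: float = 2.0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise SyntheticError("pixel_size must be positive")
        if min(self.shape) < 4:
            raise SyntheticError("image must be at least 4x4 pixels")

    @property
    def extent_um(self) -> tuple[float, float]:
        return (self.shape[1] * self.pixel_size, self.shape[0] * self.pixel_size)


def _render_spots(
    positions_um: np.ndarray,
    spec: ImageSpec,
    sigma_um: float,
    amplitude: float,
    background: float,
) -> np.ndarray:
    """Render Gaussian spots at sub-pixel positions onto a background."""
    img = np.full(spec.shape, background, dtype=float)
    sigma_px = sigma_um / spec.pixel_size
    reach = max(2, int(math.ceil(4.0 * sigma_px)))
    H, W = spec.shape
    for x_um, y_um in positions_um:
        cx, cy = x_um / spec.pixel_size, y_um / spec.pixel_size
        r0, r1 = int(math.floor(cy)) - reach, int(math.floor(cy)) + reach + 1
        c0, c1 = int(math.floor(cx)) - reach, int(math.floor(cx)) + reach + 1
        r0, r1 = max(r0, 0), min(r1, H)
        c0, c1 = max(c0, 0), min(c1, W)
        if r0 >= r1 or c0 >= c1:
            continue
        rr = np.arange(r0, r1)[:, None]
        cc = np.arange(c0, c1)[None, :]
        img[r0:r1, c0:c1] += amplitude * np.exp(
            -((cc - cx) ** 2 + (rr - cy) ** 2) / (2.0 * sigma_px**2)
        )
    return img


def generate_bead_images(
    field: DisplacementField,
    bead_density: float = 0.02,
    psf_sigma: float = 1.0,
    image_spec: ImageSpec | None = None,
    seed: int = 0,
    bead_amplitude: float = 1000.0,
    background: float = 10.0,
    poisson_noise: bool = False,
) -> tuple[np.ndarray, np.ndarray, BeadSet]:
    """Render a (reference, displaced) bead image pair with known ground truth.

    Beads are placed by a seeded uniform point process (``bead_density`` in
    beads/µm²) and rendered as Gaussian spots of width ``psf_sigma`` (µm).
    In the displaced image each bead is moved by the displacement field
    evaluated at its reference position.  The returned :class:`BeadSet`
    carries the exact per-bead displacements.
    """
    if bead_density <= 0:
        raise SyntheticError("bead_density must be positive")
    spec = image_spec or ImageSpec()
    ext_x, ext_y = spec.extent_um
    mean_spacing = 1.0 / math.sqrt(bead_density)
    if mean_spacing < 4.0 * psf_sigma:
        warnings.warn(
            "bead spots denser than resolvable (mean spacing "
            f"{mean_spacing:.2f} µm < 4 psf_sigma)",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    n_beads = max(4, int(round(bead_density * ext_x * ext_y)))
    pos_ref = rng.uniform((0.0, 0.0), (ext_x, ext_y), size=(n_beads, 2))
    disp = field.sample(pos_ref)
    disp = np.nan_to_num(disp, nan=0.0)
    pos_disp = pos_ref + disp

    ref = _render_spots(pos_ref, spec, psf_sigma, bead_amplitude, background)
    moved = _render_spots(pos_disp, spec, psf_sigma, bead_amplitude, background)
    if poisson_noise:
        ref = rng.poisson(ref).astype(float)
        moved = rng.poisson(moved).astype(float)
    beads = BeadSet(
        positions_ref=pos_ref,
        positions_disp=pos_disp,
        match_score=np.ones(n_beads),
    )
    return ref, moved, beads


# --------------------------------------------------------------------------
# Cell phantoms and FRET movies
# --------------------------------------------------------------------------

@dataclass
class CellPhantom:
    """Disk-shaped cell footprint with a probe parked just beyond one edge."""

    mask: np.ndarray
    centroid: tuple[float, float]
    diameter: float = 125.0
    edge_to_probe_distance: float = 13.0

    def __post_init__(self) -> None:
        from scipy.ndimage import label

        self.mask = np.asarray(self.mask, dtype=bool)
        if self.diameter <= 0:
            raise SyntheticError("diameter must be positive")
        n_components = label(self.mask)[1]
        if n_components != 1:
            raise SyntheticError("cell mask must be a single connected component")

    def probe_position(self, probe_radius: float = 25.0) -> tuple[float, float]:
        """Probe-tip centre placed below the cell along +y (µm)."""
        cx, cy = self.centroid
        return (cx, cy + self.diameter / 2.0 + self.edge_to_probe_distance + probe_radius)


def default_cell_phantom(
    spec: ImageSpec | None = None,
    diameter: float = 125.0,
    edge_to_probe_distance: float = 13.0,
) -> CellPhantom:
    """Disk phantom centred in the default 96x96 px, 2 µm/px field of view."""
    spec = spec or ImageSpec()
    ext_x, ext_y = spec.extent_um
    centroid = (ext_x / 2.0, ext_y / 2.0)
    H, W = spec.shape
    yy, xx = np.mgrid[0:H, 0:W].astype(float) * spec.pixel_size
    mask = (xx - centroid[0]) ** 2 + (yy - centroid[1]) ** 2 <= (diameter / 2.0) ** 2
    return CellPhantom(
        mask=mask,
        centroid=centroid,
        diameter=diameter,
        edge_to_probe_distance=edge_to_probe_distance,
    )


@dataclass(frozen=True)
class ResponseModel:
    """Ground-truth calcium response of a phantom cell.

    The calcium signal is separable, ``c(x, t) = A(x) k(t)``, with spatial
    amplitude ``A(x) = peak_relative_increase * exp(-s(x) / spatial_decay)``
    (``s`` = distance from the stimulation-proximal cell edge along the
    probe axis) and a rise-then-exponential-recovery kernel ``k`` normalized
    to unit peak.  ``spatial_decay = inf`` gives a spatially uniform (global)
    response.
    """

    true_class: str
    peak_relative_increase: float
    spatial_decay: float = math.inf
    rise_time: float = 3.0
    recovery_time: float = 30.0
    stimulus_frame: int = 10

    def __post_init__(self) -> None:
        if self.true_class not in CLASSES:
            raise SyntheticError(f"true_class must be one of {CLASSES}")
        if self.peak_relative_increase < 0:
            raise SyntheticError("peak_relative_increase must be non-negative")
        if self.true_class == "none" and self.peak_relative_increase >= 0.1:
            raise SyntheticError(
                "a non-responsive phantom must have peak_relative_increase < 0.1"
            )
        if not self.rise_time < self.recovery_time:
            raise SyntheticError("rise_time must be shorter than recovery_time")
        if self.stimulus_frame < 0:
            raise SyntheticError("stimulus_frame must be non-negative")

    @classmethod
    def for_class(cls, true_class: str, stimulus_frame: int = 10) -> "ResponseModel":
        """Default response parameters per ground-truth class."""
        if true_class == "global":
            return cls("global", 0.4, math.inf, stimulus_frame=stimulus_frame)
        if true_class == "local":
            return cls("local", 0.4, 25.0, stimulus_frame=stimulus_frame)
        if true_class == "none":
            return cls("none", 0.03, math.inf, stimulus_frame=stimulus_frame)
        raise SyntheticError(f"true_class must be one of {CLASSES}")

    def kinetic_kernel(self, t_after_stimulus: np.ndarray) -> np.ndarray:
        """Unit-peak rise/recovery kernel evaluated at times >= 0 (s)."""
        t = np.clip(np.asarray(t_after_stimulus, dtype=float), 0.0, None)
        tr, tc = self.rise_time, self.recovery_time
        raw = (1.0 - np.exp(-t / tr)) * np.exp(-t / tc)
        t_peak = tr * math.log1p(tc / tr)
        peak = (1.0 - math.exp(-t_peak / tr)) * math.exp(-t_peak / tc)
        return raw / peak


@dataclass(frozen=True)
class AcquisitionModel:
    """Camera/optics model for rendering the two channels.

    The donor (ECFP) channel falls and the acceptor (YPet) channel rises with
    calcium: ``donor = donor_gain / (1 + c)``,
    ``acceptor = acceptor_gain * baseline_ratio * (1 + c)``, so the
    region-mean YPet/ECFP ratio tracks ``baseline_ratio * (1 + c)**2`` (for
    equal gains).  ``shot_noise`` scales the Poisson variance: counts are
    drawn as ``shot_noise * Poisson(mean / shot_noise)``; 0 disables noise.
    """

    frame_interval: float = 2.0
    pixel_size: float = 2.0
    background_level: float = 100.0
    shot_noise: float = 1.0
    donor_gain: float = 800.0
    acceptor_gain: float = 800.0
    baseline_ratio: float = 2.0

    def __post_init__(self) -> None:
        if min(self.frame_interval, self.pixel_size, self.donor_gain,
               self.acceptor_gain, self.baseline_ratio) <= 0:
            raise SyntheticError("acquisition parameters must be strictly positive")
        if self.background_level < 0 or self.shot_noise < 0:
            raise SyntheticError("background_level and shot_noise must be >= 0")

    def apply_noise(self, mean_counts: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.shot_noise == 0:
            return mean_counts
        s = self.shot_noise
        return s * rng.poisson(mean_counts / s).astype(float)


def generate_fret_movie(
    cell: CellPhantom,
    resp: ResponseModel,
    acq: AcquisitionModel,
    n_frames: int = 30,
    seed: int = 0,
    probe_position: tuple[float, float] | None = None,
) -> tuple[ChannelStack, dict]:
    """Render a two-channel movie of one phantom cell.

    Returns the :class:`~vibracal.imaging.ChannelStack` and a ground-truth
    dict (true class, probe position, realized peak ratio increase in the
    closest band).  Pixels outside the cell mask carry background only.
    """
    if resp.stimulus_frame >= n_frames:
        raise SyntheticError("stimulus_frame must precede the end of the movie")
    probe = probe_position or cell.probe_position()
    rows, cols = np.nonzero(cell.mask)
    xy = np.column_stack((cols, rows)).astype(float) * acq.pixel_size
    axis = np.asarray(cell.centroid) - np.asarray(probe)
    axis = axis / np.linalg.norm(axis)
    proj = xy @ axis
    s = proj - proj.min()  # distance from the stimulation-proximal edge

    if math.isinf(resp.spatial_decay):
        A = np.full(s.shape, resp.peak_relative_increase)
    else:
        A = resp.peak_relative_increase * np.exp(-s / resp.spatial_decay)

    t = np.arange(n_frames) * acq.frame_interval
    k = np.zeros(n_frames)
    post = np.arange(resp.stimulus_frame, n_frames)
    k[post] = resp.kinetic_kernel(t[post] - t[resp.stimulus_frame])

    rng = np.random.default_rng(seed)
    H, W = cell.mask.shape
    donor = np.full((n_frames, H, W), acq.background_level, dtype=float)
    acceptor = np.full((n_frames, H, W), acq.background_level, dtype=float)
    c = A[None, :] * k[:, None]  # (T, n_cell_pixels)
    donor[:, rows, cols] += acq.donor_gain / (1.0 + c)
    acceptor[:, rows, cols] += acq.acceptor_gain * acq.baseline_ratio * (1.0 + c)
    donor = acq.apply_noise(donor, rng)
    acceptor = acq.apply_noise(acceptor, rng)

    stack = ChannelStack(
        donor=donor,
        acceptor=acceptor,
        pixel_size=acq.pixel_size,
        frame_interval=acq.frame_interval,
        stimulus_frame=resp.stimulus_frame,
    )
    gain_ratio = acq.acceptor_gain / acq.donor_gain
    truth = {
        "true_class": resp.true_class,
        "probe_position_um": [float(probe[0]), float(probe[1])],
        "baseline_ratio": acq.baseline_ratio * gain_ratio,
        "peak_relative_increase": resp.peak_relative_increase,
        "peak_ratio_increase": (1.0 + resp.peak_relative_increase) ** 2 - 1.0,
        "stimulus_frame": resp.stimulus_frame,
    }
    return stack, truth


# --------------------------------------------------------------------------
# Cohorts
# --------------------------------------------------------------------------

def draw_classes(
    p: tuple[float, float, float], n_cells: int, seed: int = 0
) -> list[str]:
    """Seeded multinomial draw of response classes (order: global, local, none)."""
    probs = np.asarray(p, dtype=float)
    if probs.min() < 0:
        raise SyntheticError("class probabilities must be non-negative")
    if abs(probs.sum() - 1.0) > 1e-9:
        raise SyntheticError("class probabilities must sum to 1")
    if n_cells < 1:
        raise SyntheticError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(CLASSES), size=n_cells, p=probs)
    return [CLASSES[i] for i in idx]


def generate_cohort(
    p: tuple[float, float, float],
    n_cells: int,
    acq: AcquisitionModel | None = None,
    cell: CellPhantom | None = None,
    templates: dict[str, ResponseModel] | None = None,
    n_frames: int = 30,
    seed: int = 0,
):
    """Yield ``(stack, truth)`` pairs for a multinomially sampled cohort.

    Classes are drawn first with the cohort seed; each movie then uses an
    independent child seed, so the cohort is reproducible end to end.
    Movies are yielded lazily to keep memory flat for large cohorts.
    """
    classes = draw_classes(p, n_cells, seed)
    acq = acq or AcquisitionModel()
    cell = cell or default_cell_phantom(ImageSpec(pixel_size=acq.pixel_size))
    templates = templates or {c: ResponseModel.for_class(c) for c in CLASSES}
    children = np.random.SeedSequence(seed).spawn(n_cells)
    for i, cls in enumerate(classes):
        child_seed = int(children[i].generate_state(1)[0] % (2**31))
        stack, truth = generate_fret_movie(
            cell, templates[cls], acq, n_frames=n_frames, seed=child_seed
        )
        truth["cell_id"] = i
        truth["seed"] = child_seed
        yield stack, truth
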