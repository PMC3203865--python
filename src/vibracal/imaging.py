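"""Two-channel ratiometric image processing and the three-band cell partition.

A calcium biosensor built on the ECFP/YPet FRET pair reports intracellular
calcium as the acceptor/donor (YPet/ECFP) emission ratio: calcium binding
raises FRET efficiency, so the acceptor emission rises while the donor
emission falls.  The analysis pipeline is: subtract a background estimated
from a cell-free region, form YPet/ECFP ratios, split the cell mask into
three bands of equal extent ordered by distance from the stimulating probe
(closer / middle / farther), and average the ratio per band per frame.

Two ratio definitions are provided.  Pixel-wise ratio maps
(:func:`compute_ratio_map`) are for display and spatial inspection.  The
response classifier consumes region ratios computed as the ratio of the mean
channel intensities over a band (:func:`extract_region_timecourses_intensity`),
i.e. mean(YPet)/mean(ECFP), which is robust to dim pixels.

Coordinates: 0-based row/column indices, origin at the top-left pixel;
physical positions in µm are ``(col * pixel_size, row * pixel_size)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ChannelStack",
    "BackgroundROI",
    "RegionPartition",
    "RatioTimeCourseSet",
    "subtract_background",
    "compute_ratio_map",
    "partition_regions",
    "extract_region_timecourses",
    "extract_region_timecourses_intensity",
    "auto_background_roi",
]

REGIONS = ("closer", "middle", "farther")


class ImagingError(ValueError):
    """Raised for malformed stacks, masks, or empty results."""


@dataclass
class ChannelStack:
    """Time-indexed two-channel fluorescence stack (donor ECFP, acceptor YPet).

    Arrays are (T, H, W) in detector counts; ``pixel_size`` is µm/pixel,
    ``frame_interval`` seconds, and ``stimulus_frame`` the first frame after
    the mechanical stimulation was triggered.
    """

    donor: np.ndarray
    acceptor: np.ndarray
    pixel_size: float
    frame_interval: float
    stimulus_frame: int

    def __post_init__(self) -> None:
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if self.donor.ndim != 3 or self.donor.shape != self.acceptor.shape:
            raise ImagingError("donor and acceptor must be congruent (T, H, W) stacks")
        if self.donor.min() < 0 or self.acceptor.min() < 0:
            raise ImagingError("intensities must be non-negative")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ImagingError("pixel_size and frame_interval must be positive")
        if not (0 <= self.stimulus_frame < self.n_frames):
            raise ImagingError("stimulus_frame must lie within the stack")

    @property
    def n_frames(self) -> int:
        return self.donor.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.donor.shape[1:]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def save(self, directory: str | Path, prefix: str = "stack") -> dict:
        """Write one multi-page TIFF per channel plus a JSON metadata sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "donor": directory / f"{prefix}_donor.tif",
            "acceptor": directory / f"{prefix}_acceptor.tif",
            "meta": directory / f"{prefix}_meta.json",
        }
        tifffile.imwrite(paths["donor"], np.round(self.donor).astype(np.uint16))
        tifffile.imwrite(paths["acceptor"], np.round(self.acceptor).astype(np.uint16))
        meta = {
            "pixel_size_um": self.pixel_size,
            "frame_interval_s": self.frame_interval,
            "stimulus_frame": self.stimulus_frame,
        }
        paths["meta"].write_text(json.dumps(meta, indent=2))
        return {k: str(v) for k, v in paths.items()}

    @classmethod
    def load(cls, donor_path: str | Path, acceptor_path: str | Path, meta_path: str | Path) -> "ChannelStack":
        meta = json.loads(Path(meta_path).read_text())
        return cls(
            donor=tifffile.imread(donor_path),
            acceptor=tifffile.imread(acceptor_path),
            pixel_size=meta["pixel_size_um"],
            frame_interval=meta["frame_interval_s"],
            stimulus_frame=meta["stimulus_frame"],
        )


@dataclass
class BackgroundROI:
    """Cell-free image region used to estimate the background signal."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ImagingError("background ROI is empty")

    def check_disjoint(self, cell_mask: np.ndarray) -> None:
        if (self.mask & np.asarray(cell_mask, dtype=bool)).any():
            raise ImagingError("background ROI overlaps the cell mask")


@dataclass
class RegionPartition:
    """Cell mask split into three bands ordered by distance from the probe.

    The bands are slabs of equal extent along ``axis``, the unit vector from
    the probe toward the cell centroid; ``closer`` is nearest the probe.
    """

    closer: np.ndarray
    middle: np.ndarray
    farther: np.ndarray
    axis: np.ndarray

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        for name in REGIONS:
            setattr(self, name, np.asarray(getattr(self, name), dtype=bool))
        if not np.isclose(np.linalg.norm(self.axis), 1.0):
            raise ImagingError("axis must be a unit vector")
        if (self.closer & self.middle).any() or (self.closer & self.farther).any() or (
            self.middle & self.farther
        ).any():
            raise ImagingError("region masks must be pairwise disjoint")

    @property
    def cell_mask(self) -> np.ndarray:
        return self.closer | self.middle | self.farther

    def masks(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in REGIONS}


@dataclass
class RatioTimeCourseSet:
    """Per-region mean YPet/ECFP ratio per frame."""

    t: np.ndarray
    r_closer: np.ndarray
    r_middle: np.ndarray
    r_farther: np.ndarray
    n_pixels: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        for name in REGIONS:
            attr = f"r_{name}"
            setattr(self, attr, np.asarray(getattr(self, attr), dtype=float))
            if getattr(self, attr).shape != self.t.shape:
                raise ImagingError("time courses must match the time axis length")

    def region(self, name: str) -> np.ndarray:
        if name not in REGIONS:
            raise KeyError(name)
        return getattr(self, f"r_{name}")

    def to_frame(self) -> pd.DataFrame:
        data = {"frame": np.arange(len(self.t)), "time_s": self.t}
        for name in REGIONS:
            data[f"r_{name}"] = self.region(name)
        if self.n_pixels is not None:
            for name in REGIONS:
                data[f"n_pixels_{name}"] = self.n_pixels[name]
        return pd.DataFrame(data)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def subtract_background(
    stack: ChannelStack,
    roi: BackgroundROI,
    cell_mask: np.ndarray | None = None,
) -> ChannelStack:
    """Subtract the per-frame mean ROI intensity from every pixel of each channel.

    Negative results are clipped at zero, which keeps downstream ratios
    stable when the background estimate slightly exceeds a dim pixel.
    """
    if cell_mask is not None:
        roi.check_disjoint(cell_mask)
    out = {}
    for name in ("donor", "acceptor"):
        channel = getattr(stack, name)
        bg = channel[:, roi.mask].mean(axis=1)
        out[name] = np.clip(channel - bg[:, None, None], 0.0, None)
    return replace(stack, donor=out["donor"], acceptor=out["acceptor"])


def compute_ratio_map(
    stack: ChannelStack,
    cell_mask: np.ndarray,
    donor_floor: float = 1.0,
) -> np.ndarray:
    """Pixel-wise YPet/ECFP ratio inside the cell mask; NaN where undefined.

    Pixels with donor intensity at or below ``donor_floor`` are flagged
    undefined rather than divided, so background-subtracted zeros never
    produce infinities.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if cell_mask.shape != stack.frame_shape:
        raise ImagingError("cell mask must be congruent with the stack frames")
    defined = cell_mask[None, :, :] & (stack.donor > donor_floor)
    if not defined.any():
        raise ImagingError("entire cell mask is below the donor floor")
    ratio = np.full(stack.donor.shape, np.nan)
    np.divide(stack.acceptor, stack.donor, out=ratio, where=defined)
    return ratio


def partition_regions(
    cell_mask: np.ndarray,
    probe_position: tuple[float, float],
    pixel_size: float,
) -> RegionPartition:
    """Split a cell mask into three equal-extent bands along the probe axis.

    Each mask pixel is projected onto the unit vector from the probe position
    (µm, x/y) toward the mask centroid; the projected extent is cut into three
    equal intervals and pixels assigned by interval.  A pixel landing exactly
    on a cut goes to the band nearer the probe.  This recovers the vertical
    three-band split when the probe sits directly below the cell, and remains
    well defined for arbitrary probe placement.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if pixel_size <= 0:
        raise ImagingError("pixel_size must be positive")
    rows, cols = np.nonzero(cell_mask)
    if rows.size == 0:
        raise ImagingError("cell mask is empty")
    xy = np.column_stack((cols, rows)).astype(float) * pixel_size
    centroid = xy.mean(axis=0)
    probe = np.asarray(probe_position, dtype=float)

    pr, pc = int(round(probe[1] / pixel_size)), int(round(probe[0] / pixel_size))
    if 0 <= pr < cell_mask.shape[0] and 0 <= pc < cell_mask.shape[1] and cell_mask[pr, pc]:
        raise ImagingError("probe position lies inside the cell mask")

    axis = centroid - probe
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ImagingError("probe coincides with the cell centroid")
    axis = axis / norm

    proj = xy @ axis
    pmin, pmax = proj.min(), proj.max()
    if pmax - pmin < 3 * pixel_size:
        raise ImagingError("cell mask extent along the probe axis is degenerate (<3 px)")
    width = (pmax - pmin) / 3.0
    c1, c2 = pmin + width, pmin + 2.0 * width

    masks = {name: np.zeros_like(cell_mask) for name in REGIONS}
    band = np.where(proj <= c1, 0, np.where(proj <= c2, 1, 2))
    for k, name in enumerate(REGIONS):
        sel = band == k
        masks[name][rows[sel], cols[sel]] = True
    return RegionPartition(axis=axis, **masks)


def _timecourse_from_means(
    t: np.ndarray, means: dict[str, np.ndarray], n_pixels: dict[str, np.ndarray]
) -> RatioTimeCourseSet:
    return RatioTimeCourseSet(
        t=t,
        r_closer=means["closer"],
        r_middle=means["middle"],
        r_farther=means["farther"],
        n_pixels=n_pixels,
    )


def extract_region_timecourses(
    ratio_map: np.ndarray,
    part: RegionPartition,
    frame_interval: float = 1.0,
) -> RatioTimeCourseSet:
    """Per-frame mean of defined ratio pixels within each band (mean-of-ratios)."""
    ratio_map = np.asarray(ratio_map, dtype=float)
    if ratio_map.ndim != 3 or ratio_map.shape[1:] != part.cell_mask.shape:
        raise ImagingError("ratio map must be (T, H, W) and congruent with the partition")
    T = ratio_map.shape[0]
    means: dict[str, np.ndarray] = {}
    counts: dict[str, np.ndarray] = {}
    for name, mask in part.masks().items():
        vals = ratio_map[:, mask]  # (T, n_region)
        defined = np.isfinite(vals)
        n = defined.sum(axis=1)
        for frame in np.nonzero(n == 0)[0]:
            raise ImagingError(
                f"region '{name}' has no defined ratio pixels in frame {frame}"
            )
        means[name] = np.nansum(np.where(defined, vals, 0.0), axis=1) / n
        counts[name] = n
    t = np.arange(T) * frame_interval
    return _timecourse_from_means(t, means, counts)


def extract_region_timecourses_intensity(
    stack: ChannelStack,
    part: RegionPartition,
    donor_floor: float = 1.0,
) -> RatioTimeCourseSet:
    """Per-frame region ratio as mean(YPet)/mean(ECFP) over each band.

    This is the ratio definition the response classifier consumes: the mean
    acceptor intensity of a band divided by its mean donor intensity.
    """
    if stack.frame_shape != part.cell_mask.shape:
        raise ImagingError("stack frames must be congruent with the partition")
    means: dict[str, np.ndarray] = {}
    counts: dict[str, np.ndarray] = {}
    for name, mask in part.masks().items():
        donor_mean = stack.donor[:, mask].mean(axis=1)
        acceptor_mean = stack.acceptor[:, mask].mean(axis=1)
        low = np.nonzero(donor_mean <= donor_floor)[0]
        if low.size:
            raise ImagingError(
                f"region '{name}' mean donor intensity at/below the floor in frame {low[0]}"
            )
        means[name] = acceptor_mean / donor_mean
        counts[name] = np.full(stack.n_frames, int(mask.sum()))
    return _timecourse_from_means(stack.times, means, counts)


def auto_background_roi(
    cell_mask: np.ndarray,
    probe_position: tuple[float, float],
    pixel_size: float,
    margin_um: float = 10.0,
    quantile: float = 0.25,
) -> BackgroundROI:
    """Pick a background region not covered by the cell and away from the probe.

    Candidate pixels lie at least ``margin_um`` from the cell mask; of those,
    the quartile farthest from the probe tip is used.
    """
    from scipy.ndimage import distance_transform_edt

    cell_mask = np.asarray(cell_mask, dtype=bool)
    dist_to_cell = distance_transform_edt(~cell_mask) * pixel_size
    candidates = dist_to_cell >= margin_um
    if not candidates.any():
        raise ImagingError("no background pixels available outside the cell margin")
    rr, cc = np.nonzero(candidates)
    xy = np.column_stack((cc, rr)).astype(float) * pixel_size
    d_probe = np.linalg.norm(xy - np.asarray(probe_position, dtype=float), axis=1)
    cutoff = np.quantile(d_probe, 1.0 - quantile)
    sel = d_probe >= cutoff
    roi = np.zeros_like(cell_mask)
    roi[rr[sel], cc[sel]] = True
    return BackgroundROI(mask=roi)
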