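"""Per-cell response quantification and global/local/none classification.

From the three-band ratio time courses, each cell gets a per-band baseline
(pre-stimulus mean), a per-band stimulated increase (baseline-normalized
peak within a post-stimulus window), and a class:

* **none** — no band's relative increase exceeds ``threshold_none``
  (default 10% of the basal level);
* **global** — the increase in the band farthest from the probe is at least
  ``global_fraction`` (default half) of that in the closest band;
* **local** — otherwise (the rise is confined near the stimulation site).

The none-rule is applied first: a cell with no band above threshold has no
response to localize.  Ties at exactly half resolve to global ("at least
half").  All comparisons use relative (fractional) increases, matching the
relative 10% criterion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .imaging import (
    REGIONS,
    BackgroundROI,
    ChannelStack,
    ImagingError,
    RatioTimeCourseSet,
    auto_background_roi,
    extract_region_timecourses_intensity,
    partition_regions,
    subtract_background,
)

__all__ = [
    "AnalysisConfig",
    "ResponseRecord",
    "compute_baseline",
    "compute_stimulated_increase",
    "classify_response",
    "run_cell",
]


class ResponseError(ValueError):
    """Raised for invalid time courses or classifier inputs."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable thresholds and windows of the per-cell pipeline.

    ``threshold_none`` and ``global_fraction`` are the published criterion
    values (10% of baseline; half of the closest-band increase).  The
    post-stimulus window over which the peak increase is taken defaults to
    60 s — the transient peaks well within a minute of stimulation.
    """

    threshold_none: float = 0.10
    global_fraction: float = 0.5
    window_s: float = 60.0
    donor_floor: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold_none < 1.0:
            raise ResponseError("threshold_none must lie in (0, 1)")
        if not 0.0 < self.global_fraction < 1.0:
            raise ResponseError("global_fraction must lie in (0, 1)")
        if self.window_s <= 0:
            raise ResponseError("window_s must be positive")


@dataclass
class ResponseRecord:
    """Per-cell baselines, stimulated increases, and the assigned class."""

    baselines: dict[str, float]
    deltas: dict[str, float]
    cls: str
    peak_frame: int
    rule: str = ""
    timecourses: RatioTimeCourseSet | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        out = {
            "class": self.cls,
            "peak_frame": self.peak_frame,
            "rule": self.rule,
        }
        for name in REGIONS:
            out[f"baseline_{name}"] = self.baselines[name]
            out[f"delta_{name}"] = self.deltas[name]
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def compute_baseline(tc: RatioTimeCourseSet, stimulus_frame: int) -> dict[str, float]:
    """Mean pre-stimulus ratio per band over frames [0, stimulus_frame)."""
    if stimulus_frame < 3:
        raise ResponseError(
            f"need at least 3 pre-stimulus frames, got {stimulus_frame}"
        )
    out = {}
    for name in REGIONS:
        baseline = float(tc.region(name)[:stimulus_frame].mean())
        if baseline <= 0:
            raise ResponseError(f"non-positive baseline in region '{name}'")
        out[name] = baseline
    return out


def compute_stimulated_increase(
    tc: RatioTimeCourseSet,
    baselines: dict[str, float],
    stimulus_frame: int,
    window: int,
) -> tuple[dict[str, float], dict[str, int]]:
    """Baseline-normalized peak ratio increase per band after stimulation.

    ``delta = (max ratio in [stimulus_frame, stimulus_frame + window] -
    baseline) / baseline``; the peak frame is taken per band.  ``window`` is
    in frames and is clipped at the end of the record.
    """
    n = len(tc.t)
    if window < 1:
        raise ResponseError("post-stimulus window must contain at least 1 frame")
    if stimulus_frame >= n:
        raise ResponseError("stimulus frame beyond the end of the record")
    stop = min(n, stimulus_frame + window + 1)
    deltas: dict[str, float] = {}
    peak_frames: dict[str, int] = {}
    for name in REGIONS:
        post = tc.region(name)[stimulus_frame:stop]
        i = int(np.argmax(post))
        deltas[name] = float((post[i] - baselines[name]) / baselines[name])
        peak_frames[name] = stimulus_frame + i
    return deltas, peak_frames


def classify_response(
    deltas: dict[str, float],
    threshold_none: float = 0.10,
    global_fraction: float = 0.5,
) -> tuple[str, str]:
    """Apply the global/local/none criterion to per-band relative increases.

    Rule order: (1) if no band's increase exceeds ``threshold_none``, the
    cell is non-responsive; (2) else if the farther-band increase is at least
    ``global_fraction`` of the closer-band increase, the response is global
    (exact equality counts as global); (3) otherwise it is local.

    Returns ``(class, rationale)`` where the rationale spells out the rule
    that fired with its operands.
    """
    values = [deltas[name] for name in REGIONS]
    if not all(np.isfinite(values)):
        raise ResponseError("deltas must be finite")
    d_closer, d_farther = deltas["closer"], deltas["farther"]
    if max(values) <= threshold_none:
        return "none", (
            f"max delta {max(values):.4f} <= threshold {threshold_none:.2f}"
        )
    if d_farther >= global_fraction * d_closer:
        return "global", (
            f"delta_farther {d_farther:.4f} >= {global_fraction:.2f} * "
            f"delta_closer {d_closer:.4f}"
        )
    return "local", (
        f"delta_farther {d_farther:.4f} < {global_fraction:.2f} * "
        f"delta_closer {d_closer:.4f}"
    )


def run_cell(
    stack: ChannelStack,
    cell_mask: np.ndarray,
    probe_position: tuple[float, float],
    config: AnalysisConfig | None = None,
    background_roi: BackgroundROI | None = None,
) -> ResponseRecord:
    """Full per-cell pipeline from raw stack to classified response.

    Stages: background subtraction -> three-band partition -> region-mean
    ratio time courses -> baseline -> stimulated increases -> class.  Any
    stage failure is re-raised annotated with the stage name.
    """
    config = config or AnalysisConfig()
    stage = "background"
    try:
        roi = background_roi or auto_background_roi(
            cell_mask, probe_position, stack.pixel_size
        )
        corrected = subtract_background(stack, roi, cell_mask=cell_mask)
        stage = "partition"
        part = partition_regions(cell_mask, probe_position, stack.pixel_size)
        stage = "timecourses"
        tc = extract_region_timecourses_intensity(
            corrected, part, donor_floor=config.donor_floor
        )
        stage = "baseline"
        baselines = compute_baseline(tc, stack.stimulus_frame)
        stage = "stimulated increase"
        window = max(1, int(round(config.window_s / stack.frame_interval)))
        deltas, peak_frames = compute_stimulated_increase(
            tc, baselines, stack.stimulus_frame, window
        )
        stage = "classification"
        cls, rule = classify_response(
            deltas, config.threshold_none, config.global_fraction
        )
    except (ImagingError, ResponseError) as exc:
        raise type(exc)(f"[{stage}] {exc}") from exc
    return ResponseRecord(
        baselines=baselines,
        deltas=deltas,
        cls=cls,
        peak_frame=peak_frames["closer"],
        rule=rule,
        timecourses=tc,
    )
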