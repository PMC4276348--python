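"""End-to-end detection pipeline and its configuration.

Stages: brain-window display mapping -> cubic contrast enhancement ->
brain extraction -> gradient-weighted smoothing -> URGA segmentation +
eight-region partition -> coinciding-regional-location lateralization ->
HU-window / darkest-fraction highlighting.  Region brightness statistics are
taken on the smoothed enhanced image; the highlighting stage always goes
back to the original calibrated HU values.  The pipeline is deterministic:
identical input and configuration give byte-identical reports.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import yaml

from . import brain_extraction, enhancement, highlighting, io_formats
from . import lateralization, partitioning, urga_segmentation
from .errors import CTStrokeError, ParameterError, PipelineStageError
from .io_formats import CTSlice

#: below this spread (display units) between hemisphere means, the reported
#: side is accompanied by a low-asymmetry warning
LOW_ASYMMETRY_SPAN = 0.1


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with its default."""

    window_center: float = io_formats.DEFAULT_WINDOW_CENTER
    window_width: float = io_formats.DEFAULT_WINDOW_WIDTH
    inflection_factor: float = enhancement.DEFAULT_INFLECTION_FACTOR
    aniso_k: float | None = None            # None -> mean gradient magnitude
    erosion_radius: int = 3
    dilation_radius: int = 3
    canny_sigma: float = 1.0
    canny_low: float | None = None          # None -> gradient-Otsu rule
    canny_high: float | None = None
    hist_radius: int = urga_segmentation.DEFAULT_HIST_RADIUS
    hist_smooth_width: int = urga_segmentation.DEFAULT_SMOOTH_WIDTH
    grow_tolerance: float = urga_segmentation.DEFAULT_GROW_TOLERANCE
    running_mean: bool = False
    csf_hu_ceiling: float = 15.0            # HU; seeds below it are excluded
    inner_axis_ratio: float = partitioning.INNER_AXIS_RATIO
    scale_minor_only: bool = False
    extract_on: str = "display"             # or "enhanced"
    delta: float = lateralization.DEFAULT_DELTA
    hu_lo: float = highlighting.DEFAULT_HU_LO
    hu_hi: float = highlighting.DEFAULT_HU_HI
    dark_fraction: float = highlighting.DEFAULT_DARK_FRACTION
    min_component_px: int = highlighting.DEFAULT_MIN_COMPONENT_PX
    fraction_scope: str = "brain"
    seed: int = 0

    def validate(self) -> None:
        if self.window_width <= 0:
            raise ParameterError("window_width must be positive")
        if not (0 < self.inflection_factor < 1):
            raise ParameterError("inflection_factor must lie in (0, 1)")
        if self.hu_lo > self.hu_hi:
            raise ParameterError("hu_lo must not exceed hu_hi")
        if not (0 < self.dark_fraction < 1):
            raise ParameterError("dark_fraction must lie in (0, 1)")
        if self.delta < 0 or self.grow_tolerance <= 0:
            raise ParameterError("delta must be >= 0 and grow_tolerance > 0")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg


@dataclass
class PipelineResult:
    """Overlay, JSON-serialisable report and per-stage intermediates."""

    overlay: np.ndarray
    report: dict
    intermediates: dict = field(default_factory=dict)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except CTStrokeError as exc:
                if isinstance(exc, PipelineStageError):
                    raise
                raise PipelineStageError(name, str(exc)) from exc
        return wrapped
    return deco


def run_pipeline(ct: CTSlice | str, config: PipelineConfig | None = None,
                 keep_intermediates: bool = False) -> PipelineResult:
    """Run the full detection pipeline on a slice (or a path to one)."""
    config = config or PipelineConfig()
    config.validate()
    if not isinstance(ct, CTSlice):
        ct = _stage("read")(io_formats.read_ct)(ct)
    warnings_seen: list[str] = []

    display = _stage("window")(io_formats.to_display)(
        ct, config.window_center, config.window_width)

    def _enhance():
        A = enhancement.compute_inflection(display, config.inflection_factor)
        if not (0.0 < A < 255.0):
            A = 127.5
        curve = enhancement.fit_cubic(A)
        return enhancement.apply_curve(display, curve), curve
    enhanced, curve = _stage("enhancement")(_enhance)()

    if config.extract_on not in ("display", "enhanced"):
        raise ParameterError("extract_on must be 'display' or 'enhanced'")
    # the cubic curve compresses bright tissue toward the top of the scale,
    # which can collapse the tissue/bone separation; extraction therefore
    # defaults to the plain windowed image
    extraction_input = display if config.extract_on == "display" else enhanced
    mask = _stage("brain_extraction")(brain_extraction.extract_brain)(
        extraction_input, config.erosion_radius, config.dilation_radius)
    smoothed = _stage("smoothing")(brain_extraction.anisotropic_smooth)(
        enhanced, config.aniso_k)

    # the CSF seeding ceiling lives in HU; carry it through window + curve
    csf_display = io_formats.hu_to_display_value(
        config.csf_hu_ceiling, config.window_center, config.window_width)
    csf_ceiling = float(np.clip(curve(csf_display), 0.0, 255.0))

    def _segment():
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            labels = urga_segmentation.urga(
                smoothed, mask,
                canny_low=config.canny_low, canny_high=config.canny_high,
                canny_sigma=config.canny_sigma, hist_radius=config.hist_radius,
                smooth_width=config.hist_smooth_width,
                tolerance=config.grow_tolerance,
                min_seed_intensity=csf_ceiling,
                running_mean=config.running_mean)
        warnings_seen.extend(str(w.message) for w in caught)
        return labels
    labels = _stage("segmentation")(_segment)()

    def _partition():
        rect = partitioning.bounding_rectangle(mask)
        parts = partitioning.partition_eight(
            mask, rect, axis_ratio=config.inner_axis_ratio,
            scale_minor_only=config.scale_minor_only)
        return rect, parts
    rect, parts = _stage("partition")(_partition)()

    def _lateralize():
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            stats = lateralization.region_means(smoothed, parts)
            result = lateralization.coincide(stats, delta=config.delta)
        warnings_seen.extend(str(w.message) for w in caught)
        return stats, result
    stats, lat = _stage("lateralization")(_lateralize)()

    left_mean = np.mean([stats[k] for k in stats
                         if k[0] == "left" and stats[k] is not None])
    right_mean = np.mean([stats[k] for k in stats
                          if k[0] == "right" and stats[k] is not None])
    if abs(left_mean - right_mean) < LOW_ASYMMETRY_SPAN:
        warnings_seen.append(
            f"low hemispheric asymmetry ({abs(left_mean - right_mean):.3f} "
            f"display units); the reported side may not be meaningful")

    stroke = _stage("highlighting")(highlighting.build_stroke_mask)(
        ct, parts, lat.side, hu_lo=config.hu_lo, hu_hi=config.hu_hi,
        fraction=config.dark_fraction,
        min_component_px=config.min_component_px,
        fraction_scope=config.fraction_scope)
    overlay = highlighting.render_overlay(display, stroke)

    report = {
        "side": lat.side,
        "case_id": lat.case_id,
        "selected_regions": [list(k) for k in lat.selected_regions],
        "trace": list(lat.trace),
        "region_means": {"-".join(k): stats[k] for k in partitioning.REGION_KEYS},
        "inflection": curve.inflection,
        "curve": {"a": curve.a, "b": curve.b, "c": curve.c},
        "n_regions": int(labels.max()),
        "brain_pixels": int(mask.sum()),
        "marked_pixels": stroke.area_px,
        "marked_area_mm2": stroke.area_mm2(ct.spacing_mm),
        "hu_cut": stroke.hu_cut,
        "warnings": warnings_seen,
    }
    intermediates = {}
    if keep_intermediates:
        intermediates = {
            "display": display, "enhanced": enhanced, "smoothed": smoothed,
            "mask": mask, "labels": labels, "rect": rect, "parts": parts,
            "stroke_mask": stroke.mask,
        }
    return PipelineResult(overlay=overlay, report=report,
                          intermediates=intermediates)


def run_metrics(records_path, positive: str) -> "dict":
    """Accumulate a records CSV into the five confusion metrics."""
    from . import metrics as m
    records = m.read_side_records(records_path)
    counts = m.counts_from_records(records, positive=positive)
    report = m.confusion_metrics(counts)
    out = report.to_dict()
    out.update({"TPN": counts.tpn, "FPN": counts.fpn,
                "TNN": counts.tnn, "FNN": counts.fnn})
    return out
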