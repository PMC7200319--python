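"""Orchestration: read → despike → average → background subtract → top-hat.

The stage order is fixed by the method, not configurable: cosmic-ray
spikes must be repaired before the frames are averaged (else a spike
survives averaging as a spurious peak), the fluorescence polynomial is
subtracted from the averaged spectrum, and the morphological top-hat runs
last on the background-subtracted spectrum. Individual stages can be
switched off, but a configuration that asks for a different ordering is
rejected rather than silently reordered.

Failure policy is fail-fast: any stage error propagates as a
:class:`~ramanclean.errors.StageError` naming the stage, and no partial
output files are written.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import baseline as _baseline
from . import despike as _despike
from . import morphology as _morphology
from .errors import ContractError, StageError
from .io import Dialect, FrameStack, Spectrum, read_frames, write_spectrum

__all__ = [
    "PipelineConfig",
    "StageRecord",
    "StageTrace",
    "average_frames",
    "run",
    "run_stack",
    "STAGE_ORDER",
]

logger = logging.getLogger("ramanclean")

#: The method's stage order; configs must respect it.
STAGE_ORDER = ("despike", "average", "baseline", "tophat")


@dataclass(frozen=True)
class PipelineConfig:
    """Every pipeline tunable, defaulting to the reference protocol for corneal measurements."""

    dialect: Dialect = Dialect()
    despike: bool = True
    spike_k: float = _despike.DEFAULT_K
    fit_zones: _baseline.ZoneSet = _baseline.DEFAULT_FIT_ZONES
    exclude_zones: _baseline.ZoneSet = _baseline.WATER_EXCLUDE_ZONES
    degree: int = _baseline.DEFAULT_DEGREE
    window: tuple[float, float] = _baseline.DEFAULT_WINDOW
    subtract_background: bool = True
    tophat: bool = True
    tophat_half_width: int | None = None  # None → derive from tophat_max_fwhm
    tophat_max_fwhm: float = 30.0  # cm⁻¹, typical Raman linewidth scale
    stage_order: tuple[str, ...] = STAGE_ORDER
    output: str | None = None
    trace_dir: str | None = None
    seed: int | None = None  # synthetic runs only

    def __post_init__(self):
        enabled = tuple(s for s in self.stage_order if s in self._enabled_stages())
        expected = tuple(s for s in STAGE_ORDER if s in self._enabled_stages())
        if enabled != expected:
            raise ContractError(
                f"stage order {self.stage_order} conflicts with the method's "
                f"order {STAGE_ORDER}; reordering is not supported"
            )
        if self.tophat_half_width is not None and self.tophat_half_width < 1:
            raise ContractError("tophat_half_width must be >= 1")

    def _enabled_stages(self) -> set:
        stages = {"average"}
        if self.despike:
            stages.add("despike")
        if self.subtract_background:
            stages.add("baseline")
        if self.tophat:
            stages.add("tophat")
        return stages

    def validate_axis(self, wavenumbers: np.ndarray) -> list[str]:
        """Warnings for zones falling outside the axis coverage."""
        warnings = []
        lo, hi = float(wavenumbers[0]), float(wavenumbers[-1])
        for name, zones in (("fit", self.fit_zones), ("exclude", self.exclude_zones)):
            for a, b in zones.intervals:
                if b < lo or a > hi:
                    warnings.append(f"{name} zone [{a}, {b}] outside axis [{lo}, {hi}]")
        return warnings

    def to_yaml(self, path) -> None:
        data = {
            "dialect": {
                "delimiter": self.dialect.delimiter,
                "decimal": self.dialect.decimal,
                "header_lines": self.dialect.header_lines,
                "comment": self.dialect.comment,
            },
            "despike": self.despike,
            "spike_k": self.spike_k,
            "fit_zones": [list(iv) for iv in self.fit_zones.intervals],
            "exclude_zones": [list(iv) for iv in self.exclude_zones.intervals],
            "degree": self.degree,
            "window": list(self.window),
            "subtract_background": self.subtract_background,
            "tophat": self.tophat,
            "tophat_half_width": self.tophat_half_width,
            "tophat_max_fwhm": self.tophat_max_fwhm,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        kwargs = {}
        if "dialect" in data:
            kwargs["dialect"] = Dialect(**data["dialect"])
        for key in (
            "despike",
            "spike_k",
            "degree",
            "subtract_background",
            "tophat",
            "tophat_half_width",
            "tophat_max_fwhm",
        ):
            if key in data:
                kwargs[key] = data[key]
        if "fit_zones" in data:
            kwargs["fit_zones"] = _baseline.ZoneSet(
                tuple(tuple(iv) for iv in data["fit_zones"])
            )
        if "exclude_zones" in data:
            kwargs["exclude_zones"] = _baseline.ZoneSet(
                tuple(tuple(iv) for iv in data["exclude_zones"])
            )
        if "window" in data:
            kwargs["window"] = tuple(data["window"])
        return cls(**kwargs)


@dataclass(frozen=True)
class StageRecord:
    """One executed stage: its name, output snapshot, and summary scalars."""

    name: str
    data: Spectrum | FrameStack
    summary: dict = field(default_factory=dict)


class StageTrace:
    """Ordered record of the stages a run executed."""

    def __init__(self):
        self.records: list[StageRecord] = []

    def add(self, name: str, data, **summary) -> None:
        self.records.append(StageRecord(name, data, dict(summary)))
        logger.info("stage=%s %s", name, " ".join(f"{k}={v}" for k, v in summary.items()))

    @property
    def final(self) -> Spectrum:
        data = self.records[-1].data
        assert isinstance(data, Spectrum)
        return data

    def stage_names(self) -> list[str]:
        return [r.name for r in self.records]


def average_frames(stack: FrameStack) -> Spectrum:
    """Arithmetic per-channel mean of the frames; reduces detector noise √N-fold."""
    mean = stack.frames.mean(axis=0)
    meta = {**stack.meta, "frames_averaged": str(stack.n_frames)}
    return Spectrum(stack.wavenumbers, mean, meta)


def _run_stage(name: str, func, *args, **kwargs):
    try:
        return func(*args, **kwargs)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(name, exc) from exc


def run_stack(config: PipelineConfig, stack: FrameStack) -> StageTrace:
    """Run the pipeline on an in-memory stack; see :func:`run` for files."""
    for warning in config.validate_axis(stack.wavenumbers):
        logger.warning(warning)
    trace = StageTrace()
    trace.add("read", stack, frames=stack.n_frames, channels=stack.n_channels)

    if config.despike and stack.n_frames >= 2:
        mask = _run_stage("despike", _despike.detect_spikes, stack, config.spike_k)
        stack = _run_stage("despike", _despike.repair_spikes, stack, mask)
        trace.add("despike", stack, repairs=mask.n_flagged, k=config.spike_k)
    elif config.despike:
        logger.warning("single frame: inter-frame despiking skipped")

    spectrum = _run_stage("average", average_frames, stack)
    trace.add("average", spectrum, frames=stack.n_frames, channels=len(spectrum))

    if config.subtract_background:
        fitted = _run_stage(
            "baseline",
            _baseline.fit_partial_polynomial,
            spectrum,
            config.fit_zones,
            config.exclude_zones,
            config.degree,
            config.window,
        )
        spectrum = _run_stage("baseline", _baseline.subtract_baseline, spectrum, fitted)
        trace.add(
            "baseline",
            spectrum,
            degree=config.degree,
            fit_rms=round(fitted.fit_rms, 6),
            channels=len(spectrum),
        )

    if config.tophat:
        if config.tophat_half_width is not None:
            se = _morphology.StructuringElement(config.tophat_half_width)
        else:
            se = _run_stage(
                "tophat", _morphology.suggest_half_width, spectrum, config.tophat_max_fwhm
            )
        cleaned = _run_stage("tophat", _morphology.tophat, spectrum.intensities, se)
        spectrum = spectrum.with_intensities(cleaned, tophat_half_width=se.half_width)
        trace.add("tophat", spectrum, half_width=se.half_width)

    return trace


def run(config: PipelineConfig, input_path) -> StageTrace:
    """Read an export, run all enabled stages, write outputs.

    Deterministic for fixed input and config. On failure nothing is
    written and a :class:`StageError` names the offending stage.
    """
    stack = _run_stage("read", read_frames, input_path, config.dialect)
    trace = run_stack(config, stack)
    if config.output is not None:
        _run_stage("write", write_spectrum, trace.final, config.output)
    if config.trace_dir is not None:
        import os

        os.makedirs(config.trace_dir, exist_ok=True)
        for i, record in enumerate(trace.records):
            target = os.path.join(config.trace_dir, f"{i:02d}_{record.name}.txt")
            if isinstance(record.data, Spectrum):
                _run_stage("trace", write_spectrum, record.data, target)
    return trace
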