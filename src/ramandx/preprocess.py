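"""Spectral preprocessing chain for tissue Raman spectra.

Order of operations (the pipeline default): artifact rejection → iterative
Savitzky-Golay baseline subtraction → wavenumber calibration against the
1003 cm^-1 phenylalanine band → unit-area normalization → light SG smoothing.

The baseline estimator is an iterative signal-removal scheme: an SG filter
with a wide window (a fixed fraction of the spectrum length) gives a running
baseline estimate; points above that estimate are treated as Raman signal and
replaced by the estimate, and the filter is re-applied.  After a fixed number
of iterations the smooth envelope that remains tracks the broad fluorescence
background while ignoring the narrow Raman bands sitting on top of it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .containers import SpectrumSet, trapezoid_area
from .errors import ParameterError, StateError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    """Tunable parameters of the preprocessing chain.

    baseline_window_fraction
        SG window for the baseline filter as a fraction of the spectrum
        length (rounded to the nearest odd point count).  ``baseline_window``
        overrides it with an absolute odd point count when the instrument's
        native resolution is known.
    baseline_iterations
        Number of signal-removal iterations of the baseline estimator.
    reference_peak
        Wavenumber (cm^-1) of the internal calibration band; the strong
        phenylalanine ring-breathing mode by default.
    spike_mad_threshold
        A spectrum is rejected as cosmic-ray-contaminated when any absolute
        second difference exceeds this multiple of the MAD of its second
        differences.
    saturation_level
        Detector ceiling; any point at or above it flags the spectrum as
        saturated.  ``None`` disables the check.
    """

    baseline_window_fraction: float = 0.07
    baseline_window: int | None = None
    baseline_iterations: int = 20
    baseline_order: int = 2
    smooth_window: int = 3
    smooth_order: int = 1
    reference_peak: float = 1003.0
    reference_search_halfwidth: float = 10.0
    spike_mad_threshold: float = 8.0
    saturation_level: float | None = None
    baseline_early_stop: float = 1e-12
    step_order: tuple[str, ...] = field(
        default=("artifacts", "baseline", "calibrate", "normalize", "smooth")
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.baseline_window_fraction < 0.5:
            raise ParameterError("baseline_window_fraction must be in (0, 0.5)")
        if self.baseline_iterations < 1:
            raise ParameterError("baseline_iterations must be >= 1")
        if self.smooth_window % 2 == 0 or self.smooth_window <= self.smooth_order:
            raise ParameterError("smooth_window must be odd and > smooth_order")
        if self.baseline_window is not None and self.baseline_window % 2 == 0:
            raise ParameterError("baseline_window must be odd")

    def window_points(self, n_points: int) -> int:
        """Resolve the baseline SG window for a spectrum of ``n_points``."""
        if self.baseline_window is not None:
            w = self.baseline_window
        else:
            w = int(round(self.baseline_window_fraction * n_points))
            if w % 2 == 0:
                w += 1
        w = max(w, self.baseline_order + 2 + (self.baseline_order % 2))
        if w % 2 == 0:
            w += 1
        if w > n_points:
            raise ParameterError(
                f"baseline window {w} exceeds spectrum length {n_points}"
            )
        return w


def flag_artifacts(
    s: SpectrumSet, cfg: PreprocessConfig
) -> tuple[SpectrumSet, list[tuple[int, str]]]:
    """Split a raw SpectrumSet into kept spectra and rejected (index, reason).

    Cosmic rays are single/few-point spikes: they dominate the second
    difference of the spectrum, so a robust z-score on second differences
    (MAD denominator) flags them.  Saturated spectra touch the detector
    ceiling.  Reasons are ``"cosmic_ray"`` and ``"saturation"``; saturation
    takes precedence when both apply.
    """
    if s.n_points < 5:
        raise ValidationError("spectra must have at least 5 points")
    rejected: list[tuple[int, str]] = []
    keep: list[int] = []
    for i in range(s.n_spectra):
        y = s.intensities[i]
        if cfg.saturation_level is not None and np.any(y >= cfg.saturation_level):
            rejected.append((i, "saturation"))
            continue
        d2 = np.diff(y, n=2)
        mad = np.median(np.abs(d2 - np.median(d2)))
        # The MAD of second differences measures the noise scale.  On clean
        # spectra it collapses toward zero and smooth peak curvature would be
        # misread as a spike, so the criterion is floored by a robust
        # amplitude scale: genuine cosmic rays (tens of times the signal)
        # clear it, smooth Raman bands (curvature << amplitude) do not.
        amp = float(np.percentile(y, 99.5) - np.percentile(y, 50.0))
        cutoff = max(cfg.spike_mad_threshold * mad, amp, np.finfo(float).tiny)
        if np.max(np.abs(d2)) > cutoff:
            rejected.append((i, "cosmic_ray"))
        else:
            keep.append(i)
    return s.subset(keep), rejected


def estimate_baseline(
    y: np.ndarray, cfg: PreprocessConfig, return_envelope_trace: bool = False
):
    """Iterative SG baseline estimate of a single spectrum.

    At each iteration the working spectrum is filtered with a wide SG window;
    points above the filtered curve (signal) are replaced by it, i.e. the
    working spectrum becomes the pointwise minimum of itself and the filter
    output.  The filter output of the final iteration is the baseline.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ValidationError("estimate_baseline expects a single spectrum")
    w = cfg.window_points(y.size)
    if w > y.size:
        raise ParameterError("baseline window longer than spectrum")
    z = y.copy()
    b = z
    trace = [z.copy()]
    for _ in range(cfg.baseline_iterations):
        b = savgol_filter(z, window_length=w, polyorder=cfg.baseline_order)
        z_new = np.minimum(z, b)
        converged = np.max(np.abs(z_new - z)) < cfg.baseline_early_stop
        z = z_new
        if return_envelope_trace:
            trace.append(z.copy())
        if converged:
            break
    if return_envelope_trace:
        return b, trace
    return b


def subtract_baseline(s: SpectrumSet, cfg: PreprocessConfig) -> SpectrumSet:
    """Subtract the per-spectrum iterative SG baseline.

    Negative residuals are retained (clipping would bias area normalization);
    the factorization stage clips its own working copy instead.
    """
    if "baseline" in s.processing_state:
        raise StateError("baseline already subtracted")
    out = np.empty_like(s.intensities)
    for i in range(s.n_spectra):
        out[i] = s.intensities[i] - estimate_baseline(s.intensities[i], cfg)
    return s.with_intensities(out, step="baseline")


def calibrate_shift(s: SpectrumSet, cfg: PreprocessConfig) -> SpectrumSet:
    """Align spectra on the reference band by integer-grid shifts.

    Within ``reference_peak ± reference_search_halfwidth`` the calibration
    band's apex is located (argmax refined by parabolic interpolation, so a
    band whose center falls between grid points does not alias into ±1-bin
    jitter) and the spectrum is rolled by the integer number of grid points
    that brings the apex onto the reference wavenumber; vacated edge points
    are filled by edge replication.  Spectra with no interior local maximum
    above the window median (e.g. flat or signal-free) are left unshifted
    and logged.
    """
    lo = cfg.reference_peak - cfg.reference_search_halfwidth
    hi = cfg.reference_peak + cfg.reference_search_halfwidth
    if s.axis[0] > lo or s.axis[-1] < hi:
        raise ParameterError(
            f"axis [{s.axis[0]:g}, {s.axis[-1]:g}] does not cover the calibration "
            f"window [{lo:g}, {hi:g}]"
        )
    window = np.nonzero((s.axis >= lo) & (s.axis <= hi))[0]
    step = float(np.median(np.diff(s.axis)))
    out = np.empty_like(s.intensities)
    n_unshifted = 0
    for i in range(s.n_spectra):
        y = s.intensities[i]
        seg = y[window].astype(float)
        if seg.size >= 5:
            # light smoothing for apex *detection* only; the data are
            # untouched here (the pipeline smooths later)
            seg = savgol_filter(seg, 3, 1)
        # detrend by the line through the window endpoints: tails of
        # neighbouring bands tilt the window and would bias the apex
        ramp = np.linspace(seg[0], seg[-1], seg.size)
        det = seg - ramp
        peak_local = int(np.argmax(det))
        # require an interior local maximum above the window median; an
        # argmax at the window edge is a monotone slope, not a peak
        interior = 0 < peak_local < det.size - 1
        if not interior or seg[peak_local] <= np.median(seg):
            out[i] = y
            n_unshifted += 1
            continue
        ym, y0, yp = det[peak_local - 1], det[peak_local], det[peak_local + 1]
        denom = ym - 2.0 * y0 + yp
        delta = 0.0 if denom == 0 else 0.5 * (ym - yp) / denom
        apex = s.axis[window[peak_local]] + np.clip(delta, -0.5, 0.5) * step
        shift = int(np.round((cfg.reference_peak - apex) / step))
        if shift == 0:
            out[i] = y
            continue
        rolled = np.roll(y, shift)
        if shift > 0:
            rolled[:shift] = y[0]
        else:
            rolled[shift:] = y[-1]
        out[i] = rolled
    if n_unshifted:
        logger.warning(
            "calibrate_shift: %d spectra had no calibration peak and were left "
            "unshifted", n_unshifted,
        )
    return s.with_intensities(out, step="calibrate")


def normalize_area(s: SpectrumSet) -> SpectrumSet:
    """Scale each spectrum so its trapezoidal integral over the axis is 1."""
    areas = trapezoid_area(s.intensities, s.axis)
    bad = np.nonzero(areas <= 0)[0]
    if bad.size:
        raise ValidationError(
            f"non-positive area for spectra at rows {bad.tolist()[:10]}"
        )
    step = None if "normalize" in s.processing_state else "normalize"
    return s.with_intensities(s.intensities / areas[:, None], step=step)


def smooth(s: SpectrumSet, cfg: PreprocessConfig) -> SpectrumSet:
    """Light SG smoothing (default window 3, order 1: a 3-point moving mean)."""
    if cfg.smooth_window > s.n_points:
        raise ParameterError("smooth window longer than spectrum")
    out = savgol_filter(
        s.intensities, window_length=cfg.smooth_window, polyorder=cfg.smooth_order,
        axis=1,
    )
    return s.with_intensities(out, step="smooth")


@dataclass
class PreprocessReport:
    """Rejection counts and surviving per-biopsy inventory of a pipeline run."""

    n_input: int
    n_kept: int
    rejected: list[tuple[int, str]]
    rejection_counts: dict[str, int]
    per_biopsy_counts: dict[str, int]
    steps: list[str]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            sorted(self.per_biopsy_counts.items()),
            columns=["biopsy_id", "n_spectra"],
        )


def preprocess_pipeline(
    raw: SpectrumSet, cfg: PreprocessConfig | None = None
) -> tuple[SpectrumSet, PreprocessReport]:
    """Run the full chain in the configured order and report what happened."""
    cfg = cfg or PreprocessConfig()
    s = raw
    rejected: list[tuple[int, str]] = []
    steps: list[str] = []
    for step in cfg.step_order:
        if step == "artifacts":
            s, rejected = flag_artifacts(s, cfg)
        elif step == "baseline":
            s = subtract_baseline(s, cfg)
        elif step == "calibrate":
            s = calibrate_shift(s, cfg)
        elif step == "normalize":
            s = normalize_area(s)
        elif step == "smooth":
            s = smooth(s, cfg)
        else:
            raise ParameterError(f"unknown pipeline step {step!r}")
        steps.append(step)
    counts: dict[str, int] = {}
    for r in rejected:
        counts[r[1]] = counts.get(r[1], 0) + 1
    per_biopsy = s.meta.groupby("biopsy_id").size().to_dict()
    report = PreprocessReport(
        n_input=raw.n_spectra,
        n_kept=s.n_spectra,
        rejected=rejected,
        rejection_counts=counts,
        per_biopsy_counts=per_biopsy,
        steps=steps,
    )
    return s, report
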