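"""Band-pass filtering and R-peak-centered beat segmentation.

The diagnostic content of the ECG lies between 0.5 and 50 Hz, so the raw
signal is cleaned with a linear-phase FIR band-pass applied forward and
backward (zero phase), which removes baseline drift and powerline
interference without shifting the annotated R-peak positions.  Beats are
then cut as asymmetric windows of 75 ms before to 110 ms after each
annotated R peak; annotations are trusted verbatim, no re-detection is
performed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .synthetic import AnnotatedRecord

PRE_R_SECONDS = 0.075
POST_R_SECONDS = 0.110


def round_half_up(x: float) -> int:
    """Round to nearest integer with ties going up (2.5 -> 3)."""
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class FilterSpec:
    """Linear-phase FIR band-pass specification.

    ``order`` is the number of filter taps minus one and must be even so
    the filter is a symmetric (type I) FIR; the default 128 is defined at
    360 Hz and scaled proportionally for other rates so the impulse
    response keeps the same time extent.
    """

    low_hz: float = 0.5
    high_hz: float = 50.0
    order: int | None = None
    window: str = "hamming"

    def taps_for(self, fs: float) -> int:
        if self.order is not None:
            order = self.order
        else:
            order = 2 * max(1, round(128 * fs / 360.0 / 2))
        if order % 2:
            raise ValueError(f"filter order must be even, got {order}")
        return order + 1

    def validate(self, fs: float) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError("need 0 < low cutoff < high cutoff")
        if self.high_hz >= fs / 2:
            raise ValueError(
                f"high cutoff {self.high_hz} Hz requires fs > {2 * self.high_hz} Hz, got {fs}"
            )


def design_bandpass(fs: float, spec: FilterSpec | None = None) -> np.ndarray:
    """Return the FIR band-pass kernel for sampling rate ``fs``.

    The windowed-sinc design cannot realize the 0.5 Hz low edge at
    practical orders (the transition band is several Hz wide), so the
    kernel is corrected by subtracting a window-shaped component that
    forces an exact spectral null at DC.  This leaves the pass band
    (|H| within 1% at 10 Hz) and the upper stop band (>50 dB at 60 Hz
    for the 360 Hz profile) intact while guaranteeing full rejection of
    constant offsets.
    """
    spec = spec or FilterSpec()
    spec.validate(fs)
    taps = spec.taps_for(fs)
    h = sps.firwin(
        taps, [spec.low_hz, spec.high_hz], pass_zero=False, fs=fs, window=spec.window
    )
    win = sps.get_window(spec.window, taps, fftbins=False)
    return h - h.sum() * win / win.sum()


def bandpass_filter(
    signal: np.ndarray, fs: float, spec: FilterSpec | None = None
) -> np.ndarray:
    """Zero-phase band-pass: forward-backward application of the FIR kernel.

    Output has the same length as the input and R peaks are not shifted.
    """
    spec = spec or FilterSpec()
    h = design_bandpass(fs, spec)
    x = np.asarray(signal, dtype=float)
    if len(x) <= len(h):
        raise ValueError(
            f"signal length {len(x)} must exceed the filter length {len(h)}"
        )
    return sps.filtfilt(h, [1.0], x)


@dataclass
class BeatSegment:
    """One fixed-length excerpt of filtered signal centered on an R peak."""

    samples: np.ndarray
    r_index: int
    label: str | None
    record_id: str
    global_r_index: int
    beat_index: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)


@dataclass
class SegmentationResult:
    segments: list[BeatSegment]
    n_dropped: int
    n_before: int
    n_after: int

    @property
    def segment_length(self) -> int:
        return self.n_before + self.n_after


def window_sizes(fs: float) -> tuple[int, int]:
    """(n_before, n_after) sample counts for the 75/110 ms beat window."""
    return round_half_up(PRE_R_SECONDS * fs), round_half_up(POST_R_SECONDS * fs)


def segment_beats(
    record: AnnotatedRecord, signal: np.ndarray | None = None
) -> SegmentationResult:
    """Cut one window ``[R - n_before, R + n_after)`` per annotated beat.

    ``signal`` defaults to ``record.signal``; pass the filtered signal to
    segment after band-pass filtering.  Beats whose window would cross a
    record boundary are dropped and counted.  Window sizes per profile:
    67 samples at 360 Hz, 47 at 250 and 257 Hz.
    """
    sig = record.signal if signal is None else np.asarray(signal, dtype=float)
    n_before, n_after = window_sizes(record.fs)
    segments: list[BeatSegment] = []
    dropped = 0
    for i, (r, lab) in enumerate(zip(record.r_peaks, record.labels)):
        lo, hi = r - n_before, r + n_after
        if lo < 0 or hi > len(sig):
            dropped += 1
            continue
        segments.append(
            BeatSegment(
                samples=sig[lo:hi].copy(),
                r_index=n_before,
                label=lab,
                record_id=record.record_id,
                global_r_index=int(r),
                beat_index=i,
            )
        )
    return SegmentationResult(
        segments=segments, n_dropped=dropped, n_before=n_before, n_after=n_after
    )


def preprocess_record(
    record: AnnotatedRecord, spec: FilterSpec | None = None
) -> SegmentationResult:
    """Filter then segment: the standard front half of the pipeline."""
    filtered = bandpass_filter(record.signal, record.fs, spec)
    return segment_beats(record, signal=filtered)
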