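"""Per-beat feature descriptors.

Each heartbeat segment is summarized by six descriptor blocks,
concatenated in a fixed order into one feature vector:

====== ===========================================================
block  content (width at 360 Hz / other profiles)
====== ===========================================================
lbp    1D local binary pattern histogram, uniform taxonomy (60)
hos    skewness + excess kurtosis of 6 subsegments (12)
cm     5th-order central moment of the whole segment (1)
hbf    Hermite basis function expansion coefficients (16)
dwt    level-3 Haar approximation of the resampled segment (32 / 26)
rr     RR-interval timing context of the beat (10)
====== ===========================================================

Total width: 131 for the 360 Hz profile, 125 for the 250/257 Hz
profiles (the DWT block shrinks because those segments are resampled
to 208 rather than 256 samples).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy import signal as sps
from scipy import stats
from scipy.special import eval_hermite

from .preprocess import BeatSegment, SegmentationResult, preprocess_record
from .synthetic import AnnotatedRecord

BLOCKS = ("lbp", "hos", "cm", "hbf", "dwt", "rr")


@dataclass(frozen=True)
class DescriptorProfile:
    """Descriptor settings tied to a sampling-rate profile.

    The resample length controls the DWT block width: a level-3 Haar
    decomposition of 256 samples leaves 32 approximation coefficients
    (360 Hz profile), of 208 samples leaves 26 (250/257 Hz profiles).
    """

    name: str
    fs: float
    resample_len: int
    wavelet: str = "haar"
    dwt_level: int = 3
    lbp_neighbors: int = 8
    hermite_order: int = 16
    hos_subsegments: int = 6
    hermite_sigma_frac: float = 1.0 / 6.0

    @property
    def dwt_len(self) -> int:
        return self.resample_len // 2**self.dwt_level

    @property
    def n_features(self) -> int:
        return 60 + 12 + 1 + self.hermite_order + self.dwt_len + 10

    def block_widths(self) -> dict[str, int]:
        return {
            "lbp": 60,
            "hos": 12,
            "cm": 1,
            "hbf": self.hermite_order,
            "dwt": self.dwt_len,
            "rr": 10,
        }

    def feature_names(self) -> list[str]:
        names = []
        for block, width in self.block_widths().items():
            names += [f"{block}_{i:02d}" for i in range(width)]
        return names


PROFILES: dict[str, DescriptorProfile] = {
    "mitbih": DescriptorProfile(name="mitbih", fs=360.0, resample_len=256),
    "edb": DescriptorProfile(name="edb", fs=250.0, resample_len=208),
    "incart": DescriptorProfile(name="incart", fs=257.0, resample_len=208),
}


def profile_for(fs: float) -> DescriptorProfile:
    """The named profile matching ``fs``, or a custom one.

    Custom rates at or above 300 Hz use the 256-sample resample length
    (32 DWT coefficients); lower rates use 208 (26 coefficients).
    """
    for prof in PROFILES.values():
        if np.isclose(prof.fs, fs):
            return prof
    return DescriptorProfile(
        name=f"custom:{fs:g}", fs=fs, resample_len=256 if fs >= 300 else 208
    )


# ---------------------------------------------------------------------------
# 1D local binary patterns


def _circular_transitions(code: int, bits: int = 8) -> int:
    prev = (code >> (bits - 1)) & 1
    count = 0
    for b in range(bits):
        cur = (code >> b) & 1
        if cur != prev:
            count += 1
        prev = cur
    return count


def _build_lbp_table() -> np.ndarray:
    """Map each 8-bit code to one of 60 bins.

    Bins 0..57: the 58 uniform patterns (at most 2 circular transitions)
    in ascending code order.  Bin 58 pools codes with exactly 4 circular
    transitions, bin 59 pools codes with more than 4.  (Circular
    transition counts of an 8-bit code are always even.)
    """
    table = np.empty(256, dtype=np.intp)
    uniform = [c for c in range(256) if _circular_transitions(c) <= 2]
    assert len(uniform) == 58
    idx = {c: i for i, c in enumerate(uniform)}
    for code in range(256):
        u = _circular_transitions(code)
        if u <= 2:
            table[code] = idx[code]
        elif u == 4:
            table[code] = 58
        else:
            table[code] = 59
    return table


_LBP_TABLE = _build_lbp_table()


def lbp_histogram(segment: np.ndarray | BeatSegment) -> np.ndarray:
    """Normalized 60-bin histogram of 1D-LBP codes over the segment.

    Each interior sample is compared with its 4 left and 4 right
    neighbors (neighbor >= center -> bit 1, nearest neighbors in the
    least significant bits, left side first), giving an 8-bit code that
    is pooled by the uniform-pattern taxonomy.
    """
    x = _samples(segment)
    if len(x) <= 8:
        raise ValueError(f"segment too short for 8-neighbor LBP: {len(x)}")
    center = x[4:-4]
    codes = np.zeros(len(center), dtype=np.intp)
    bit = 0
    for offset in (-1, -2, -3, -4, 1, 2, 3, 4):
        neighbor = x[4 + offset : len(x) - 4 + offset]
        codes |= (neighbor >= center).astype(np.intp) << bit
        bit += 1
    hist = np.bincount(_LBP_TABLE[codes], minlength=60).astype(float)
    return hist / hist.sum()


# ---------------------------------------------------------------------------
# Higher-order statistics and central moment


def hos_features(segment: np.ndarray | BeatSegment, n_subsegments: int = 6) -> np.ndarray:
    """Skewness and excess kurtosis of equal contiguous subsegments.

    Returns ``(skew_1, kurt_1, ..., skew_6, kurt_6)``.  A zero-variance
    subsegment yields 0 for both statistics by convention.
    """
    x = _samples(segment)
    if len(x) < 4 * n_subsegments:
        raise ValueError(
            f"segment of {len(x)} samples cannot give {n_subsegments} "
            "subsegments of >= 4 samples"
        )
    out = np.empty(2 * n_subsegments)
    for i, part in enumerate(np.array_split(x, n_subsegments)):
        if np.ptp(part) == 0:
            out[2 * i] = out[2 * i + 1] = 0.0
        else:
            out[2 * i] = stats.skew(part)
            out[2 * i + 1] = stats.kurtosis(part)  # Fisher: excess kurtosis
    return out


def central_moment(segment: np.ndarray | BeatSegment, order: int = 5) -> float:
    """Central moment of the whole segment (5th order by default)."""
    x = _samples(segment)
    if len(x) == 0:
        raise ValueError("empty segment")
    if np.ptp(x) == 0:
        return 0.0
    return float(stats.moment(x, order))


# ---------------------------------------------------------------------------
# Hermite basis expansion


def hermite_design(
    n_samples: int, r_index: int, order: int = 16, sigma: float | None = None
) -> np.ndarray:
    """Design matrix of the first ``order`` Hermite functions.

    Column k is ``H_k(u) * exp(-u^2 / 2)`` (physicists' Hermite
    polynomial times a Gaussian envelope) evaluated at
    ``u = (i - r_index) / sigma`` on the sample grid, normalized to unit
    Euclidean norm.  ``sigma`` defaults to one sixth of the segment
    length, so the envelope covers the whole beat window.
    """
    if sigma is None:
        sigma = n_samples / 6.0
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    u = (np.arange(n_samples) - r_index) / sigma
    cols = []
    for k in range(order):
        col = eval_hermite(k, u) * np.exp(-0.5 * u**2)
        norm = np.linalg.norm(col)
        if norm == 0 or not np.isfinite(norm):
            raise ValueError(
                f"Hermite basis column {k} degenerate for sigma={sigma}"
            )
        cols.append(col / norm)
    design = np.column_stack(cols)
    if np.linalg.matrix_rank(design) < order:
        raise ValueError(f"rank-deficient Hermite design (sigma={sigma})")
    return design


def hermite_coeffs(
    segment: np.ndarray | BeatSegment,
    order: int = 16,
    sigma: float | None = None,
    r_index: int | None = None,
) -> np.ndarray:
    """Least-squares projection of the segment onto the Hermite basis."""
    x = _samples(segment)
    if r_index is None:
        r_index = segment.r_index if isinstance(segment, BeatSegment) else len(x) // 2
    design = hermite_design(len(x), r_index, order=order, sigma=sigma)
    coeffs, *_ = np.linalg.lstsq(design, x, rcond=None)
    return coeffs


# ---------------------------------------------------------------------------
# Discrete wavelet transform


def dwt_features(
    segment: np.ndarray | BeatSegment, profile: DescriptorProfile
) -> np.ndarray:
    """Level-3 Haar approximation coefficients of the resampled segment.

    The segment is Fourier-resampled to the profile's resample length
    (256 or 208 samples) so that the approximation has a fixed width of
    32 or 26 coefficients regardless of the raw window size.
    """
    x = _samples(segment)
    resampled = sps.resample(x, profile.resample_len)
    coeffs = pywt.wavedec(resampled, profile.wavelet, level=profile.dwt_level)
    return np.asarray(coeffs[0], dtype=float)


# ---------------------------------------------------------------------------
# RR-interval context


def rr_features(
    r_peaks: np.ndarray, beat_index: int, fs: float, local_window: int = 10
) -> np.ndarray:
    """Ten RR-interval timing features of beat ``beat_index``.

    In order: pre-RR, post-RR, local mean RR (over the ~10 surrounding
    beats), global mean RR, pre/post, pre/local, post/local, pre/global,
    post/global, local RR standard deviation — intervals in seconds.
    Edge beats lacking a pre- or post-interval substitute the local mean.
    """
    r_peaks = np.asarray(r_peaks)
    if len(r_peaks) < 2:
        raise ValueError("RR features require at least 2 annotated beats")
    if not 0 <= beat_index < len(r_peaks):
        raise IndexError(f"beat index {beat_index} out of range")
    rr = np.diff(r_peaks) / fs  # rr[i] is the interval between beats i and i+1
    half = local_window // 2
    lo = max(0, beat_index - half)
    hi = min(len(rr), beat_index + half)
    local = rr[lo:hi]
    local_mean = float(local.mean())
    local_sd = float(local.std())
    global_mean = float(rr.mean())
    pre = float(rr[beat_index - 1]) if beat_index >= 1 else local_mean
    post = float(rr[beat_index]) if beat_index < len(rr) else local_mean
    return np.array(
        [
            pre,
            post,
            local_mean,
            global_mean,
            pre / post,
            pre / local_mean,
            post / local_mean,
            pre / global_mean,
            post / global_mean,
            local_sd,
        ]
    )


# ---------------------------------------------------------------------------
# Full extraction


def beat_vector(
    segment: BeatSegment,
    r_peaks: np.ndarray,
    profile: DescriptorProfile,
) -> np.ndarray:
    """Concatenated descriptor vector for one beat, in block order."""
    sigma = len(segment.samples) * profile.hermite_sigma_frac
    return np.concatenate(
        [
            lbp_histogram(segment),
            hos_features(segment, profile.hos_subsegments),
            [central_moment(segment)],
            hermite_coeffs(segment, order=profile.hermite_order, sigma=sigma),
            dwt_features(segment, profile),
            rr_features(r_peaks, segment.beat_index, profile.fs),
        ]
    )


def extract_segments(
    segmentation: SegmentationResult,
    r_peaks: np.ndarray,
    profile: DescriptorProfile,
) -> pd.DataFrame:
    """Feature matrix (one row per emitted segment) with a label column."""
    names = profile.feature_names()
    rows = [beat_vector(seg, r_peaks, profile) for seg in segmentation.segments]
    matrix = np.vstack(rows) if rows else np.empty((0, profile.n_features))
    df = pd.DataFrame(matrix, columns=names)
    df["label"] = [seg.label for seg in segmentation.segments]
    return df


def extract_all(
    record: AnnotatedRecord, profile: DescriptorProfile | None = None
) -> pd.DataFrame:
    """Filter, segment and featurize a whole record.

    Row width is ``profile.n_features`` + 1 label column: 131 features
    under the 360 Hz profile, 125 under the 250/257 Hz profiles.
    """
    if profile is None:
        profile = profile_for(record.fs)
    elif not np.isclose(profile.fs, record.fs):
        raise ValueError(
            f"profile fs {profile.fs} does not match record fs {record.fs}"
        )
    segmentation = preprocess_record(record)
    return extract_segments(segmentation, record.r_peaks, profile)


def write_features(df: pd.DataFrame, path) -> None:
    """Write a feature matrix as headered CSV at full float precision."""
    df.to_csv(path, index=False, float_format="%.17g")


def read_features(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def _samples(segment: np.ndarray | BeatSegment) -> np.ndarray:
    if isinstance(segment, BeatSegment):
        return segment.samples
    return np.asarray(segment, dtype=float)
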