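"""Synthetic single-channel ECG records with per-beat AAMI class labels.

The generator produces annotated records in which the four AAMI beat
classes (N normal, S supraventricular ectopic, VEB ventricular ectopic,
F fusion) differ both in morphology and in RR-interval structure, so the
whole classification pipeline can be exercised without any external
recording.  Each beat is a sum of five Gaussians — one per P, Q, R, S and
T wave — which is the simplest shape model with controllable class
differences:

* ``N``   — narrow QRS, normal P wave, regular RR intervals.
* ``S``   — narrow QRS with a reduced P wave and a *premature* RR
  signature (shortened pre-RR, compensatory pause after).
* ``VEB`` — wide, large-amplitude QRS with no P wave and a discordant T
  wave, plus the premature RR signature.
* ``F``   — fusion morphology: the elementwise average of the N and VEB
  wave parameters, with normal timing.

On top of the beat train the generator adds the three disturbance types
an ECG front-end has to cope with: sinusoidal baseline wander,
powerline interference and white Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

AAMI_CLASSES = ("N", "S", "VEB", "F")
WAVES = ("P", "Q", "R", "S", "T")

#: Minimum RR interval emitted by the generator (seconds); intervals are
#: clipped here so pathological configurations cannot produce overlapping
#: or negative beat spacing.
RR_FLOOR = 0.2

#: Half-extent of a beat template around its R wave (seconds).
TEMPLATE_HALF_SPAN = 0.35


@dataclass(frozen=True)
class MorphologyParams:
    """Gaussian wave parameters for one beat class.

    ``waves`` maps each of P/Q/R/S/T to ``(amplitude_mv, center_ms,
    width_ms)`` where the center offset is relative to the R peak and the
    width is the Gaussian standard deviation.
    """

    waves: dict[str, tuple[float, float, float]]

    def __post_init__(self) -> None:
        for name in WAVES:
            if name not in self.waves:
                raise ValueError(f"missing wave parameters for {name!r}")
            amp, _center, width = self.waves[name]
            if width <= 0:
                raise ValueError(f"wave {name!r} width must be > 0, got {width}")
        if self.waves["R"][0] <= 0:
            raise ValueError("R amplitude must be positive")


def _average_morphology(a: MorphologyParams, b: MorphologyParams) -> MorphologyParams:
    waves = {}
    for name in WAVES:
        waves[name] = tuple(
            (x + y) / 2.0 for x, y in zip(a.waves[name], b.waves[name])
        )
    return MorphologyParams(waves=waves)


_N_MORPH = MorphologyParams(
    waves={
        "P": (0.15, -160.0, 22.0),
        "Q": (-0.12, -18.0, 7.0),
        "R": (1.0, 0.0, 6.0),
        "S": (-0.25, 18.0, 7.0),
        "T": (0.35, 230.0, 55.0),
    }
)

_S_MORPH = MorphologyParams(
    waves={
        "P": (0.06, -140.0, 20.0),
        "Q": (-0.10, -17.0, 7.0),
        "R": (0.92, 0.0, 6.0),
        "S": (-0.22, 17.0, 7.0),
        "T": (0.30, 215.0, 50.0),
    }
)

# Wide-complex ventricular beat: absent P wave, broad QRS, discordant T.
_VEB_MORPH = MorphologyParams(
    waves={
        "P": (0.0, -160.0, 22.0),
        "Q": (-0.08, -50.0, 16.0),
        "R": (1.3, 0.0, 16.0),
        "S": (-0.5, 50.0, 18.0),
        "T": (-0.4, 270.0, 70.0),
    }
)

DEFAULT_MORPHOLOGIES: dict[str, MorphologyParams] = {
    "N": _N_MORPH,
    "S": _S_MORPH,
    "VEB": _VEB_MORPH,
    "F": _average_morphology(_N_MORPH, _VEB_MORPH),
}


@dataclass
class SimConfig:
    """Configuration for one synthetic record.

    Defaults follow the 360 Hz recording profile; noise levels are white
    noise sd 0.05 mV, baseline wander 0.1 mV at 0.3 Hz and powerline
    interference 0.02 mV at 50 Hz.
    """

    fs: float = 360.0
    n_beats: int = 600
    class_proportions: dict[str, float] = field(
        default_factory=lambda: {"N": 0.70, "S": 0.10, "VEB": 0.15, "F": 0.05}
    )
    base_rr: float = 0.8
    rr_jitter_sd: float = 0.04
    prematurity: float = 0.65
    noise_sd: float = 0.05
    wander_amplitude: float = 0.1
    wander_freq: float = 0.3
    powerline_amplitude: float = 0.02
    powerline_freq: float = 50.0
    seed: int = 0
    max_duration: float = 36000.0
    morphologies: dict[str, MorphologyParams] | None = None

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.n_beats < 1:
            raise ValueError("need at least one beat")
        props = self.class_proportions
        unknown = set(props) - set(AAMI_CLASSES)
        if unknown:
            raise ValueError(f"unknown classes in proportions: {sorted(unknown)}")
        vals = np.array([props.get(c, 0.0) for c in AAMI_CLASSES], dtype=float)
        if (vals < 0).any():
            raise ValueError("class proportions must be nonnegative")
        if not np.isclose(vals.sum(), 1.0, atol=1e-6):
            raise ValueError(f"class proportions must sum to 1, got {vals.sum()}")
        if not 0.0 < self.prematurity < 1.0:
            raise ValueError("prematurity factor must lie in (0, 1)")
        if self.base_rr <= 0:
            raise ValueError("base RR must be positive")


@dataclass
class AnnotatedRecord:
    """A single-channel signal plus R-peak annotations and beat labels."""

    signal: np.ndarray
    fs: float
    r_peaks: np.ndarray
    labels: list[str]
    record_id: str = "synthetic"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.r_peaks = np.asarray(self.r_peaks, dtype=int)
        if len(self.r_peaks) != len(self.labels):
            raise ValueError("r_peaks and labels must have equal length")
        if len(self.r_peaks) and (np.diff(self.r_peaks) <= 0).any():
            raise ValueError("r_peaks must be strictly increasing")
        if len(self.r_peaks) and (
            self.r_peaks[0] < 0 or self.r_peaks[-1] >= len(self.signal)
        ):
            raise ValueError("r_peaks must lie within the signal extent")

    @property
    def n_beats(self) -> int:
        return len(self.r_peaks)

    @property
    def duration(self) -> float:
        return len(self.signal) / self.fs


def waveform_from_waves(
    waves: dict[str, tuple[float, float, float]], fs: float
) -> np.ndarray:
    """Sum-of-Gaussians waveform on the template grid (±350 ms around R).

    ``waves`` maps wave names to ``(amplitude_mv, center_ms, width_ms)``;
    the grid's center sample (``template_center_index(fs)``) sits at
    offset 0 ms.
    """
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    n_side = template_center_index(fs)
    t_ms = (np.arange(-n_side, n_side + 1) / fs) * 1000.0
    wave = np.zeros_like(t_ms)
    for amp, center, width in waves.values():
        wave += amp * np.exp(-0.5 * ((t_ms - center) / width) ** 2)
    return wave


def beat_template(
    class_label: str,
    morphology: MorphologyParams | None = None,
    fs: float = 360.0,
) -> np.ndarray:
    """Return one beat waveform as a sum of five Gaussian waves.

    The template spans ±350 ms around the R wave; its center sample
    (index ``template_center_index(fs)``) falls exactly on the R-wave
    center, where the waveform attains its maximum absolute amplitude
    for the default morphologies.
    """
    if morphology is None:
        if class_label not in DEFAULT_MORPHOLOGIES:
            raise ValueError(
                f"unknown class label {class_label!r}; expected one of {AAMI_CLASSES}"
            )
        morphology = DEFAULT_MORPHOLOGIES[class_label]
    elif class_label not in AAMI_CLASSES:
        raise ValueError(
            f"unknown class label {class_label!r}; expected one of {AAMI_CLASSES}"
        )
    return waveform_from_waves(morphology.waves, fs)


def template_center_index(fs: float) -> int:
    """Index of the R-wave sample within a beat template."""
    return int(round(TEMPLATE_HALF_SPAN * fs))


def generate_rr_series(
    labels: list[str] | np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Pre-R-R interval (seconds) for every beat in ``labels``.

    Normal and fusion beats get ``base_rr`` plus Gaussian jitter.
    Premature ectopics (S, VEB) get exactly ``prematurity * base_rr`` as
    their pre-RR, and the following non-premature beat gets a
    compensatory pause of ``(2 - prematurity) * base_rr`` plus jitter.
    All intervals are clipped at a 0.2 s floor.
    """
    labels = list(labels)
    for lab in labels:
        if lab not in AAMI_CLASSES:
            raise ValueError(f"unknown class label {lab!r}")
    n = len(labels)
    rr = np.empty(n)
    for i, lab in enumerate(labels):
        if lab in ("S", "VEB"):
            rr[i] = config.prematurity * config.base_rr
        else:
            base = config.base_rr
            if i > 0 and labels[i - 1] in ("S", "VEB"):
                base = (2.0 - config.prematurity) * config.base_rr
            rr[i] = base + config.rr_jitter_sd * rng.standard_normal()
    return np.maximum(rr, RR_FLOOR)


def generate_record(config: SimConfig) -> AnnotatedRecord:
    """Generate one annotated record from ``config``.

    Beat templates are laid down at cumulative RR positions, then
    baseline wander, powerline interference and white noise are added.
    Annotations mark the sample nearest each true R-wave center.
    """
    rng = np.random.default_rng(config.seed)
    props = np.array(
        [config.class_proportions.get(c, 0.0) for c in AAMI_CLASSES], dtype=float
    )
    props = props / props.sum()
    labels = [
        AAMI_CLASSES[i] for i in rng.choice(len(AAMI_CLASSES), size=config.n_beats, p=props)
    ]
    rr = generate_rr_series(labels, config, rng)

    lead_in = 0.4
    peak_times = lead_in + np.concatenate([[0.0], np.cumsum(rr[1:])])
    # Snap R-wave centers to the sample grid (≤ half-sample shift) so the
    # annotation marks the true R sample and noiseless beat windows equal
    # their class template exactly.
    peak_times = np.round(peak_times * config.fs) / config.fs
    duration = peak_times[-1] + 0.5
    if duration > config.max_duration:
        raise ValueError(
            f"requested {config.n_beats} beats span {duration:.1f} s, "
            f"exceeding max_duration={config.max_duration} s"
        )
    n = int(round(duration * config.fs))
    t = np.arange(n) / config.fs
    signal = np.zeros(n)

    morphs = dict(DEFAULT_MORPHOLOGIES)
    if config.morphologies:
        morphs.update(config.morphologies)

    # Each beat only contributes within ±TEMPLATE_HALF_SPAN of its R wave,
    # so the Gaussians are evaluated on a local window for O(n) cost.
    half = int(np.ceil(TEMPLATE_HALF_SPAN * config.fs)) + 1
    for time, lab in zip(peak_times, labels):
        center = int(round(time * config.fs))
        lo, hi = max(0, center - half), min(n, center + half + 1)
        t_ms = (t[lo:hi] - time) * 1000.0
        seg = np.zeros(hi - lo)
        for amp, c_ms, w_ms in morphs[lab].waves.values():
            seg += amp * np.exp(-0.5 * ((t_ms - c_ms) / w_ms) ** 2)
        signal[lo:hi] += seg

    if config.wander_amplitude:
        phase = rng.uniform(0, 2 * np.pi)
        signal += config.wander_amplitude * np.sin(
            2 * np.pi * config.wander_freq * t + phase
        )
    if config.powerline_amplitude:
        phase = rng.uniform(0, 2 * np.pi)
        signal += config.powerline_amplitude * np.sin(
            2 * np.pi * config.powerline_freq * t + phase
        )
    if config.noise_sd:
        signal += config.noise_sd * rng.standard_normal(n)

    r_peaks = np.round(peak_times * config.fs).astype(int)
    return AnnotatedRecord(
        signal=signal,
        fs=config.fs,
        r_peaks=r_peaks,
        labels=labels,
        record_id=f"synthetic-{config.seed}",
        seed=config.seed,
    )


def well_separated_config(
    n_beats: int = 400,
    fs: float = 360.0,
    seed: int = 0,
    noise_sd: float = 0.02,
) -> SimConfig:
    """A configuration with large inter-class margins and balanced classes.

    Used for pipeline tests where the question is whether tuning and
    evaluation behave correctly, not whether the classes are hard.
    """
    return SimConfig(
        fs=fs,
        n_beats=n_beats,
        class_proportions={"N": 0.4, "S": 0.2, "VEB": 0.25, "F": 0.15},
        noise_sd=noise_sd,
        wander_amplitude=0.05,
        seed=seed,
    )
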