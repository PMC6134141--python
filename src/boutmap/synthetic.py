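"""Ground-truth synthetic experiments.

Emulates the study's recordings so every downstream stage is testable
without data downloads: a 315 s single-plane trial of alternating 10 s
moving / 5 s static optomotor grating, a 250 Hz tail-bend trace whose swim
bouts occur preferentially during stimulus motion, and a two-channel movie
(green activity + static red anatomy with red-to-green bleed-through) in
which planted ROIs follow one of five activity archetypes:

``swim_locked``
    a calcium transient at each bout onset (impulse train * kernel);
``stim_on``
    sustained elevation while the grating moves (boxcar * kernel);
``mixed``
    a sensorimotor intermediate: a (weaker) transient at each bout plus an
    adapting stimulus drive that peaks at motion onset and decays during
    the motion period;
``stim_suppressed``
    a positive baseline shut off during motion (floored at zero);
``silent``
    no activity.

The mixed archetype's stimulus component adapts because a non-adapting
sum of the swim and stimulus drives is, after stimulus-triggered
averaging, collinear with the pure sustained response: no correlation
threshold could then separate the two archetypes.  Adaptation gives the
mixed archetype the intermediate phasic/tonic profile that makes the four
active archetypes genuinely distinct — the condition the analysis is
designed to detect.

All generation is driven by ``numpy.random.Generator``; fixing the seed
makes traces and movies bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import InvalidParameterError, InvalidSceneError
from .kinematics import TailTrace, write_tail_trace_csv
from .stimulus import StimulusSchedule, make_schedule

__all__ = [
    "ARCHETYPES",
    "CalciumKernel",
    "BoutParams",
    "PlantedBout",
    "NoiseParams",
    "SyntheticScene",
    "make_scene",
    "generate_tail_trace",
    "ground_truth_dff",
    "simulate_traces",
    "make_red_anatomy",
    "generate_movie",
    "write_simulation",
]

ARCHETYPES = ("swim_locked", "stim_on", "mixed", "stim_suppressed", "silent")

# Full experimental geometry preset (512 x 249 px); the desk-scale default
# below keeps generated movies small enough for routine testing.
EXPERIMENT_FRAME_SHAPE = (249, 512)
DEFAULT_FRAME_SHAPE = (128, 64)
DEFAULT_FRAME_RATE_HZ = 5.81
DEFAULT_BEHAVIOR_RATE_HZ = 250.0


@dataclass(frozen=True)
class CalciumKernel:
    """Slow-decay calcium impulse response, normalized to unit peak.

    Defaults (rise 0.05 s, decay 1.0 s) are of the order of GCaMP5
    kinetics; both time constants are configurable.
    """

    rise_tau: float = 0.05
    decay_tau: float = 1.0

    def __post_init__(self) -> None:
        if self.rise_tau <= 0 or self.decay_tau <= 0:
            raise InvalidParameterError("kernel time constants must be > 0")

    def sample(self, rate_hz: float, duration_s: float | None = None) -> np.ndarray:
        """Kernel sampled at ``rate_hz``, unit peak."""
        if duration_s is None:
            duration_s = self.rise_tau + 8.0 * self.decay_tau
        t = np.arange(0.0, duration_s, 1.0 / rate_hz)
        k = (1.0 - np.exp(-t / self.rise_tau)) * np.exp(-t / self.decay_tau)
        peak = k.max()
        if peak <= 0:
            raise InvalidParameterError("kernel peak is not positive")
        return k / peak


@dataclass(frozen=True)
class BoutParams:
    """Swim-bout statistics for the tail-trace generator.

    No numeric bout rates or amplitudes are reported for the experiments;
    these defaults are realistic for optomotor swimming in 5-6 dpf larvae
    and are the single fixed study condition for all tests.  The bout rate
    is sparse enough that a triggered window is dominated by its own
    triggering bout — the regime in which event-triggered averaging is
    informative.
    """

    motion_rate_hz: float = 0.15    # bout rate during motion
    static_rate_hz: float = 0.02    # spontaneous rate during static grating
    onset_boost: float = 0.0        # optional extra rate factor after motion onset
    boost_tau_s: float = 1.5        # decay of the onset boost
    beat_hz: float = 20.0           # tail-beat frequency within a bout
    duration_mean_s: float = 0.25
    duration_sigma: float = 0.3     # lognormal shape
    duration_range: tuple[float, float] = (0.15, 0.5)
    amplitude_mean_deg: float = 30.0
    amplitude_sd_deg: float = 5.0
    amplitude_range: tuple[float, float] = (10.0, 60.0)
    baseline_noise_deg: float = 1.0
    min_gap_s: float = 0.2          # refractory gap between bouts
    envelope_ramp_s: float = 0.04   # amplitude rise/fall time at bout edges

    def __post_init__(self) -> None:
        if self.motion_rate_hz < self.static_rate_hz:
            raise InvalidParameterError("motion bout rate must be >= static rate")
        if min(self.motion_rate_hz, self.static_rate_hz) < 0:
            raise InvalidParameterError("bout rates must be >= 0")
        if self.beat_hz <= 0 or self.duration_mean_s <= 0:
            raise InvalidParameterError("beat_hz and duration_mean_s must be > 0")


@dataclass(frozen=True)
class PlantedBout:
    """Ground-truth bout interval planted by the generator."""

    start_s: float
    end_s: float
    amplitude_deg: float = 0.0

    excluded: str = "none"

    @property
    def is_excluded(self) -> bool:
        return False


@dataclass(frozen=True)
class NoiseParams:
    """Movie noise: Poisson shot noise plus additive Gaussian read noise.

    ``photon_scale`` converts intensity units to expected photon counts;
    setting it to 0 disables shot noise, ``read_noise_sd = 0`` disables
    read noise.
    """

    photon_scale: float = 1.0
    read_noise_sd: float = 2.0

    @property
    def noise_free(self) -> bool:
        return self.photon_scale == 0 and self.read_noise_sd == 0


@dataclass
class SyntheticScene:
    """Planted ROI geometry and labels for one synthetic plane.

    ``footprints`` are per-ROI full-frame weight images, non-negative and
    normalized to unit sum.  ``ground_truth_traces`` (noiseless dF/F, one
    row per ROI) is filled in by :func:`simulate_traces` /
    :func:`generate_movie`.
    """

    frame_shape: tuple[int, int]
    footprints: np.ndarray
    archetypes: list[str]
    bleed_factor: float = 0.1
    seed: int | None = None
    ground_truth_traces: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.footprints = np.asarray(self.footprints, dtype=float)
        if self.footprints.ndim != 3 or self.footprints.shape[1:] != tuple(self.frame_shape):
            raise InvalidSceneError(
                f"footprints of shape {self.footprints.shape} do not fit frame "
                f"{self.frame_shape}"
            )
        if len(self.archetypes) != self.footprints.shape[0]:
            raise InvalidSceneError("one archetype label per ROI required")
        unknown = set(self.archetypes) - set(ARCHETYPES)
        if unknown:
            raise InvalidSceneError(f"unknown archetypes: {sorted(unknown)}")
        if np.any(self.footprints < 0):
            raise InvalidSceneError("footprints must be non-negative")
        sums = self.footprints.sum(axis=(1, 2))
        if np.any(sums <= 0):
            raise InvalidSceneError("every footprint needs positive total weight")
        self.footprints = self.footprints / sums[:, None, None]
        if self.bleed_factor < 0:
            raise InvalidSceneError("bleed_factor must be >= 0")

    @property
    def n_rois(self) -> int:
        return self.footprints.shape[0]

    def footprint_mask(self) -> np.ndarray:
        """Boolean union of all footprint supports."""
        return self.footprints.sum(axis=0) > 0

    def rois_of(self, archetype: str) -> np.ndarray:
        return np.flatnonzero([a == archetype for a in self.archetypes])


def _gaussian_blob(shape: tuple[int, int], center: tuple[int, int], sigma: float) -> np.ndarray:
    """2-D Gaussian truncated at 2 sigma, full-frame image."""
    r = int(np.ceil(2.0 * sigma))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    g = np.exp(-(yy**2 + xx**2) / (2.0 * sigma**2))
    g[yy**2 + xx**2 > (2.0 * sigma) ** 2] = 0.0
    img = np.zeros(shape)
    cy, cx = center
    if cy - r < 0 or cx - r < 0 or cy + r >= shape[0] or cx + r >= shape[1]:
        raise InvalidSceneError("blob does not fit inside the frame")
    img[cy - r : cy + r + 1, cx - r : cx + r + 1] = g
    return img


def make_scene(
    n_per_archetype: dict[str, int] | int = 20,
    frame_shape: tuple[int, int] = DEFAULT_FRAME_SHAPE,
    blob_sigma_px: float = 1.5,
    bleed_factor: float = 0.1,
    seed: int | None = 0,
) -> SyntheticScene:
    """Place non-overlapping Gaussian ROI footprints of known archetype.

    Blobs occupy randomly chosen cells of a grid whose cell size exceeds
    the blob support by two pixels, which guarantees non-overlap — and a
    gap of at least two pixels between supports, so the 2x2 spatial mean
    filter used downstream never mixes two ROIs.  ``n_per_archetype`` may
    be a single count applied to the four active archetypes (plus half as
    many silent ROIs) or an explicit mapping.
    """
    rng = np.random.default_rng(seed)
    if isinstance(n_per_archetype, int):
        counts = {a: n_per_archetype for a in ARCHETYPES if a != "silent"}
        counts["silent"] = max(1, n_per_archetype // 2)
    else:
        counts = {a: int(n) for a, n in n_per_archetype.items() if n > 0}
    n_total = sum(counts.values())

    r = int(np.ceil(2.0 * blob_sigma_px))
    box = 2 * r + 1
    cell = box + 2
    ny, nx = frame_shape[0] // cell, frame_shape[1] // cell
    if ny * nx < n_total:
        raise InvalidSceneError(
            f"frame {frame_shape} fits only {ny * nx} blobs of sigma "
            f"{blob_sigma_px}, need {n_total}"
        )
    cells = [(i, j) for i in range(ny) for j in range(nx)]
    order = rng.permutation(len(cells))[:n_total]

    labels = [a for a in counts for _ in range(counts[a])]
    rng.shuffle(labels)

    footprints = np.empty((n_total, *frame_shape))
    for k, ci in enumerate(order):
        i, j = cells[ci]
        center = (i * cell + 1 + r, j * cell + 1 + r)
        footprints[k] = _gaussian_blob(frame_shape, center, blob_sigma_px)

    return SyntheticScene(
        frame_shape=tuple(frame_shape),
        footprints=footprints,
        archetypes=labels,
        bleed_factor=bleed_factor,
        seed=seed,
    )


def _bout_rate(t: float, schedule: StimulusSchedule, params: BoutParams) -> float:
    for t_on, t_off in schedule.intervals:
        if t_on <= t < t_off:
            boost = params.onset_boost * np.exp(-(t - t_on) / params.boost_tau_s)
            return params.motion_rate_hz * (1.0 + boost)
    return params.static_rate_hz


def generate_tail_trace(
    schedule: StimulusSchedule,
    rate_hz: float = DEFAULT_BEHAVIOR_RATE_HZ,
    params: BoutParams = BoutParams(),
    seed: int | np.random.Generator | None = 0,
) -> tuple[TailTrace, list[PlantedBout]]:
    """Bend-angle trace with planted bouts and the exact planted intervals.

    Bout onsets follow an inhomogeneous Poisson process (thinning) whose
    rate is onset-boosted during motion; each bout is a Tukey-enveloped
    sinusoid at the tail-beat frequency, superimposed on low-amplitude
    Gaussian baseline noise.
    """
    from scipy.signal.windows import tukey

    if rate_hz <= 0:
        raise InvalidParameterError("rate_hz must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    duration = schedule.trial_duration
    n = int(round(duration * rate_hz))
    times = np.arange(n) / rate_hz
    angles = rng.normal(0.0, params.baseline_noise_deg, n)

    bouts: list[PlantedBout] = []
    lam_max = params.motion_rate_hz * (1.0 + params.onset_boost)
    if lam_max > 0:
        t = 0.0
        prev_end = -np.inf
        while True:
            t += rng.exponential(1.0 / lam_max)
            if t >= duration:
                break
            if rng.uniform() >= _bout_rate(t, schedule, params) / lam_max:
                continue
            if t < prev_end + params.min_gap_s:
                continue
            dur = float(
                np.clip(
                    rng.lognormal(np.log(params.duration_mean_s), params.duration_sigma),
                    *params.duration_range,
                )
            )
            if t + dur > duration:
                continue
            amp = float(
                np.clip(rng.normal(params.amplitude_mean_deg, params.amplitude_sd_deg),
                        *params.amplitude_range)
            )
            i0 = int(round(t * rate_hz))
            i1 = min(n, int(round((t + dur) * rate_hz)))
            if i1 - i0 < 2:
                continue
            tt = times[i0:i1] - t
            wave = amp * np.sin(2.0 * np.pi * params.beat_hz * tt)
            alpha = float(np.clip(2.0 * params.envelope_ramp_s / dur, 0.0, 1.0))
            wave *= tukey(i1 - i0, alpha=alpha)
            angles[i0:i1] += wave
            bouts.append(PlantedBout(start_s=t, end_s=t + dur, amplitude_deg=amp))
            prev_end = t + dur
    trace = TailTrace(times=times, angles=angles, rate_hz=rate_hz, provenance="synthetic")
    return trace, bouts


def _causal_conv(drive: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Causal convolution with steady-state initial history.

    The drive is assumed to have held its first value for one kernel
    length before t = 0, which removes the trial-start turn-on transient
    for sustained drives.
    """
    pad = np.full(kernel.size, drive[0])
    full = np.convolve(np.concatenate([pad, drive]), kernel)
    return full[kernel.size : kernel.size + drive.size]


def ground_truth_dff(
    scene: SyntheticScene,
    schedule: StimulusSchedule,
    bouts: list[PlantedBout],
    kernel: CalciumKernel = CalciumKernel(),
    frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ,
    transient_amp: float = 1.0,
    sustained_amp: float = 0.8,
    mixed_swim_weight: float = 0.1,
    adapt_tau_s: float = 1.0,
    gain_jitter_sd: float = 0.1,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless per-ROI dF/F traces on the imaging clock.

    Each archetype's drive (impulse train at bout onsets, boxcar over
    motion intervals, the mixed swim-plus-adapting-stimulus combination,
    or a positive baseline minus the boxcar floored at zero) is convolved
    with the calcium kernel and scaled so an isolated bout transient peaks
    at ``transient_amp`` and a sustained stimulus plateau sits at
    ``sustained_amp``.  The mixed archetype carries
    ``mixed_swim_weight * transient_amp`` bout transients on top of a
    stimulus drive that decays with ``adapt_tau_s`` during each motion
    period.  Per-ROI multiplicative gain jitter emulates expression-level
    variability.

    Returns ``(dff, frame_times)`` with ``dff`` of shape (n_rois, n_frames).
    """
    for b in bouts:
        if b.start_s < 0 or b.end_s > schedule.trial_duration:
            raise InvalidParameterError("bout outside the trial")
    if rng is None:
        rng = np.random.default_rng(scene.seed)
    n_frames = int(round(schedule.trial_duration * frame_rate_hz))
    frame_times = np.arange(n_frames) / frame_rate_hz
    k = kernel.sample(frame_rate_hz)
    ksum = k.sum()

    impulses = np.zeros(n_frames)
    for b in bouts:
        idx = int(round(b.start_s * frame_rate_hz))
        if 0 <= idx < n_frames:
            impulses[idx] += 1.0
    box = schedule.motion_mask(frame_times).astype(float)
    adapting = np.zeros(n_frames)
    for t_on, t_off in schedule.intervals:
        m = (frame_times >= t_on) & (frame_times < t_off)
        adapting[m] = np.exp(-(frame_times[m] - t_on) / adapt_tau_s)

    conv_imp = _causal_conv(impulses, k)                 # unit peak per isolated bout
    conv_box = _causal_conv(box, k) / ksum               # plateau ~1 during motion
    conv_adapt = _causal_conv(adapting, k) / ksum
    conv_sup = _causal_conv(np.maximum(1.0 - box, 0.0), k) / ksum

    shapes = {
        "swim_locked": transient_amp * conv_imp,
        "stim_on": sustained_amp * conv_box,
        "mixed": mixed_swim_weight * transient_amp * conv_imp
        + sustained_amp * conv_adapt,
        "stim_suppressed": sustained_amp * conv_sup,
        "silent": np.zeros(n_frames),
    }
    dff = np.empty((scene.n_rois, n_frames))
    for i, a in enumerate(scene.archetypes):
        gain = 1.0
        if gain_jitter_sd > 0:
            gain = float(np.clip(rng.normal(1.0, gain_jitter_sd), 0.5, 1.5))
        dff[i] = gain * shapes[a]
    scene.ground_truth_traces = dff
    return dff, frame_times


def simulate_traces(
    scene: SyntheticScene,
    schedule: StimulusSchedule,
    bouts: list[PlantedBout],
    kernel: CalciumKernel = CalciumKernel(),
    frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ,
    dff_noise_sd: float = 0.05,
    seed: int | np.random.Generator | None = 0,
    **gt_kwargs,
) -> tuple[np.ndarray, np.ndarray]:
    """Noisy per-ROI dF/F traces without rendering pixels.

    Equivalent to extracting ROI traces from a rendered movie at matched
    signal-to-noise; used where pixel data is not needed.  Returns
    ``(dff, frame_times)``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    clean, frame_times = ground_truth_dff(
        scene, schedule, bouts, kernel, frame_rate_hz, rng=rng, **gt_kwargs
    )
    noisy = clean + rng.normal(0.0, dff_noise_sd, clean.shape)
    return noisy, frame_times


def make_red_anatomy(
    scene: SyntheticScene,
    n_cells: int = 30,
    blob_sigma_px: float = 1.5,
    background: float = 20.0,
    intensity_range: tuple[float, float] = (50.0, 150.0),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Static red-channel anatomy image with blobs avoiding green footprints."""
    if rng is None:
        rng = np.random.default_rng(scene.seed)
    shape = scene.frame_shape
    occupied = scene.footprint_mask()
    img = np.full(shape, background)
    r = int(np.ceil(2.0 * blob_sigma_px))
    placed, attempts = 0, 0
    while placed < n_cells and attempts < 50 * n_cells:
        attempts += 1
        cy = int(rng.integers(r, shape[0] - r))
        cx = int(rng.integers(r, shape[1] - r))
        if occupied[max(0, cy - r) : cy + r + 1, max(0, cx - r) : cx + r + 1].any():
            continue
        amp = rng.uniform(*intensity_range)
        img += amp * _gaussian_blob(shape, (cy, cx), blob_sigma_px)
        placed += 1
    return img


def generate_movie(
    scene: SyntheticScene,
    schedule: StimulusSchedule,
    bouts: list[PlantedBout],
    kernel: CalciumKernel = CalciumKernel(),
    frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ,
    noise: NoiseParams = NoiseParams(),
    baseline_f0: float = 100.0,
    green_background: float = 30.0,
    simulate_bleed: bool = True,
    seed: int | np.random.Generator | None = 0,
    **gt_kwargs,
):
    """Render the two-channel movie for a scene.

    Each ROI's fluorescence ``F0 * (1 + dff)`` is projected through its
    footprint (scaled to unit peak) onto a constant green background; the
    red channel carries static anatomy.  When ``simulate_bleed`` is on,
    ``scene.bleed_factor`` times the clean red image leaks into the green
    channel before noise is applied.

    Returns ``(green, red, dff, frame_times)`` where green/red are
    ``boutmap.preprocess.Movie`` objects and ``dff`` is the noiseless
    ground truth per ROI.
    """
    from .preprocess import Movie

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dff, frame_times = ground_truth_dff(
        scene, schedule, bouts, kernel, frame_rate_hz, rng=rng, **gt_kwargs
    )
    n_frames = dff.shape[1]
    shape = scene.frame_shape
    n_px = shape[0] * shape[1]

    peak = scene.footprints.max(axis=(1, 2))
    shapes = (scene.footprints / peak[:, None, None]).reshape(scene.n_rois, n_px)
    flo = baseline_f0 * (1.0 + dff)                         # (n_rois, T)
    green_clean = green_background + (flo.T @ shapes)       # (T, n_px)
    green_clean = green_clean.reshape(n_frames, *shape)

    red_img = make_red_anatomy(scene, rng=rng)
    red_clean = np.broadcast_to(red_img, (n_frames, *shape)).copy()

    green_pre = green_clean
    if simulate_bleed and scene.bleed_factor > 0:
        green_pre = green_clean + scene.bleed_factor * red_img

    def _noisify(frames: np.ndarray) -> np.ndarray:
        out = frames
        if noise.photon_scale > 0:
            out = rng.poisson(out * noise.photon_scale) / noise.photon_scale
        if noise.read_noise_sd > 0:
            out = out + rng.normal(0.0, noise.read_noise_sd, out.shape)
        return np.maximum(out, 0.0)

    green = Movie(frames=_noisify(green_pre), frame_rate_hz=frame_rate_hz, channel="green")
    red = Movie(frames=_noisify(red_clean), frame_rate_hz=frame_rate_hz, channel="red")
    return green, red, dff, frame_times


def _bounding_box(footprint: np.ndarray) -> list[int]:
    ys, xs = np.nonzero(footprint)
    return [int(ys.min()), int(xs.min()), int(ys.max()), int(xs.max())]


def write_simulation(
    outdir,
    scene: SyntheticScene,
    schedule: StimulusSchedule,
    trace: TailTrace,
    bouts: list[PlantedBout],
    green=None,
    red=None,
) -> dict:
    """Write TIFF channels, the tail CSV and a ground-truth manifest JSON.

    Returns the manifest dictionary.
    """
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_tail_trace_csv(trace, outdir / "tail_trace.csv")
    if green is not None:
        tifffile.imwrite(outdir / "green.tif", green.frames.astype(np.float32))
    if red is not None:
        tifffile.imwrite(outdir / "red.tif", red.frames.astype(np.float32))
    manifest = {
        "frame_shape": list(scene.frame_shape),
        "bleed_factor": scene.bleed_factor,
        "seed": scene.seed,
        "schedule": {
            "trial_duration": schedule.trial_duration,
            "intervals": [list(iv) for iv in schedule.intervals],
        },
        "rois": [
            {"roi_id": i, "archetype": a, "bbox": _bounding_box(scene.footprints[i])}
            for i, a in enumerate(scene.archetypes)
        ],
        "bouts": [
            {"start_s": b.start_s, "end_s": b.end_s, "amplitude_deg": b.amplitude_deg}
            for b in bouts
        ],
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
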