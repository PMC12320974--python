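"""Ground-truth simulator for prepupal heart-tube recordings.

The *Drosophila* prepupal assay films the semi-transparent heart tube for
30 s at 100 frames/s and reads heart rate (HR), arrhythmicity index (AI) and
fractional shortening (FS) off an M-mode kymograph, before (BTP) and after
(ATP) tachypacing.  No recordings are deposited with the study this emulates,
so everything downstream is validated against this generator, which produces:

* stochastic beat-interval series with known event times,
* two-wall motion traces (raised-cosine contraction pulses),
* rendered kymographs and full image stacks with controlled noise,
* paired BTP/ATP cohorts across strains and treatments whose effect sizes
  are seeded from the study's printed group means (e.g. wild type loses
  14.35 BPM after pacing; the p.N210K variant reaches an AI of 0.46 A.U.).

Beat-interval model: base intervals are log-normal with requested mean and
coefficient of variation; with probability ``pause_prob`` an interval is
multiplied by ``pause_factor``, emulating the occasional long pauses of an
AF-like rhythm.  The first event falls at a uniform phase offset.  All
randomness is a pure function of the parameter set and seed.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import lognorm

from . import metrics as _metrics
from .beats import BeatIntervalSeries
from .exceptions import ConfigError, GeometryError, OverlappingPulsesError, TooFewBeatsError
from .kymo import KymographImage

__all__ = [
    "BeatModelParams",
    "TubeGeometry",
    "ImagingParams",
    "GroundTruth",
    "WallTrace",
    "GroupEffect",
    "CohortDesign",
    "CohortResult",
    "simulate_intervals",
    "simulate_wall_trace",
    "render_kymograph",
    "render_stack",
    "generate_cohort",
    "period_for_heart_rate",
    "cv_for_arrhythmicity_index",
    "interval_mixture_moments",
    "interval_mixture_median",
    "five_strain_design",
    "treatment_design",
    "null_design",
]

_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))  # Gaussian FWHM / sigma


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class BeatModelParams:
    """Stochastic beat-interval process for one recording.

    mean_period: seconds; period_cv: coefficient of variation of the
    log-normal base interval; pause_prob: per-beat probability of an
    arrhythmic pause; pause_factor: multiplier applied to a paused interval;
    duration: seconds; seed: RNG seed.
    """

    mean_period: float = 0.5
    period_cv: float = 0.05
    pause_prob: float = 0.0
    pause_factor: float = 2.0
    duration: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_period <= 0:
            raise ValueError("mean_period must be > 0")
        if self.period_cv < 0:
            raise ValueError("period_cv must be >= 0")
        if not 0 <= self.pause_prob < 1:
            raise ValueError("pause_prob must be in [0, 1)")
        if self.pause_factor < 1:
            raise ValueError("pause_factor must be >= 1")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")


@dataclass(frozen=True)
class TubeGeometry:
    """Heart-tube cross-section seen by the scan line (micrometres/seconds)."""

    diastolic_diameter: float = 50.0
    systolic_diameter: float = 30.0
    wall_thickness: float = 4.0
    contraction_width: float = 0.2  # seconds, full width of the pulse
    center_position: float = 40.0  # micrometres from field edge

    def __post_init__(self) -> None:
        if not 0 < self.systolic_diameter <= self.diastolic_diameter:
            raise ValueError("need 0 < systolic_diameter <= diastolic_diameter")
        if self.wall_thickness <= 0:
            raise ValueError("wall_thickness must be > 0")
        if self.contraction_width <= 0:
            raise ValueError("contraction_width must be > 0")


@dataclass(frozen=True)
class ImagingParams:
    """Line-scan acquisition parameters; defaults are the study's 30 s at 100 fps."""

    frame_rate: float = 100.0
    duration: float = 30.0
    pixel_size: float = 1.0  # micrometres per pixel
    line_length: int = 80  # pixels along the scan line
    noise_sd: float = 0.0  # additive Gaussian intensity noise
    background_level: float = 1.0
    wall_contrast: float = 0.8  # depth of the dark wall bands
    drift_rate: float = 0.0  # micrometres per second, tube-centre drift

    def __post_init__(self) -> None:
        if min(self.frame_rate, self.duration, self.pixel_size) <= 0:
            raise ValueError("frame_rate, duration and pixel_size must be > 0")
        if self.line_length < 2:
            raise ValueError("line_length must be >= 2 pixels")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))


@dataclass
class GroundTruth:
    """True event times, intervals and metric values for one simulated recording.

    The metric fields are computed from the true intervals/diameters with the
    same formulas the metrics module applies, so truth and pipeline output are
    directly comparable.
    """

    event_times: np.ndarray
    intervals: np.ndarray
    hr: float
    ai: float | None
    dd: float | None = None
    sd: float | None = None
    fs: float | None = None
    seed: int | None = None


@dataclass
class WallTrace:
    """Per-frame positions (micrometres) of the two heart walls."""

    times: np.ndarray
    lower: np.ndarray  # wall nearer the field origin
    upper: np.ndarray
    geometry: TubeGeometry
    imaging: ImagingParams

    @property
    def diameter(self) -> np.ndarray:
        return self.upper - self.lower


# ---------------------------------------------------------------------------
# interval process


def simulate_intervals(params: BeatModelParams) -> tuple[BeatIntervalSeries, GroundTruth]:
    """Simulate one recording's contraction event times.

    Base intervals are log-normal with mean ``mean_period`` and CV
    ``period_cv``; a fraction ``pause_prob`` are stretched by
    ``pause_factor``.  The first event falls at a uniform phase offset in
    ``[0, mean_period)`` and the series is truncated at ``duration``.
    Identical parameter sets (including seed) give identical output.
    """
    if params.duration < params.mean_period:
        raise TooFewBeatsError(
            f"too few beats: duration {params.duration} s is shorter than one "
            f"mean period {params.mean_period} s",
            n_events=0,
        )
    rng = np.random.default_rng(params.seed)
    t0 = rng.uniform(0.0, params.mean_period)

    m, c = params.mean_period, params.period_cv
    # draw in blocks until the cumulative time passes `duration`
    events = [t0]
    t = t0
    while t <= params.duration:
        n = max(8, int(np.ceil((params.duration - t) / m * 1.5)) + 4)
        if c > 0:
            sigma2 = np.log1p(c * c)
            mu = np.log(m) - sigma2 / 2.0
            iv = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)
        else:
            iv = np.full(n, m)
        if params.pause_prob > 0:
            paused = rng.random(n) < params.pause_prob
            iv = np.where(paused, iv * params.pause_factor, iv)
        for x in iv:
            t += x
            if t > params.duration:
                break
            events.append(t)

    times = np.asarray(events)
    if times.size < 2:
        raise TooFewBeatsError(
            f"too few beats: only {times.size} event(s) within {params.duration} s",
            n_events=int(times.size),
        )
    series = BeatIntervalSeries(event_times=times, duration=params.duration)
    truth = GroundTruth(
        event_times=times,
        intervals=series.intervals,
        hr=_metrics.heart_rate(series),
        ai=_metrics.arrhythmicity_index(series) if times.size >= 3 else None,
        seed=params.seed,
    )
    return series, truth


def interval_mixture_moments(
    mean_period: float, period_cv: float, pause_prob: float, pause_factor: float
) -> tuple[float, float]:
    """Exact mean and SD of the pause-mixture interval law."""
    m, c, p, f = mean_period, period_cv, pause_prob, pause_factor
    mean = m * (1.0 + p * (f - 1.0))
    ex2 = m * m * (1.0 + c * c) * (1.0 - p + p * f * f)
    var = max(ex2 - mean * mean, 0.0)
    return mean, float(np.sqrt(var))


def interval_mixture_median(
    mean_period: float, period_cv: float, pause_prob: float, pause_factor: float
) -> float:
    """Median of the pause-mixture interval law (closed form where possible)."""
    m, c, p, f = mean_period, period_cv, pause_prob, pause_factor
    if c == 0:
        return m if p < 0.5 else m * f
    sigma2 = np.log1p(c * c)
    base_median = m / np.sqrt(1.0 + c * c)
    if p == 0 or f == 1.0:
        return float(base_median)
    dist = lognorm(s=np.sqrt(sigma2), scale=base_median)

    def cdf(t: float) -> float:
        return (1.0 - p) * dist.cdf(t) + p * dist.cdf(t / f)

    lo, hi = base_median / 4.0, base_median * f * 4.0
    return float(brentq(lambda t: cdf(t) - 0.5, lo, hi))


def analytic_arrhythmicity_index(
    mean_period: float, period_cv: float, pause_prob: float, pause_factor: float
) -> float:
    """Population AI (SD / median) implied by the interval law."""
    _, sd = interval_mixture_moments(mean_period, period_cv, pause_prob, pause_factor)
    med = interval_mixture_median(mean_period, period_cv, pause_prob, pause_factor)
    return sd / med


def period_for_heart_rate(hr_bpm: float, pause_prob: float = 0.0, pause_factor: float = 2.0) -> float:
    """Base mean period giving the requested HR = 60 / mean(interval)."""
    if hr_bpm <= 0:
        raise ValueError("heart rate must be positive")
    return (60.0 / hr_bpm) / (1.0 + pause_prob * (pause_factor - 1.0))


@lru_cache(maxsize=4096)
def cv_for_arrhythmicity_index(
    target_ai: float, pause_prob: float = 0.0, pause_factor: float = 2.0
) -> float:
    """Base-interval CV that makes the population AI hit ``target_ai``.

    AI is scale-free, so the result does not depend on the mean period.
    Without pauses the closed form ``AI = c * sqrt(1 + c^2)`` is inverted
    directly; with pauses the residual CV is found by root bracketing.
    Raises when the pauses alone already exceed the target.
    """
    if target_ai < 0:
        raise ValueError("target AI must be >= 0")
    if pause_prob == 0 or pause_factor == 1.0:
        # c^2 = (sqrt(1 + 4 t^2) - 1) / 2
        return float(np.sqrt((np.sqrt(1.0 + 4.0 * target_ai**2) - 1.0) / 2.0))
    floor = analytic_arrhythmicity_index(1.0, 0.0, pause_prob, pause_factor)
    if target_ai < floor - 1e-12:
        raise ConfigError(
            f"target AI {target_ai:.3g} below the pause-only floor {floor:.3g}; "
            "reduce pause_prob or pause_factor"
        )
    if target_ai <= floor:
        return 0.0
    f = lambda c: analytic_arrhythmicity_index(1.0, c, pause_prob, pause_factor) - target_ai
    return float(brentq(f, 0.0, 5.0))


# ---------------------------------------------------------------------------
# wall kinematics and rendering


def simulate_wall_trace(
    series: BeatIntervalSeries, geometry: TubeGeometry, imaging: ImagingParams
) -> WallTrace:
    """Render per-frame wall positions for an event series.

    Between beats the wall-to-wall distance is the diastolic diameter; during
    a raised-cosine pulse of full width ``contraction_width`` centred at each
    event the distance dips to exactly the systolic diameter at pulse centre.
    The tube centre may drift linearly.
    """
    iv = series.intervals
    too_close = np.flatnonzero(iv < geometry.contraction_width)
    if too_close.size:
        i = int(too_close[0])
        raise OverlappingPulsesError(
            f"contraction pulses of events {i} and {i + 1} overlap: interval "
            f"{iv[i]:.4f} s < pulse width {geometry.contraction_width:.4f} s",
            pair=(i, i + 1),
        )
    n = imaging.n_frames
    t = np.arange(n) / imaging.frame_rate
    depth = np.zeros(n)
    half = geometry.contraction_width / 2.0
    for tc in series.event_times:
        lo = np.searchsorted(t, tc - half, "left")
        hi = np.searchsorted(t, tc + half, "right")
        if lo >= hi:
            continue
        phase = (t[lo:hi] - tc) * (np.pi / half)
        depth[lo:hi] = np.maximum(depth[lo:hi], 0.5 * (1.0 + np.cos(phase)))
    diameter = geometry.diastolic_diameter - depth * (
        geometry.diastolic_diameter - geometry.systolic_diameter
    )
    center = geometry.center_position + imaging.drift_rate * t
    return WallTrace(
        times=t,
        lower=center - diameter / 2.0,
        upper=center + diameter / 2.0,
        geometry=geometry,
        imaging=imaging,
    )


def _wall_image(trace: WallTrace, imaging: ImagingParams, dark_walls: bool) -> np.ndarray:
    """Noiseless (line_length, n_frames) rendering of the two wall bands."""
    extent = (imaging.line_length - 1) * imaging.pixel_size
    for name, wall in (("lower", trace.lower), ("upper", trace.upper)):
        bad = np.flatnonzero((wall < 0) | (wall > extent))
        if bad.size:
            raise GeometryError(
                f"{name} wall leaves the field of view at frame {int(bad[0])} "
                f"(position {wall[bad[0]]:.2f} um, field 0..{extent:.2f} um)"
            )
    y = (np.arange(imaging.line_length) * imaging.pixel_size)[:, None]
    sigma = trace.geometry.wall_thickness / _FWHM
    bands = np.exp(-0.5 * ((y - trace.lower[None, :]) / sigma) ** 2)
    bands += np.exp(-0.5 * ((y - trace.upper[None, :]) / sigma) ** 2)
    sign = -1.0 if dark_walls else 1.0
    return imaging.background_level + sign * imaging.wall_contrast * bands


def render_kymograph(
    trace: WallTrace,
    imaging: ImagingParams | None = None,
    seed: int | None = None,
    *,
    dark_walls: bool = True,
) -> KymographImage:
    """Render the synthetic M-mode kymograph for a wall trace.

    One column per frame; each wall is a Gaussian band whose FWHM equals the
    wall thickness, dark against a light background by default.  Additive
    Gaussian noise of SD ``noise_sd`` is applied when a seed is given or
    ``noise_sd > 0``; a fixed seed gives a bit-identical image.
    """
    imaging = imaging or trace.imaging
    img = _wall_image(trace, imaging, dark_walls)
    if imaging.noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, imaging.noise_sd, size=img.shape)
    return KymographImage(
        intensity=img,
        pixel_size=imaging.pixel_size,
        frame_rate=imaging.frame_rate,
        metadata={"synthetic": True, "seed": seed, "dark_walls": dark_walls},
    )


def render_stack(
    trace: WallTrace,
    imaging: ImagingParams | None = None,
    seed: int | None = None,
    *,
    width: int = 64,
    dark_walls: bool = True,
) -> np.ndarray:
    """Render a full (frames, height, width) image stack of the tube.

    The tube runs horizontally: each frame repeats the scan-line profile
    across ``width`` columns, so any vertical line through the tube
    reproduces :func:`render_kymograph`'s column for that frame in the
    noiseless case.  Noise is drawn independently per voxel.
    """
    imaging = imaging or trace.imaging
    profile = _wall_image(trace, imaging, dark_walls)  # (height, frames)
    stack = np.repeat(profile.T[:, :, None], width, axis=2)
    if imaging.noise_sd > 0:
        rng = np.random.default_rng(seed)
        stack = stack + rng.normal(0.0, imaging.noise_sd, size=stack.shape)
    return stack


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class GroupEffect:
    """Per (strain, treatment) cell: BTP baseline and ATP shifts.

    ``hr_btp`` and ``ai_btp`` set the baseline; ``d_hr`` is the ATP - BTP
    heart-rate shift in BPM, ``ai_atp`` the target post-pacing AI (None means
    unchanged), ``d_fs`` the FS shift in percentage points (the study finds
    none).  Arrhythmic cells may add pauses after pacing.
    """

    hr_btp: float = 120.0
    ai_btp: float = 0.08
    d_hr: float = 0.0
    ai_atp: float | None = None
    d_fs: float = 0.0
    pause_prob_btp: float = 0.0
    pause_prob_atp: float = 0.0
    pause_factor: float = 2.0


@dataclass
class CohortDesign:
    """Paired BTP/ATP study design across strains and treatments.

    Every (strain, treatment) cell needs a :class:`GroupEffect`.  Per-animal
    random effects: the animal's mean period is scaled by a normal factor
    with CV ``animal_cv``; the ATP heart-rate shift gets SD ``hr_shift_sd``
    (BPM); the interval CV gets a multiplicative jitter of CV ``ai_jitter``.
    Diameters: animal DD ~ N(dd_mean, dd_sd) um; FS ~ N(fs_btp, fs_sd) %
    with an extra per-condition wobble of SD ``fs_shift_sd``.
    """

    strains: list[str]
    treatments: list[str]
    n_per_group: int
    effects: dict[tuple[str, str], GroupEffect]
    seed: int = 0
    duration: float = 30.0
    animal_cv: float = 0.05
    hr_shift_sd: float = 3.0
    ai_jitter: float = 0.10
    dd_mean: float = 50.0
    dd_sd: float = 2.0
    fs_btp: float = 40.0
    fs_sd: float = 2.0
    fs_shift_sd: float = 1.5

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ConfigError("n_per_group must be >= 2")
        missing = [
            (s, t)
            for s, t in itertools.product(self.strains, self.treatments)
            if (s, t) not in self.effects
        ]
        if missing:
            raise ConfigError(f"effect table missing cells: {missing}")

    def effect_for(self, strain: str, treatment: str) -> GroupEffect:
        try:
            return self.effects[(strain, treatment)]
        except KeyError:
            raise ConfigError(
                f"unknown cell ({strain!r}, {treatment!r}); allowed strains "
                f"{self.strains}, treatments {self.treatments}"
            ) from None


@dataclass
class CohortResult:
    """Generated cohort: metrics table, per-recording ground truth, manifest."""

    table: pd.DataFrame
    ground_truth: dict[tuple[str, str], GroundTruth]
    design: CohortDesign
    manifest: pd.DataFrame | None = None


def _animal_recordings(
    effect: GroupEffect, design: CohortDesign, rng: np.random.Generator, rec_seeds: tuple[int, int]
) -> list[dict]:
    """Simulate one animal's paired BTP and ATP recordings at interval level."""
    mp_btp_cell = period_for_heart_rate(effect.hr_btp, effect.pause_prob_btp, effect.pause_factor)
    factor = max(rng.normal(1.0, design.animal_cv), 0.5)
    mp_btp = mp_btp_cell * factor
    hr_btp = 60.0 / (mp_btp * (1.0 + effect.pause_prob_btp * (effect.pause_factor - 1.0)))
    d_hr = rng.normal(effect.d_hr, design.hr_shift_sd)
    hr_atp = max(hr_btp + d_hr, 20.0)
    mp_atp = period_for_heart_rate(hr_atp, effect.pause_prob_atp, effect.pause_factor)

    ai_atp_target = effect.ai_atp if effect.ai_atp is not None else effect.ai_btp
    cvs = {
        "BTP": cv_for_arrhythmicity_index(effect.ai_btp, effect.pause_prob_btp, effect.pause_factor),
        "ATP": cv_for_arrhythmicity_index(ai_atp_target, effect.pause_prob_atp, effect.pause_factor),
    }
    dd = rng.normal(design.dd_mean, design.dd_sd)
    fs_btp = rng.normal(design.fs_btp, design.fs_sd)
    fs_atp = fs_btp + effect.d_fs + rng.normal(0.0, design.fs_shift_sd)

    out = []
    for cond, mp, fs, seed in (
        ("BTP", mp_btp, fs_btp, rec_seeds[0]),
        ("ATP", mp_atp, fs_atp, rec_seeds[1]),
    ):
        pause_prob = effect.pause_prob_btp if cond == "BTP" else effect.pause_prob_atp
        cv = cvs[cond] * max(rng.normal(1.0, design.ai_jitter), 0.0)
        params = BeatModelParams(
            mean_period=mp,
            period_cv=cv,
            pause_prob=pause_prob,
            pause_factor=effect.pause_factor,
            duration=design.duration,
            seed=seed,
        )
        series, truth = simulate_intervals(params)
        sd_diam = dd * (1.0 - fs / 100.0)
        truth.dd, truth.sd = dd, sd_diam
        truth.fs = (dd - sd_diam) / dd * 100.0
        out.append(
            {
                "condition": cond,
                "params": params,
                "series": series,
                "truth": truth,
                "hr_bpm": truth.hr,
                "ai_au": truth.ai,
                "fs_pct": truth.fs,
                "dd_um": dd,
                "sd_um": sd_diam,
                "n_beats": series.n_events,
                "seed": seed,
            }
        )
    return out


def generate_cohort(
    design: CohortDesign,
    *,
    render: str | None = None,
    out_dir: str | Path | None = None,
    imaging: ImagingParams | None = None,
    geometry: TubeGeometry | None = None,
) -> CohortResult:
    """Generate a paired BTP/ATP cohort from a design.

    With ``render=None`` (default) recordings exist at interval level only:
    the metrics table carries the ground-truth HR/AI/FS of every recording,
    which is what the statistics layer consumes.  With ``render="kymograph"``
    or ``"stack"`` each recording is additionally rendered and written as a
    TIFF plus JSON sidecar under ``out_dir``, and a manifest CSV links files,
    labels and seeds.  The whole cohort is reproducible from ``design.seed``.
    """
    if render not in (None, "kymograph", "stack"):
        raise ConfigError("render must be None, 'kymograph' or 'stack'")
    if render is not None and out_dir is None:
        raise ConfigError("out_dir is required when rendering")

    root = np.random.SeedSequence(design.seed)
    rows: list[dict] = []
    truths: dict[tuple[str, str], GroundTruth] = {}
    manifest_rows: list[dict] = []
    imaging = imaging or ImagingParams(duration=design.duration)

    cells = list(itertools.product(design.strains, design.treatments))
    cell_seqs = root.spawn(len(cells))
    for (strain, treatment), cell_seq in zip(cells, cell_seqs):
        effect = design.effect_for(strain, treatment)
        animal_seqs = cell_seq.spawn(design.n_per_group)
        for a_idx, a_seq in enumerate(animal_seqs):
            rng = np.random.default_rng(a_seq)
            rec_seeds = tuple(int(s) for s in a_seq.generate_state(2) >> 1)
            animal_id = f"{strain}_{treatment}_a{a_idx:02d}"
            for rec in _animal_recordings(effect, design, rng, rec_seeds):
                key = (animal_id, rec["condition"])
                truths[key] = rec["truth"]
                row = {
                    "animal_id": animal_id,
                    "strain": strain,
                    "treatment": treatment,
                    **{k: rec[k] for k in ("condition", "hr_bpm", "ai_au", "fs_pct",
                                            "dd_um", "sd_um", "n_beats", "seed")},
                }
                if render is not None:
                    path = _render_recording(
                        rec, design, imaging, geometry, Path(out_dir), animal_id, render
                    )
                    row["path"] = str(path)
                    manifest_rows.append(
                        {
                            "animal_id": animal_id,
                            "strain": strain,
                            "treatment": treatment,
                            "condition": rec["condition"],
                            "path": str(path),
                            "seed": rec["seed"],
                        }
                    )
                rows.append(row)

    table = pd.DataFrame(rows)
    manifest = pd.DataFrame(manifest_rows) if manifest_rows else None
    if manifest is not None:
        manifest.to_csv(Path(out_dir) / "manifest.csv", index=False)
    return CohortResult(table=table, ground_truth=truths, design=design, manifest=manifest)


def _render_recording(
    rec: dict,
    design: CohortDesign,
    imaging: ImagingParams,
    geometry: TubeGeometry | None,
    out_dir: Path,
    animal_id: str,
    render: str,
) -> Path:
    """Render one recording to TIFF + JSON sidecar; returns the TIFF path."""
    from . import io as _io

    truth = rec["truth"]
    geo = geometry or TubeGeometry()
    geo = replace(geo, diastolic_diameter=truth.dd, systolic_diameter=truth.sd)
    trace = simulate_wall_trace(rec["series"], geo, imaging)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = f"{animal_id}_{rec['condition']}"
    meta = {
        "animal_id": animal_id,
        "condition": rec["condition"],
        "frame_rate": imaging.frame_rate,
        "pixel_size": imaging.pixel_size,
        "seed": rec["seed"],
    }
    if render == "kymograph":
        kymo = render_kymograph(trace, imaging, seed=rec["seed"])
        path = out_dir / f"{stem}_kymo.tif"
        _io.write_kymograph(path, kymo)
    else:
        stack = render_stack(trace, imaging, seed=rec["seed"])
        path = out_dir / f"{stem}_stack.tif"
        _io.write_stack(path, stack, frame_rate=imaging.frame_rate, pixel_size=imaging.pixel_size)
    (out_dir / f"{stem}.json").write_text(json.dumps(meta, indent=1))
    return path


# ---------------------------------------------------------------------------
# study presets; numeric shifts follow the printed group means of the source
# cohorts (HR drops per strain; post-pacing AI for the arrhythmic variants)


def five_strain_design(n_per_group: int = 15, seed: int = 0) -> CohortDesign:
    """Baseline five-strain paired design (no drug treatment).

    Wild type and all four lamin variants lose heart rate after pacing; only
    p.N210K (AI 0.46 A.U.) and p.R264Q (0.15 A.U.) become arrhythmic; FS is
    unchanged throughout.  p.R264Q starts from a higher baseline HR.
    """
    effects = {
        ("WT", "none"): GroupEffect(d_hr=-14.35),
        ("dN", "none"): GroupEffect(d_hr=-20.0),
        ("R205W", "none"): GroupEffect(d_hr=-25.9),
        ("N210K", "none"): GroupEffect(d_hr=-22.3, ai_atp=0.46, pause_prob_atp=0.10),
        ("R264Q", "none"): GroupEffect(hr_btp=130.0, d_hr=-25.14, ai_atp=0.15, pause_prob_atp=0.05,
                                       pause_factor=1.5),
    }
    return CohortDesign(
        strains=["WT", "dN", "R205W", "N210K", "R264Q"],
        treatments=["none"],
        n_per_group=n_per_group,
        effects=effects,
        seed=seed,
    )


def treatment_design(n_per_group: int = 15, seed: int = 0) -> CohortDesign:
    """Drug-modulation design: WT / p.N210K / p.R264Q x DMSO / RVX-208 / taxol.

    Under vehicle (DMSO) all three strains become arrhythmic after pacing;
    RVX-208 prevents the AI rise in WT and p.R264Q but not p.N210K; taxol
    protects all three.  HR falls after pacing in every cell except
    taxol-treated p.R264Q.
    """
    base = {"WT": 120.0, "N210K": 120.0, "R264Q": 130.0}
    ai_dmso = {"WT": 0.20, "N210K": 0.46, "R264Q": 0.15}
    effects: dict[tuple[str, str], GroupEffect] = {}
    for s in base:
        effects[(s, "DMSO")] = GroupEffect(
            hr_btp=base[s], d_hr=-18.0, ai_atp=ai_dmso[s], pause_prob_atp=0.08
        )
        effects[(s, "RVX208")] = GroupEffect(
            hr_btp=base[s],
            d_hr=-18.0,
            ai_atp=0.46 if s == "N210K" else None,
            pause_prob_atp=0.08 if s == "N210K" else 0.0,
        )
        effects[(s, "taxol")] = GroupEffect(
            hr_btp=base[s], d_hr=-5.0 if s == "R264Q" else -18.0
        )
    return CohortDesign(
        strains=list(base),
        treatments=["DMSO", "RVX208", "taxol"],
        n_per_group=n_per_group,
        effects=effects,
        seed=seed,
    )


def null_design(n_per_group: int = 15, seed: int = 0) -> CohortDesign:
    """Single-cell design with no ATP effect (type-I error calibration)."""
    return CohortDesign(
        strains=["WT"],
        treatments=["none"],
        n_per_group=n_per_group,
        effects={("WT", "none"): GroupEffect(d_hr=0.0)},
        seed=seed,
    )
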