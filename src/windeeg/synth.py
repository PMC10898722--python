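"""Synthetic wind-pleasantness EEG experiments.

Emulates the study design: 3 sessions x 40 trials, each trial 2 s rest +
10 s wind + 6 s report, four wind velocities (0.44/1.0/2.0/4.0 m/s) in
pseudo-random order with no consecutive repeats, a 1.0-9.0 visual-analog
pleasantness report per trial, and 64-channel/512 Hz EEG in which band power
in six frontal regions covaries with the reported pleasantness while
optional velocity-locked activity sits in a non-ROI region.

Signal model per trial:

* pleasantness carrier — a band-limited (default alpha, 8-13 Hz) process,
  coherent across each ROI's vertices, with per-vertex amplitude
  ``roi_amp * (1 + effect_beta * (score - 5))`` in units of the per-vertex
  background sigma;
* velocity confound — a band-limited process in a designated non-ROI region
  with amplitude ``confound_gamma * velocity`` (same units);
* 1/f background at every vertex plus white sensor noise.

The background is sampled directly at the sensors as a 64-channel Gaussian
process with spatial covariance ``L L^T`` (Cholesky mixing of independent
pink-noise series) — the exact law of independent unit-variance pink sources
at all vertices projected through the lead field, at a fraction of the cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.fft

from .exceptions import InvalidParameterError, SchedulingError
from .forward import ForwardModel
from .geometry import DEFAULT_CONFOUND_REGION, PLEASANTNESS_ROIS, AtlasLabels, SourceSpace

FS = 512
REST_S = 2.0
WIND_S = 10.0
REPORT_S = 6.0
TRIAL_S = REST_S + WIND_S + REPORT_S

VELOCITIES = (0.44, 1.0, 2.0, 4.0)

#: Grand-mean pleasantness per velocity (m/s -> VAS score) used as the
#: generator's default; the second-strongest wind is the most pleasant and
#: the weakest the least.
DEFAULT_CONDITION_MEANS = {0.44: 4.3, 1.0: 5.5, 2.0: 6.9, 4.0: 5.3}


@dataclass
class TrialSchedule:
    """Ordered trial list: (session, trial index within session, velocity)."""

    trials: pd.DataFrame  # columns: session, trial, velocity
    seed: int

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def velocities(self) -> np.ndarray:
        return self.trials["velocity"].to_numpy()


@dataclass
class ParticipantProfile:
    """Generator parameters for one synthetic participant.

    Amplitude parameters (``roi_amp``, ``confound_gamma``) are expressed in
    units of the per-vertex background standard deviation, so they read as
    source-level signal-to-background ratios.
    """

    condition_means: dict[float, float] = field(
        default_factory=lambda: dict(DEFAULT_CONDITION_MEANS)
    )
    participant_offset: float = 0.0
    trial_noise_sd: float = 1.0
    effect_beta: float = 0.15
    confound_gamma: float = 0.5
    roi_amp: float = 2.0
    signal_band: tuple[float, float] = (8.0, 13.0)
    confound_band: tuple[float, float] = (14.0, 30.0)
    confound_region: str = DEFAULT_CONFOUND_REGION
    background_rms_uv: float = 10.0
    sensor_noise_uv: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trial_noise_sd < 0:
            raise InvalidParameterError("trial_noise_sd must be >= 0")
        for v, m in self.condition_means.items():
            if not 1.0 <= m <= 9.0:
                raise InvalidParameterError(
                    f"condition mean {m} for velocity {v} outside [1, 9]"
                )
        if self.roi_amp < 0 or self.confound_gamma < 0:
            raise InvalidParameterError("signal amplitudes must be >= 0")
        if self.background_rms_uv < 0 or self.sensor_noise_uv < 0:
            raise InvalidParameterError("noise amplitudes must be >= 0")

    def with_(self, **kwargs) -> "ParticipantProfile":
        return replace(self, **kwargs)


@dataclass
class Recording:
    """One participant's continuous multichannel EEG plus event list.

    ``data`` is (n_channels, n_samples) in microvolts at 512 Hz; sessions are
    laid out back to back. ``events`` has one row per marker with columns
    onset_sample, kind (wind_on / wind_off / report), session, trial,
    velocity, score.
    """

    data: np.ndarray
    fs: float
    channel_names: tuple[str, ...]
    events: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


def make_trial_schedule(
    n_sessions: int = 3,
    trials_per_session: int = 40,
    velocities: tuple[float, ...] = VELOCITIES,
    seed: int = 0,
    max_restarts: int = 1000,
) -> TrialSchedule:
    """Balanced pseudo-random velocity schedule with no consecutive repeats.

    Each session contains every velocity equally often; no two consecutive
    trials (including across session boundaries) share a velocity. Built by
    seeded sequential sampling proportional to remaining counts, restarting
    the session on a dead end.
    """
    if n_sessions < 1 or trials_per_session < 1:
        raise InvalidParameterError("need at least one session and one trial")
    if trials_per_session % len(velocities) != 0:
        raise SchedulingError(
            f"{trials_per_session} trials/session not divisible by "
            f"{len(velocities)} velocities (balanced design)"
        )
    if len(velocities) < 2 and trials_per_session > 1:
        raise SchedulingError("no-repeat constraint unsatisfiable with one velocity")

    per = trials_per_session // len(velocities)
    rng = np.random.default_rng(seed)
    vels = np.asarray(velocities, float)

    rows = []
    prev = np.nan
    restarts = 0
    session = 0
    while session < n_sessions:
        counts = np.full(len(vels), per, dtype=float)
        seq: list[float] = []
        last = prev
        ok = True
        for _ in range(trials_per_session):
            weights = counts.copy()
            if not np.isnan(last):
                weights[vels == last] = 0.0
            total = weights.sum()
            if total == 0:
                ok = False
                break
            choice = rng.choice(len(vels), p=weights / total)
            seq.append(vels[choice])
            counts[choice] -= 1
            last = vels[choice]
        if not ok:
            restarts += 1
            if restarts > max_restarts:
                raise SchedulingError(
                    "could not satisfy the no-repeat constraint "
                    f"after {max_restarts} restarts"
                )
            continue
        rows.extend(
            {"session": session, "trial": t, "velocity": v} for t, v in enumerate(seq)
        )
        prev = seq[-1]
        session += 1

    return TrialSchedule(trials=pd.DataFrame(rows), seed=seed)


def sample_pleasantness(
    velocity: float, profile: ParticipantProfile, rng: np.random.Generator
) -> float:
    """One visual-analog pleasantness report (1.0-9.0 in 0.1 steps)."""
    try:
        mean = profile.condition_means[velocity]
    except KeyError:
        raise InvalidParameterError(
            f"velocity {velocity} has no condition mean in the profile"
        ) from None
    raw = mean + profile.participant_offset + rng.normal(0.0, profile.trial_noise_sd)
    return float(np.clip(np.round(raw, 1), 1.0, 9.0))


def pink_noise(n_channels: int, n_samples: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f-power noise, shape (n_channels, n_samples), float32.

    Synthesised directly in the frequency domain: a complex Gaussian
    spectrum with amplitude proportional to f^-1/2 (zero DC), inverted by a
    single irfft per channel block.
    """
    n_bins = n_samples // 2 + 1
    amp = np.empty(n_bins, dtype=np.float32)
    amp[0] = 0.0  # kill DC
    amp[1:] = 1.0 / np.sqrt(np.arange(1, n_bins, dtype=np.float32))
    spec = amp * (
        rng.standard_normal((n_channels, n_bins), dtype=np.float32)
        + 1j * rng.standard_normal((n_channels, n_bins), dtype=np.float32)
    )
    out = scipy.fft.irfft(spec, n=n_samples, axis=-1)
    # analytic unit-variance normalisation (Hermitian expansion of the rfft):
    # Var(x_t) = 4 * sum_k amp_k^2 / n^2
    var = 4.0 * float((amp[1:] ** 2).sum()) / n_samples**2
    out /= np.float32(np.sqrt(var))
    return out


def bandlimited_noise(
    n_samples: int,
    band: tuple[float, float],
    rng: np.random.Generator,
    fs: float = FS,
    ramp_s: float = 0.1,
) -> np.ndarray:
    """Unit-RMS band-limited Gaussian carrier with cosine onset/offset ramps."""
    white = rng.standard_normal(n_samples, dtype=np.float32)
    spec = scipy.fft.rfft(white)
    freqs = scipy.fft.rfftfreq(n_samples, d=1.0 / fs)
    spec[(freqs < band[0]) | (freqs > band[1])] = 0.0
    x = scipy.fft.irfft(spec, n=n_samples)
    x /= x.std() or 1.0
    n_ramp = int(round(ramp_s * fs))
    if n_ramp > 0:
        ramp = (0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))).astype(x.dtype)
        x[:n_ramp] *= ramp
        x[-n_ramp:] *= ramp[::-1]
    return x


def simulate_recording(
    schedule: TrialSchedule,
    profile: ParticipantProfile,
    forward: ForwardModel,
    atlas: AtlasLabels,
    space: SourceSpace,
    rng: np.random.Generator | None = None,
) -> Recording:
    """Simulate the full experiment (all sessions, back to back) for one participant."""
    if not (forward.n_sources == space.n_sources == len(atlas.labels)):
        raise InvalidParameterError(
            "forward model, atlas and source space disagree on the source count"
        )
    if rng is None:
        rng = np.random.default_rng(profile.seed)

    lead = forward.lead_field
    # Cholesky factor of the background spatial covariance L L^T
    gram = lead @ lead.T
    jitter = 1e-10 * np.trace(gram) / gram.shape[0]
    chol = np.linalg.cholesky(gram + jitter * np.eye(gram.shape[0]))
    # scale source units so the mean background channel RMS is background_rms_uv
    channel_rms = np.sqrt(np.diag(gram))
    # python float so float32 blocks are not promoted to float64
    gain = float(profile.background_rms_uv / channel_rms.mean())

    # coherent patches: the pattern is the mean member column, so the
    # injected sensor amplitude does not grow with mesh resolution
    # (amp stays in units of the per-vertex background sigma)
    roi_patterns = np.column_stack(
        [
            gain * lead[:, atlas.vertices_of(name)].mean(axis=1)
            for name in PLEASANTNESS_ROIS
        ]
    ).astype(np.float32)
    confound_col = (
        gain * lead[:, atlas.vertices_of(profile.confound_region)].mean(axis=1)
    ).astype(np.float32)

    n_rest, n_wind, n_report = int(REST_S * FS), int(WIND_S * FS), int(REPORT_S * FS)
    n_trial = n_rest + n_wind + n_report
    sessions = sorted(schedule.trials["session"].unique())
    per_session = {s: schedule.trials[schedule.trials["session"] == s] for s in sessions}

    data_blocks = []
    event_rows = []
    offset = 0
    for s in sessions:
        trials = per_session[s]
        ns = n_trial * len(trials)
        block = gain * (chol.astype(np.float32) @ pink_noise(lead.shape[0], ns, rng))
        block += profile.sensor_noise_uv * rng.standard_normal(block.shape, dtype=np.float32)

        for k, (_, row) in enumerate(trials.iterrows()):
            velocity = float(row["velocity"])
            score = sample_pleasantness(velocity, profile, rng)
            t0 = k * n_trial
            wind0, wind1 = t0 + n_rest, t0 + n_rest + n_wind

            amp = profile.roi_amp * (1.0 + profile.effect_beta * (score - 5.0))
            amp = max(amp, 0.0)
            carriers = np.stack(
                [
                    bandlimited_noise(n_wind, profile.signal_band, rng)
                    for _ in range(roi_patterns.shape[1])
                ]
            ).astype(np.float32, copy=False)
            block[:, wind0:wind1] += roi_patterns @ (np.float32(amp) * carriers)

            c_amp = profile.confound_gamma * velocity
            if c_amp > 0:
                carrier = bandlimited_noise(n_wind, profile.confound_band, rng)
                block[:, wind0:wind1] += confound_col[:, None] * (
                    np.float32(c_amp) * carrier.astype(np.float32, copy=False)
                )

            base = offset + t0
            event_rows += [
                dict(onset_sample=base + n_rest, kind="wind_on", session=s,
                     trial=int(row["trial"]), velocity=velocity, score=score),
                dict(onset_sample=base + n_rest + n_wind, kind="wind_off", session=s,
                     trial=int(row["trial"]), velocity=velocity, score=score),
                dict(onset_sample=base + n_rest + n_wind, kind="report", session=s,
                     trial=int(row["trial"]), velocity=velocity, score=score),
            ]
        data_blocks.append(block)
        offset += ns

    events = pd.DataFrame(event_rows).sort_values(
        ["onset_sample", "kind"], kind="stable"
    ).reset_index(drop=True)
    return Recording(
        data=np.concatenate(data_blocks, axis=1),
        fs=float(FS),
        channel_names=forward.channel_names,
        events=events,
        meta={"seed": profile.seed, "profile": _profile_dict(profile)},
    )


def _profile_dict(profile: ParticipantProfile) -> dict:
    d = dict(profile.__dict__)
    d["condition_means"] = {str(k): v for k, v in profile.condition_means.items()}
    return d
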