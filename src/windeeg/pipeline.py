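"""Cohort orchestration: generate -> preprocess -> invert -> featurize ->
classify -> group statistics, with config, logging and provenance."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, stats
from .exceptions import InvalidParameterError, WindEEGError
from .features import aggregate_rois, band_powers, build_feature_table, welch_psd
from .forward import ForwardModel, build_lead_field
from .geometry import AtlasLabels, SourceSpace, build_atlas, build_source_space
from .inverse import apply_inverse, compute_eloreta_operator, compute_noise_covariance
from .preprocess import preprocess_recording
from .synth import ParticipantProfile, make_trial_schedule, simulate_recording

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of a cohort run; serialised verbatim into every output."""

    n_participants: int = 18
    source_level: int = 4
    atlas_seed: int = 0
    seed: int = 0
    families: tuple[str, ...] = classify.FAMILIES
    n_repetitions: int = 5
    tuning_budget: int = 20
    # generator
    effect_beta: float = 0.15
    confound_gamma: float = 0.5
    roi_amp: float = 2.0
    trial_noise_sd: float = 1.0
    offset_sd: float = 0.5
    background_rms_uv: float = 10.0
    sensor_noise_uv: float = 2.0
    # preprocessing / inverse
    ptp_thresh_uv: float = 150.0
    bad_channel_z: float = 5.0
    shrinkage: float = 0.1
    alpha_snr: float = 3.0
    # stages
    run_importance: bool = False

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise InvalidParameterError("n_participants must be >= 1")
        self.families = tuple(self.families)
        unknown = set(self.families) - set(classify.FAMILIES)
        if unknown:
            raise InvalidParameterError(f"unknown families in config: {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["families"] = list(self.families)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        return cls.from_dict(yaml.safe_load(text))

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class CohortAssets:
    """Geometry shared by every participant of a cohort."""

    space: SourceSpace
    atlas: AtlasLabels
    forward: ForwardModel


@dataclass
class ParticipantResult:
    index: int
    included: bool
    reason: str = ""
    protocol: classify.ProtocolResult | None = None
    importance: stats.ImportanceResult | None = None
    score_summary: pd.DataFrame | None = None
    error: str = ""


@dataclass
class CohortResult:
    config: RunConfig
    participants: list[ParticipantResult]
    accuracy_stats: stats.GroupStats | None
    importance_stats: stats.GroupStats | None = None
    score_table: pd.DataFrame | None = None

    def accuracy_matrix(self) -> dict[str, np.ndarray]:
        """Per-family per-included-participant mean accuracies."""
        out: dict[str, list[float]] = {f: [] for f in self.config.families}
        for p in self.participants:
            if p.included and p.protocol is not None:
                for f in self.config.families:
                    out[f].append(p.protocol.per_family_mean[f])
        return {f: np.asarray(v) for f, v in out.items()}


def build_cohort_assets(config: RunConfig) -> CohortAssets:
    space = build_source_space(config.source_level)
    atlas = build_atlas(space, seed=config.atlas_seed)
    forward = build_lead_field(space)
    return CohortAssets(space=space, atlas=atlas, forward=forward)


def participant_profile(config: RunConfig, index: int) -> ParticipantProfile:
    """Deterministic per-participant profile (offset drawn from the master seed)."""
    ss = np.random.SeedSequence([config.seed, 1000 + index])
    rng = np.random.default_rng(ss)
    offset = float(rng.normal(0.0, config.offset_sd))
    child_seed = int(rng.integers(2**31 - 1))
    return ParticipantProfile(
        participant_offset=offset,
        trial_noise_sd=config.trial_noise_sd,
        effect_beta=config.effect_beta,
        confound_gamma=config.confound_gamma,
        roi_amp=config.roi_amp,
        background_rms_uv=config.background_rms_uv,
        sensor_noise_uv=config.sensor_noise_uv,
        seed=child_seed,
    )


def participant_features(
    config: RunConfig, assets: CohortAssets, index: int, chunk_size: int = 24
) -> pd.DataFrame:
    """Simulate one participant and run the signal chain to the feature table."""
    profile = participant_profile(config, index)
    schedule = make_trial_schedule(seed=profile.seed)
    recording = simulate_recording(
        schedule, profile, assets.forward, assets.atlas, assets.space
    )
    _, windows = preprocess_recording(
        recording,
        channel_positions=assets.forward.channel_positions,
        z_thresh=config.bad_channel_z,
        ptp_thresh_uv=config.ptp_thresh_uv,
    )
    noise_cov = compute_noise_covariance(windows.baseline, shrinkage=config.shrinkage)
    operator = compute_eloreta_operator(
        assets.forward, noise_cov, alpha_snr=config.alpha_snr
    )

    band_blocks = []
    freqs = None
    n = windows.analysis.shape[0]
    for start in range(0, n, chunk_size):
        sl = slice(start, min(start + chunk_size, n))
        source = apply_inverse(
            windows.analysis[sl], operator, windows.baseline[sl]
        )
        freqs, psd = welch_psd(source, fs=windows.fs)
        region = aggregate_rois(psd, assets.atlas)
        band_blocks.append(band_powers(region, freqs))
    bands = np.concatenate(band_blocks, axis=0)
    return build_feature_table(bands, assets.atlas, windows.metadata)


def _score_summary(table: pd.DataFrame) -> pd.DataFrame:
    return (
        table.groupby("velocity")["score"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )


def run_participant(
    config: RunConfig, assets: CohortAssets, index: int
) -> ParticipantResult:
    table = participant_features(config, assets, index)
    labeled, included = classify.label_and_filter(table)
    summary = _score_summary(table)
    if not included:
        n_unpl, n_pl = labeled.class_counts()
        return ParticipantResult(
            index=index,
            included=False,
            reason=f"class counts (unpleasant={n_unpl}, pleasant={n_pl}) below 30",
            score_summary=summary,
        )
    protocol = classify.run_protocol(
        labeled,
        families=config.families,
        n_repetitions=config.n_repetitions,
        seed=int(
            np.random.default_rng(
                np.random.SeedSequence([config.seed, 2000 + index])
            ).integers(2**31 - 1)
        ),
        tuning_budget=config.tuning_budget,
    )
    if all(np.isnan(v) for v in protocol.per_family_mean.values()):
        return ParticipantResult(
            index=index,
            included=False,
            reason="no feasible folds",
            score_summary=summary,
        )
    importance = None
    if config.run_importance:
        importance = stats.band_ablation_importance(
            labeled,
            seed=protocol.seed,
            tuning_budget=config.tuning_budget,
            n_repetitions=config.n_repetitions,
        )
    return ParticipantResult(
        index=index,
        included=True,
        protocol=protocol,
        importance=importance,
        score_summary=summary,
    )


def run_cohort(config: RunConfig, out_dir: str | Path | None = None) -> CohortResult:
    """Run every participant, isolate failures, and compute group statistics."""
    assets = build_cohort_assets(config)
    participants: list[ParticipantResult] = []
    for index in range(config.n_participants):
        try:
            participants.append(run_participant(config, assets, index))
        except WindEEGError as exc:  # isolate per-participant failures
            logger.error("participant %d failed: %s", index, exc)
            participants.append(
                ParticipantResult(index=index, included=False, error=str(exc))
            )

    result = CohortResult(config=config, participants=participants, accuracy_stats=None)
    acc = result.accuracy_matrix()
    n_included = len(next(iter(acc.values()))) if acc else 0
    if n_included >= 2:
        try:
            result.accuracy_stats = stats.group_statistics(acc, mu0=0.5)
        except WindEEGError as exc:  # e.g. degenerate tiny cohorts
            logger.warning("group accuracy statistics unavailable: %s", exc)
    if config.run_importance and n_included >= 2:
        by_band = {
            band: np.array(
                [
                    p.importance.drops[band]
                    for p in participants
                    if p.included and p.importance is not None
                ]
            )
            for band in stats.BAND_NAMES
        }
        try:
            result.importance_stats = stats.group_statistics(by_band, mu0=0.0)
        except WindEEGError as exc:
            logger.warning("group importance statistics unavailable: %s", exc)

    frames = [
        p.score_summary.assign(participant=p.index)
        for p in participants
        if p.score_summary is not None
    ]
    if frames:
        pooled = pd.concat(frames, ignore_index=True)
        result.score_table = (
            pooled.groupby("velocity")
            .apply(
                lambda g: pd.Series(
                    {
                        "mean_score": np.average(g["mean"], weights=g["count"]),
                        "n_trials": g["count"].sum(),
                    }
                ),
                include_groups=False,
            )
            .reset_index()
        )

    if out_dir is not None:
        _write_cohort(result, Path(out_dir))
    return result


def _write_cohort(result: CohortResult, out: Path) -> None:
    from .io import write_json

    out.mkdir(parents=True, exist_ok=True)
    write_json(result.config.to_dict(), out / "config.json")
    rows = []
    for p in result.participants:
        entry = {
            "participant": p.index,
            "included": p.included,
            "reason": p.reason,
            "error": p.error,
        }
        if p.protocol is not None:
            entry["per_family_mean"] = p.protocol.per_family_mean
            entry["skipped_folds"] = p.protocol.skipped_folds
            entry["seed"] = p.protocol.seed
            for fam, a in p.protocol.accuracies.items():
                for (rep, fold), val in np.ndenumerate(a):
                    rows.append(
                        {
                            "participant": p.index,
                            "family": fam,
                            "repetition": rep,
                            "test_velocity": p.protocol.fold_velocities[fold],
                            "accuracy": val,
                        }
                    )
        if p.importance is not None:
            entry["importance"] = p.importance.drops
        write_json(entry, out / f"participant_{p.index:02d}.json")
    pd.DataFrame(rows).to_csv(out / "fold_accuracies.csv", index=False)
    (out / "report.md").write_text(make_report(result))


def report_from_dir(results_dir: str | Path) -> str:
    """Rebuild the cohort report from on-disk per-participant artifacts."""
    results_dir = Path(results_dir)
    config_path = results_dir / "config.json"
    if not config_path.exists():
        raise InvalidParameterError(f"no config.json under {results_dir}")
    config = RunConfig.from_dict(json.loads(config_path.read_text()))

    participants: list[ParticipantResult] = []
    for path in sorted(results_dir.glob("participant_*.json")):
        entry = json.loads(path.read_text())
        p = ParticipantResult(
            index=int(entry["participant"]),
            included=bool(entry["included"]),
            reason=entry.get("reason", ""),
            error=entry.get("error", ""),
        )
        if "per_family_mean" in entry:
            p.protocol = classify.ProtocolResult(
                accuracies={},
                fold_velocities=(),
                per_family_mean={
                    k: float(v) for k, v in entry["per_family_mean"].items()
                },
                seed=int(entry.get("seed", 0)),
            )
        participants.append(p)
    if not participants:
        raise InvalidParameterError(f"no participant artifacts under {results_dir}")

    result = CohortResult(config=config, participants=participants, accuracy_stats=None)
    acc = result.accuracy_matrix()
    if acc and len(next(iter(acc.values()))) >= 2:
        try:
            result.accuracy_stats = stats.group_statistics(acc, mu0=0.5)
        except WindEEGError as exc:
            logger.warning("group accuracy statistics unavailable: %s", exc)
    return make_report(result)


def make_report(result: CohortResult) -> str:
    """Human-readable cohort report (accuracy, statistics, scores, provenance)."""
    cfg = result.config
    lines = [
        "# Cohort report",
        "",
        f"config hash: `{cfg.config_hash}`",
        f"participants: {cfg.n_participants} "
        f"({sum(p.included for p in result.participants)} included)",
        "",
    ]
    excluded = [p for p in result.participants if not p.included]
    if excluded:
        lines.append("## Exclusions")
        lines += [
            f"- participant {p.index}: {p.reason or p.error}" for p in excluded
        ]
        lines.append("")

    if result.accuracy_stats is not None:
        g = result.accuracy_stats
        lines += [
            "## Classification accuracy",
            "",
            "| classifier | mean | sd | t | p (Holm) |",
            "|---|---|---|---|---|",
        ]
        for name in g.condition_names:
            t = g.t_tests[name]
            lines.append(
                f"| {name} | {g.means[name]:.3f} | {g.sds[name]:.3f} "
                f"| {t.t:.2f} | {g.p_holm[name]:.4f} |"
            )
        if g.anova is not None:
            a = g.anova
            lines += [
                "",
                f"RM-ANOVA across classifiers: F({a.df1}, {a.df2}) = {a.F:.2f}, "
                f"eps = {a.epsilon:.2f}, corrected p = {a.p:.3f}",
            ]
        lines.append("")

    included = [p for p in result.participants if p.included and p.protocol]
    if included:
        families = list(cfg.families)
        lines += [
            "## Per-participant accuracy",
            "",
            "| participant | " + " | ".join(families) + " |",
            "|" + "---|" * (len(families) + 1),
        ]
        for p in included:
            cells = " | ".join(
                f"{p.protocol.per_family_mean.get(f, float('nan')):.3f}"
                for f in families
            )
            lines.append(f"| {p.index} | {cells} |")
        lines.append("")

    if result.importance_stats is not None:
        g = result.importance_stats
        lines += [
            "## Band-ablation feature importance",
            "",
            "| band | mean drop | sd | p (Holm) |",
            "|---|---|---|---|",
        ]
        for name in g.condition_names:
            lines.append(
                f"| {name} | {g.means[name]:.3f} | {g.sds[name]:.3f} "
                f"| {g.p_holm[name]:.4f} |"
            )
        lines.append("")

    if result.score_table is not None:
        lines += ["## Pleasantness scores", "", "| velocity (m/s) | mean score | trials |", "|---|---|---|"]
        for _, row in result.score_table.iterrows():
            lines.append(
                f"| {row['velocity']} | {row['mean_score']:.2f} | {int(row['n_trials'])} |"
            )
        lines.append("")
    return "\n".join(lines)
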