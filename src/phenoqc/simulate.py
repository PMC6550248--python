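"""Synthetic digital-phenotyping cohort generator.

Emulates a smartphone study in which battery-constrained sensors sample
on alternating on/off cycles (accelerometer 10 Hz, 60 s on / 60 s off;
GPS 1 Hz, 60 s on / 600 s off) and subjects receive a symptom survey at
10 a.m. every Monday, Wednesday and Friday.  Controlled missingness is
injected at three levels: whole-burst dropout (probability ``pi_b``),
burst truncation (the realised on-cycle lasts ``d * U`` seconds with
``U ~ Uniform(t_low, 1)``), and within-burst ping thinning (each ping
retained with probability ``pi_p``).

Survey behaviour is driven by a known generative process: weekly mean
domain scores follow the random-intercept regression

    Y_ij = b0 + mu_i + b . X_{i, j - l*} + e_ij

on the *realised* data-quality covariates X = (A, G, V, C, T) of the
week lagged by the configured true lag ``l*``, view latencies follow a
two-component log-normal mixture (bimodal: immediate vs delayed
responders), and survey completion is Bernoulli with a logistic link to
the latent symptom level.  Item responses are integers obtained by
largest-remainder apportionment of the continuous weekly score, so the
observed weekly domain mean equals the generated outcome up to a
rounding error bounded by 1/(2k) for a k-item domain.  The exact
continuous outcomes, subject intercepts and realised covariates are
exported as ground truth.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from . import __version__
from .bursts import daily_metrics
from .schedules import DEFAULT_SCHEDULES, SECONDS_PER_DAY, SamplingSchedule
from .surveys import DomainMap, SurveyEvent, default_domain_map
from .weekly import COVARIATES

#: Monday 2023-01-02 00:00:00 UTC — default enrollment epoch of subject 1.
DEFAULT_ENROLLMENT_EPOCH = 1_672_617_600

_SENSOR_PAYLOADS = {
    "accelerometer": ("x", "y", "z"),
    "gps": ("lat", "lon", "accuracy"),
}


@dataclass(frozen=True)
class MissingnessConfig:
    """Missingness mechanism for one sensor stream."""

    burst_dropout: float = 0.0       # pi_b: P(an on-cycle records nothing)
    truncation_low: float = 1.0      # lower bound of the Uniform truncation draw
    ping_retention: float = 1.0      # pi_p: P(an emitted ping is kept)

    def __post_init__(self) -> None:
        for name in ("burst_dropout", "ping_retention"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if not 0.0 < self.truncation_low <= 1.0:
            raise ValueError("truncation_low must lie in (0, 1]")


@dataclass(frozen=True)
class SurveySimConfig:
    """Prompt schedule and response-behaviour parameters.

    Weekdays are 0=Monday..6=Sunday; the default prompts fire at
    10:00 on Monday, Wednesday and Friday.  View latency is a mixture
    of two log-normals (seconds): an immediate component and a delayed
    one.  Completion is Bernoulli with probability
    ``expit(intercept + slope * (s - b0))`` where ``s`` is the
    subject-week latent symptom level.  Latencies are capped at
    ``max_latency`` (the survey expires before the next prompt window).
    """

    prompt_weekdays: tuple[int, ...] = (0, 2, 4)
    prompt_hour: float = 10.0
    view_prob: float = 0.95
    mixture_weight: float = 0.5          # weight of the immediate component
    view_medians: tuple[float, float] = (30.0, 3600.0)
    view_sigmas: tuple[float, float] = (0.8, 1.0)
    completion_intercept: float = 2.2
    completion_slope: float = -0.5
    completion_median: float = 180.0
    completion_sigma: float = 0.6
    max_latency: float = 48 * 3600.0


@dataclass(frozen=True)
class TruthConfig:
    """Known coefficients of the generative weekly outcome model.

    The defaults are a realism preset: effect signs follow the
    qualitative associations the metrics are expected to carry (worse
    scores with lower accelerometer coverage, higher GPS coverage,
    faster viewing, slower completion, fewer completed surveys) at
    magnitudes that keep weekly scores interior to the 0-3 scale.
    Calibration studies pass their own coefficients explicitly.
    """

    beta0: float = 1.2
    beta: tuple[float, float, float, float, float] = (-0.3, 0.2, -3e-5, 2e-4, -0.05)
    sigma_subject: float = 0.3
    sigma_resid: float = 0.2
    true_lag: int = 1

    def __post_init__(self) -> None:
        if self.sigma_subject < 0 or self.sigma_resid < 0:
            raise ValueError("variance components must be non-negative")
        if len(self.beta) != len(COVARIATES):
            raise ValueError(f"beta must have {len(COVARIATES)} entries")
        if self.true_lag < 1:
            raise ValueError("true_lag must be >= 1")


@dataclass(frozen=True)
class SimulationConfig:
    """Full study configuration; a fixed seed makes output byte-identical."""

    n_subjects: int = 16
    n_weeks: int = 13
    n_days: int | None = None            # defaults to 7 * n_weeks
    schedules: dict[str, SamplingSchedule] = field(
        default_factory=lambda: dict(DEFAULT_SCHEDULES)
    )
    missingness: dict[str, MissingnessConfig] = field(
        default_factory=lambda: {
            "accelerometer": MissingnessConfig(0.25, 0.56, 0.80),
            "gps": MissingnessConfig(0.30, 0.70, 0.85),
        }
    )
    survey: SurveySimConfig = field(default_factory=SurveySimConfig)
    truth: TruthConfig = field(default_factory=TruthConfig)
    seed: int = 0
    enrollment_epoch: int = DEFAULT_ENROLLMENT_EPOCH
    enrollment_stagger_days: int = 1

    @property
    def days(self) -> int:
        return self.n_days if self.n_days is not None else 7 * self.n_weeks

    @property
    def weeks(self) -> int:
        return self.n_weeks

    def subject_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_subjects)]

    def enrollment_s(self, index: int) -> float:
        return float(self.enrollment_epoch + index * self.enrollment_stagger_days * 86_400)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["schedules"] = {
            k: dataclasses.asdict(v) for k, v in self.schedules.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "schedules" in d:
            d["schedules"] = {
                k: SamplingSchedule(**v) for k, v in d["schedules"].items()
            }
        if "missingness" in d:
            d["missingness"] = {
                k: MissingnessConfig(**v) for k, v in d["missingness"].items()
            }
        if "survey" in d:
            sv = dict(d["survey"])
            for key in ("prompt_weekdays", "view_medians", "view_sigmas"):
                if key in sv:
                    sv[key] = tuple(sv[key])
            d["survey"] = SurveySimConfig(**sv)
        if "truth" in d:
            tr = dict(d["truth"])
            if "beta" in tr:
                tr["beta"] = tuple(tr["beta"])
            d["truth"] = TruthConfig(**tr)
        return cls(**d)


def zero_missingness_config(**overrides) -> SimulationConfig:
    """A fully compliant study: no sensor missingness, full survey adherence."""
    base = SimulationConfig(**overrides)
    return dataclasses.replace(
        base,
        missingness={name: MissingnessConfig() for name in base.schedules},
        survey=dataclasses.replace(
            base.survey, view_prob=1.0, completion_intercept=50.0, completion_slope=0.0
        ),
    )


# ---------------------------------------------------------------------------
# sensor streams
# ---------------------------------------------------------------------------

def simulate_pings(
    schedule: SamplingSchedule,
    missingness: MissingnessConfig,
    n_days: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate one sensor stream; returns ping times in seconds from enrollment.

    On-cycles start every ``d + r`` seconds from enrollment and run
    continuously across day boundaries (the device does not re-anchor
    its cycle at midnight).  For each scheduled on-cycle: drop it with
    probability ``pi_b``; otherwise draw a truncation fraction
    ``U ~ Uniform(t_low, 1)`` and emit ``ceil(f * d * U)`` pings at
    spacing ``1/f``, each retained with probability ``pi_p``.
    """
    horizon = n_days * SECONDS_PER_DAY
    n_cycles = int(math.ceil(horizon / schedule.period))
    starts = np.arange(n_cycles, dtype=float) * schedule.period
    starts = starts[starts < horizon]

    if missingness.burst_dropout > 0:
        keep = rng.random(starts.size) >= missingness.burst_dropout
        starts = starts[keep]
    if starts.size == 0:
        return np.empty(0)

    full = int(round(schedule.f * schedule.d))
    if missingness.truncation_low < 1.0:
        u = rng.uniform(missingness.truncation_low, 1.0, starts.size)
        counts = np.ceil(schedule.f * schedule.d * u).astype(np.int64)
    else:
        counts = np.full(starts.size, full, dtype=np.int64)

    total = int(counts.sum())
    base = np.repeat(starts, counts)
    offsets = np.arange(total, dtype=np.int64) - np.repeat(
        np.cumsum(counts) - counts, counts
    )
    ts = base + offsets / schedule.f
    if missingness.ping_retention < 1.0:
        ts = ts[rng.random(total) < missingness.ping_retention]
    return ts


def to_epoch_ms(seconds_from_enrollment: np.ndarray, enrollment_s: float) -> np.ndarray:
    """Convert relative ping times to integer epoch milliseconds."""
    return np.round((seconds_from_enrollment + enrollment_s) * 1000.0).astype(np.int64)


def expected_coverage(
    schedule: SamplingSchedule, missingness: MissingnessConfig
) -> float:
    """Approximate expected daily coverage under the missingness mechanism.

    ``(1 - pi_b) * pi_p * E[U]`` with ``U ~ Uniform(t_low, 1)``;
    ignores the sub-ping effect of the ceiling in the truncated ping
    count, which is below one ping per burst.
    """
    mean_trunc = (missingness.truncation_low + 1.0) / 2.0
    return (1.0 - missingness.burst_dropout) * missingness.ping_retention * mean_trunc


# ---------------------------------------------------------------------------
# surveys and outcomes
# ---------------------------------------------------------------------------

def _apportion_items(target: float, items: tuple[str, ...]) -> dict[str, int]:
    """Integer Likert responses whose mean is the closest multiple of 1/k."""
    k = len(items)
    clipped = min(max(target, 0.0), 3.0)
    units = int(round(clipped * k))
    base, rem = divmod(units, k)
    return {item: base + (1 if idx < rem else 0) for idx, item in enumerate(items)}


def baseline_covariates(config: SimulationConfig) -> dict[str, float]:
    """Population-level covariate values used before the true lag is reachable."""
    sv = config.survey
    w = sv.mixture_weight
    v0 = w * sv.view_medians[0] * math.exp(sv.view_sigmas[0] ** 2 / 2) + (1 - w) * (
        sv.view_medians[1] * math.exp(sv.view_sigmas[1] ** 2 / 2)
    )
    c0 = sv.completion_median * math.exp(sv.completion_sigma ** 2 / 2)
    t0 = 3.0 * sv.view_prob * float(expit(sv.completion_intercept))
    out = {"V": v0, "C": c0, "T": t0}
    roles = {"accelerometer": "A", "gps": "G"}
    for sensor, role in roles.items():
        if sensor in config.schedules:
            out[role] = expected_coverage(
                config.schedules[sensor], config.missingness[sensor]
            )
        else:
            out[role] = 0.0
    return out


def _draw_view_latency(sv: SurveySimConfig, rng: np.random.Generator) -> float:
    fast = rng.random() < sv.mixture_weight
    median = sv.view_medians[0] if fast else sv.view_medians[1]
    sigma = sv.view_sigmas[0] if fast else sv.view_sigmas[1]
    return float(min(rng.lognormal(math.log(median), sigma), sv.max_latency - 1.0))


def simulate_surveys(
    config: SimulationConfig,
    subject_id: str,
    mu: float,
    weekly_ag: pd.DataFrame,
    enrollment_s: float,
    rng: np.random.Generator,
    domain_map: DomainMap | None = None,
) -> tuple[list[SurveyEvent], pd.DataFrame]:
    """Generate the survey events and ground-truth weekly rows for one subject.

    ``weekly_ag`` carries the realised weekly sensor coverages (columns
    ``week, A, G``) computed from the subject's simulated streams; they
    enter the outcome equation at the configured true lag together with
    the realised survey covariates of that week.
    """
    domain_map = domain_map or default_domain_map()
    sv, truth = config.survey, config.truth
    beta = np.asarray(truth.beta)
    x0 = baseline_covariates(config)
    ag = weekly_ag.set_index("week")

    enroll_weekday = int(((enrollment_s // 86_400) + 3) % 7)  # epoch day 0 = Thursday(=3)

    realized: dict[int, dict[str, float]] = {}
    events: list[SurveyEvent] = []
    truth_rows = []
    counter = 0
    for week in range(1, config.weeks + 1):
        lw = week - truth.true_lag
        if lw >= 1 and lw in realized:
            x = dict(realized[lw])
            for key, val in x.items():
                if isinstance(val, float) and math.isnan(val):
                    x[key] = x0[key]
        else:
            x = dict(x0)
        xvec = np.array([x[c] for c in COVARIATES])
        latent = truth.beta0 + mu + float(beta @ xvec)
        eps = rng.normal(0.0, truth.sigma_resid, len(domain_map.labels))
        y = {dom: latent + eps[k] for k, dom in enumerate(domain_map.labels)}

        week_start_day = (week - 1) * 7
        view_lats, comp_lats, n_completed = [], [], 0
        for day in range(week_start_day, min(week_start_day + 7, config.days)):
            weekday = (enroll_weekday + day) % 7
            if weekday not in sv.prompt_weekdays:
                continue
            delivered_rel = day * 86_400.0 + sv.prompt_hour * 3600.0
            counter += 1
            event = SurveyEvent(
                subject_id=subject_id,
                survey_id=f"{subject_id}-{counter:03d}",
                delivered_ts=enrollment_s + delivered_rel,
            )
            if rng.random() < sv.view_prob:
                vlat = _draw_view_latency(sv, rng)
                event.first_view_ts = event.delivered_ts + vlat
                view_lats.append(vlat)
                p_complete = float(
                    expit(sv.completion_intercept + sv.completion_slope * (latent - truth.beta0))
                )
                if rng.random() < p_complete:
                    clat = float(rng.lognormal(math.log(sv.completion_median), sv.completion_sigma))
                    clat = min(clat, sv.max_latency - vlat - 1.0)
                    event.submit_ts = event.first_view_ts + clat
                    comp_lats.append(clat)
                    n_completed += 1
                    responses = {}
                    for dom in domain_map.labels:
                        responses.update(_apportion_items(y[dom], domain_map.items_for(dom)))
                    event.responses = responses
            events.append(event)

        row = ag.loc[week] if week in ag.index else None
        realized[week] = {
            "A": float(row["A"]) if row is not None else math.nan,
            "G": float(row["G"]) if row is not None else math.nan,
            "V": float(np.mean(view_lats)) if view_lats else math.nan,
            "C": float(np.mean(comp_lats)) if comp_lats else math.nan,
            "T": float(n_completed),
        }
        truth_rows.append(
            {
                "subject_id": subject_id,
                "week": week,
                **realized[week],
                "latent": latent,
                **{f"Y_{dom}": y[dom] for dom in domain_map.labels},
            }
        )
    return events, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# whole-cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class SubjectData:
    """In-memory simulated data for one subject."""

    subject_id: str
    enrollment_s: float
    mu: float
    sensors: dict[str, np.ndarray]       # relative ping times, seconds
    events: list[SurveyEvent]
    daily: pd.DataFrame                  # daily metrics per sensor
    truth: pd.DataFrame                  # weekly ground truth


def _subject_streams(config: SimulationConfig, index: int):
    ss = np.random.SeedSequence(config.seed)
    child = ss.spawn(config.n_subjects)[index]
    sensor_names = sorted(config.schedules)
    streams = child.spawn(2 * len(sensor_names) + 1)
    sensor_rngs = {n: np.random.default_rng(streams[k]) for k, n in enumerate(sensor_names)}
    payload_rngs = {
        n: np.random.default_rng(streams[len(sensor_names) + k])
        for k, n in enumerate(sensor_names)
    }
    survey_rng = np.random.default_rng(streams[-1])
    return sensor_rngs, payload_rngs, survey_rng


def simulate_subject(
    config: SimulationConfig,
    index: int,
    domain_map: DomainMap | None = None,
) -> SubjectData:
    """Simulate one subject's sensor streams, surveys and ground truth."""
    domain_map = domain_map or default_domain_map()
    sid = config.subject_ids()[index]
    enroll = config.enrollment_s(index)
    sensor_rngs, _, survey_rng = _subject_streams(config, index)

    mu = float(survey_rng.normal(0.0, config.truth.sigma_subject))
    sensors, daily_frames = {}, []
    for name in sorted(config.schedules):
        schedule = config.schedules[name]
        ts = simulate_pings(schedule, config.missingness[name], config.days, sensor_rngs[name])
        sensors[name] = ts
        daily_frames.append(daily_metrics(ts, schedule, 0.0, config.days, subject_id=sid))
    daily = pd.concat(daily_frames, ignore_index=True)

    daily["week"] = (daily["day_index"] - 1) // 7 + 1
    weekly_ag = (
        daily.groupby(["sensor", "week"], as_index=False)["coverage"]
        .mean()
        .pivot(index="week", columns="sensor", values="coverage")
        .rename(columns={"accelerometer": "A", "gps": "G"})
        .reset_index()
    )
    for col in ("A", "G"):
        if col not in weekly_ag:
            weekly_ag[col] = math.nan
    daily = daily.drop(columns="week")

    events, truth = simulate_surveys(
        config, sid, mu, weekly_ag, enroll, survey_rng, domain_map
    )
    return SubjectData(sid, enroll, mu, sensors, events, daily, truth)


def simulate_study(
    config: SimulationConfig,
    outdir: str | Path,
    force: bool = False,
    domain_map: DomainMap | None = None,
) -> Path:
    """Simulate the whole cohort and write the study directory.

    Layout: ``sensors/<subject>_<sensor>.csv`` (``timestamp_ms`` plus
    payload columns), ``surveys.csv`` (long format, one row per item),
    ``ground_truth/{subjects,weekly}.csv``, ``config.yaml`` and
    ``manifest.json`` with per-file SHA-256 digests.  Refuses to write
    into a non-empty directory unless ``force`` is set.
    """
    from .io import write_pings_csv, write_surveys_csv, write_yaml_config

    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"output directory {outdir} is not empty (use force=True)")
    (outdir / "sensors").mkdir(parents=True, exist_ok=True)
    (outdir / "ground_truth").mkdir(exist_ok=True)
    domain_map = domain_map or default_domain_map()

    manifest_subjects, all_events, truths, mus = [], [], [], []
    files: dict[str, str] = {}
    for i in range(config.n_subjects):
        sub = simulate_subject(config, i, domain_map)
        _, payload_rngs, _ = _subject_streams(config, i)
        entry = {"id": sub.subject_id, "enrollment_ms": int(round(sub.enrollment_s * 1000)),
                 "files": {}}
        for name, ts in sub.sensors.items():
            rel = f"sensors/{sub.subject_id}_{name}.csv"
            payload = _SENSOR_PAYLOADS.get(name, ("v1", "v2", "v3"))
            write_pings_csv(
                outdir / rel,
                to_epoch_ms(ts, sub.enrollment_s),
                payload_columns=payload,
                rng=payload_rngs[name],
            )
            entry["files"][name] = rel
        manifest_subjects.append(entry)
        all_events.extend(sub.events)
        truths.append(sub.truth)
        mus.append({"subject_id": sub.subject_id, "mu": sub.mu})

    write_surveys_csv(outdir / "surveys.csv", all_events)
    pd.DataFrame(mus).to_csv(outdir / "ground_truth" / "subjects.csv", index=False)
    pd.concat(truths, ignore_index=True).to_csv(
        outdir / "ground_truth" / "weekly.csv", index=False, float_format="%.12g"
    )
    write_yaml_config(outdir / "config.yaml", config.to_dict())

    for path in sorted(outdir.rglob("*.csv")) + [outdir / "config.yaml"]:
        files[str(path.relative_to(outdir))] = hashlib.sha256(path.read_bytes()).hexdigest()
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "n_subjects": config.n_subjects,
        "n_weeks": config.weeks,
        "n_days": config.days,
        "subjects": manifest_subjects,
        "domains": {k: list(v) for k, v in domain_map.domains.items()},
        "files": files,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir


# ---------------------------------------------------------------------------
# table-level generator for model calibration studies
# ---------------------------------------------------------------------------

def simulate_weekly_table(
    n_subjects: int,
    n_weeks: int,
    truth: TruthConfig,
    rng: np.random.Generator,
    domains: tuple[str, ...] = ("overall",),
) -> pd.DataFrame:
    """Generate a subject-week feature table directly from the outcome model.

    Covariates are drawn i.i.d. per subject-week from distributions
    shaped like the pipeline's output (coverages near 0.5, a bimodal
    log-normal view latency, log-normal completion latency, binomial
    completion count); outcomes follow the random-intercept regression
    exactly at the configured true lag, independently per domain.  Used
    for parameter-recovery, type-I-error and FDR calibration studies
    where the outcome equation must hold without measurement rounding.
    """
    n = n_subjects * n_weeks
    sid = np.repeat([f"S{i + 1:03d}" for i in range(n_subjects)], n_weeks)
    week = np.tile(np.arange(1, n_weeks + 1), n_subjects)
    a = np.clip(rng.normal(0.47, 0.12, n), 0.0, 1.0)
    g = np.clip(rng.normal(0.50, 0.12, n), 0.0, 1.0)
    fast = rng.random(n) < 0.5
    v = np.where(
        fast,
        rng.lognormal(math.log(30.0), 0.8, n),
        rng.lognormal(math.log(3600.0), 1.0, n),
    )
    c = rng.lognormal(math.log(180.0), 0.6, n)
    t = rng.binomial(3, 0.85, n).astype(float)
    df = pd.DataFrame(
        {"subject_id": sid, "week": week, "A": a, "G": g, "V": v, "C": c, "T": t}
    )

    beta = np.asarray(truth.beta)
    mu = rng.normal(0.0, truth.sigma_subject, n_subjects)
    x = df[list(COVARIATES)].to_numpy()
    subj_idx = np.repeat(np.arange(n_subjects), n_weeks)
    for dom in domains:
        y = np.full(n, np.nan)
        lagged_ok = week > truth.true_lag
        # covariate row at week j - l* for the same subject is l* rows back
        src = np.flatnonzero(lagged_ok) - truth.true_lag
        eps = rng.normal(0.0, truth.sigma_resid, src.size)
        y[lagged_ok] = truth.beta0 + mu[subj_idx[lagged_ok]] + x[src] @ beta + eps
        df[f"Y_{dom}"] = y
    return df


# ---------------------------------------------------------------------------
# distributional check used on simulated view latencies
# ---------------------------------------------------------------------------

def is_bimodal(sample: np.ndarray, min_separation: float = 2.0) -> bool:
    """Flag a positive-valued sample as bimodal on the log scale.

    Fits one- and two-component Gaussian mixtures to ``log(sample)``
    and reports bimodality when the two-component fit wins on BIC and
    the components are well separated (Ashman's D above
    ``min_separation``).
    """
    from sklearn.mixture import GaussianMixture

    x = np.log(np.asarray(sample, dtype=float)).reshape(-1, 1)
    gm1 = GaussianMixture(1, random_state=0).fit(x)
    gm2 = GaussianMixture(2, random_state=0, n_init=3).fit(x)
    if gm2.bic(x) >= gm1.bic(x):
        return False
    m = gm2.means_.ravel()
    s2 = gm2.covariances_.ravel()
    ashman_d = abs(m[0] - m[1]) / math.sqrt((s2[0] + s2[1]) / 2.0)
    return ashman_d > min_separation
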