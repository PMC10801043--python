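"""Synthetic cohort generator for the VR object-relocation task.

The generator reproduces the statistical structure of the study protocol so
the whole pipeline runs without any raw-data download:

* 7 participants with the observed dropout pattern (5 complete both VR
  conditions, 1 completes only the semi-immersive one, 1 completes neither);
* per completed session 16 trials (4 items x 4 repetition blocks), with the
  landmark cue (allocentric vs egocentric recall) assigned per block, two of
  each in random order;
* recall displacement = encoding location + isotropic bivariate Gaussian
  noise N(0, sigma^2 I) with sigma configurable per landmark x condition
  cell, so the recall distance error is Rayleigh(sigma) with mean
  sigma*sqrt(pi/2) — an analytically checkable contract;
* 100 Hz motion-pad traces from a clipped mean-reverting (Ornstein-Uhlenbeck)
  process spanning the configured phase durations;
* SUS and ITC-SOPI negative-effects responses from a latent-Gaussian model
  rounded into the 1–5 Likert domain, aimed at configurable per-condition
  mean/SD targets with a participant trait shared across conditions.

Randomness derives from one root seed via documented ``SeedSequence``
substreams keyed (participant_index, condition_index, stream), so
regenerating one participant never perturbs the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.signal import lfilter

from ._exceptions import ConfigError
from .session_io import (
    CONDITIONS,
    LANDMARKS,
    MotionTrace,
    QuestionnaireResponse,
    SessionLog,
    TrialRecord,
)

#: per-cell displacement sigma (virtual units) back-solved from the reported
#: mean distance errors via the Rayleigh mean, sigma = mean / sqrt(pi/2)
DEFAULT_DISPLACEMENT_SIGMA: dict[tuple[str, str], float] = {
    ("allocentric", "semi_immersive"): 20.70 / math.sqrt(math.pi / 2),
    ("egocentric", "semi_immersive"): 26.47 / math.sqrt(math.pi / 2),
    ("allocentric", "immersive"): 21.19 / math.sqrt(math.pi / 2),
    ("egocentric", "immersive"): 20.55 / math.sqrt(math.pi / 2),
}

#: phase durations in minutes, (mean, sd) per condition; encoding times are
#: the reported per-condition averages, recall times are a design choice
DEFAULT_ENCODING_DURATION = {"immersive": (10.3, 3.21), "semi_immersive": (8.51, 2.29)}
DEFAULT_RECALL_DURATION = {"immersive": (6.0, 2.0), "semi_immersive": (6.0, 2.0)}

#: questionnaire (mean, sd) targets per instrument x condition
DEFAULT_QUESTIONNAIRE_TARGETS = {
    ("SUS", "immersive"): (65.0, 22.97),
    ("SUS", "semi_immersive"): (69.17, 25.52),
    ("ITC_SOPI_NE", "immersive"): (2.03, 0.91),
    ("ITC_SOPI_NE", "semi_immersive"): (1.53, 0.56),
}

DEFAULT_DROPOUT = ("both", "both", "both", "both", "both", "semi_only", "none")

_SAMPLES_PER_MIN = 6000  # 100 Hz
_DT_S = 0.01


@dataclass(frozen=True)
class MotionModel:
    """Clipped mean-reverting tilt dynamics of the foot-motion pad.

    ``mean_reversion_rate`` (1/s) pulls the tilt back to neutral,
    ``volatility`` (1/sqrt(s)) drives it, and samples are clipped to
    [-clip, clip].  The stationary tilt SD is volatility/sqrt(2*rate).
    """

    mean_reversion_rate: float = 1.0
    volatility: float = 0.35
    clip: float = 1.0


@dataclass
class CohortConfig:
    """All knobs of the synthetic cohort; the defaults are the study setup."""

    n_participants: int = 7
    dropout_pattern: tuple[str, ...] = DEFAULT_DROPOUT
    displacement_sigma: float | Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_DISPLACEMENT_SIGMA)
    )
    item_layout_radius: float = 20.0
    motion_model: MotionModel = field(default_factory=MotionModel)
    encoding_duration: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ENCODING_DURATION)
    )
    recall_duration: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RECALL_DURATION)
    )
    questionnaire_targets: Mapping[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_QUESTIONNAIRE_TARGETS)
    )
    #: within-participant correlation of questionnaire latents across conditions
    questionnaire_rho: float = 0.8
    n_itc_items: int = 6
    correct_radius: float = 6.0
    seed: int = 0

    def sigma_for(self, landmark: str, condition: str) -> float:
        if isinstance(self.displacement_sigma, Mapping):
            return float(self.displacement_sigma[(landmark, condition)])
        return float(self.displacement_sigma)

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        if len(self.dropout_pattern) != self.n_participants:
            raise ConfigError(
                f"dropout_pattern length {len(self.dropout_pattern)} != "
                f"n_participants {self.n_participants}"
            )
        if any(p not in ("both", "semi_only", "none") for p in self.dropout_pattern):
            raise ConfigError(f"unknown dropout pattern in {self.dropout_pattern}")
        for lm in LANDMARKS:
            for cond in CONDITIONS:
                try:
                    sigma = self.sigma_for(lm, cond)
                except KeyError:
                    raise ConfigError(f"displacement_sigma missing cell ({lm}, {cond})")
                if sigma < 0 or not math.isfinite(sigma):
                    raise ConfigError(f"displacement_sigma[{lm},{cond}] = {sigma} invalid")
        mm = self.motion_model
        if mm.clip <= 0 or mm.mean_reversion_rate < 0 or mm.volatility < 0:
            raise ConfigError(f"invalid motion model {mm}")
        for name, mapping in (("encoding", self.encoding_duration), ("recall", self.recall_duration)):
            for cond in CONDITIONS:
                if cond not in mapping:
                    raise ConfigError(f"{name}_duration missing condition {cond!r}")
                mean, sd = mapping[cond]
                if mean <= 0 or sd < 0:
                    raise ConfigError(f"{name}_duration[{cond}] = ({mean}, {sd}) invalid")
        for key, (mean, sd) in self.questionnaire_targets.items():
            if sd < 0:
                raise ConfigError(f"questionnaire target sd < 0 for {key}")
        if not -1.0 <= self.questionnaire_rho <= 1.0:
            raise ConfigError("questionnaire_rho must lie in [-1, 1]")
        if self.n_itc_items < 1:
            raise ConfigError("n_itc_items must be >= 1")
        if self.correct_radius <= 0:
            raise ConfigError("correct_radius must be > 0")


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Documented substream rule: PCG64(SeedSequence(seed, spawn_key=key))."""
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed, spawn_key=key)))


def _item_layout(radius: float) -> dict[int, tuple[float, float]]:
    """Four items equally spaced on a circle around the square's center."""
    out = {}
    for k in range(4):
        ang = math.radians(45.0 + 90.0 * k)
        out[k + 1] = (radius * math.cos(ang), radius * math.sin(ang))
    return out


def _ou_trace(rng: np.random.Generator, n: int, model: MotionModel) -> MotionTrace:
    """Exact AR(1) discretization of the OU tilt process, clipped post hoc.

    The clip sits ~4 stationary SDs out under the defaults, so clipping is a
    rare-event truncation rather than a change of dynamics.
    """
    phi = math.exp(-model.mean_reversion_rate * _DT_S)
    sd_stat = (
        model.volatility / math.sqrt(2.0 * model.mean_reversion_rate)
        if model.mean_reversion_rate > 0
        else model.volatility * math.sqrt(_DT_S)
    )
    axes = []
    for _ in range(2):
        x0 = rng.normal(0.0, sd_stat)
        eps = rng.normal(0.0, sd_stat * math.sqrt(max(1.0 - phi * phi, 1e-12)), size=n)
        x, _ = lfilter([1.0], [1.0, -phi], eps, zi=[phi * x0])
        axes.append(np.clip(x, -model.clip, model.clip))
    t_ms = np.arange(n, dtype=np.int64) * 10
    return MotionTrace(t_ms, axes[0], axes[1])


def _phase(rng: np.random.Generator, spec: tuple[float, float]):
    mean, sd = spec
    minutes = max(float(rng.normal(mean, sd)), 0.05)
    n = max(2, int(round(minutes * _SAMPLES_PER_MIN)))
    duration = n / _SAMPLES_PER_MIN  # store the realized, sample-exact duration
    return duration, n


def _session_trials(
    rng: np.random.Generator, cfg: CohortConfig, pid: str, condition: str, recall_minutes: float
) -> list[TrialRecord]:
    items = _item_layout(cfg.item_layout_radius)
    # two allocentric + two egocentric recall blocks in random order
    landmarks = list(LANDMARKS) * 2
    rng.shuffle(landmarks)
    latency_mu = math.log(max(recall_minutes * 60.0 / 16.0, 1.0))
    trials = []
    for rep, landmark in enumerate(landmarks, start=1):
        sigma = cfg.sigma_for(landmark, condition)
        for item_id in rng.permutation([1, 2, 3, 4]):
            item_id = int(item_id)
            ex, ez = items[item_id]
            dx, dz = rng.normal(0.0, 1.0, size=2) * sigma
            trials.append(
                TrialRecord(
                    participant_id=pid,
                    condition=condition,
                    landmark=landmark,
                    item_id=item_id,
                    repetition=rep,
                    enc_x=ex,
                    enc_z=ez,
                    rec_x=ex + dx,
                    rec_z=ez + dz,
                    recall_latency=float(rng.lognormal(latency_mu, 0.4)),
                )
            )
    return trials


def _likert(latent: np.ndarray) -> tuple[int, ...]:
    return tuple(int(v) for v in np.clip(np.rint(latent), 1, 5))


def _questionnaires(
    rng: np.random.Generator, cfg: CohortConfig, pid: str, condition: str, trait: float
) -> list[QuestionnaireResponse]:
    rho = cfg.questionnaire_rho
    mix = math.sqrt(max(1.0 - rho * rho, 0.0))
    out = []

    sus_mean, sus_sd = cfg.questionnaire_targets[("SUS", condition)]
    u = sus_mean + sus_sd * (rho * trait + mix * rng.normal())
    p = float(np.clip(u, 0.0, 100.0)) / 100.0  # latent usability on [0, 1]
    odd = 1.0 + 4.0 * p + rng.normal(0.0, 0.5, size=5)
    even = 5.0 - 4.0 * p + rng.normal(0.0, 0.5, size=5)
    items = np.empty(10)
    items[0::2], items[1::2] = odd, even
    out.append(QuestionnaireResponse(pid, condition, "SUS", _likert(items)))

    itc_mean, itc_sd = cfg.questionnaire_targets[("ITC_SOPI_NE", condition)]
    m = itc_mean + itc_sd * (rho * trait + mix * rng.normal())
    latent = np.clip(m, 1.0, 5.0) + rng.normal(0.0, 0.45, size=cfg.n_itc_items)
    out.append(QuestionnaireResponse(pid, condition, "ITC_SOPI_NE", _likert(latent)))
    return out


def generate_cohort(
    cfg: CohortConfig | None = None, seed: int | None = None
) -> tuple[list[SessionLog], list[QuestionnaireResponse]]:
    """Generate a full synthetic cohort; deterministic given the seed.

    ``seed`` overrides ``cfg.seed``.  Returns the session logs (one per
    completed participant x condition) and the questionnaire responses of the
    completed sessions.
    """
    cfg = cfg if cfg is not None else CohortConfig()
    cfg.validate()
    seed = cfg.seed if seed is None else int(seed)
    sessions: list[SessionLog] = []
    questionnaires: list[QuestionnaireResponse] = []
    for i, pattern in enumerate(cfg.dropout_pattern):
        pid = f"P{i + 1:02d}"
        conds = {"both": list(CONDITIONS), "semi_only": ["semi_immersive"], "none": []}[pattern]
        trait = float(_rng(seed, i, 99, 0).normal())  # shared across conditions
        for cond in conds:
            c = CONDITIONS.index(cond)
            dur_rng = _rng(seed, i, c, 4)
            enc_minutes, enc_n = _phase(dur_rng, cfg.encoding_duration[cond])
            rec_minutes, rec_n = _phase(dur_rng, cfg.recall_duration[cond])
            trials = _session_trials(_rng(seed, i, c, 0), cfg, pid, cond, rec_minutes)
            sessions.append(
                SessionLog(
                    participant_id=pid,
                    condition=cond,
                    trials=trials,
                    encoding_trace=_ou_trace(_rng(seed, i, c, 1), enc_n, cfg.motion_model),
                    recall_trace=_ou_trace(_rng(seed, i, c, 2), rec_n, cfg.motion_model),
                    encoding_duration=enc_minutes,
                    recall_duration=rec_minutes,
                    completed=True,
                )
            )
            questionnaires.extend(_questionnaires(_rng(seed, i, c, 3), cfg, pid, cond, trait))
    return sessions, questionnaires


#: pinned seed of the frozen reference cohort
REFERENCE_SEED = 20240108


def reference_config() -> CohortConfig:
    """Configuration of the frozen reference cohort used by example tests.

    Identical to the study defaults except for short phase durations, which
    keep the fixture's motion traces small and the test suite fast.
    """
    return CohortConfig(
        encoding_duration={"immersive": (0.6, 0.12), "semi_immersive": (0.5, 0.1)},
        recall_duration={"immersive": (0.4, 0.08), "semi_immersive": (0.4, 0.08)},
        seed=REFERENCE_SEED,
    )


def reference_fixture() -> tuple[list[SessionLog], list[QuestionnaireResponse]]:
    """The frozen, seed-pinned small cohort shared by example-based tests."""
    return generate_cohort(reference_config())
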