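"""Task and cohort configuration objects.

The approach-avoidance conflict game ("Task 1") and the safe predator
exposure task ("Task 2") are fully determined by a small set of generative
constants: the per-100-ms wake-up hazard of the three predators, the timing
of reward-token appearance, and the epoch/block structure.  ``TaskConfig``
holds those constants; ``ApproachPolicy`` and ``ExposurePolicy`` describe a
simulated agent's behaviour; ``CohortSpec`` describes a whole cohort of
control and lesion agents.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import yaml

THREAT_LEVELS = ("low", "med", "high")

#: linear contrast codes used by the generative decision model
THREAT_CODES = {"low": -1.0, "med": 0.0, "high": 1.0}


class ConfigurationError(ValueError):
    """Raised when a config or policy violates its invariants."""


@dataclass(frozen=True)
class TaskConfig:
    """Generative constants of Tasks 1 and 2.

    Parameters
    ----------
    hazards
        Predator activation probability per ``step_ms`` time step for the
        three threat levels, strictly increasing, each in (0, 1).
    n_blocks_task1
        Number of Task-1 blocks per subject.
    epochs_per_block
        Epochs in a Task-1 block (45 by default).
    tokens_per_epoch
        Token cycles scheduled per epoch (6 by default).
    availability_mean
        Mean (ms) of the exponential token-availability duration.
    wait_offset
        Constant (ms) added to the exponential inter-token wait.
    approach_window, return_window
        Open latency-acceptance intervals (ms) used at analysis time.
    exposure_attempts_max
        Exposure attempts per Task-2 epoch before the key is disabled.
    exposure_epochs_per_block
        Task-2 epochs per block.
    step_ms
        Width of the discrete hazard step (100 ms).
    """

    hazards: Mapping[str, float] = field(
        default_factory=lambda: {"low": 0.1, "med": 0.2, "high": 0.3}
    )
    n_blocks_task1: int = 4
    epochs_per_block: int = 45
    tokens_per_epoch: int = 6
    availability_mean: float = 1250.0
    wait_offset: float = 500.0
    approach_window: tuple[float, float] = (150.0, 2000.0)
    return_window: tuple[float, float] = (0.0, 2000.0)
    exposure_attempts_max: int = 6
    exposure_epochs_per_block: int = 36
    n_blocks_task2: int = 2
    step_ms: float = 100.0

    def __post_init__(self) -> None:
        hz = [self.hazards.get(lv) for lv in THREAT_LEVELS]
        if any(h is None for h in hz):
            raise ConfigurationError(
                f"hazards must define levels {THREAT_LEVELS}, got {self.hazards}"
            )
        if not all(0.0 < h < 1.0 for h in hz):
            raise ConfigurationError(f"hazards must lie in (0, 1): {hz}")
        if not (hz[0] < hz[1] < hz[2]):
            raise ConfigurationError(f"hazards must increase with threat: {hz}")
        for name in ("availability_mean", "wait_offset", "step_ms"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for name in ("epochs_per_block", "tokens_per_epoch",
                     "exposure_attempts_max", "exposure_epochs_per_block",
                     "n_blocks_task1"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        lo, hi = self.approach_window
        rlo, rhi = self.return_window
        if not (0 <= lo < hi and 0 <= rlo < rhi):
            raise ConfigurationError("latency windows must be ordered")

    def hazard(self, threat: str) -> float:
        return float(self.hazards[threat])

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hazards"] = dict(self.hazards)
        d["approach_window"] = list(self.approach_window)
        d["return_window"] = list(self.return_window)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "TaskConfig":
        d = dict(d)
        if "approach_window" in d:
            d["approach_window"] = tuple(d["approach_window"])
        if "return_window" in d:
            d["return_window"] = tuple(d["return_window"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "TaskConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _require_finite(obj, names: Sequence[str]) -> None:
    for name in names:
        v = getattr(obj, name)
        if not math.isfinite(v):
            raise ConfigurationError(f"{name} must be finite, got {v!r}")


@dataclass(frozen=True)
class ApproachPolicy:
    """Generative behavioural policy of a Task-1 agent.

    The approach decision for each token is Bernoulli with logistic
    probability ``sigmoid(intercept + b_threat*c_threat + b_loss*loss)``
    where ``c_threat`` is the linear threat code (-1, 0, 1) and ``loss`` the
    number of tokens already held (0-5).  Approach and return latencies are
    Gaussian around a linear predictor in the same regressors, truncated at
    1 ms.  Default values produce control-like behaviour: near-ceiling
    approach at no potential loss, marked decline with loss and threat,
    slower approaches and faster returns under threat.
    """

    approach_intercept: float = 3.2
    approach_coef_threat: float = -0.5
    approach_coef_loss: float = -0.8
    al_base: float = 450.0
    al_coef_threat: float = 40.0
    al_coef_loss: float = 25.0
    rl_base: float = 150.0
    rl_coef_threat: float = -20.0
    rl_coef_loss: float = -5.0
    latency_noise_sd: float = 80.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require_finite(self, [f.name for f in self.__dataclass_fields__.values()
                               if f.name != "seed"])
        if self.latency_noise_sd < 0:
            raise ConfigurationError("latency_noise_sd must be >= 0")

    def approach_probability(self, threat: str, loss: int) -> float:
        eta = (self.approach_intercept
               + self.approach_coef_threat * THREAT_CODES[threat]
               + self.approach_coef_loss * loss)
        return 1.0 / (1.0 + math.exp(-eta))

    def replace(self, **kw) -> "ApproachPolicy":
        d = asdict(self)
        d.update(kw)
        return ApproachPolicy(**d)


@dataclass(frozen=True)
class ExposurePolicy:
    """Generative press-timing policy of a Task-2 agent.

    Press times are a two-component mixture: with probability ``w`` the
    press is unrelated to tokens (uniform over the epoch timeline), and with
    probability ``1 - w`` it is a simple response to the most recent token
    onset with an exponentially-modified Gaussian (exGauss) delay of
    Gaussian mean ``mu``, SD ``sigma`` and exponential rate ``lam``.
    """

    w: float = 0.35
    mu: float = 350.0
    sigma: float = 90.0
    lam: float = 1.0 / 400.0
    presses_per_epoch_mean: float = 3.0

    def __post_init__(self) -> None:
        _require_finite(self, ["w", "mu", "sigma", "lam",
                               "presses_per_epoch_mean"])
        if not 0.0 <= self.w <= 1.0:
            raise ConfigurationError(f"w must lie in [0, 1], got {self.w}")
        if self.sigma < 0:
            raise ConfigurationError("sigma must be >= 0")
        if self.lam <= 0:
            raise ConfigurationError("lam must be > 0")
        if self.presses_per_epoch_mean <= 0:
            raise ConfigurationError("presses_per_epoch_mean must be > 0")

    def replace(self, **kw) -> "ExposurePolicy":
        d = asdict(self)
        d.update(kw)
        return ExposurePolicy(**d)


@dataclass(frozen=True)
class PatientSpec:
    """One lesion agent: a label, a group tag, and policy perturbations.

    ``approach_overrides`` / ``exposure_overrides`` replace individual
    fields of the cohort-mean policies, emulating a lesion that perturbs a
    specific component of the behavioural policy (e.g. an attenuated
    ``approach_coef_loss`` for a hippocampal-like agent, an increased
    ``rl_base`` for an amygdala-like agent).
    """

    label: str
    group: str = "patient"
    approach_overrides: Mapping[str, float] = field(default_factory=dict)
    exposure_overrides: Mapping[str, float] = field(default_factory=dict)
    control_group_id: str = "controls"


@dataclass(frozen=True)
class CohortSpec:
    """A cohort of control agents plus optional lesion agents.

    Control policy parameters are drawn per subject from independent
    Gaussians centred on ``control_policy_mean`` with SDs
    ``control_policy_sd`` (parameters absent from either mapping keep the
    ``ApproachPolicy``/``ExposurePolicy`` defaults / zero SD).  Memory
    ratings are simulated as ``rating_slope * true_rate + rating_bias +
    noise``; the defaults reproduce the near-unit slope (0.99) and the
    +36.3 percentage-point overestimation observed in healthy players.
    """

    n_controls: int = 10
    patients: tuple[PatientSpec, ...] = ()
    control_policy_mean: Mapping[str, float] = field(default_factory=dict)
    control_policy_sd: Mapping[str, float] = field(default_factory=dict)
    control_exposure_mean: Mapping[str, float] = field(default_factory=dict)
    control_exposure_sd: Mapping[str, float] = field(default_factory=dict)
    rating_bias: float = 36.3
    rating_slope: float = 0.99
    rating_noise_sd: float = 5.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_controls < 2:
            raise ConfigurationError("n_controls must be >= 2")
        labels = [p.label for p in self.patients]
        if len(set(labels)) != len(labels):
            raise ConfigurationError(f"duplicate patient labels: {labels}")


def derive_seed(master_seed: int, *keys) -> int:
    """Derive a stable 31-bit stream seed from a master seed and keys."""
    blob = json.dumps([int(master_seed), *map(str, keys)]).encode()
    return int.from_bytes(hashlib.sha256(blob).digest()[:4], "big") % (2**31)
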