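"""Synthetic post-craniectomy ICP cohorts.

No public ICP dataset accompanies the analysis this package implements, so
every downstream stage is exercised on simulated cohorts that reproduce the
*statistical regime* of early postoperative monitoring: a 30-min sampling
grid over up to 72 h, a per-patient baseline pressure, episodic plateau-wave
elevations (Lundberg-A-like sustained rises, modelled as raised-cosine bumps
so that threshold crossings fall between samples), additive sensor noise,
occasional early termination of monitoring, and a death label coupled to the
realized normalized AUC.

The outcome link operates on the normalized AUC *computed from the generated
samples* (post-noise, post-censoring), which closes the loop with the burden
metrics: association and model stages can be tested against a known
generative coupling.  Two links are available:

* ``logistic``: P(death) = expit(alpha + beta * nAUC)
* ``rule``: death iff nAUC >= cutoff (default 0.6), giving a perfectly
  separable cohort for sanity checks.

Survivors receive an mRS drawn uniformly from 0..5; only the death
dichotomy is analyzed downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .burden import normalized_auc
from .io import Cohort, IcpTrace, OutcomeRecord

# spawn key for the outcome stream; patient streams use (patient_index,)
_OUTCOME_STREAM = 1 << 32


@dataclass
class SimConfig:
    """Generator parameters.  Defaults are the package's reference regime.

    ``wave_rate_per_72h`` is the expected number of plateau episodes in a
    72-h window; ``censor_prob`` is the probability that monitoring stops
    early, uniformly between ``censor_min_h`` and ``window_h``.
    """

    n_patients: int
    seed: int
    window_h: float = 72.0
    interval_h: float = 0.5
    baseline_mean_mmHg: float = 12.0
    baseline_sd_mmHg: float = 4.0
    wave_rate_per_72h: float = 2.0
    wave_amp_mean_mmHg: float = 12.0
    wave_amp_sd_mmHg: float = 5.0
    wave_dur_mean_h: float = 6.0
    noise_sd_mmHg: float = 1.5
    censor_prob: float = 0.2
    censor_min_h: float = 40.0
    outcome_link: str = "logistic"
    link_intercept: float = -4.0
    link_slope: float = 8.0
    rule_cutoff: float = 0.6

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.window_h <= 0 or self.interval_h <= 0:
            raise ValueError("window_h and interval_h must be positive")
        for name in ("baseline_sd_mmHg", "wave_amp_sd_mmHg", "noise_sd_mmHg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.censor_prob <= 1:
            raise ValueError("censor_prob must be in [0, 1]")
        if not 0 < self.censor_min_h <= self.window_h:
            raise ValueError("censor_min_h must be in (0, window_h]")
        if self.outcome_link not in ("logistic", "rule"):
            raise ValueError(f"unknown outcome link {self.outcome_link!r}")
        if self.wave_rate_per_72h < 0 or self.wave_dur_mean_h <= 0:
            raise ValueError("wave rate must be >= 0 and mean duration > 0")

    def to_dict(self) -> dict:
        return asdict(self)


def _patient_rng(config: SimConfig, patient_index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(patient_index,))
    return np.random.default_rng(ss)


def generate_trace(
    config: SimConfig, patient_index: int, rng: np.random.Generator | None = None
) -> IcpTrace:
    """Generate one patient's trace on the nominal sampling grid.

    Deterministic given (seed, patient_index); the per-patient stream is
    derived by seed-sequence spawning so traces are independent and
    individually reproducible.
    """
    if rng is None:
        rng = _patient_rng(config, patient_index)

    censored = rng.random() < config.censor_prob
    end_h = rng.uniform(config.censor_min_h, config.window_h)  # drawn either way for stream stability
    if not censored:
        end_h = config.window_h
    times = np.arange(0.0, end_h + config.interval_h / 2, config.interval_h)

    baseline = rng.normal(config.baseline_mean_mmHg, config.baseline_sd_mmHg)
    n_waves = rng.poisson(config.wave_rate_per_72h * config.window_h / 72.0)
    centers = rng.uniform(0.0, config.window_h, size=n_waves)
    amps = np.maximum(rng.normal(config.wave_amp_mean_mmHg, config.wave_amp_sd_mmHg, size=n_waves), 0.0)
    # plateau durations: gamma(shape 2) keeps the configured mean with a
    # realistic right tail and no hard floor
    durs = rng.gamma(shape=2.0, scale=config.wave_dur_mean_h / 2.0, size=n_waves)

    icp = np.full_like(times, baseline)
    for c, a, d in zip(centers, amps, durs):
        inside = np.abs(times - c) < d / 2
        icp[inside] += a * np.cos(np.pi * (times[inside] - c) / d) ** 2
    icp = icp + rng.normal(0.0, config.noise_sd_mmHg, size=times.size)
    icp = np.maximum(icp, 0.0)
    return IcpTrace(f"P{patient_index:04d}", times, icp)


def generate_cohort(config: SimConfig) -> Cohort:
    """Generate traces and coupled outcomes for ``config.n_patients`` patients."""
    traces = {
        tr.patient_id: tr
        for tr in (generate_trace(config, i) for i in range(config.n_patients))
    }
    nauc = np.array([normalized_auc(traces[pid]) for pid in sorted(traces)])

    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(_OUTCOME_STREAM,))
    )
    u = rng.random(config.n_patients)
    survivor_mrs = rng.integers(0, 6, size=config.n_patients)
    if config.outcome_link == "logistic":
        logit = config.link_intercept + config.link_slope * nauc
        p_death = 1.0 / (1.0 + np.exp(-logit))
        dead = u < p_death
    else:  # rule link
        dead = nauc >= config.rule_cutoff

    outcomes = {}
    for k, pid in enumerate(sorted(traces)):
        mrs = 6 if dead[k] else int(survivor_mrs[k])
        outcomes[pid] = OutcomeRecord(pid, mrs)
    return Cohort(traces=traces, outcomes=outcomes)
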