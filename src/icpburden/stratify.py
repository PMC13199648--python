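"""Risk-band stratification of normalized ICP-AUC.

Patients are banded by normalized AUC around a central cutoff of 0.5 with a
configurable intermediate ("grey") zone of half-width delta, plus two flags:

* ``certain_poor_flag``: normalized AUC >= 0.6, the region in which every
  observed patient died;
* ``time_rule_flag``: ICP above 20 mmHg for more than 30 % of the monitored
  period, an independent supra-threshold dose rule associated with death.

Cutoffs are left-closed (>=) for escalation; the time rule is strict (>).
The intermediate half-width is a package choice (the underlying grey zone is
only described qualitatively) and defaults to 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

from .burden import BurdenSummary
from .exceptions import ConfigError

#: band ordering, low risk first
BAND_LEVELS = {"low": 0, "intermediate": 1, "high": 2}


@dataclass(frozen=True)
class RiskBands:
    """Band cutpoints on normalized AUC plus the time-above rule."""

    cutoff: float = 0.5
    intermediate_halfwidth: float = 0.05
    certain_poor_cutoff: float = 0.6
    time_rule_threshold_mmHg: float = 20.0
    time_rule_fraction: float = 0.30

    def __post_init__(self) -> None:
        eps = 1e-9  # tolerate float round-off in user-supplied cutpoints
        lo = self.cutoff - self.intermediate_halfwidth
        hi = self.cutoff + self.intermediate_halfwidth
        if not (0 < lo < hi <= self.certain_poor_cutoff + eps <= 1 + 2 * eps):
            raise ConfigError(
                "require 0 < cutoff - delta < cutoff + delta <= certain_poor_cutoff <= 1"
            )
        if not 0 < self.time_rule_fraction < 1:
            raise ConfigError("time_rule_fraction must be in (0, 1)")


@dataclass(frozen=True)
class RiskLabel:
    band: str
    certain_poor_flag: bool
    time_rule_flag: bool

    def __post_init__(self) -> None:
        if self.band not in BAND_LEVELS:
            raise ValueError(f"unknown band {self.band!r}")
        if self.certain_poor_flag and self.band != "high":
            raise ValueError("certain_poor_flag implies band == 'high'")


def classify(summary: BurdenSummary, bands: RiskBands = RiskBands()) -> RiskLabel:
    """Assign the risk band and flags for one patient summary.

    Band boundaries: low if nAUC < cutoff - delta; intermediate if
    cutoff - delta <= nAUC < cutoff + delta; high otherwise.
    """
    nauc = summary.normalized_auc
    lo = bands.cutoff - bands.intermediate_halfwidth
    hi = bands.cutoff + bands.intermediate_halfwidth
    if nauc < lo:
        band = "low"
    elif nauc < hi:
        band = "intermediate"
    else:
        band = "high"

    theta = float(bands.time_rule_threshold_mmHg)
    if theta not in summary.frac_above:
        raise ConfigError(
            f"summary for {summary.patient_id!r} lacks frac_above[{theta:g}] "
            "needed by the time-above rule"
        )
    return RiskLabel(
        band=band,
        certain_poor_flag=nauc >= bands.certain_poor_cutoff,
        time_rule_flag=summary.frac_above[theta] > bands.time_rule_fraction,
    )


def classify_cohort(summaries, bands: RiskBands = RiskBands()) -> dict[str, RiskLabel]:
    """Classify a mapping of summaries keyed by patient id."""
    return {pid: classify(s, bands) for pid, s in summaries.items()}
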