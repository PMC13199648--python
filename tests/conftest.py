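import numpy as np
import pytest

import icpburden as ib


def make_trace(times, values, pid="T", **kwargs):
    return ib.IcpTrace(pid, np.asarray(times, float), np.asarray(values, float), **kwargs)


def random_trace(rng, span_h=24.0, interval_h=0.5, mean=15.0, sd=8.0, pid="R"):
    """A noisy trace around the clinical thresholds, clipped at 0 mmHg."""
    t = np.arange(0.0, span_h + interval_h / 2, interval_h)
    v = np.maximum(rng.normal(mean, sd, size=t.size), 0.0)
    return make_trace(t, v, pid=pid)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def small_cohort():
    """Logistic-link cohort of 30 patients with its burden summaries."""
    cohort = ib.generate_cohort(ib.SimConfig(n_patients=30, seed=5))
    return cohort, ib.summarize_cohort(cohort.traces)


@pytest.fixture(scope="session")
def cohort200():
    """Strongly coupled (logistic, slope 8) cohort of 200 patients."""
    cohort = ib.generate_cohort(ib.SimConfig(n_patients=200, seed=0))
    return cohort, ib.summarize_cohort(cohort.traces)


@pytest.fixture(scope="session")
def cohort200_rule():
    """Rule-link cohort: death deterministic above normalized AUC 0.6."""
    cohort = ib.generate_cohort(ib.SimConfig(n_patients=200, seed=0, outcome_link="rule"))
    return cohort, ib.summarize_cohort(cohort.traces)
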