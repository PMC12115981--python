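"""Shared fixtures: codes, modulation specs and boards used across tests."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from golayscan import (
    ModulationSpec,
    Pipeline,
    generate_golay_pair,
    reference_specimen,
)

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


def brute_force_autocorrelation(seq):
    """O(N^2) shift-multiply-sum aperiodic autocorrelation oracle.

    Independent of any library correlation routine; exact integers.
    """
    seq = list(int(v) for v in seq)
    n = len(seq)
    out = []
    for lag in range(-(n - 1), n):
        acc = 0
        for i in range(n):
            j = i + lag
            if 0 <= j < n:
                acc += seq[i] * seq[j]
        out.append(acc)
    return np.array(out, dtype=np.int64)


def brute_force_correlate(x, ref):
    """O(n*m) direct full convolution oracle (x against reference)."""
    x = np.asarray(x, dtype=float)
    ref = np.asarray(ref, dtype=float)
    n, m = len(x), len(ref)
    out = np.zeros(n + m - 1)
    for i in range(n):
        for j in range(m):
            out[i + j] += x[i] * ref[j]
    return out


@pytest.fixture(scope="session")
def pair8():
    """The length-8 Golay complementary pair."""
    return generate_golay_pair(3)


@pytest.fixture(scope="session")
def unit_spec():
    """Baseband spec with one sample per chip (code-domain identity)."""
    return ModulationSpec(carrier_freq=0.0, fs=1.0, chip_period=1.0)


@pytest.fixture(scope="session")
def carrier_spec():
    """Default 75 kHz square-carrier drive at 4.8 MHz sampling."""
    return ModulationSpec()


@pytest.fixture(scope="session")
def fast_carrier_spec():
    """Cheaper 75 kHz drive (32 samples/cycle) for scan-heavy tests."""
    return ModulationSpec(fs=2.4e6)


@pytest.fixture(scope="session")
def board():
    return reference_specimen()


@pytest.fixture(scope="session")
def fast_pipeline(fast_carrier_spec):
    return Pipeline(spec=fast_carrier_spec)
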