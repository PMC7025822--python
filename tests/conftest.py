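"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive quantities by brute force or
explicit simulation (Gillespie birth-death, event-level elongation) so the
closed-form paths in the package are checked against something that does
not share their code.
"""

from __future__ import annotations

import numpy as np
import pytest

from fishkin import myc_like_transcript


@pytest.fixture(scope="session")
def myc_model():
    return myc_like_transcript()


def gillespie_birth_death(beta: float, delta: float, t_end: float, rng, sample_every: float = 2.0):
    """Exact stochastic simulation of births (rate beta) and per-molecule
    deaths (rate delta * M); returns M sampled every ``sample_every`` time
    units after a burn-in of 10 mean lifetimes."""
    t, M = 0.0, 0
    burn_in = 10.0 / delta
    next_sample = burn_in
    samples = []
    while t < t_end:
        rate = beta + delta * M
        t += rng.exponential(1.0 / rate)
        while next_sample < t and next_sample < t_end:
            samples.append(M)
            next_sample += sample_every
        if rng.random() < beta / rate:
            M += 1
        else:
            M -= 1
    return np.array(samples)


def elongation_polymerase_load(beta: float, L: float, v: float, rng, n_samples: int = 2000):
    """Explicit elongation simulation: polymerases initiate as a Poisson
    process at rate beta and occupy the gene for exactly L/v hours. The
    load is sampled on a grid spaced two dwell times apart, so successive
    counts depend on disjoint initiation windows and are independent."""
    dwell = L / v
    sample_times = dwell + 2.0 * dwell * np.arange(n_samples)
    t_end = sample_times[-1] + dwell
    n_events = rng.poisson(beta * t_end)
    starts = np.sort(rng.uniform(0.0, t_end, size=n_events))
    counts = np.searchsorted(starts, sample_times) - np.searchsorted(
        starts, sample_times - dwell
    )
    return counts


@pytest.fixture(scope="session")
def oracles():
    class Oracles:
        gillespie = staticmethod(gillespie_birth_death)
        elongation = staticmethod(elongation_polymerase_load)

    return Oracles
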