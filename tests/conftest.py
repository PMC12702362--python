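"""Shared fixtures: one small fast screen and one default-scale screen.

Both are generated at test time from the seeded simulator (no stored data).
The default-scale screen is session-scoped because several recovery tests
reuse the same fitted contrasts.
"""

from dataclasses import dataclass

import pytest

import serpindms as s


@dataclass
class FittedScreen:
    screen: s.SimulatedScreen
    res_0h: s.EnrichmentResults
    res_48h: s.EnrichmentResults
    refined: "object"


def _fit(screen: s.SimulatedScreen) -> FittedScreen:
    res_0h = s.EnrichmentModel(
        screen.counts, screen.samples, ("sel0h", "input")
    ).fit()
    res_48h = s.EnrichmentModel(
        screen.counts, screen.samples, ("sel48h", "input")
    ).fit()
    refined = s.refine_functional_stability(res_0h.scores, res_48h.scores)
    return FittedScreen(screen, res_0h, res_48h, refined)


@pytest.fixture(scope="session")
def small_config() -> s.SimConfig:
    return s.SimConfig(
        L=40,
        depth=200_000,
        spike_ins=(),
        planted_regions=((10, 20),),
        seed=0,
    )


@pytest.fixture(scope="session")
def small_screen(small_config) -> s.SimulatedScreen:
    return s.simulate_screen(small_config)


@pytest.fixture(scope="session")
def small_fitted(small_screen) -> FittedScreen:
    return _fit(small_screen)


@pytest.fixture(scope="session")
def default_screen() -> s.SimulatedScreen:
    """The stated world at full scale: L=379, depth 2e6, 3 replicates,
    dispersion 0.05, seed 0."""
    return s.simulate_screen(s.SimConfig(seed=0))


@pytest.fixture(scope="session")
def default_fitted(default_screen) -> FittedScreen:
    return _fit(default_screen)
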