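"""Shared fixtures: small deterministic synthetic studies and helpers."""

from __future__ import annotations

import numpy as np
import pytest

from wingmorph.landmark_io import LandmarkConfiguration, Sample, SampleSet
from wingmorph import synthgen


def random_wing(rng: np.random.Generator, wing_id: str = "w", side: str = "right",
                scale: float = 600.0) -> LandmarkConfiguration:
    """A generic non-degenerate 19-landmark wing."""
    pts = synthgen.default_template() * scale
    pts = pts + rng.normal(0.0, 2.0, pts.shape)
    return LandmarkConfiguration(pts + rng.uniform(0, 1000, 2), wing_id=wing_id, side=side)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_study():
    """Two areas x two periods, 8 colonies each, modest separations."""
    groups = [
        synthgen.GroupSpec("intra_pre", 8, area="intra", period="pre2000",
                           wings_mean=8, cubital_index=2.75),
        synthgen.GroupSpec("extra_pre", 8, area="extra", period="pre2000",
                           ln_cs_mean=6.44, wings_mean=8, cubital_index=2.67),
        synthgen.GroupSpec("intra_post", 8, area="intra", period="post2000",
                           wings_mean=8, cubital_index=2.75),
        synthgen.GroupSpec("extra_post", 8, area="extra", period="post2000",
                           ln_cs_mean=6.44, wings_mean=8, cubital_index=2.67),
    ]
    d2 = np.array([
        [0.0, 9.28, 6.92, 15.68],
        [9.28, 0.0, 11.59, 7.79],
        [6.92, 11.59, 0.0, 8.00],
        [15.68, 7.79, 8.00, 0.0],
    ])
    cfg = synthgen.SyntheticConfig(groups=groups, target_d2=d2)
    return synthgen.simulate_study(cfg, seed=7, return_truth=True)


@pytest.fixture(scope="session")
def reference_fixture_truth():
    """The packaged study-scale fixture with its ground truth."""
    return synthgen.reference_fixture(return_truth=True)


@pytest.fixture(scope="session")
def reference_fixture(reference_fixture_truth):
    return reference_fixture_truth[0]


def tiny_sampleset(rng: np.random.Generator, n_samples: int = 2,
                   wings_per_sample: int = 3) -> SampleSet:
    samples = []
    for i in range(n_samples):
        cfgs = [
            random_wing(rng, wing_id=f"s{i}-w{j}", side="left" if j % 2 else "right")
            for j in range(wings_per_sample)
        ]
        samples.append(
            Sample(f"s{i}", cfgs, area="intra" if i % 2 == 0 else "extra",
                   year=1990 + i, latitude=45.0 + i, longitude=24.0,
                   altitude=300.0 + 10 * i, mean_annual_temperature=9.0 - 0.1 * i)
        )
    return SampleSet(samples)
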