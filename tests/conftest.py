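import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from dimnp import (
    LocusTestTrack,
    OccupancyProfile,
    PlantedRegion,
    SyntheticConfig,
    profiles_from_fragments,
    simulate_samples,
)


@pytest.fixture
def track_from_pvalues():
    """Build a LocusTestTrack directly from a P-value vector."""

    def _build(pvalues, chrom="chrT", df=2):
        p = np.asarray(pvalues, dtype=float)
        return LocusTestTrack(
            chrom=chrom,
            chi2=np.zeros_like(p),
            pvalue=p,
            df=df,
            testable=np.ones(len(p), dtype=bool),
        )

    return _build


@pytest.fixture
def flat_profile():
    """A constant mean-1 profile factory."""

    def _build(length=1000, value=1.0, chrom="chrT", sample_id="s"):
        return OccupancyProfile(
            chrom=chrom,
            values=np.full(length, value),
            sample_id=sample_id,
            raw_mean=10.0,
        )

    return _build


@pytest.fixture(scope="session")
def planted_run():
    """A small simulated 3-sample experiment with planted 3-fold regions,
    shared across tests that only read from it."""
    regions = [PlantedRegion(s, s + 300, (0,), 3.0) for s in range(2_000, 50_000, 5_000)]
    cfg = SyntheticConfig(
        chrom_length=50_000,
        n_samples=3,
        reads_per_nucleosome=30,
        planted_regions=regions,
        seed=11,
    )
    samples, truth = simulate_samples(cfg)
    profiles = [profiles_from_fragments(s)["chrS"] for s in samples]
    return samples, truth, profiles
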