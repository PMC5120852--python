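import numpy as np
import pytest

from epihet import simdata


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_design(seed: int = 0) -> simdata.SimulationDesign:
    """Compact 6-sample design for fast pipeline tests."""
    low = simdata.EpialleleMixtureParams(rho=0.0)
    admixed = simdata.EpialleleMixtureParams(rho=0.10)
    groups = (("8w", 2), ("18w", 2), ("17m", 2))
    flat = {g: low for g, _ in groups}
    shifted = {"8w": admixed, "18w": low, "17m": low}
    regions = []
    cursor = 1000
    for i in range(4):
        regions.append(
            simdata.RegionSpec(
                name=f"pnull_{i}", feature_class="promoter", chrom="chr1",
                start=cursor, n_cpg=10, group_mixture=flat, pattern="mixture",
            )
        )
        cursor += 2000
    for i in range(2):
        regions.append(
            simdata.RegionSpec(
                name=f"pshift_{i}", feature_class="promoter", chrom="chr1",
                start=cursor, n_cpg=10, group_mixture=shifted, pattern="mixture",
            )
        )
        cursor += 2000
    regions.append(
        simdata.RegionSpec(
            name="ICR_T", feature_class="ICR:T", chrom="chr1",
            start=cursor, n_cpg=10, group_mixture=shifted, pattern="mixture",
        )
    )
    cursor += 2000
    regions.append(
        simdata.RegionSpec(
            name="LINE_T", feature_class="LINE", chrom="chr1", start=cursor,
            n_cpg=20,
            group_mixture={g: simdata.mixture_for_mean(0.8) for g, _ in groups},
            pattern="uniform",
        )
    )
    return simdata.SimulationDesign(
        groups=groups, regions=tuple(regions), mean_coverage=25.0, seed=seed
    )


@pytest.fixture
def tiny_dataset(tmp_path):
    """Simulated small dataset on disk plus its design."""
    design = small_design(seed=7)
    manifest = simdata.simulate_dataset(design, tmp_path / "data")
    return design, manifest
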