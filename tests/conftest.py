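import pytest

from ewdclim.pipeline import RunConfig, run_in_memory
from ewdclim.synthetic import make_benchmark_dataset

BENCH_SEED = 7


@pytest.fixture(scope="session")
def bench():
    """One paper-shaped synthetic study (63 density cores, station climate)."""
    return make_benchmark_dataset(BENCH_SEED)


@pytest.fixture(scope="session")
def bench_run(bench):
    """Full pipeline result on the benchmark (seeded bootstrap)."""
    cfg = RunConfig(seed=BENCH_SEED, calibration_span=(1953, 2008), n_boot=500)
    return run_in_memory(bench.measurements, bench.climate, cfg)
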