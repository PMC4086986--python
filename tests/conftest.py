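import matplotlib

matplotlib.use("Agg")

import pytest

import barcodegap as bg

BENCH_SEED = 11


@pytest.fixture(scope="session")
def benchmark():
    """One synthetic case-study benchmark shared across the session."""
    return bg.synthetic_benchmark(seed=BENCH_SEED)


@pytest.fixture(scope="session")
def benchmark_analysis(benchmark):
    """Full pipeline run on the benchmark (distances, scan, Klee, consensus)."""
    return bg.analyze(benchmark.coi, benchmark.table)
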