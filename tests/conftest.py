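"""Shared fixtures: synthetic experiments at two scales.

The session-scoped benchmark run executes the full pipeline once on the
default 300-protein two-condition design; end-to-end tests and the
benchmark-metric tests all read from it instead of re-running the pipeline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dialion.config import PipelineConfig
from dialion.pipeline import quantify_experiment, run_benchmark
from dialion.synth import SyntheticConfig, generate_experiment, render_spectra

SPECIES_TRUTH = {"HUMAN": "unchanged", "YEAST": "up", "ECOLI": "down"}
EXPECTED_LOG2FC = {"HUMAN": 0.0, "YEAST": 1.0, "ECOLI": -2.0}


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(seed=417, n_proteins={"HUMAN": 20, "YEAST": 10, "ECOLI": 10})


@pytest.fixture(scope="session")
def small_experiment(small_config):
    library, records, metadata, truth = generate_experiment(small_config)
    return library, records, metadata, truth


@pytest.fixture(scope="session")
def small_spectra(small_config, small_experiment):
    _, _, _, truth = small_experiment
    return render_spectra(truth, small_config)


@pytest.fixture(scope="session")
def small_result(small_config, small_experiment, small_spectra):
    library, records, metadata, _ = small_experiment
    return quantify_experiment(
        library, records, metadata, small_spectra, PipelineConfig(seed=1)
    )


@pytest.fixture(scope="session")
def benchmark_config() -> SyntheticConfig:
    """The default benchmark design: 300 proteins, 3 species, 2 x 4 runs."""
    return SyntheticConfig(seed=2026)


@pytest.fixture(scope="session")
def benchmark_experiment(benchmark_config):
    return generate_experiment(benchmark_config)


@pytest.fixture(scope="session")
def benchmark_result(benchmark_config, benchmark_experiment):
    library, records, metadata, truth = benchmark_experiment
    spectra = render_spectra(truth, benchmark_config)
    return quantify_experiment(
        library, records, metadata, spectra, PipelineConfig(seed=7)
    )


@pytest.fixture(scope="session")
def benchmark_scores(benchmark_result):
    return run_benchmark(
        benchmark_result, SPECIES_TRUTH, EXPECTED_LOG2FC, config=PipelineConfig(seed=7)
    )
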