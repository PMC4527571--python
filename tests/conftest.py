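"""Shared fixtures: one synthetic experiment reused across the suite."""

from __future__ import annotations

import random

import pytest

from mirmodule import reporting
from mirmodule import synthetic_data as synth


@pytest.fixture(scope="session")
def small_config() -> synth.SimulationConfig:
    return synth.SimulationConfig(
        seed=7,
        n_known=30,
        n_novel=10,
        genome_length=60_000,
        depth_A=30_000,
        depth_B=30_000,
        hub_inverse_targets=12,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config) -> synth.SyntheticDataset:
    return synth.simulate_all(small_config)


@pytest.fixture(scope="session")
def pipeline_result(small_dataset) -> reporting.PipelineResult:
    ds = small_dataset
    return reporting.run_in_memory(
        ds.libraries,
        ds.genome,
        ds.mature_reference,
        structural_references=ds.structural_references,
        transcripts=ds.transcripts,
        gene_de=dict(zip(ds.gene_de.gene_id, ds.gene_de.status)),
    )


@pytest.fixture()
def rng() -> random.Random:
    return random.Random(0)


def random_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))
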