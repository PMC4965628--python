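from __future__ import annotations

import io

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from daac import (
    BenchmarkConfig,
    DomainArchitecture,
    ScoringParams,
    WeightTable,
    build_architectures,
    filter_experimental,
    generate,
    parse_gaf,
    parse_hits,
    parse_obo,
    propagate,
)


def da(*elements: str, pid: str = "q") -> DomainArchitecture:
    return DomainArchitecture(protein_id=pid, elements=tuple(elements))


def unit_weights(*accessions: str) -> WeightTable:
    return WeightTable(
        weights={a: 1.0 for a in accessions}, n_total=1, n_by_domain={}
    )


def make_weights(**weights: float) -> WeightTable:
    return WeightTable(weights=dict(weights), n_total=1, n_by_domain={})


def random_da(rng: np.random.Generator, alphabet, max_len: int = 6,
              gap_rate: float = 0.25, pid: str = "q") -> DomainArchitecture:
    """Random valid DA: >= 1 real domain, no two consecutive GAPs."""
    n = int(rng.integers(1, max_len + 1))
    elements: list[str] = []
    for _ in range(n):
        if elements and elements[-1] != "GAP" and rng.random() < gap_rate:
            elements.append("GAP")
        else:
            elements.append(alphabet[rng.integers(len(alphabet))])
    if all(e == "GAP" for e in elements):
        elements.append(alphabet[rng.integers(len(alphabet))])
    return DomainArchitecture(protein_id=pid, elements=tuple(elements))


@pytest.fixture(scope="session")
def default_params() -> ScoringParams:
    return ScoringParams()


@pytest.fixture(scope="session")
def benchmark():
    """The default synthetic benchmark, generated once per session."""
    return generate(BenchmarkConfig())


@pytest.fixture(scope="session")
def benchmark_pipeline(benchmark):
    """Parsed benchmark: (das, ontology, propagated annotations)."""
    proteins, hits = parse_hits(io.StringIO(benchmark.hits_tsv))
    das = build_architectures(proteins, hits)
    ontology = parse_obo(io.StringIO(benchmark.obo_text))
    anns = propagate(
        filter_experimental(parse_gaf(io.StringIO(benchmark.gaf_text))),
        ontology,
    )
    return das, ontology, anns
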