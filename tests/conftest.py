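"""Shared fixtures.

The seed-42 synthetic dataset and its full pipeline run are expensive
(a couple of minutes), so they are built once per session and shared by
the unit and acceptance tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from srnakit.config import Thresholds
from srnakit.genome_index import build_index, map_library
from srnakit.mirna_discovery import call_mirnas
from srnakit.read_processing import collapse, filter_reads
from srnakit.synthetic_data import Dataset, simulate_dataset


@pytest.fixture(scope="session")
def thresholds() -> Thresholds:
    return Thresholds()


@pytest.fixture(scope="session")
def dataset42(thresholds) -> Dataset:
    return simulate_dataset(seed=42, thresholds=thresholds)


@dataclass
class PipelineRun:
    dataset: Dataset
    unique_reads: list
    filtered_reads: list
    candidates: list
    hits_by_read: dict


@pytest.fixture(scope="session")
def pipeline42(dataset42, thresholds) -> PipelineRun:
    uniq = collapse(dataset42.reads.records)
    filt = filter_reads(uniq, (thresholds.mirna_len_min,
                               thresholds.mirna_len_max),
                        dataset42.contaminants)
    cands = call_mirnas(filt, dataset42.genome.scaffolds,
                        dataset42.genome.genes, thresholds)
    all_filt = filter_reads(uniq, (thresholds.read_len_min,
                                   thresholds.read_len_max),
                            dataset42.contaminants)
    index = build_index(dataset42.genome.scaffolds)
    hits_by_read, _ = map_library(index, all_filt)
    return PipelineRun(dataset=dataset42, unique_reads=uniq,
                       filtered_reads=filt, candidates=cands,
                       hits_by_read=hits_by_read)
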