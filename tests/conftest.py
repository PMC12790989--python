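"""Shared fixtures: small synthetic datasets built once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from caretile import simdata, teslade

REGION = ("chrS", 0, 20_000)


@pytest.fixture(scope="session")
def small_library():
    return simdata.make_guide_library(REGION, 100, (2, 3), 30, seed=1)


@pytest.fixture(scope="session")
def null_truth(small_library):
    return simdata.ScreenTruth(
        planted_elements=[],
        control_guide_ids=set(small_library.loc[small_library.is_control, "guide_id"]),
    )


@pytest.fixture(scope="session")
def planted_truth(small_library):
    # the enriched slope is kept modest: in a 200-bin toy region a strongly
    # enriched element dominates the per-sample totals and the CPM
    # composition effect would drag every other guide significant
    elements = [
        simdata.PlantedElement("chrS", 5000, 5300, -0.05, "depleted"),
        simdata.PlantedElement("chrS", 12_000, 12_300, 0.02, "enriched"),
    ]
    return simdata.ScreenTruth(
        planted_elements=elements,
        control_guide_ids=set(small_library.loc[small_library.is_control, "guide_id"]),
    )


@pytest.fixture(scope="session")
def screen_data(small_library, planted_truth):
    counts, samples = simdata.simulate_screen_counts(
        small_library, planted_truth, [5, 20, 29, 33], 2, 2e5, seed=11
    )
    return counts, samples


@pytest.fixture(scope="session")
def gene_panel():
    genes = [f"gene{i:02d}" for i in range(12)]
    return pd.DataFrame(
        {
            "gene": genes,
            "chrom": "chrS",
            "tss": np.linspace(500, 19_500, 12).astype(int),
            "strand": (["+", "-"] * 6),
        }
    )


@pytest.fixture(scope="session")
def tesla_library():
    """Compact library (~75 targeting guides) so 2,000 cells give every
    guide a workable number of carrier cells."""
    return simdata.make_guide_library(("chrS", 0, 3000), 100, (2, 3), 15, seed=6)


@pytest.fixture(scope="session")
def tesla_small(tesla_library, gene_panel):
    """2,000-cell experiment with two strong planted links."""
    targeting = tesla_library.loc[~tesla_library.is_control, "guide_id"]
    links = [(targeting.iloc[10], "gene03", 1.5), (targeting.iloc[50], "gene08", -1.5)]
    truth = simdata.TeslaTruth(
        links=links,
        baseline_means={g: 6.0 for g in gene_panel["gene"]},
        batch_factors={"run1": 1.0, "run2": 1.3},
    )
    expt = simdata.simulate_tesla_counts(
        gene_panel, tesla_library, truth, n_cells=2000, moi=1.0, seed=7
    )
    return expt, truth


@pytest.fixture(scope="session")
def tesla_filtered(tesla_small):
    expt, truth = tesla_small
    assignment = teslade.threshold_guide_counts(expt.guide_counts)
    filtered = teslade.filter_cells_genes(expt, assignment)
    assignment = teslade.GuideAssignment(
        filtered.guide_counts, assignment.threshold, assignment.method
    )
    return filtered, assignment, truth
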