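"""Shared fixtures: one default-scale synthetic study, generated once per
session, plus a small builder for hand-crafted expression matrices."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fusiontarget import synthgen as sg
from fusiontarget.cohorts import ExpressionMatrix

DEFAULT_SEED = 11


@pytest.fixture(scope="session")
def config() -> sg.SynthConfig:
    return sg.SynthConfig(seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def dataset(config) -> sg.SynthDataset:
    return sg.generate(config)


@pytest.fixture(scope="session")
def synth_dir(dataset, tmp_path_factory):
    d = tmp_path_factory.mktemp("synth")
    dataset.write(d)
    return d


def make_expr(
    values: np.ndarray | list,
    genes: list[str] | None = None,
    samples: list[str] | None = None,
    types: list[str] | None = None,
    cohort: str = "toy",
) -> ExpressionMatrix:
    """Build a labelled ExpressionMatrix from a raw FPKM array."""
    arr = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{i}" for i in range(arr.shape[1])]
    types = types or ["T"] * len(samples)
    df = pd.DataFrame(arr, index=genes, columns=samples)
    labels = pd.DataFrame(
        {"cohort": cohort, "type_label": types}, index=pd.Index(samples, name="sample_id")
    )
    return ExpressionMatrix(values=df, labels=labels)
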