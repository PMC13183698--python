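"""Shared fixtures: the rendered synthetic study corpus (built once)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rppg_confidence import label_windows
from rppg_confidence.pipeline import synthetic_study
from rppg_confidence.synthetic import FEATURE_NAMES, generate_feature_table

#: Seed for every seeded fixture in the suite.
SUITE_SEED = 1


@pytest.fixture(scope="session")
def study_records() -> pd.DataFrame:
    """Window records for the full synthetic motion study (~1 min to build)."""
    return synthetic_study(seed=SUITE_SEED)


@pytest.fixture(scope="session")
def labeled_study(study_records) -> pd.DataFrame:
    return label_windows(study_records)


def make_records_from_table(table: pd.DataFrame, n_subjects: int = 10,
                            n_datasets: int = 1, seed: int = 0) -> pd.DataFrame:
    """Dress a Gaussian feature table up as window records.

    Subjects and datasets are assigned round-robin; the absolute error is set
    consistently with the class label (1 bpm for reliable, 8 bpm for
    unreliable) so that relabeling reproduces the table's labels.
    """
    rng = np.random.default_rng(seed)
    df = table.copy().reset_index(drop=True)
    order = rng.permutation(len(df))
    df = df.iloc[order].reset_index(drop=True)
    idx = np.arange(len(df))
    df["subject_id"] = [f"s{i % n_subjects:02d}" for i in idx]
    df["dataset_id"] = [f"d{(i % n_subjects) % n_datasets}" for i in idx]
    df["video_id"] = df["subject_id"] + "_v0"
    df["window_end_s"] = idx + 12.0
    df["method"] = "GREEN"
    df["hr_ref_bpm"] = 80.0
    df["abs_err_bpm"] = np.where(df["label"] == 1, 1.0, 8.0)
    df["hr_bpm"] = df["hr_ref_bpm"] + df["abs_err_bpm"]
    df["label"] = df["label"].astype(float)
    return df


@pytest.fixture()
def gaussian_records() -> pd.DataFrame:
    """Well-separated 4-D Gaussian records with subjects and one dataset."""
    return make_records_from_table(
        generate_feature_table(400, 3.0, seed=SUITE_SEED), n_subjects=10)
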