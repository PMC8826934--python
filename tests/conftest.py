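import numpy as np
import pytest

from tempomics import MoleculeAnnotation, TimeGrid, TimecourseDataset


def make_dataset(values, times, groups=None, subjects=None):
    """Build a TimecourseDataset from a (subjects x molecules x times) array."""
    values = np.asarray(values, dtype=float)
    if values.ndim == 2:  # single molecule convenience
        values = values[:, None, :]
    n_sub, n_mol, _ = values.shape
    subjects = subjects or [f"S{j + 1}" for j in range(n_sub)]
    groups = groups or ["other"] * n_mol
    molecules = [MoleculeAnnotation(f"M{k + 1}", g) for k, g in enumerate(groups)]
    return TimecourseDataset(subjects, molecules, TimeGrid(tuple(times)), values)


@pytest.fixture
def two_subject_dataset():
    """2 subjects x 1 molecule on grid (0, 60): the hand-arithmetic example."""
    return make_dataset([[10.0, 20.0], [20.0, 40.0]], (0, 60))


@pytest.fixture(scope="session")
def study_run(tmp_path_factory):
    """One full pipeline run on the study-like preset, shared across tests."""
    import tempomics as tm

    ds, truth = tm.generate_dataset(tm.study_like(seed=11))
    cfg = tm.PipelineConfig(
        output_dir=str(tmp_path_factory.mktemp("study_run")), seed=11
    )
    summary = tm.run_pipeline(cfg, dataset=ds)
    return ds, truth, cfg, summary
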