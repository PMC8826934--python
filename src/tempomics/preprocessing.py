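"""Missing-data exclusion and inter-individual normalization.

A molecule is excluded when its missing-cell count exceeds the top 5% of its
subject x time budget (strictly greater than ``floor(N_individual x
N_time_raw x 0.05)``; for 20 subjects x 14 raw draws that is 14 cells).

Normalization expresses each subject's excursion from fasting in units of
the molecule's typical cross-subject dispersion:

    S_kt   = population s.d. of x across subjects at time t  (denominator N)
    Sbar_k = time-mean of S_kt
    Y_jkt  = (x_jkt - x_jk0) / Sbar_k
    Ybar_kt = subject mean of Y_jkt

The population (N) denominator here is deliberate and is *not* shared with
the TVRI z-scores, which use the sample (N-1) denominator; the two
statistics are defined that way and each module implements its own form.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import TimecourseDataset, TimeGrid

logger = logging.getLogger("tempomics")


@dataclass
class NormalizedDataset:
    """Normalized trajectories Y, their cross-subject means, and exclusions."""

    subjects: list[str]
    molecule_ids: list[str]
    grid: TimeGrid
    Y: np.ndarray          # (n_subjects, n_molecules, n_times)
    Ybar: np.ndarray       # (n_molecules, n_times)
    Sbar: np.ndarray       # (n_molecules,), original units
    excluded: list[tuple[str, str]] = field(default_factory=list)

    def ybar_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.Ybar, index=self.molecule_ids, columns=list(self.grid))

    def y_frame(self) -> pd.DataFrame:
        rows = []
        for j, s in enumerate(self.subjects):
            for k, m in enumerate(self.molecule_ids):
                for t, time in enumerate(self.grid):
                    rows.append((s, m, time, self.Y[j, k, t]))
        return pd.DataFrame(rows, columns=["subject_id", "molecule", "time_min", "Y"])


def missing_cell_threshold(n_subjects: int, n_times_raw: int, top_fraction: float = 0.05) -> int:
    """Maximum tolerated missing cells: floor(n_subjects * n_times * fraction)."""
    if not 0.0 <= top_fraction <= 1.0:
        raise ValueError(f"top_fraction must lie in [0, 1], got {top_fraction}")
    return math.floor(n_subjects * n_times_raw * top_fraction)


def filter_missing_molecules(
    ds: TimecourseDataset, top_fraction: float = 0.05
) -> tuple[TimecourseDataset, pd.DataFrame]:
    """Drop molecules whose missing-cell count exceeds the 5% budget.

    Applied to the raw (pre-collapse) grid so the cell budget matches the
    full draw schedule. Returns the filtered dataset and a per-molecule
    report (molecule, n_missing, threshold, excluded).
    """
    threshold = missing_cell_threshold(ds.n_subjects, ds.grid.n_times, top_fraction)
    n_missing = np.isnan(ds.values).sum(axis=(0, 2))
    excluded = n_missing > threshold  # strictly greater: at-threshold retained
    report = pd.DataFrame(
        {
            "molecule": ds.molecule_ids,
            "n_missing": n_missing.astype(int),
            "threshold": threshold,
            "excluded": excluded,
        }
    )
    keep = [m for m, drop in zip(ds.molecule_ids, excluded) if not drop]
    for m, n in zip(report.loc[excluded, "molecule"], report.loc[excluded, "n_missing"]):
        logger.info("excluding %r: %d missing cells > threshold %d", m, n, threshold)
    return ds.subset_molecules(keep), report


def normalize_timecourses(ds: TimecourseDataset) -> NormalizedDataset:
    """Compute Y, Ybar and Sbar for every molecule on the post-collapse grid.

    Per-time-point statistics use the subjects available at that time
    (complete-case per time point); a time point with fewer than 2 available
    subjects leaves S undefined there and is skipped in the Sbar average.
    Molecules with Sbar = 0 (constant across subjects and times) are
    excluded with reason "zero dispersion".
    """
    if 0 not in ds.grid.times:
        raise ValueError("normalization requires the fasting time point t=0")
    x = ds.values
    n_sub, n_mol, n_t = x.shape

    present = ~np.isnan(x)
    available = present.sum(axis=0)  # (n_mol, n_t)
    x0 = np.where(present, x, 0.0)
    xbar = x0.sum(axis=0) / np.maximum(available, 1)
    # population denominator N (as defined), over available subjects
    dev2 = (np.where(present, x - xbar[None, :, :], 0.0) ** 2).sum(axis=0)
    S = np.where(available >= 2, np.sqrt(dev2 / np.maximum(available, 1)), np.nan)
    s_valid = ~np.isnan(S)
    n_valid_t = s_valid.sum(axis=1)
    Sbar = np.where(
        n_valid_t > 0,
        np.where(s_valid, S, 0.0).sum(axis=1) / np.maximum(n_valid_t, 1),
        np.nan,
    )

    excluded: list[tuple[str, str]] = []
    keep_mask = np.ones(n_mol, dtype=bool)
    for k, mol in enumerate(ds.molecule_ids):
        if np.isnan(Sbar[k]):
            excluded.append((mol, "no time point with >= 2 subjects"))
            keep_mask[k] = False
        elif Sbar[k] == 0.0:
            excluded.append((mol, "zero dispersion"))
            keep_mask[k] = False
    for mol, reason in excluded:
        logger.info("normalization excluded %r: %s", mol, reason)

    fast = x[:, :, ds.grid.fasting_index][:, :, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        Y = (x - fast) / Sbar[None, :, None]
    y_present = ~np.isnan(Y)
    n_y = y_present.sum(axis=0)
    Ybar = np.where(
        n_y > 0,
        np.where(y_present, Y, 0.0).sum(axis=0) / np.maximum(n_y, 1),
        np.nan,
    )

    idx = np.flatnonzero(keep_mask)
    return NormalizedDataset(
        subjects=list(ds.subjects),
        molecule_ids=[ds.molecule_ids[k] for k in idx],
        grid=ds.grid,
        Y=Y[:, idx, :],
        Ybar=Ybar[idx, :],
        Sbar=Sbar[idx],
        excluded=excluded,
    )
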