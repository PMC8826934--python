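"""Inter-individual and inter-molecule temporal similarity indices.

Three bespoke statistics characterise a molecule's time course across a
cohort:

TVRI (temporal variation of relationships among individuals)
    At each time point the concentrations are z-scored across subjects
    (sample s.d., denominator N-1). A subject whose z-score is constant
    over time keeps the same position relative to the cohort throughout the
    test. TVRI = 1 - mean over subjects of the time-wise s.d. of their
    z-scores (denominator N_time - 1); it equals 1 exactly when every
    subject's relative position never changes, and decreases as subjects
    reshuffle.

TPSI (temporal pattern similarity among individuals)
    For every unordered pair of subjects, both difference-from-fasting
    trajectories are laid side by side; one Pearson correlation over the
    full concatenation of all N-choose-2 pairs (190 for 20 subjects) gives
    the index. The fasting entries (identically 0) are part of the
    concatenation by definition.

TPSM (temporal pattern similarity among molecules)
    Each molecule's difference-from-fasting trajectories are concatenated
    over subjects in a fixed subject order; TPSM(k, l) is the Pearson
    correlation of the two concatenations and TPSM_Abs its absolute value.

Missing values contribute nothing: only positions where both members of a
comparison are present enter the correlation (pairwise complete).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import DifferencedDataset, TimecourseDataset

logger = logging.getLogger("tempomics")


@dataclass
class SimilarityTable:
    per_molecule: pd.DataFrame         # molecule, TPSI, TVRI (+skip reasons)
    tpsm: pd.DataFrame                 # molecule x molecule, in [-1, 1]
    tpsm_abs: pd.DataFrame             # |TPSM|
    fasting_correlation: pd.DataFrame | None = None  # molecule x time
    skipped: dict[str, str] = field(default_factory=dict)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r over jointly finite positions; NaN on zero variance."""
    ok = ~np.isnan(a) & ~np.isnan(b)
    a, b = a[ok], b[ok]
    if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return np.nan
    a = a - a.mean()
    b = b - b.mean()
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


def tvri(ds: TimecourseDataset) -> pd.DataFrame:
    """Per-molecule TVRI; molecules with any missing cell are skipped.

    Returns a frame (molecule, tvri, reason) where ``reason`` explains a
    NaN: incomplete data or zero cross-subject variance at some time point
    (the z-score is then undefined), mirroring the exclusion of molecules
    not measured at every draw.
    """
    rows = []
    for k, mol in enumerate(ds.molecule_ids):
        x = ds.values[:, k, :]
        if np.isnan(x).any():
            rows.append((mol, np.nan, "missing data"))
            continue
        sd_t = x.std(axis=0, ddof=1)
        if np.any(sd_t == 0):
            rows.append((mol, np.nan, "zero cross-subject variance"))
            continue
        z = (x - x.mean(axis=0)) / sd_t
        s_z = z.std(axis=1, ddof=1)  # per-subject variation over time
        rows.append((mol, float(1.0 - s_z.mean()), ""))
    return pd.DataFrame(rows, columns=["molecule", "tvri", "reason"])


def tpsi(dd: DifferencedDataset) -> pd.DataFrame:
    """Per-molecule TPSI over all unordered subject-pair concatenations."""
    n_sub = len(dd.subjects)
    pairs = [(i, j) for i in range(n_sub) for j in range(i + 1, n_sub)]
    rows = []
    for k, mol in enumerate(dd.molecule_ids):
        if mol in dd.flagged:
            rows.append((mol, np.nan, "no fasting values"))
            continue
        xp = dd.xprime[:, k, :]
        xs, ys = [], []
        for i, j in pairs:
            ok = ~np.isnan(xp[i]) & ~np.isnan(xp[j])
            xs.append(xp[i][ok])
            ys.append(xp[j][ok])
        X = np.concatenate(xs)
        Y = np.concatenate(ys)
        r = _pearson(X, Y)
        rows.append((mol, r, "" if not np.isnan(r) else "zero variance"))
    return pd.DataFrame(rows, columns=["molecule", "tpsi", "reason"])


def tpsi_pair_count(n_subjects: int) -> int:
    """Number of subject pairs entering the TPSI concatenation (n choose 2)."""
    return n_subjects * (n_subjects - 1) // 2


def tpsm(dd: DifferencedDataset) -> tuple[pd.DataFrame, pd.DataFrame]:
    """TPSM and TPSM_Abs matrices over subject-concatenated trajectories."""
    mols = dd.molecule_ids
    if len(mols) < 2:
        raise ValueError("TPSM needs at least 2 molecules")
    n = len(mols)
    # concatenate subjects in the dataset's fixed subject order
    concat = dd.xprime.transpose(1, 0, 2).reshape(n, -1)
    mat = np.full((n, n), np.nan)
    usable = [m not in dd.flagged for m in mols]
    for a in range(n):
        if not usable[a]:
            continue
        if np.nanstd(concat[a]) > 0:
            mat[a, a] = 1.0
        for b in range(a + 1, n):
            if not usable[b]:
                continue
            mat[a, b] = mat[b, a] = _pearson(concat[a], concat[b])
    tpsm_df = pd.DataFrame(mat, index=mols, columns=mols)
    return tpsm_df, tpsm_df.abs()


def fasting_correlation_profile(
    ds: TimecourseDataset, molecules: list[str] | None = None, min_subjects: int = 3
) -> pd.DataFrame:
    """Cross-subject Pearson r between fasting and each time point.

    Rows are molecules (optionally a responder subset), columns the grid
    times; the t=0 column is identically 1 wherever the fasting values
    vary. The resulting matrix is what the 4-cluster fasting-correlation
    clustering operates on.
    """
    mols = molecules if molecules is not None else ds.molecule_ids
    i0 = ds.grid.fasting_index
    out = np.full((len(mols), ds.grid.n_times), np.nan)
    for row, mol in enumerate(mols):
        k = ds.molecule_index(mol)
        x0 = ds.values[:, k, i0]
        if np.nanstd(x0) == 0:
            logger.warning("molecule %r has zero fasting variance; row undefined", mol)
            continue
        for t_idx in range(ds.grid.n_times):
            xt = ds.values[:, k, t_idx]
            ok = ~np.isnan(x0) & ~np.isnan(xt)
            if ok.sum() < min_subjects:
                continue
            out[row, t_idx] = _pearson(x0, xt)
    return pd.DataFrame(out, index=mols, columns=list(ds.grid))


def similarity_table(
    ds: TimecourseDataset,
    dd: DifferencedDataset,
    fasting_molecules: list[str] | None = None,
) -> SimilarityTable:
    """Bundle TPSI, TVRI, TPSM and the fasting-correlation profile."""
    tv = tvri(ds)
    tp = tpsi(dd)
    per_molecule = tp.merge(tv, on="molecule", suffixes=("_tpsi", "_tvri"))
    tpsm_df, tpsm_abs_df = tpsm(dd)
    fast = fasting_correlation_profile(ds, fasting_molecules)
    skipped = {
        r["molecule"]: r["reason"]
        for _, r in tv.iterrows()
        if r["reason"]
    }
    return SimilarityTable(
        per_molecule=per_molecule,
        tpsm=tpsm_df,
        tpsm_abs=tpsm_abs_df,
        fasting_correlation=fast,
        skipped=skipped,
    )
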