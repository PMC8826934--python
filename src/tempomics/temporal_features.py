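"""Per-individual amplitude and rate features: AUC and T_AUC1/2.

The per-subject amplitude of a molecule's response is the signed trapezoidal
area of its difference-from-fasting trajectory x' over 0-240 min
(concentration x min); the per-subject rate is T_AUC1/2, the earliest time
at which the cumulative signed area first reaches half the total, located by
linear interpolation inside the bracketing interval. A trajectory whose
cumulative area crosses the half-way mark more than once is flagged
non-monotone and keeps the earliest crossing. These two features are the
individual-level counterparts of the PC1 (amplitude) and PC1:PC2 (rate)
scores of the panel-level PCA.

The correlation screen relates each target molecule's feature vector across
subjects to that of a reference molecule (glucose or insulin), with Storey
q-values over the pooled screen family and significance at q < 0.1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import DifferencedDataset
from .response_detection import storey_qvalues


@dataclass
class FeatureTable:
    """Per (subject, molecule): auc, t_auc_half and validity flags."""

    table: pd.DataFrame  # subject, molecule, auc, t_auc_half, auc_defined, non_monotone

    def feature_matrix(self, feature: str) -> pd.DataFrame:
        """subject x molecule matrix of one feature."""
        return self.table.pivot(index="subject", columns="molecule", values=feature)


def _bridge_missing(times: np.ndarray, traj: np.ndarray):
    """Linearly interpolate interior NaNs; drop leading/trailing NaNs."""
    ok = ~np.isnan(traj)
    if ok.sum() < 2:
        return None, None
    t_ok, x_ok = times[ok], traj[ok]
    filled = np.interp(times, t_ok, x_ok)
    keep = (times >= t_ok[0]) & (times <= t_ok[-1])
    return times[keep], filled[keep]


def auc(times, trajectory) -> float:
    """Signed trapezoidal area of x' over the observation window.

    Interior missing points are bridged by linear interpolation between
    their neighbours; fewer than 2 points leaves the area undefined (NaN).
    """
    times = np.asarray(times, dtype=float)
    traj = np.asarray(trajectory, dtype=float)
    t, x = _bridge_missing(times, traj)
    if t is None:
        return np.nan
    return float(np.trapezoid(x, t))


def t_auc_half(times, trajectory) -> tuple[float, bool]:
    """(T_AUC1/2, non_monotone_flag).

    The cumulative signed area is piecewise quadratic between grid points;
    the crossing of AUC/2 is located by linear interpolation of the
    cumulative area within the bracketing interval, and the earliest
    crossing wins. Undefined (NaN, False) when the total area is 0 or the
    trajectory has fewer than 2 points.
    """
    times = np.asarray(times, dtype=float)
    traj = np.asarray(trajectory, dtype=float)
    t, x = _bridge_missing(times, traj)
    if t is None:
        return np.nan, False
    seg = np.diff(t) * (x[:-1] + x[1:]) / 2.0
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total == 0.0:
        return np.nan, False
    half = total / 2.0
    # crossings of the half level, in the direction of the total's sign
    rel = (cum - half) * np.sign(total)
    crossing_idx = np.flatnonzero((rel[:-1] < 0) & (rel[1:] >= 0))
    if crossing_idx.size == 0:
        return np.nan, False
    i = int(crossing_idx[0])
    # linear interpolation of the cumulative curve inside [t_i, t_{i+1}]
    dc = cum[i + 1] - cum[i]
    frac = (half - cum[i]) / dc if dc != 0 else 0.0
    t_half = t[i] + frac * (t[i + 1] - t[i])
    non_monotone = crossing_idx.size > 1
    return float(t_half), bool(non_monotone)


def feature_table(dd: DifferencedDataset, molecules: list[str] | None = None) -> FeatureTable:
    """AUC and T_AUC1/2 for every (subject, molecule)."""
    mols = molecules if molecules is not None else dd.molecule_ids
    times = np.asarray(dd.grid.times, dtype=float)
    post = times >= 0
    rows = []
    for mol in mols:
        k = dd.molecule_index(mol)
        for j, subj in enumerate(dd.subjects):
            traj = dd.xprime[j, k, post]
            area = auc(times[post], traj)
            t_half, flag = t_auc_half(times[post], traj)
            rows.append(
                dict(
                    subject=subj,
                    molecule=mol,
                    auc=area,
                    t_auc_half=t_half,
                    auc_defined=not np.isnan(area),
                    non_monotone=flag,
                )
            )
    return FeatureTable(pd.DataFrame(rows))


def feature_correlation_screen(
    ft: FeatureTable,
    references: list[str],
    targets: list[str],
    q_threshold: float = 0.1,
    lam: float = 0.5,
    min_subjects: int = 3,
) -> pd.DataFrame:
    """Pearson r of per-subject features between references and targets.

    One row per (reference, target, feature); Storey q-values are computed
    over the pooled family of all screen p-values. Pairs with degenerate
    variance or fewer than ``min_subjects`` complete subjects are skipped.
    """
    rows = []
    for feature in ("auc", "t_auc_half"):
        matrix = ft.feature_matrix(feature)
        for ref in references:
            if ref not in matrix.columns:
                continue
            for target in targets:
                if target == ref or target not in matrix.columns:
                    continue
                a = matrix[ref].to_numpy(dtype=float)
                b = matrix[target].to_numpy(dtype=float)
                ok = ~np.isnan(a) & ~np.isnan(b)
                if ok.sum() < min_subjects:
                    continue
                if np.ptp(a[ok]) == 0 or np.ptp(b[ok]) == 0:
                    continue
                with warnings.catch_warnings():
                    # T_AUC1/2 is scale-invariant, so its spread across
                    # subjects can be legitimately tiny
                    warnings.simplefilter("ignore", stats.NearConstantInputWarning)
                    r, p = stats.pearsonr(a[ok], b[ok])
                rows.append(
                    dict(reference=ref, target=target, feature=feature,
                         r=float(r), p=float(p), n=int(ok.sum()))
                )
    screen = pd.DataFrame(rows, columns=["reference", "target", "feature", "r", "p", "n"])
    if len(screen):
        screen["q"] = storey_qvalues(screen["p"].to_numpy(), lam=lam)
        screen["significant"] = screen["q"] < q_threshold
    else:
        screen["q"] = []
        screen["significant"] = []
    return screen
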