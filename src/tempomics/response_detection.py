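"""Glucose-responsive molecule calling.

A molecule is called responsive when, at some post-ingestion time point, its
mean log2 fold change from fasting exceeds 0.585 in magnitude (a 1.5-fold
change, since 2^0.585 = 1.5) *and* the Storey q-value of the paired t-test
at that time point is below 0.1. The direction of a responder (increase or
decrease) is read off the sign of the change at the earliest significant
time point, so molecules that cross zero later keep the direction of their
first significant excursion. The same operation applied to a water-control
arm acts as the negative control.

Fold changes are computed per subject and then averaged —
``mean_j log2(x_jt / x_j0)`` — which matches the paired design of the test;
the ratio-of-means alternative is available via ``fc_mode="ratio_of_means"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import TimecourseDataset

logger = logging.getLogger("tempomics")

FC_THRESHOLD = 0.585   # |log2 FC| cut; 2**0.585 = 1.5-fold
Q_THRESHOLD = 0.1
MIN_PAIRS = 3


@dataclass
class ResponseTable:
    """Per (molecule, time) statistics and per-molecule responder calls."""

    per_time: pd.DataFrame    # molecule, time_min, log2fc, t, p, q, significant
    per_molecule: pd.DataFrame  # molecule, responder, direction, earliest_sig_time

    @property
    def responders(self) -> list[str]:
        mask = self.per_molecule["responder"]
        return list(self.per_molecule.loc[mask, "molecule"])


def paired_tests(ds: TimecourseDataset) -> pd.DataFrame:
    """Two-tailed paired t-test of x(t) vs x(0) per (molecule, time > 0).

    Pairs with a missing value at either end are dropped pairwise; cells
    with fewer than 3 complete pairs get ``p = NaN``. The degenerate case of
    identical nonzero differences across all subjects (zero variance) is
    reported as ``p = 0`` with ``degenerate = True``; identical zero
    differences give ``t = 0, p = 1``.
    """
    i0 = ds.grid.fasting_index
    rows = []
    for k, mol in enumerate(ds.molecule_ids):
        x0 = ds.values[:, k, i0]
        for t_idx, time in enumerate(ds.grid):
            if time <= 0:
                continue
            xt = ds.values[:, k, t_idx]
            ok = ~np.isnan(x0) & ~np.isnan(xt)
            n = int(ok.sum())
            if n < MIN_PAIRS:
                rows.append((mol, time, n, np.nan, np.nan, False))
                continue
            diff = xt[ok] - x0[ok]
            if np.all(diff == diff[0]):
                if diff[0] == 0.0:
                    rows.append((mol, time, n, 0.0, 1.0, False))
                else:
                    rows.append((mol, time, n, np.inf * np.sign(diff[0]), 0.0, True))
                continue
            t_stat, p = stats.ttest_rel(xt[ok], x0[ok])
            rows.append((mol, time, n, float(t_stat), float(p), False))
    return pd.DataFrame(
        rows, columns=["molecule", "time_min", "n_pairs", "t", "p", "degenerate"]
    )


def storey_pi0(p: np.ndarray, lam: float = 0.5, smoother: bool = False) -> float:
    """Estimate the null proportion pi0.

    Fixed-lambda estimator ``#{p > lambda} / ((1 - lambda) m)`` by default;
    with ``smoother=True`` a natural cubic spline of pi0(lambda) over the
    grid 0.05..0.90 is evaluated at the largest lambda.
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    if smoother:
        grid = np.arange(0.05, 0.901, 0.05)
        pi0s = np.array([(p > g).sum() / ((1.0 - g) * m) for g in grid])
        from scipy.interpolate import CubicSpline

        pi0 = float(CubicSpline(grid, pi0s, bc_type="natural")(grid[-1]))
    else:
        pi0 = (p > lam).sum() / ((1.0 - lam) * m)
    return float(min(max(pi0, 1.0 / m), 1.0))  # clip into (0, 1]


def storey_qvalues(
    p, lam: float = 0.5, smoother: bool = False, pi0: float | None = None
) -> np.ndarray:
    """Storey q-values: ``q_i = pi0 * min_{p_j >= p_i} (m p_j / rank_j)``.

    Equivalent to pi0 times the Benjamini-Hochberg adjusted p-values.
    NaN entries are passed through and do not count toward the family size.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    valid = ~np.isnan(p)
    pv = p[valid]
    if pv.size == 0:
        return np.full(p.shape, np.nan)
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    pi0_hat = storey_pi0(pv, lam=lam, smoother=smoother) if pi0 is None else pi0

    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    # step-up: running minimum from the largest p downwards
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(pi0_hat * q_sorted, 0.0, 1.0)
    out = np.full(p.shape, np.nan)
    out[valid] = q
    return out


def log2_fold_changes(ds: TimecourseDataset, mode: str = "per_subject") -> pd.DataFrame:
    """Mean log2 fold change from fasting per (molecule, time > 0).

    ``per_subject`` (default): mean over subjects of log2(x_t / x_0), pairs
    with a nonpositive or missing value dropped with a warning.
    ``ratio_of_means``: log2(mean x_t / mean x_0) over complete pairs.
    """
    if mode not in ("per_subject", "ratio_of_means"):
        raise ValueError(f"unknown fold-change mode {mode!r}")
    i0 = ds.grid.fasting_index
    rows = []
    warned = set()
    for k, mol in enumerate(ds.molecule_ids):
        x0 = ds.values[:, k, i0]
        for t_idx, time in enumerate(ds.grid):
            if time <= 0:
                continue
            xt = ds.values[:, k, t_idx]
            ok = ~np.isnan(x0) & ~np.isnan(xt)
            pos = ok & (x0 > 0) & (xt > 0)
            if pos.sum() < ok.sum() and mol not in warned:
                logger.warning(
                    "molecule %r has nonpositive values; cells dropped from fold change", mol
                )
                warned.add(mol)
            if pos.sum() == 0:
                rows.append((mol, time, np.nan))
                continue
            if mode == "per_subject":
                fc = float(np.mean(np.log2(xt[pos] / x0[pos])))
            else:
                fc = float(np.log2(np.mean(xt[pos]) / np.mean(x0[pos])))
            rows.append((mol, time, fc))
    return pd.DataFrame(rows, columns=["molecule", "time_min", "log2fc"])


def call_responders(
    ds: TimecourseDataset,
    fc_threshold: float = FC_THRESHOLD,
    q_threshold: float = Q_THRESHOLD,
    family: str = "pooled",
    lam: float = 0.5,
    smoother: bool = False,
    fc_mode: str = "per_subject",
) -> ResponseTable:
    """Full responder screen: fold changes, paired tests, q-values, calls.

    ``family`` controls the multiple-testing family for Storey's procedure:
    ``"pooled"`` (default) treats all molecule x time tests as one family;
    ``"per-molecule"`` adjusts each molecule's time course separately.
    Both threshold comparisons are strict (``>`` for |log2FC|, ``<`` for q).
    """
    tests = paired_tests(ds)
    fcs = log2_fold_changes(ds, mode=fc_mode)
    table = tests.merge(fcs, on=["molecule", "time_min"], how="left")

    if family == "pooled":
        table["q"] = storey_qvalues(table["p"].to_numpy(), lam=lam, smoother=smoother)
    elif family == "per-molecule":
        table["q"] = np.nan
        for mol, idx in table.groupby("molecule").groups.items():
            table.loc[idx, "q"] = storey_qvalues(
                table.loc[idx, "p"].to_numpy(), lam=lam, smoother=smoother
            )
    else:
        raise ValueError(f"unknown family {family!r}")

    table["significant"] = (
        (table["log2fc"].abs() > fc_threshold) & (table["q"] < q_threshold)
    ).fillna(False)

    mol_rows = []
    for mol, sub in table.groupby("molecule", sort=False):
        sig = sub[sub["significant"]].sort_values("time_min")
        if len(sig):
            first = sig.iloc[0]
            direction = "increase" if first["log2fc"] > 0 else "decrease"
            mol_rows.append((mol, True, direction, int(first["time_min"])))
        else:
            mol_rows.append((mol, False, "none", None))
    per_molecule = pd.DataFrame(
        mol_rows, columns=["molecule", "responder", "direction", "earliest_sig_time"]
    )
    per_time = table[
        ["molecule", "time_min", "log2fc", "t", "p", "q", "significant", "n_pairs", "degenerate"]
    ]
    return ResponseTable(per_time=per_time, per_molecule=per_molecule)
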