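"""Domain containers and I/O for multi-subject blood-molecule time courses.

The central object is :class:`TimecourseDataset`: a dense ``subject x
molecule x time`` array of concentrations (NaN marks a missing draw) with a
sampling grid in minutes since glucose ingestion and a molecule -> metabolic
group annotation. The canonical interchange format is a tidy long CSV with
one measurement per row, which makes missing values unambiguous (an absent or
empty cell) and round-trips exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("tempomics")

#: Closed set of metabolic group labels used throughout the pipeline.
METABOLIC_GROUPS = (
    "glucose-related",
    "lipid",
    "amino acid",
    "ion",
    "hormone",
    "other",
)

#: Post-ingestion sampling grid of the reference study design, in minutes.
STUDY_GRID = (0, 10, 20, 30, 45, 60, 75, 90, 120, 150, 180, 210, 240)


@dataclass(frozen=True)
class TimeGrid:
    """Ordered sampling times in integer minutes since ingestion.

    The grid must be strictly increasing, contain the fasting time 0, and may
    reach back at most 10 min before ingestion (the duplicate fasting draw).
    """

    times: tuple[int, ...]

    def __post_init__(self) -> None:
        times = tuple(int(t) for t in self.times)
        object.__setattr__(self, "times", times)
        if len(times) < 1:
            raise ValueError("time grid is empty")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(f"time grid must be strictly increasing: {times}")
        if 0 not in times:
            raise ValueError("time grid must contain the fasting time 0")
        if times[0] < -10:
            raise ValueError("times before -10 min are not part of the protocol")

    @property
    def fasting_index(self) -> int:
        return self.times.index(0)

    @property
    def n_times(self) -> int:
        return len(self.times)

    def __iter__(self):
        return iter(self.times)

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class MoleculeAnnotation:
    """A measured blood molecule and its metabolic group."""

    molecule_id: str
    metabolic_group: str = "other"
    display_name: str = ""

    def __post_init__(self) -> None:
        if self.metabolic_group not in METABOLIC_GROUPS:
            raise ValueError(
                f"unknown metabolic group {self.metabolic_group!r} for "
                f"{self.molecule_id!r}; expected one of {METABOLIC_GROUPS}"
            )
        if not self.display_name:
            object.__setattr__(self, "display_name", self.molecule_id)


@dataclass
class TimecourseDataset:
    """Concentrations indexed by (subject, molecule, time).

    ``values[j, k, t]`` is the concentration of molecule ``k`` in subject
    ``j`` at grid position ``t`` in the molecule's original measurement
    units; ``NaN`` marks a missing draw. Subjects and molecules keep their
    input order and all outputs carry ids, never positional indices.
    """

    subjects: list[str]
    molecules: list[MoleculeAnnotation]
    grid: TimeGrid
    values: np.ndarray
    demographics: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.subjects), len(self.molecules), self.grid.n_times)
        if self.values.shape != expected:
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"(subjects, molecules, times) = {expected}"
            )
        ids = [m.molecule_id for m in self.molecules]
        if len(set(ids)) != len(ids):
            raise ValueError("molecule ids are not unique")
        if len(set(self.subjects)) != len(self.subjects):
            raise ValueError("subject ids are not unique")

    @property
    def molecule_ids(self) -> list[str]:
        return [m.molecule_id for m in self.molecules]

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def groups(self) -> dict[str, str]:
        """molecule_id -> metabolic group."""
        return {m.molecule_id: m.metabolic_group for m in self.molecules}

    def molecule_index(self, molecule_id: str) -> int:
        return self.molecule_ids.index(molecule_id)

    def get(self, subject: str, molecule_id: str) -> np.ndarray:
        """One subject's trajectory for one molecule (length n_times)."""
        j = self.subjects.index(subject)
        k = self.molecule_index(molecule_id)
        return self.values[j, k]

    def subset_molecules(self, molecule_ids: list[str]) -> "TimecourseDataset":
        idx = [self.molecule_index(m) for m in molecule_ids]
        return TimecourseDataset(
            subjects=list(self.subjects),
            molecules=[self.molecules[i] for i in idx],
            grid=self.grid,
            values=self.values[:, idx, :].copy(),
            demographics=self.demographics,
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy long table (subject_id, molecule, time_min, concentration)."""
        rows = []
        for j, subj in enumerate(self.subjects):
            for k, mol in enumerate(self.molecules):
                for t, time in enumerate(self.grid):
                    rows.append((subj, mol.molecule_id, time, self.values[j, k, t]))
        return pd.DataFrame(
            rows, columns=["subject_id", "molecule", "time_min", "concentration"]
        )


@dataclass
class DifferencedDataset:
    """Concentration differences from the fasting value, x' = x(t) - x(0)."""

    subjects: list[str]
    molecules: list[MoleculeAnnotation]
    grid: TimeGrid
    xprime: np.ndarray
    #: molecules whose fasting value was missing for every subject
    flagged: list[str] = field(default_factory=list)

    @property
    def molecule_ids(self) -> list[str]:
        return [m.molecule_id for m in self.molecules]

    def molecule_index(self, molecule_id: str) -> int:
        return self.molecule_ids.index(molecule_id)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_annotation_csv(path) -> dict[str, str]:
    """Read a molecule -> metabolic_group table; validates group labels."""
    table = pd.read_csv(path, dtype=str)
    for col in ("molecule", "metabolic_group"):
        if col not in table.columns:
            raise ValueError(f"annotation CSV missing column {col!r}")
    mapping: dict[str, str] = {}
    for _, row in table.iterrows():
        group = row["metabolic_group"]
        if group not in METABOLIC_GROUPS:
            raise ValueError(
                f"unknown metabolic group {group!r} for molecule {row['molecule']!r}"
            )
        mapping[row["molecule"]] = group
    return mapping


def read_timecourse_csv(
    path,
    annotation_path=None,
    demographics_path=None,
) -> TimecourseDataset:
    """Read a tidy long timecourse CSV into a dense dataset.

    The grid is inferred from the distinct ``time_min`` values; every
    (subject, molecule, time) cell is populated or NaN. Molecules absent
    from the annotation table fall back to group "other" with a warning.
    """
    table = pd.read_csv(
        path,
        dtype={"subject_id": str, "molecule": str},
        keep_default_na=True,
        float_precision="round_trip",
    )
    required = ["subject_id", "molecule", "time_min", "concentration"]
    for col in required:
        if col not in table.columns:
            raise ValueError(f"timecourse CSV missing column {col!r}")

    conc = pd.to_numeric(table["concentration"], errors="coerce")
    bad = conc.isna() & table["concentration"].notna() & (
        table["concentration"].astype(str).str.strip() != ""
    )
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"non-numeric concentration {table['concentration'].iloc[row]!r} "
            f"at data row {row + 2} of {path}"  # +2: header + 1-based
        )
    table = table.assign(concentration=conc, time_min=table["time_min"].astype(int))

    dup = table.duplicated(subset=["subject_id", "molecule", "time_min"], keep=False)
    if dup.any():
        first = table.loc[dup].iloc[0]
        raise ValueError(
            "duplicate measurement for (subject, molecule, time) = "
            f"({first['subject_id']!r}, {first['molecule']!r}, {first['time_min']})"
        )

    subjects = list(dict.fromkeys(table["subject_id"]))
    molecule_ids = list(dict.fromkeys(table["molecule"]))
    times = sorted(table["time_min"].unique())
    grid = TimeGrid(tuple(times))

    groups = read_annotation_csv(annotation_path) if annotation_path else {}
    molecules = []
    for mol in molecule_ids:
        if mol not in groups:
            if annotation_path is not None:
                logger.warning("molecule %r not annotated; assigned group 'other'", mol)
            molecules.append(MoleculeAnnotation(mol, "other"))
        else:
            molecules.append(MoleculeAnnotation(mol, groups[mol]))

    values = np.full((len(subjects), len(molecules), len(times)), np.nan)
    j_of = {s: j for j, s in enumerate(subjects)}
    k_of = {m: k for k, m in enumerate(molecule_ids)}
    t_of = {t: i for i, t in enumerate(times)}
    values[
        table["subject_id"].map(j_of).to_numpy(),
        table["molecule"].map(k_of).to_numpy(),
        table["time_min"].map(t_of).to_numpy(),
    ] = table["concentration"].to_numpy()

    demographics = None
    if demographics_path is not None:
        demographics = pd.read_csv(demographics_path, dtype={"subject_id": str})

    return TimecourseDataset(subjects, molecules, grid, values, demographics)


def write_timecourse_csv(ds: TimecourseDataset, path) -> None:
    """Write the tidy long CSV; missing cells become empty fields.

    Floats are written with 17 significant digits so a read-back reproduces
    every value bit-exactly.
    """
    ds.to_frame().to_csv(path, index=False, float_format="%.17g")


def write_annotation_csv(ds: TimecourseDataset, path) -> None:
    pd.DataFrame(
        {
            "molecule": ds.molecule_ids,
            "metabolic_group": [m.metabolic_group for m in ds.molecules],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Fasting handling and differencing
# ---------------------------------------------------------------------------

def collapse_fasting_duplicates(raw: TimecourseDataset) -> TimecourseDataset:
    """Merge the duplicate pre-ingestion draws (-10 and 0 min) into t = 0.

    Where both draws are present the fasting value becomes their mean; where
    only one is present it is used unchanged. The returned grid starts at 0.
    """
    times = raw.grid.times
    if -10 not in times:
        return raw
    i_pre = times.index(-10)
    i_zero = times.index(0)
    pre = raw.values[:, :, i_pre]
    zero = raw.values[:, :, i_zero]
    both = ~np.isnan(pre) & ~np.isnan(zero)
    fasting = np.where(both, (pre + zero) / 2.0, np.where(np.isnan(zero), pre, zero))
    keep = [i for i in range(len(times)) if i != i_pre]
    values = raw.values[:, :, keep].copy()
    new_zero = keep.index(i_zero)
    values[:, :, new_zero] = fasting
    logger.info("collapsed duplicate fasting draws: t=0 set to mean of -10 and 0 min")
    return TimecourseDataset(
        subjects=list(raw.subjects),
        molecules=list(raw.molecules),
        grid=TimeGrid(tuple(times[i] for i in keep)),
        values=values,
        demographics=raw.demographics,
    )


def difference_from_fasting(ds: TimecourseDataset) -> DifferencedDataset:
    """x'(j,k,t) = x(j,k,t) - x(j,k,0); missingness propagates.

    Molecules whose fasting value is missing for every subject are flagged
    and carry all-NaN rows; downstream x'-based indices skip them.
    """
    if 0 not in ds.grid.times:
        raise ValueError("dataset has no fasting time point (t=0)")
    fast = ds.values[:, :, ds.grid.fasting_index][:, :, None]
    xprime = ds.values - fast
    flagged = [
        mol
        for k, mol in enumerate(ds.molecule_ids)
        if np.all(np.isnan(ds.values[:, k, ds.grid.fasting_index]))
    ]
    for mol in flagged:
        logger.warning("molecule %r has no fasting values; excluded from x'-based indices", mol)
    return DifferencedDataset(
        subjects=list(ds.subjects),
        molecules=list(ds.molecules),
        grid=ds.grid,
        xprime=xprime,
        flagged=flagged,
    )
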