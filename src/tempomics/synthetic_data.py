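"""Synthetic multi-subject postprandial time courses with known ground truth.

The generator emulates the structure of an oral-glucose-tolerance-test (OGTT)
cohort: a fixed sampling grid over 0-240 min, molecules organised into
metabolic groups that share a temporal archetype (a large transient increase
peaking at 20-60 min for glucose-related molecules, a sustained decrease for
amino acids, a transient decrease for lipids, flat for non-responsive
molecules), subject-specific multiplicative baselines, and three dials that
control the statistics the pipeline measures:

``shape_noise_sd``
    s.d. of the per-subject shape perturbation; 0 makes every subject share
    the molecule's exact template, driving the inter-individual temporal
    pattern similarity (TPSI) to 1.
``rank_stability``
    probability that a subject's shape offset persists across time points
    rather than being redrawn; 1 keeps the cross-subject ordering constant
    over time (high TVRI), 0 reshuffles it at every draw (low TVRI).
``within_group_corr``
    fraction of perturbation variance shared by molecules of the same group;
    raises within-group temporal pattern similarity among molecules (TPSM).

Concentrations are built as ``baseline * (1 + template + perturbation)`` and
floored at 1% of the subject baseline so they stay positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core_data import (
    STUDY_GRID,
    MoleculeAnnotation,
    TimeGrid,
    TimecourseDataset,
)

ARCHETYPE_SHAPES = (
    "transient_increase",
    "sustained_decrease",
    "transient_decrease",
    "flat",
    "late_rebound",
)


@dataclass(frozen=True)
class ArchetypeSpec:
    """Deterministic temporal template for one molecule group.

    ``peak_amplitude`` is the extremum magnitude as a multiple of the
    subject baseline; ``return_fraction`` is the fraction of that extremum
    still present at the last grid point.
    """

    shape: str
    peak_time: float = 45.0
    peak_amplitude: float = 1.0
    return_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.shape not in ARCHETYPE_SHAPES:
            raise ValueError(f"unknown archetype shape {self.shape!r}")
        if self.shape != "flat" and self.peak_amplitude <= 0:
            raise ValueError("peak_amplitude must be > 0 for non-flat shapes")
        if not 0.0 <= self.return_fraction <= 1.0:
            raise ValueError("return_fraction must lie in [0, 1]")
        if self.shape == "sustained_decrease" and self.return_fraction < 0.5:
            raise ValueError(
                "a sustained decrease keeps >= 50% of its extremum at the end "
                f"of the window (got return_fraction={self.return_fraction})"
            )


def archetype_curve(spec: ArchetypeSpec, grid: TimeGrid) -> np.ndarray:
    """Evaluate the unitless template on the grid; exactly 0 at t = 0.

    Transient/sustained shapes rise (or fall) along a half-sine to the signed
    extremum at ``peak_time`` and relax along a power curve to
    ``return_fraction * peak_amplitude`` at the last grid point. The late
    rebound falls to its extremum and then turns upward, ending at
    ``+return_fraction * peak_amplitude``.
    """
    t = np.asarray(grid.times, dtype=float)
    post = np.clip(t, 0.0, None)  # template is 0 before ingestion
    if spec.shape == "flat":
        return np.zeros_like(t)

    t_end = float(t[-1])
    peak = float(spec.peak_time)
    if not 0.0 < peak <= t_end:
        raise ValueError(
            f"peak_time {peak} is outside the interpolable range (0, {t_end}]"
        )
    amp = spec.peak_amplitude
    rf = spec.return_fraction
    sign = 1.0 if spec.shape == "transient_increase" else -1.0

    rise = np.sin(0.5 * np.pi * post / peak)
    if peak < t_end:
        decay_frac = (t_end - post) / (t_end - peak)
    else:
        decay_frac = np.ones_like(post)

    if spec.shape == "late_rebound":
        # fall to -amp at peak, then rebound to +rf*amp at the window end
        frac = (post - peak) / (t_end - peak) if peak < t_end else np.zeros_like(post)
        rebound = -amp + (1.0 + rf) * amp * np.clip(frac, 0.0, 1.0) ** 2
        curve = np.where(post <= peak, -amp * rise, rebound)
    else:
        relax = amp * (rf + (1.0 - rf) * np.clip(decay_frac, 0.0, 1.0) ** 1.5)
        curve = sign * np.where(post <= peak, amp * rise, relax)
    curve[post == 0.0] = 0.0
    return curve


@dataclass
class GeneratorSpec:
    """Full description of a synthetic cohort.

    ``groups`` is a list of ``(metabolic_group, n_molecules, ArchetypeSpec)``
    entries; the same group label may appear several times (e.g. responsive
    and flat amino acids). ``bridge`` optionally names two group labels; one
    extra molecule is then generated whose template and group-shared noise
    are the average of the two, so it sits between both groups in the
    similarity network (a citrulline-like bridge).
    """

    n_subjects: int = 20
    grid: TimeGrid = field(default_factory=lambda: TimeGrid(STUDY_GRID))
    groups: list = field(default_factory=list)
    baseline_cv: float = 0.2
    shape_noise_sd: float = 0.08
    rank_stability: float = 0.7
    within_group_corr: float = 0.5
    missing_rate: float = 0.0
    #: fraction of molecules that carry missing cells at all; 1.0 spreads
    #: missingness uniformly, lower values concentrate it in a random subset
    #: of molecules the way instrument dropouts do in practice
    missing_molecule_fraction: float = 1.0
    duplicate_fasting: bool = False
    bridge: tuple[str, str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        for name, value in (
            ("rank_stability", self.rank_stability),
            ("within_group_corr", self.within_group_corr),
            ("missing_rate", self.missing_rate),
            ("missing_molecule_fraction", self.missing_molecule_fraction),
        ):
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.baseline_cv < 0 or self.shape_noise_sd < 0:
            raise ValueError("dispersion parameters must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid"] = list(self.grid.times)
        d["groups"] = [
            {"metabolic_group": g, "n_molecules": n, "archetype": asdict(a)}
            for g, n, a in self.groups
        ]
        d["bridge"] = list(self.bridge) if self.bridge else None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorSpec":
        d = dict(d)
        d["grid"] = TimeGrid(tuple(d["grid"]))
        d["groups"] = [
            (g["metabolic_group"], g["n_molecules"], ArchetypeSpec(**g["archetype"]))
            for g in d["groups"]
        ]
        if d.get("bridge"):
            d["bridge"] = tuple(d["bridge"])
        return cls(**d)


def _molecule_plan(spec: GeneratorSpec):
    """Expand the group entries into one row per molecule."""
    plan = []
    counter: dict[str, int] = {}
    for group, n, arch in spec.groups:
        for _ in range(n):
            counter[group] = counter.get(group, 0) + 1
            mol_id = f"{group.replace(' ', '_')}_{counter[group]:02d}"
            plan.append((mol_id, group, arch, None))
    if spec.bridge is not None:
        g1, g2 = spec.bridge
        # mix the first-listed (i.e. responsive) archetype of each group
        arches: dict[str, ArchetypeSpec] = {}
        for g, _, a in spec.groups:
            arches.setdefault(g, a)
        if g1 not in arches or g2 not in arches:
            raise ValueError(f"bridge groups {spec.bridge} not present in the plan")
        plan.append((f"bridge_{g1.replace(' ', '_')}_{g2.replace(' ', '_')}",
                     g1, None, (arches[g1], arches[g2])))
    return plan


def generate_dataset(spec: GeneratorSpec):
    """Draw one synthetic cohort.

    Returns ``(dataset, ground_truth)`` where ``ground_truth`` has a
    ``molecules`` table (molecule, group, shape, template parameters) and a
    ``subject_offsets`` table (subject, molecule, persistent shape offset).
    Identical specs (including seed) give bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    plan = _molecule_plan(spec)
    n_mol = len(plan)
    n_sub = spec.n_subjects

    times = spec.grid.times
    if spec.duplicate_fasting:
        times = (-10,) + times if times[0] != -10 else times
    grid = TimeGrid(times)
    n_t = grid.n_times

    group_labels = sorted({g for _, g, _, _ in plan})
    g_index = {g: i for i, g in enumerate(group_labels)}

    # Per-molecule reference scale spans two decades, mimicking the spread of
    # measurement units across metabolite panels.
    ref = 10.0 ** rng.uniform(0.0, 2.0, size=n_mol)

    # Lognormal subject baselines with the requested CV and mean = ref.
    sigma = np.sqrt(np.log1p(spec.baseline_cv**2))
    baseline = ref[None, :] * np.exp(
        rng.normal(0.0, 1.0, size=(n_sub, n_mol)) * sigma - 0.5 * sigma**2
    )

    templates = np.empty((n_mol, n_t))
    for k, (_, _, arch, mix) in enumerate(plan):
        if mix is None:
            templates[k] = archetype_curve(arch, grid)
        else:
            a, b = mix
            templates[k] = 0.5 * (archetype_curve(a, grid) + archetype_curve(b, grid))

    # One subject-shape process per molecule, built from a group-shared and a
    # molecule-private component (marginal s.d. = shape_noise_sd, within-group
    # correlation = w). Each draw is either the subject's persistent offset
    # (probability rank_stability) or a fresh draw at that time point.
    # Persistent draws are constant over time, so they cancel in the
    # difference from fasting (raising TPSI) and keep the cross-subject
    # ordering fixed (raising TVRI); fresh draws do the opposite.
    w = spec.within_group_corr
    n_g = len(group_labels)
    shared_pers = rng.normal(0.0, 1.0, size=(n_g, n_sub))
    shared_fresh = rng.normal(0.0, 1.0, size=(n_g, n_sub, n_t))
    priv_pers = rng.normal(0.0, 1.0, size=(n_sub, n_mol))
    priv_fresh = rng.normal(0.0, 1.0, size=(n_sub, n_mol, n_t))
    keep = rng.random(size=(n_sub, n_mol, n_t)) < spec.rank_stability

    pert = np.empty((n_sub, n_mol, n_t))
    persistent = np.empty((n_sub, n_mol))
    for k, (_, g, _, mix) in enumerate(plan):
        if mix is None:
            sh_p = shared_pers[g_index[g]]
            sh_f = shared_fresh[g_index[g]]
        else:
            ga, gb = spec.bridge
            sh_p = (shared_pers[g_index[ga]] + shared_pers[g_index[gb]]) / np.sqrt(2.0)
            sh_f = (shared_fresh[g_index[ga]] + shared_fresh[g_index[gb]]) / np.sqrt(2.0)
        pers_k = np.sqrt(w) * sh_p[:, None] + np.sqrt(1.0 - w) * priv_pers[:, [k]]
        fresh_k = np.sqrt(w) * sh_f + np.sqrt(1.0 - w) * priv_fresh[:, k, :]
        persistent[:, k] = spec.shape_noise_sd * pers_k[:, 0]
        pert[:, k, :] = spec.shape_noise_sd * np.where(
            keep[:, k, :], pers_k, fresh_k
        )

    x = baseline[:, :, None] * (1.0 + templates[None, :, :] + pert)
    x = np.maximum(x, 0.01 * baseline[:, :, None])  # concentrations stay positive

    if spec.missing_rate > 0:
        drop = rng.random(size=x.shape) < spec.missing_rate
        if spec.missing_molecule_fraction < 1.0:
            n_affected = int(round(spec.missing_molecule_fraction * n_mol))
            affected = rng.choice(n_mol, size=n_affected, replace=False)
            mask = np.zeros(n_mol, dtype=bool)
            mask[affected] = True
            drop &= mask[None, :, None]
        x = np.where(drop, np.nan, x)

    molecules = [MoleculeAnnotation(mol_id, group) for mol_id, group, _, _ in plan]
    subjects = [f"S{j + 1:02d}" for j in range(n_sub)]
    ds = TimecourseDataset(subjects, molecules, grid, x)

    mol_rows = []
    for k, (mol_id, group, arch, mix) in enumerate(plan):
        a = arch if arch is not None else mix[0]
        mol_rows.append(
            dict(
                molecule=mol_id,
                metabolic_group=group,
                shape="bridge" if mix is not None else a.shape,
                peak_time=a.peak_time,
                peak_amplitude=a.peak_amplitude,
                return_fraction=a.return_fraction,
                reference_scale=ref[k],
            )
        )
    off_rows = [
        dict(subject=subjects[j], molecule=plan[k][0], offset=persistent[j, k])
        for j in range(n_sub)
        for k in range(n_mol)
    ]
    ground_truth = {
        "molecules": pd.DataFrame(mol_rows),
        "subject_offsets": pd.DataFrame(off_rows),
    }
    return ds, ground_truth


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def study_like(n_subjects: int = 20, seed: int = 0, missing_rate: float = 0.03) -> GeneratorSpec:
    """An 83-molecule, 20-subject OGTT-like cohort.

    The shape census mirrors the reference study panel: six glucose-related
    molecules with a large transient increase peaking 20-60 min, a lipid
    group with a transient decrease bottoming mid-window, a responsive
    amino-acid group with a sustained decrease, two rebounding hormones, and
    flat filler molecules in every group, plus one citrulline-like bridge
    molecule mixing the amino-acid and lipid templates.
    """
    up = ArchetypeSpec("transient_increase", peak_time=45, peak_amplitude=2.5,
                       return_fraction=0.15)
    lipid_down = ArchetypeSpec("transient_decrease", peak_time=150,
                               peak_amplitude=0.6, return_fraction=0.2)
    aa_down = ArchetypeSpec("sustained_decrease", peak_time=120,
                            peak_amplitude=0.5, return_fraction=0.85)
    rebound = ArchetypeSpec("late_rebound", peak_time=150, peak_amplitude=0.5,
                            return_fraction=0.5)
    flat = ArchetypeSpec("flat")
    return GeneratorSpec(
        n_subjects=n_subjects,
        groups=[
            ("glucose-related", 6, up),
            ("glucose-related", 2, flat),
            ("lipid", 3, lipid_down),
            ("lipid", 7, flat),
            ("amino acid", 8, aa_down),
            ("amino acid", 12, flat),
            ("hormone", 2, rebound),
            ("hormone", 5, flat),
            ("ion", 5, flat),
            ("other", 32, flat),
        ],
        baseline_cv=0.2,
        shape_noise_sd=0.08,
        rank_stability=0.7,
        within_group_corr=0.5,
        missing_rate=missing_rate,
        missing_molecule_fraction=0.3,
        bridge=("amino acid", "lipid"),
        seed=seed,
    )


def water_like(n_subjects: int = 20, seed: int = 0) -> GeneratorSpec:
    """Water-ingestion control arm: every archetype flat, same panel size."""
    spec = study_like(n_subjects=n_subjects, seed=seed, missing_rate=0.0)
    flat = ArchetypeSpec("flat")
    spec.groups = [(g, n, flat) for g, n, _ in spec.groups]
    spec.bridge = None
    # keep the panel at 83 molecules despite dropping the bridge molecule
    spec.groups.append(("amino acid", 1, flat))
    return spec


def amino_acid_like(n_subjects: int = 20, seed: int = 0) -> GeneratorSpec:
    """High shape fidelity, fully stable subject ranks: high TPSI, high TVRI."""
    arch = ArchetypeSpec("sustained_decrease", peak_time=120,
                         peak_amplitude=0.5, return_fraction=0.85)
    return GeneratorSpec(
        n_subjects=n_subjects,
        groups=[("amino acid", 8, arch)],
        baseline_cv=0.02,
        shape_noise_sd=0.3,
        rank_stability=1.0,
        within_group_corr=0.5,
        seed=seed,
    )


def glucose_like(n_subjects: int = 20, seed: int = 0) -> GeneratorSpec:
    """High shape fidelity, unstable subject ranks: high TPSI, low TVRI."""
    arch = ArchetypeSpec("transient_increase", peak_time=45,
                         peak_amplitude=2.5, return_fraction=0.15)
    return GeneratorSpec(
        n_subjects=n_subjects,
        groups=[("glucose-related", 8, arch)],
        baseline_cv=0.02,
        shape_noise_sd=0.2,
        rank_stability=0.0,
        within_group_corr=0.5,
        seed=seed,
    )


PRESETS = {
    "study-like": study_like,
    "water": water_like,
    "amino-acid-like": amino_acid_like,
    "glucose-like": glucose_like,
}
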