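"""Synthetic phosphoproteome and prediction-score generators with known truth.

Everything the pipeline consumes can be generated here: per-kinase
proteome-wide raw-score backgrounds, regulated prediction tables in which a
chosen subset of kinases carries a known location shift in normalized-score
space, and paired study-like phosphosite tables with controlled site/protein
overlap and borderline fold-changes. All generators are pure functions of
(spec, seed) so every downstream result is reproducible and gradable against
ground truth.

Shifts are planted in normalized-score space (after the rank/percentile
transform), not raw-score space: the downstream distribution test operates
entirely on normalized scores, so a planted effect size is directly
interpretable against the score histograms. Under the null the normalized
scores of a continuous background follow the log-percentile law
``P(s >= t) ~ 10^(-t)`` — an exponential with rate ``ln 10`` — regardless of
the raw-score family, which is the rank-invariance the pipeline relies on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diffkinase import KinomeFilter, differential_activity_from_samples
from .phosphodata import PhosphoSite, SiteCollection
from .scores import ScoreBackground

__all__ = [
    "SyntheticSpec",
    "StudyPairSpec",
    "generate_background",
    "generate_regulated",
    "generate_phosphosite_fixture",
    "make_kinome_lists",
    "quantile_profile_samples",
    "simulate_replicates",
]


class SyntheticSpecError(ValueError):
    """Infeasible or inconsistent generator parameters."""


_LAWS = {"lognormal", "exponential", "normal", "uniform"}


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic score universe.

    Defaults mirror the study conditions the pipeline targets: a 9500-site
    non-regulated background, ~25 regulated predictions per kinase, and a
    heavy-tailed raw-score law so the high-percentile range is populated.
    ``shifted_kinases`` maps kinase name to a signed location shift in
    normalized-score units.
    """

    n_kinases: int = 100
    n_background_sites: int = 9500
    n_regulated_sites_per_kinase: int | tuple[int, int] = 25
    shifted_kinases: dict[str, float] = field(default_factory=dict)
    background_law: tuple[str, dict] = ("lognormal", {"mean": 0.0, "sigma": 1.0})
    prediction_density: float = 1.0
    residue_mix: dict[str, float] = field(
        default_factory=lambda: {"S": 0.86, "T": 0.11, "Y": 0.03}
    )
    sites_per_protein_mean: float = 2.0
    background_floor: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_kinases < 1 or self.n_background_sites < 1:
            raise SyntheticSpecError("kinase and background-site counts must be positive")
        law, params = self.background_law
        if law not in _LAWS:
            raise SyntheticSpecError(f"unknown background law {law!r}")
        if law == "lognormal" and params.get("sigma", 1.0) <= 0:
            raise SyntheticSpecError("lognormal sigma must be positive")
        if law == "exponential" and params.get("scale", 1.0) <= 0:
            raise SyntheticSpecError("exponential scale must be positive")
        if not 0.0 < self.prediction_density <= 1.0:
            raise SyntheticSpecError("prediction_density must lie in (0, 1]")
        total = sum(self.residue_mix.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise SyntheticSpecError(f"residue_mix must sum to 1, got {total}")
        unknown = set(self.shifted_kinases) - set(self.kinases)
        if unknown:
            raise SyntheticSpecError(f"shift specified for unknown kinases: {sorted(unknown)}")
        for shift in self.shifted_kinases.values():
            if not math.isfinite(shift):
                raise SyntheticSpecError("shifts must be finite")

    @property
    def kinases(self) -> list[str]:
        return [f"KIN{i + 1:03d}" for i in range(self.n_kinases)]

    def _draw_raw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        law, params = self.background_law
        if law == "lognormal":
            return rng.lognormal(params.get("mean", 0.0), params.get("sigma", 1.0), size)
        if law == "exponential":
            return rng.exponential(params.get("scale", 1.0), size)
        if law == "normal":
            return rng.normal(params.get("loc", 0.0), params.get("scale", 1.0), size)
        return rng.uniform(params.get("low", 0.0), params.get("high", 1.0), size)

    def _n_regulated(self, rng: np.random.Generator) -> int:
        n = self.n_regulated_sites_per_kinase
        if isinstance(n, tuple):
            lo, hi = n
            return int(rng.integers(lo, hi + 1))
        return int(n)


def _site_keys(
    rng: np.random.Generator,
    n_sites: int,
    mean_per_protein: float,
    residue_mix: Mapping[str, float],
    prefix: str,
) -> pd.DataFrame:
    """Distinct (protein, position, residue) keys with geometric multiplicity."""
    residues = list(residue_mix)
    probs = np.array([residue_mix[r] for r in residues], dtype=float)
    rows: list[tuple[str, int, str]] = []
    protein_idx = 0
    p_geom = 1.0 / max(mean_per_protein, 1.0)
    while len(rows) < n_sites:
        protein_idx += 1
        count = int(rng.geometric(p_geom))
        count = min(count, n_sites - len(rows))
        choices = rng.choice(len(residues), size=count, p=probs)
        for j in range(count):
            rows.append((f"{prefix}{protein_idx:06d}", 10 * (j + 1), residues[choices[j]]))
    return pd.DataFrame(rows, columns=["protein", "position", "residue"])


def generate_background(spec: SyntheticSpec) -> tuple[ScoreBackground, pd.DataFrame]:
    """Per-kinase raw-score backgrounds plus the normalized background table.

    Each background site carries a prediction for each kinase with
    probability ``prediction_density``; raw scores are i.i.d. draws from the
    background law, and the returned table's ``score`` column is each raw
    score self-normalized against its own kinase's distribution.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    sites = _site_keys(
        rng, spec.n_background_sites, spec.sites_per_protein_mean, spec.residue_mix, "BGP"
    )
    raw_by_kinase: dict[str, np.ndarray] = {}
    chunks: list[pd.DataFrame] = []
    for kinase in spec.kinases:
        if spec.prediction_density < 1.0:
            mask = rng.random(len(sites)) < spec.prediction_density
            chosen = sites[mask]
        else:
            chosen = sites
        raw = spec._draw_raw(rng, len(chosen))
        raw_by_kinase[kinase] = raw
        chunk = chosen.copy()
        chunk["kinase"] = kinase
        chunk["raw_score"] = raw
        chunks.append(chunk)
    background = ScoreBackground(raw_by_kinase, min_size=min(spec.background_floor, spec.n_background_sites))
    table = pd.concat(chunks, ignore_index=True)
    table["score"] = np.concatenate(
        [background.normalize(k, raw_by_kinase[k]) for k in spec.kinases]
    )
    return background, table


def generate_regulated(
    spec: SyntheticSpec, background: ScoreBackground
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Regulated prediction table with planted shifts, plus ground truth.

    Null kinases' regulated scores are fresh draws from the background law
    normalized identically to the background (exchangeable under the null);
    shifted kinases get the planted location shift added in normalized-score
    space and clamped at zero. Ground truth lists each kinase's shift.
    """
    missing = [k for k in spec.kinases if k not in background]
    if missing:
        raise SyntheticSpecError(f"background lacks kinases: {missing[:5]}")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    chunks: list[pd.DataFrame] = []
    truth_rows: list[dict] = []
    site_counter = 0
    for kinase in spec.kinases:
        n = spec._n_regulated(rng)
        raw = spec._draw_raw(rng, n)
        score = np.asarray(background.normalize(kinase, raw), dtype=float)
        shift = float(spec.shifted_kinases.get(kinase, 0.0))
        if shift != 0.0:
            score = np.clip(score + shift, 0.0, None)
        proteins = [f"RGP{site_counter + i + 1:06d}" for i in range(n)]
        site_counter += n
        residues = rng.choice(
            list(spec.residue_mix), size=n, p=list(spec.residue_mix.values())
        )
        chunks.append(
            pd.DataFrame(
                {
                    "protein": proteins,
                    "position": 10,
                    "residue": residues,
                    "kinase": kinase,
                    "raw_score": raw,
                    "score": score,
                }
            )
        )
        truth_rows.append({"kinase": kinase, "shift": shift, "is_shifted": shift != 0.0})
    table = pd.concat(chunks, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return table, truth


# ---------------------------------------------------------------------------
# Two-study phosphosite fixture
# ---------------------------------------------------------------------------

@dataclass
class StudyPairSpec:
    """Shape parameters for a pair of study-like phosphosite tables.

    Defaults reproduce the published shape of the two source
    phosphoproteomes this pipeline was designed around: study A reports
    sites up-regulated by the full agonist (Ang II) and/or the biased
    agonist (SII), study B reports SII-regulated sites only. Overlap,
    borderline-conflict, residue and multiplicity structure are all
    controlled so that every merge statistic has a known expected value.
    """

    # study A (two conditions)
    n_sites_a: int = 1182
    n_proteins_a: int = 530
    n_sites_a_cond2: int = 424
    n_proteins_a_cond2: int = 204
    # study B (condition 2 only)
    n_sites_b: int = 207
    n_proteins_b: int = 146
    # overlap structure between the condition-2 subsets
    n_shared_cond2_sites: int = 31
    n_shared_cond2_proteins: int = 51
    # cross-study regulation conflicts (regulated cond1-only in A, cond2 in B)
    n_borderline: int = 15
    n_borderline_promoted: int = 5
    n_conflict_unrecorded: int = 4
    # extra shared protein with disjoint sites (A side cond1-only)
    n_extra_shared_proteins: int = 1
    # residue composition (remaining sites are serines)
    n_tyr_a: int = 8
    n_thr_a: int = 170
    n_tyr_b: int = 7
    n_thr_b: int = 30
    # union-level multiplicity target
    n_multi_site_proteins: int = 345
    # fold-changes
    fold_regulated: float = 2.0
    fold_borderline_high: float = 1.5
    fold_borderline_low: float = 1.3
    fold_threshold: float = 1.4
    conditions: tuple[str, str] = ("AngII", "SII")
    label_a: str = "A"
    label_b: str = "B"


def _partition_counts(n_sites: int, n_proteins: int, n_multi: int) -> list[int]:
    """Deterministic per-protein site counts: singles plus a flat multi tail."""
    if n_proteins == 0:
        if n_sites:
            raise SyntheticSpecError("sites without proteins")
        return []
    if not 0 <= n_multi <= n_proteins:
        raise SyntheticSpecError("invalid multi-site protein count")
    singles = n_proteins - n_multi
    remaining = n_sites - singles
    if n_multi == 0:
        if remaining != 0:
            raise SyntheticSpecError("site count incompatible with all-singleton group")
        return [1] * singles
    if remaining < 2 * n_multi:
        raise SyntheticSpecError("too few sites for the requested multi-site proteins")
    base, extra = divmod(remaining - 2 * n_multi, n_multi)
    counts = [2 + base + (1 if i < extra else 0) for i in range(n_multi)]
    return counts + [1] * singles


def generate_phosphosite_fixture(
    spec: StudyPairSpec | None = None,
) -> tuple[SiteCollection, SiteCollection, dict]:
    """Two study-like site collections plus the expected merge statistics.

    The construction is fully deterministic. The returned truth dict holds
    every count the merge/overlap/composition operations should reproduce:
    per-study totals, union totals, site/protein overlaps (full tables and
    condition-2 subsets), borderline examined/promoted, the union
    multiplicity fraction and mean, and study A's tyrosine fraction.
    """
    s = spec or StudyPairSpec()
    cond1, cond2 = s.conditions
    n_conflict = s.n_borderline + s.n_conflict_unrecorded

    if s.n_shared_cond2_sites and s.n_shared_cond2_proteins < s.n_shared_cond2_sites:
        raise SyntheticSpecError("need at least one protein per shared condition-2 site")
    n_g1 = s.n_shared_cond2_sites
    n_g2 = s.n_shared_cond2_proteins - n_g1
    n_g3 = s.n_proteins_a_cond2 - s.n_shared_cond2_proteins
    sites_g3 = s.n_sites_a_cond2 - n_g1 - n_g2
    n_g6 = s.n_proteins_a - s.n_proteins_a_cond2 - n_conflict - s.n_extra_shared_proteins
    sites_g6 = s.n_sites_a - s.n_sites_a_cond2 - n_conflict - s.n_extra_shared_proteins
    n_g7 = s.n_proteins_b - s.n_shared_cond2_proteins - n_conflict - s.n_extra_shared_proteins
    sites_g7 = s.n_sites_b - n_g1 - n_g2 - n_conflict - s.n_extra_shared_proteins
    for name, value in {
        "g2 proteins": n_g2, "g3 proteins": n_g3, "g3 sites": sites_g3,
        "g6 proteins": n_g6, "g6 sites": sites_g6,
        "g7 proteins": n_g7, "g7 sites": sites_g7,
    }.items():
        if value < 0:
            raise SyntheticSpecError(f"infeasible study-pair spec: negative {name}")
    if s.n_borderline_promoted > s.n_borderline:
        raise SyntheticSpecError("cannot promote more borderline sites than examined")

    # union multiplicity: g2 and the extra shared proteins are 2-site by
    # construction; the rest of the target is met inside g3/g6/g7.
    fixed_multi = n_g2 + s.n_extra_shared_proteins
    rest_target = s.n_multi_site_proteins - fixed_multi
    caps = {
        "g3": max(sites_g3 - n_g3, 0),
        "g6": max(sites_g6 - n_g6, 0),
        "g7": max(sites_g7 - n_g7, 0),
    }
    mins = {g: (1 if caps[g] > 0 else 0) for g in caps}
    if not sum(mins.values()) <= rest_target <= sum(caps.values()):
        raise SyntheticSpecError(
            f"multiplicity target {s.n_multi_site_proteins} infeasible "
            f"(needs {fixed_multi + sum(mins.values())}..{fixed_multi + sum(caps.values())})"
        )
    total_cap = sum(caps.values()) or 1
    alloc = {g: mins[g] + int((rest_target - sum(mins.values())) * caps[g] / total_cap) for g in caps}
    # distribute rounding remainder where capacity remains
    short = rest_target - sum(alloc.values())
    for g in sorted(caps, key=lambda g: caps[g] - alloc[g], reverse=True):
        take = min(short, caps[g] - alloc[g])
        alloc[g] += take
        short -= take
    assert short == 0

    study_a: SiteCollection = {}
    study_b: SiteCollection = {}
    protein_counter = 0

    def new_protein() -> str:
        nonlocal protein_counter
        protein_counter += 1
        return f"PRT{protein_counter:05d}"

    def add(coll: SiteCollection, protein: str, position: int, residue: str,
            folds: dict, regulated: set, label: str) -> None:
        site = PhosphoSite(protein, position, residue, dict(folds), set(regulated), {label})
        coll[site.key] = site

    # residue pools: tyrosine/threonine quotas live on study-exclusive sites
    if s.n_tyr_a + s.n_thr_a > sites_g3 + sites_g6:
        raise SyntheticSpecError("residue quotas exceed study-A exclusive sites")
    if s.n_tyr_b + s.n_thr_b > sites_g7:
        raise SyntheticSpecError("residue quotas exceed study-B exclusive sites")
    a_excl_residues = (
        ["Y"] * s.n_tyr_a + ["T"] * s.n_thr_a + ["S"] * (sites_g3 + sites_g6)
    )[: sites_g3 + sites_g6]
    b_excl_residues = (["Y"] * s.n_tyr_b + ["T"] * s.n_thr_b + ["S"] * sites_g7)[:sites_g7]
    a_iter = iter(a_excl_residues)
    b_iter = iter(b_excl_residues)

    reg_fold = {cond2: s.fold_regulated}

    # g1: shared condition-2 sites, one per protein
    for _ in range(n_g1):
        protein = new_protein()
        add(study_a, protein, 10, "S", reg_fold, {cond2}, s.label_a)
        add(study_b, protein, 10, "S", reg_fold, {cond2}, s.label_b)

    # g2: shared proteins, disjoint condition-2 sites
    for _ in range(n_g2):
        protein = new_protein()
        add(study_a, protein, 10, "S", reg_fold, {cond2}, s.label_a)
        add(study_b, protein, 20, "S", reg_fold, {cond2}, s.label_b)

    # g3: study-A exclusive condition-2 proteins
    for count in _partition_counts(sites_g3, n_g3, alloc["g3"]):
        protein = new_protein()
        for j in range(count):
            add(study_a, protein, 10 * (j + 1), next(a_iter), reg_fold, {cond2}, s.label_a)

    # g4: conflict sites — condition-1 regulated in A, condition-2 in B
    for i in range(n_conflict):
        protein = new_protein()
        folds_a = {cond1: s.fold_regulated}
        if i < s.n_borderline_promoted:
            folds_a[cond2] = s.fold_borderline_high
        elif i < s.n_borderline:
            folds_a[cond2] = s.fold_borderline_low
        add(study_a, protein, 10, "S", folds_a, {cond1}, s.label_a)
        add(study_b, protein, 10, "S", reg_fold, {cond2}, s.label_b)

    # g5: shared proteins with disjoint sites, A side condition-1 only
    for _ in range(s.n_extra_shared_proteins):
        protein = new_protein()
        add(study_a, protein, 10, "S", {cond1: s.fold_regulated}, {cond1}, s.label_a)
        add(study_b, protein, 20, "S", reg_fold, {cond2}, s.label_b)

    # g6: study-A condition-1-only proteins
    for count in _partition_counts(sites_g6, n_g6, alloc["g6"]):
        protein = new_protein()
        for j in range(count):
            add(study_a, protein, 10 * (j + 1), next(a_iter),
                {cond1: s.fold_regulated}, {cond1}, s.label_a)

    # g7: study-B exclusive proteins
    for count in _partition_counts(sites_g7, n_g7, alloc["g7"]):
        protein = new_protein()
        for j in range(count):
            add(study_b, protein, 10 * (j + 1), next(b_iter), reg_fold, {cond2}, s.label_b)

    n_union_sites = s.n_sites_a + s.n_sites_b - (n_g1 + n_conflict)
    n_union_proteins = (
        s.n_proteins_a + s.n_proteins_b
        - (s.n_shared_cond2_proteins + n_conflict + s.n_extra_shared_proteins)
    )
    truth = {
        "n_sites_a": s.n_sites_a,
        "n_proteins_a": s.n_proteins_a,
        "n_sites_a_cond2": s.n_sites_a_cond2,
        "n_proteins_a_cond2": s.n_proteins_a_cond2,
        "n_sites_b": s.n_sites_b,
        "n_proteins_b": s.n_proteins_b,
        "n_sites_merged": n_union_sites,
        "n_proteins_merged": n_union_proteins,
        "n_sites_overlap": n_g1 + n_conflict,
        "n_proteins_overlap": s.n_shared_cond2_proteins + n_conflict + s.n_extra_shared_proteins,
        "n_cond2_sites_merged": s.n_sites_a_cond2 + s.n_sites_b - n_g1,
        "n_cond2_proteins_merged": s.n_proteins_a_cond2 + s.n_proteins_b - s.n_shared_cond2_proteins,
        "n_cond2_sites_overlap": n_g1,
        "n_cond2_proteins_overlap": s.n_shared_cond2_proteins,
        "n_borderline_examined": s.n_borderline,
        "n_borderline_promoted": s.n_borderline_promoted,
        "multi_site_fraction": s.n_multi_site_proteins / n_union_proteins,
        "mean_sites_per_protein": n_union_sites / n_union_proteins,
        "tyr_fraction_a": s.n_tyr_a / s.n_sites_a,
        "conditions": s.conditions,
    }
    assert len(study_a) == s.n_sites_a and len(study_b) == s.n_sites_b
    assert len({k[0] for k in study_a}) == s.n_proteins_a
    assert len({k[0] for k in study_b}) == s.n_proteins_b
    return study_a, study_b, truth


# ---------------------------------------------------------------------------
# Kinome lists and deterministic activity profiles
# ---------------------------------------------------------------------------

def make_kinome_lists(
    n_supported: int = 207, n_expressed: int = 285, n_usable: int = 121
) -> KinomeFilter:
    """Synthetic predictor-supported and expressed kinase lists.

    The first ``n_usable`` kinase names are shared; the remainder of each
    list is exclusive, reproducing a configured intersection size.
    """
    if n_usable > min(n_supported, n_expressed):
        raise SyntheticSpecError("usable kinome cannot exceed either list")
    usable = [f"KIN{i + 1:03d}" for i in range(n_usable)]
    supported = usable + [f"SUP{i + 1:03d}" for i in range(n_supported - n_usable)]
    expressed = usable + [f"EXP{i + 1:03d}" for i in range(n_expressed - n_usable)]
    return KinomeFilter(supported=supported, expressed=expressed)


def _null_quantiles(n: int) -> np.ndarray:
    """Quantile grid of the null normalized-score law P(s >= t) = 10^(-t)."""
    u = (np.arange(n) + 0.5) / n
    return -np.log10(1.0 - u)


def quantile_profile_samples(
    n_kinases: int = 121,
    n_activated: int = 48,
    n_inhibited: int = 10,
    shift: float = 1.0,
    n_regulated: int = 25,
    n_background: int = 2000,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], pd.DataFrame]:
    """Deterministic per-kinase score samples with planted direction labels.

    A noise-free stand-in for an archived per-kinase KS-results table: each
    kinase's background is the quantile grid of the null normalized-score
    law; activated/inhibited kinases get the same grid location-shifted by
    ``+shift`` / ``-shift`` (clamped at zero) for their regulated sample,
    null kinases an unshifted grid. Being quantile grids rather than random
    draws, the resulting statistics are exactly reproducible. Labelled
    synthetic: stands in for supplementary result tables that are not
    redistributable.
    """
    if n_activated + n_inhibited > n_kinases:
        raise SyntheticSpecError("planted kinases exceed kinome size")
    bg = _null_quantiles(n_background)
    reg_base = _null_quantiles(n_regulated)
    regulated: dict[str, np.ndarray] = {}
    background: dict[str, np.ndarray] = {}
    rows = []
    for i in range(n_kinases):
        kinase = f"KIN{i + 1:03d}"
        if i < n_activated:
            sample, label = np.clip(reg_base + shift, 0.0, None), "activated"
        elif i < n_activated + n_inhibited:
            sample, label = np.clip(reg_base - shift, 0.0, None), "inhibited"
        else:
            sample, label = reg_base.copy(), "unchanged"
        regulated[kinase] = sample
        background[kinase] = bg
        rows.append({"kinase": kinase, "truth": label})
    return regulated, background, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Replicated simulation of the full statistical pipeline
# ---------------------------------------------------------------------------

def simulate_replicates(
    spec: SyntheticSpec,
    n_replicates: int,
    seed: int,
    min_sites: int = 5,
    alpha: float = 0.005,
) -> pd.DataFrame:
    """Run the per-kinase KS pipeline on freshly drawn data, many times.

    Each replicate draws a new background (``n_background_sites`` scores per
    kinase, thinned by ``prediction_density``) and a new regulated sample
    per kinase, plants the spec's shifts in normalized-score space, and runs
    the same statistical core the table-level pipeline uses. Returns one row
    per replicate with false/correct/missed call counts against ground
    truth — the raw material for type-I and power estimates.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    records = []
    n_bg = max(int(round(spec.prediction_density * spec.n_background_sites)), 1)
    for rep in range(n_replicates):
        regulated: dict[str, np.ndarray] = {}
        background: dict[str, np.ndarray] = {}
        for kinase in spec.kinases:
            bg_raw = spec._draw_raw(rng, n_bg)
            bg_sorted = np.sort(bg_raw)
            bg_scores = -np.log10(
                (n_bg - np.searchsorted(bg_sorted, bg_raw, side="left") + 1.0) / (n_bg + 1.0)
            )
            n_reg = spec._n_regulated(rng)
            reg_raw = spec._draw_raw(rng, n_reg)
            reg_scores = -np.log10(
                (n_bg - np.searchsorted(bg_sorted, reg_raw, side="left") + 1.0) / (n_bg + 1.0)
            )
            shift = spec.shifted_kinases.get(kinase, 0.0)
            if shift:
                reg_scores = np.clip(reg_scores + shift, 0.0, None)
            regulated[kinase] = reg_scores
            background[kinase] = bg_scores
        results = differential_activity_from_samples(
            regulated, background, min_sites=min_sites, alpha=alpha
        )
        false_calls = correct = missed = wrong_direction = 0
        for res in results:
            shift = spec.shifted_kinases.get(res.kinase, 0.0)
            if shift == 0.0:
                false_calls += res.call in ("activated", "inhibited")
            else:
                expected = "activated" if shift > 0 else "inhibited"
                if res.call == expected:
                    correct += 1
                elif res.call in ("activated", "inhibited"):
                    wrong_direction += 1
                else:
                    missed += 1
        records.append(
            {
                "replicate": rep,
                "false_calls": false_calls,
                "correct_direction": correct,
                "wrong_direction": wrong_direction,
                "missed": missed,
                "n_planted": len(spec.shifted_kinases),
                "n_null": spec.n_kinases - len(spec.shifted_kinases),
            }
        )
    return pd.DataFrame(records)
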