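"""Differential kinase activity from per-kinase score distributions.

For each kinase, the normalized prediction scores of regulated phosphosites
are compared with the same kinase's scores on a large non-regulated
background using the two-sample Kolmogorov-Smirnov test. A kinase whose
regulated-site scores are shifted toward higher values is called activated;
shifted lower, inhibited. Two-sided p-values are corrected across all tested
kinases with the Benjamini-Hochberg step-up procedure, and the direction of
a significant call is assigned by the dominant one-sided statistic.

Statistics implemented here:

* ``D_plus  = sup_t [F_bg(t) - F_reg(t)]`` — positive when the regulated
  sample is stochastically larger (activation signal);
* ``D_minus = sup_t [F_reg(t) - F_bg(t)]`` — inhibition signal;
* ``D = max(D_plus, D_minus)`` — the usual two-sided statistic;
* two-sided p from the Kolmogorov limiting law with the small-sample
  correction ``lambda = (sqrt(ne) + 0.12 + 0.11/sqrt(ne)) * D``,
  ``ne = n*m/(n+m)``;
* one-sided p from the asymptotic bound ``exp(-2 * ne * D_side^2)``;
* an exact/permutation p-value as a small-sample oracle.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

RESULT_COLUMNS = [
    "kinase",
    "n_regulated",
    "n_background",
    "D",
    "D_plus",
    "D_minus",
    "p_two_sided",
    "p_up",
    "p_down",
    "q",
    "call",
]

#: statistics too close to call a direction are treated as ties
_DIRECTION_TIE_TOL = 1e-12


class DiffKinaseError(ValueError):
    """Invalid input to the differential-activity analysis."""


@dataclass
class KinomeFilter:
    """Restriction of the analysis to the usable kinome.

    ``supported``: kinases the upstream predictor can score; ``expressed``:
    kinases detected in the studied cell system. Only their intersection is
    analyzable — a prediction for an unexpressed kinase is biologically
    meaningless, and an expressed kinase without predictor support is
    untestable.
    """

    supported: frozenset[str]
    expressed: frozenset[str]

    def __init__(self, supported: Iterable[str], expressed: Iterable[str]):
        object.__setattr__(self, "supported", frozenset(supported))
        object.__setattr__(self, "expressed", frozenset(expressed))

    @property
    def usable(self) -> frozenset[str]:
        return self.supported & self.expressed

    @classmethod
    def read(cls, supported_path: str | Path, expressed_path: str | Path) -> "KinomeFilter":
        return cls(_read_kinase_list(supported_path), _read_kinase_list(expressed_path))


def _read_kinase_list(path: str | Path) -> list[str]:
    with open(path, "r", encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip() and not line.startswith("#")]


def filter_kinome(predictions: pd.DataFrame, kinome: KinomeFilter) -> pd.DataFrame:
    """Keep only predictions for kinases in the usable kinome."""
    usable = kinome.usable
    if not usable:
        raise DiffKinaseError(
            "usable kinome is empty (no overlap between supported and expressed kinases)"
        )
    return predictions[predictions["kinase"].isin(usable)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Kolmogorov-Smirnov statistics and p-values
# ---------------------------------------------------------------------------

def ks_statistics(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Two-sample KS statistics (D, D_plus, D_minus).

    ``x`` is the regulated sample, ``y`` the background. ``D_plus`` is the
    supremum of ``F_y - F_x`` over the pooled jump points (positive when x
    sits to the right of y); ``D_minus`` the supremum of ``F_x - F_y``.
    ECDFs are right-continuous step functions; evaluating at the pooled
    values is exact and handles ties deterministically.
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    if x.size == 0 or y.size == 0:
        raise DiffKinaseError("ks_statistics: empty sample")
    pooled = np.concatenate([x, y])
    pooled.sort()
    f_x = np.searchsorted(x, pooled, side="right") / x.size
    f_y = np.searchsorted(y, pooled, side="right") / y.size
    d_plus = float(max(np.max(f_y - f_x), 0.0))
    d_minus = float(max(np.max(f_x - f_y), 0.0))
    return max(d_plus, d_minus), d_plus, d_minus


def _effective_size(n: int, m: int) -> float:
    return n * m / (n + m)


def ks_pvalue_asymptotic(D: float, n: int, m: int) -> float:
    """Two-sided p-value from the Kolmogorov limiting distribution.

    Uses ``Q(lam) = 2 * sum_{k>=1} (-1)^(k-1) exp(-2 k^2 lam^2)`` with the
    finite-sample adjustment ``lam = (sqrt(ne) + 0.12 + 0.11/sqrt(ne)) * D``;
    the series is truncated when a term falls below 1e-12 and the result is
    clamped to (0, 1].
    """
    if not 0.0 <= D <= 1.0 + 1e-12:
        raise DiffKinaseError(f"KS statistic must lie in [0, 1], got {D}")
    if n < 1 or m < 1:
        raise DiffKinaseError("sample sizes must be >= 1")
    if D == 0.0:
        return 1.0
    ne = _effective_size(n, m)
    lam = (math.sqrt(ne) + 0.12 + 0.11 / math.sqrt(ne)) * D
    total = 0.0
    for k in range(1, 101):
        term = 2.0 * (-1.0) ** (k - 1) * math.exp(-2.0 * k * k * lam * lam)
        total += term
        if abs(term) < 1e-12:
            break
    return float(min(max(total, np.nextafter(0.0, 1.0)), 1.0))


def one_sided_pvalues(D_plus: float, D_minus: float, n: int, m: int) -> tuple[float, float]:
    """One-sided KS p-values ``p ~ exp(-2 * ne * D_side^2)``, clamped to (0, 1]."""
    ne = _effective_size(n, m)
    p_up = min(math.exp(-2.0 * ne * D_plus * D_plus), 1.0)
    p_down = min(math.exp(-2.0 * ne * D_minus * D_minus), 1.0)
    return float(p_up), float(p_down)


def _side_statistic(x: np.ndarray, y: np.ndarray, side: str) -> float:
    d, d_plus, d_minus = ks_statistics(x, y)
    if side == "two":
        return d
    if side == "up":
        return d_plus
    if side == "down":
        return d_minus
    raise DiffKinaseError(f"unknown side {side!r}")


def ks_pvalue_permutation(
    x: Sequence[float],
    y: Sequence[float],
    side: str = "two",
    n_perm: int = 2000,
    seed: int | None = None,
) -> float:
    """Permutation/enumeration p-value for the chosen KS statistic.

    Small pooled samples (n + m <= 12) are enumerated exactly over all
    C(n+m, n) assignments of the pooled values to the two groups; larger
    samples are Monte-Carlo sampled with the add-one estimator
    ``(1 + #{stat >= observed}) / (1 + n_perm)``, reproducible under a
    fixed seed. This is the independent small-sample oracle for the
    asymptotic formulas.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DiffKinaseError("ks_pvalue_permutation: empty sample")
    if n_perm < 1:
        raise DiffKinaseError("n_perm must be >= 1")
    observed = _side_statistic(x, y, side)
    pooled = np.concatenate([x, y])
    n, total = x.size, x.size + y.size

    if total <= 12:
        indices = range(total)
        hits = 0
        count = 0
        for combo in itertools.combinations(indices, n):
            mask = np.zeros(total, dtype=bool)
            mask[list(combo)] = True
            stat = _side_statistic(pooled[mask], pooled[~mask], side)
            hits += stat >= observed - 1e-12
            count += 1
        return hits / count

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        stat = _side_statistic(perm[:n], perm[n:], side)
        hits += stat >= observed - 1e-12
    return (1 + hits) / (1 + n_perm)


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order.

    ``q_(i) = min_{j >= i} (m * p_(j) / j)`` over the sorted p-values,
    clamped to <= 1; adjustment preserves the ranking and ``q >= p``.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DiffKinaseError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# Per-kinase differential activity
# ---------------------------------------------------------------------------

@dataclass
class KinaseActivityResult:
    """KS comparison of one kinase's regulated vs background scores."""

    kinase: str
    n_regulated: int
    n_background: int
    D: float = float("nan")
    D_plus: float = float("nan")
    D_minus: float = float("nan")
    p_two_sided: float = float("nan")
    p_up: float = float("nan")
    p_down: float = float("nan")
    q: float = float("nan")
    call: str = "insufficient_data"


def differential_activity_from_samples(
    regulated: Mapping[str, Sequence[float]],
    background: Mapping[str, Sequence[float]],
    min_sites: int = 5,
    alpha: float = 0.005,
) -> list[KinaseActivityResult]:
    """Core per-kinase KS analysis on score arrays.

    ``regulated`` and ``background`` map kinase -> normalized score sample.
    Kinases with fewer than ``min_sites`` regulated scores (or no background)
    are reported as ``insufficient_data`` and excluded from the BH family.
    A kinase is called activated if its BH-adjusted two-sided p <= ``alpha``
    and ``D_plus > D_minus``; inhibited if ``D_minus > D_plus``; otherwise
    unchanged.
    """
    if not 0.0 < alpha < 1.0:
        raise DiffKinaseError("alpha must lie in (0, 1)")
    results: list[KinaseActivityResult] = []
    tested: list[KinaseActivityResult] = []
    for kinase in sorted(regulated):
        reg = np.asarray(regulated[kinase], dtype=float)
        bg = np.asarray(background.get(kinase, ()), dtype=float)
        res = KinaseActivityResult(kinase, int(reg.size), int(bg.size))
        results.append(res)
        if reg.size < min_sites or bg.size == 0:
            continue
        d, d_plus, d_minus = ks_statistics(reg, bg)
        res.D, res.D_plus, res.D_minus = d, d_plus, d_minus
        res.p_two_sided = ks_pvalue_asymptotic(d, reg.size, bg.size)
        res.p_up, res.p_down = one_sided_pvalues(d_plus, d_minus, reg.size, bg.size)
        tested.append(res)
    if not tested:
        raise DiffKinaseError(
            f"no kinase has >= {min_sites} regulated predictions with background"
        )
    qvals = benjamini_hochberg([r.p_two_sided for r in tested])
    for res, q in zip(tested, qvals):
        res.q = float(q)
        if q <= alpha and res.D_plus > res.D_minus + _DIRECTION_TIE_TOL:
            res.call = "activated"
        elif q <= alpha and res.D_minus > res.D_plus + _DIRECTION_TIE_TOL:
            res.call = "inhibited"
        else:
            res.call = "unchanged"
    return results


def _scores_by_kinase(predictions: pd.DataFrame) -> dict[str, np.ndarray]:
    return {
        str(kinase): group["score"].to_numpy(float)
        for kinase, group in predictions.groupby("kinase")
    }


def differential_kinase_activity(
    regulated_predictions: pd.DataFrame,
    background_predictions: pd.DataFrame,
    kinome: KinomeFilter | None = None,
    min_sites: int = 5,
    alpha: float = 0.005,
) -> list[KinaseActivityResult]:
    """Per-kinase differential activity from prediction tables.

    Both tables must carry identically normalized ``score`` columns. When a
    :class:`KinomeFilter` is given, both tables are restricted to the usable
    kinome symmetrically before testing.
    """
    if kinome is not None:
        regulated_predictions = filter_kinome(regulated_predictions, kinome)
        background_predictions = filter_kinome(background_predictions, kinome)
    reg = _scores_by_kinase(regulated_predictions)
    bg = _scores_by_kinase(background_predictions)
    if not reg:
        raise DiffKinaseError("no regulated predictions after filtering")
    return differential_activity_from_samples(reg, bg, min_sites=min_sites, alpha=alpha)


def results_to_frame(results: Sequence[KinaseActivityResult]) -> pd.DataFrame:
    """Tabulate results sorted by q (NaN last) then kinase name."""
    frame = pd.DataFrame([vars(r) for r in results], columns=RESULT_COLUMNS)
    return frame.sort_values(["q", "kinase"], na_position="last").reset_index(drop=True)


def classify_from_results(
    frame: pd.DataFrame, alpha: float = 0.005, min_sites: int = 5
) -> pd.DataFrame:
    """(Re)apply BH correction and direction calls to a KS results table.

    Accepts a table with columns (kinase, n_regulated, n_background,
    p_two_sided, D_plus, D_minus) — e.g. previously computed per-kinase KS
    results — recomputes q across the tested family and assigns calls. Used
    to classify archived result tables without access to the raw scores.
    """
    out = frame.copy()
    testable = (out["n_regulated"] >= min_sites) & out["p_two_sided"].notna()
    out["q"] = np.nan
    out["call"] = "insufficient_data"
    if testable.any():
        q = benjamini_hochberg(out.loc[testable, "p_two_sided"].to_numpy(float))
        out.loc[testable, "q"] = q
        sig = testable & (out["q"] <= alpha)
        up = sig & (out["D_plus"] > out["D_minus"] + _DIRECTION_TIE_TOL)
        down = sig & (out["D_minus"] > out["D_plus"] + _DIRECTION_TIE_TOL)
        out.loc[testable, "call"] = "unchanged"
        out.loc[up, "call"] = "activated"
        out.loc[down, "call"] = "inhibited"
    return out


def write_results(
    results: Sequence[KinaseActivityResult],
    path: str | Path,
    metadata: Mapping[str, object] | None = None,
    sep: str = "\t",
) -> None:
    """Write the results table plus a side-car run-metadata block."""
    frame = results_to_frame(results)
    frame.to_csv(path, sep=sep, index=False)
    if metadata is not None:
        meta_path = Path(str(path) + ".meta")
        with open(meta_path, "w", encoding="utf-8") as fh:
            for key in sorted(metadata):
                fh.write(f"{key}\t{metadata[key]}\n")


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

def phospho_enrichment_fisher(
    activated: Iterable[str],
    phosphorylated: Iterable[str],
    universe: Iterable[str],
) -> tuple[np.ndarray, float]:
    """Fisher exact test for overlap of activated and phosphorylated kinases.

    Builds the 2x2 contingency table over ``universe`` and returns it with
    the two-sided exact p-value (sum of table probabilities <= the observed
    table's at fixed margins).
    """
    universe = set(universe)
    if not universe:
        raise DiffKinaseError("empty kinase universe")
    activated = set(activated) & universe
    phosphorylated = set(phosphorylated) & universe
    a = len(activated & phosphorylated)
    b = len(activated - phosphorylated)
    c = len(phosphorylated - activated)
    d = len(universe) - a - b - c
    table = np.array([[a, b], [c, d]], dtype=int)
    _, p = fisher_exact(table, alternative="two-sided")
    return table, float(p)
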