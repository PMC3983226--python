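"""Kinase-substrate prediction scores and their percentile normalization.

Upstream predictors emit raw scores on kinase-specific, mutually
incomparable scales. To make scores comparable across kinases they are
normalized against each kinase's proteome-wide raw-score distribution and
log-transformed:

    s = -log10( (#background raw scores >= raw + 1) / (N_background + 1) )

i.e. minus log10 of the add-one-smoothed exceedance fraction. A normalized
score of 3 means the raw score beats ~99.9% of the proteome background for
that kinase; the add-one term keeps s finite for scores above the entire
background, and ties with background values count as exceedances (the
conservative choice). The transform is rank-based, so any strictly monotone
rescaling of raw scores leaves normalized scores unchanged.

A toy position-specific scoring matrix (:class:`MotifModel`) stands in for
the upstream motif predictor so the whole pipeline can be exercised
self-contained; it is a test double, not a reimplementation of any
published predictor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PAD = "-"

PREDICTION_COLUMNS = ["protein", "position", "residue", "kinase", "score"]


class ScoreModelError(ValueError):
    """Invalid score table, background, or motif input."""


class ScoreBackground:
    """Per-kinase proteome-wide raw-score distributions.

    Stores one sorted array of raw scores per kinase; used both as the
    normalization reference and (after self-normalization) as the null
    score sample in downstream distribution tests.
    """

    #: minimum background size for meaningful percentile resolution up to s ~ 3
    MIN_SIZE = 1000

    def __init__(self, raw_scores: Mapping[str, Sequence[float]], min_size: int | None = None):
        floor = self.MIN_SIZE if min_size is None else min_size
        self._sorted: dict[str, np.ndarray] = {}
        for kinase, values in raw_scores.items():
            arr = np.sort(np.asarray(values, dtype=float))
            if arr.size < floor:
                raise ScoreModelError(
                    f"background for kinase {kinase!r} has {arr.size} values, "
                    f"below the floor of {floor}"
                )
            if not np.all(np.isfinite(arr)):
                raise ScoreModelError(f"non-finite background scores for {kinase!r}")
            self._sorted[kinase] = arr

    @property
    def kinases(self) -> list[str]:
        return sorted(self._sorted)

    def __contains__(self, kinase: str) -> bool:
        return kinase in self._sorted

    def size(self, kinase: str) -> int:
        return self._sorted[kinase].size

    def raw(self, kinase: str) -> np.ndarray:
        return self._sorted[kinase]

    def exceedance(self, kinase: str, raw_score) -> np.ndarray:
        """Add-one exceedance fraction (#background >= raw + 1) / (N + 1)."""
        if kinase not in self._sorted:
            raise ScoreModelError(f"kinase {kinase!r} missing from the score background")
        bg = self._sorted[kinase]
        raw_score = np.asarray(raw_score, dtype=float)
        n_ge = bg.size - np.searchsorted(bg, raw_score, side="left")
        return (n_ge + 1.0) / (bg.size + 1.0)

    def normalize(self, kinase: str, raw_score) -> np.ndarray:
        """Normalized log score s = -log10(exceedance)."""
        return -np.log10(self.exceedance(kinase, raw_score))

    # -- IO ---------------------------------------------------------------
    @classmethod
    def read_table(cls, path: str | Path, sep: str = "\t", **kwargs) -> "ScoreBackground":
        """Read a (kinase, raw_score) two-column delimited table."""
        frame = pd.read_csv(path, sep=sep, float_precision="round_trip")
        if not {"kinase", "raw_score"}.issubset(frame.columns):
            raise ScoreModelError(f"{path}: needs columns 'kinase' and 'raw_score'")
        grouped = {k: g["raw_score"].to_numpy(float) for k, g in frame.groupby("kinase")}
        return cls(grouped, **kwargs)

    def write_table(self, path: str | Path, sep: str = "\t") -> None:
        frames = [
            pd.DataFrame({"kinase": k, "raw_score": v}) for k, v in sorted(self._sorted.items())
        ]
        pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False)


def normalize_scores(raw: pd.DataFrame, background: ScoreBackground) -> pd.DataFrame:
    """Attach normalized log scores to a raw prediction table.

    ``raw`` must carry columns (protein, position, residue, kinase,
    raw_score); the result adds ``score``. Every kinase in ``raw`` must have
    a background distribution. (site, kinase) pairs must be unique.
    """
    required = {"protein", "position", "residue", "kinase", "raw_score"}
    missing = required - set(raw.columns)
    if missing:
        raise ScoreModelError(f"prediction table missing columns {sorted(missing)}")
    dup = raw.duplicated(subset=["protein", "position", "residue", "kinase"])
    if dup.any():
        first = raw[dup].iloc[0]
        raise ScoreModelError(
            f"duplicate (site, kinase) pair: {tuple(first[['protein', 'position', 'residue', 'kinase']])}"
        )
    absent = sorted(set(raw["kinase"]) - set(background.kinases))
    if absent:
        raise ScoreModelError(f"kinases missing from background: {absent}")
    out = raw.copy()
    scores = np.empty(len(out), dtype=float)
    for kinase, group in out.groupby("kinase"):
        scores[out.index.get_indexer(group.index)] = background.normalize(
            kinase, group["raw_score"].to_numpy(float)
        )
    out["score"] = scores
    return out


def read_predictions(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read a prediction table with columns (protein, position, residue, kinase, score[, raw_score])."""
    frame = pd.read_csv(path, sep=sep, float_precision="round_trip")
    missing = set(PREDICTION_COLUMNS) - set(frame.columns)
    if missing:
        raise ScoreModelError(f"{path}: prediction table missing columns {sorted(missing)}")
    frame["position"] = frame["position"].astype(int)
    return frame


def write_predictions(frame: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    cols = [c for c in PREDICTION_COLUMNS + ["raw_score"] if c in frame.columns]
    frame[cols].to_csv(path, sep=sep, index=False)


@dataclass
class MotifModel:
    """Additive position-specific scoring matrix around a phosphoacceptor.

    ``weights[offset][residue]`` scores one residue at one offset in the
    window of +/- ``w`` positions around the central S/T/Y; the padding
    symbol ``-`` scores window positions beyond a protein terminus.
    """

    kinase: str
    w: int = 5
    weights: dict[int, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        alphabet = set(AMINO_ACIDS) | {PAD}
        for offset in range(-self.w, self.w + 1):
            row = self.weights.setdefault(offset, {})
            for symbol in alphabet:
                row.setdefault(symbol, 0.0)

    @property
    def window_length(self) -> int:
        return 2 * self.w + 1

    @classmethod
    def random(cls, kinase: str, rng: np.random.Generator, w: int = 5, scale: float = 1.0) -> "MotifModel":
        weights = {
            offset: {aa: float(rng.normal(0.0, scale)) for aa in AMINO_ACIDS}
            for offset in range(-w, w + 1)
        }
        return cls(kinase=kinase, w=w, weights=weights)


def score_with_motif(model: MotifModel, sequence_window: str) -> float:
    """Sum of per-position weights over a 2w+1 window centred on S/T/Y."""
    window = sequence_window.upper()
    if len(window) != model.window_length:
        raise ScoreModelError(
            f"window length {len(window)} != {model.window_length} for kinase {model.kinase!r}"
        )
    centre = window[model.w]
    if centre not in "STY":
        raise ScoreModelError(f"window centre must be S/T/Y, got {centre!r}")
    total = 0.0
    for i, symbol in enumerate(window):
        offset = i - model.w
        row = model.weights[offset]
        if symbol not in row:
            raise ScoreModelError(f"unknown residue symbol {symbol!r} at offset {offset}")
        total += row[symbol]
    return total


def distribution_summary(
    groups: Mapping[str, Sequence[float]],
    bin_width: float = 0.25,
) -> pd.DataFrame:
    """Percentage histograms of scores on shared bin edges, one column per group.

    Each group's bar heights sum to 100 regardless of group size, so a small
    regulated set is directly comparable with a background ten times or a
    hundred times larger. Bin edges are aligned to multiples of
    ``bin_width``.
    """
    if bin_width <= 0:
        raise ScoreModelError("bin width must be positive")
    arrays = {name: np.asarray(vals, dtype=float) for name, vals in groups.items()}
    for name, arr in arrays.items():
        if arr.size == 0:
            raise ScoreModelError(f"empty score group {name!r}")
    pooled = np.concatenate(list(arrays.values()))
    lo = np.floor(pooled.min() / bin_width) * bin_width
    hi = np.ceil(pooled.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    data = {"bin_left": edges[:-1], "bin_right": edges[1:]}
    for name, arr in arrays.items():
        counts, _ = np.histogram(arr, bins=edges)
        data[f"pct_{name}"] = 100.0 * counts / arr.size
    return pd.DataFrame(data)
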