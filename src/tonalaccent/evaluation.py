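"""Rater-agreement machinery: pairwise correlations and m-consensus.

Human raters mark accents on a 1-5 salience scale per category (M = metrical,
C = melodic contour, H = harmonic); unmarked sonorities are coded as 0, so
every rater contributes a full-length vector over the note universe.
Agreement is summarized by the average Pearson correlation over all rater
pairs.  Categories can be combined by the element-wise maximum (MC, CH, MCH),
applied identically to ratings and to model output.  A consensus vector
retains, at each note, the mean of the *marking* (nonzero) raters' values,
but only where at least m raters marked; the model is compared against the
consensus over a grid of m values and the best-correlating m is reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RatingSet",
    "ConsensusVector",
    "pairwise_mean_correlation",
    "combine_categories",
    "consensus_rating",
    "model_vs_consensus",
    "read_ratings_csv",
    "write_ratings_csv",
]

log = logging.getLogger(__name__)

CATEGORIES = ("M", "C", "H")


@dataclass
class RatingSet:
    """Raters x notes salience matrix for one accent category."""

    matrix: np.ndarray  # shape (n_raters, n_notes)
    rater_ids: list[str] = field(default_factory=list)
    category: str = "C"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("rating matrix must be 2-D (raters x notes)")
        if np.any(self.matrix < 0) or np.any(self.matrix > 5):
            raise ValueError("saliences must lie in [0, 5]")
        if not self.rater_ids:
            self.rater_ids = [f"r{i+1}" for i in range(self.matrix.shape[0])]
        if len(self.rater_ids) != self.matrix.shape[0]:
            raise ValueError("rater_ids length must match matrix rows")

    @property
    def n_raters(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_notes(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class ConsensusVector:
    values: np.ndarray
    m: int


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.corrcoef(a, b)[0, 1])


def pairwise_mean_correlation(ratings: RatingSet) -> tuple[float, float, float]:
    """Mean, min and max Pearson r over all unordered rater pairs.

    Raters with zero variance (e.g. no marks at all) are skipped pairwise
    with a warning; fewer than two usable raters is an error.
    """
    if ratings.n_raters < 2:
        raise ValueError("need at least two raters")
    if ratings.n_notes < 3:
        raise ValueError("need at least three notes")
    rs = []
    for i in range(ratings.n_raters):
        for j in range(i + 1, ratings.n_raters):
            a, b = ratings.matrix[i], ratings.matrix[j]
            if np.std(a) == 0 or np.std(b) == 0:
                log.warning(
                    "skipping rater pair (%s, %s): zero variance",
                    ratings.rater_ids[i],
                    ratings.rater_ids[j],
                )
                continue
            rs.append(_pearson(a, b))
    if not rs:
        raise ValueError("no rater pair with nonzero variance")
    return float(np.mean(rs)), float(np.min(rs)), float(np.max(rs))


def combine_categories(*vectors: Sequence[float]) -> np.ndarray:
    """Element-wise maximum of 2-3 aligned per-note salience vectors."""
    if not 2 <= len(vectors) <= 3:
        raise ValueError("combine 2 or 3 category vectors")
    arrays = [np.asarray(v, dtype=float) for v in vectors]
    n = arrays[0].shape
    if any(a.shape != n for a in arrays):
        raise ValueError("category vectors must be aligned (equal length)")
    return np.maximum.reduce(arrays)


def consensus_rating(ratings: RatingSet, m: int) -> ConsensusVector:
    """Consensus salience: mean of marking raters where >= m raters marked."""
    if not 1 <= m <= ratings.n_raters:
        raise ValueError(f"m must lie in [1, {ratings.n_raters}]")
    mat = ratings.matrix
    marked = mat > 0
    n_marked = marked.sum(axis=0)
    sums = np.where(marked, mat, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(n_marked > 0, sums / np.maximum(n_marked, 1), 0.0)
    values = np.where(n_marked >= m, means, 0.0)
    return ConsensusVector(values=values, m=m)


def model_vs_consensus(
    model: Sequence[float], ratings: RatingSet, m_grid: Sequence[int] | None = None
) -> tuple[float, int, dict[int, float]]:
    """Best correlation between model saliences and the m-consensus.

    Returns ``(best_r, best_m, r_by_m)``; grid points with a zero-variance
    consensus are skipped and logged.  Ties prefer the smallest m.
    """
    model_v = np.asarray(model, dtype=float)
    if model_v.shape[0] != ratings.n_notes:
        raise ValueError("model vector and ratings cover different note universes")
    if m_grid is None:
        m_grid = range(1, ratings.n_raters + 1)
    if np.std(model_v) == 0:
        raise ValueError("model vector has zero variance")
    r_by_m: dict[int, float] = {}
    for m in m_grid:
        cons = consensus_rating(ratings, m).values
        if np.std(cons) == 0:
            log.warning("m=%d skipped: consensus has zero variance", m)
            continue
        r_by_m[m] = _pearson(model_v, cons)
    if not r_by_m:
        raise ValueError("no m in the grid produced a usable consensus")
    best_m = max(sorted(r_by_m), key=lambda m: r_by_m[m])
    # max() keeps the first (smallest) m on exact ties because sorted order
    best_m = min(m for m in r_by_m if r_by_m[m] == r_by_m[best_m])
    return r_by_m[best_m], best_m, r_by_m


# -- ratings CSV ------------------------------------------------------------


def write_ratings_csv(
    path: str | Path,
    ratings_by_category: Mapping[str, RatingSet],
    piece_id: str = "piece",
) -> None:
    """Serialize rating sets to long-format CSV (absent rows mean 0)."""
    rows = []
    for cat, rs in ratings_by_category.items():
        for i, rater in enumerate(rs.rater_ids):
            for note in range(rs.n_notes):
                v = rs.matrix[i, note]
                if v > 0:
                    rows.append(
                        {
                            "piece_id": piece_id,
                            "sonority_index": note,
                            "rater_id": rater,
                            "category": cat,
                            "salience": int(round(v)) if v == int(v) else v,
                        }
                    )
    pd.DataFrame(
        rows, columns=["piece_id", "sonority_index", "rater_id", "category", "salience"]
    ).to_csv(path, index=False)


def read_ratings_csv(
    path: str | Path, n_notes: int | None = None
) -> dict[str, RatingSet]:
    """Read a long-format ratings CSV into per-category rating sets.

    The note universe spans indices 0..n_notes-1; when ``n_notes`` is not
    given it is inferred from the largest index present.
    """
    df = pd.read_csv(path)
    required = {"piece_id", "sonority_index", "rater_id", "category", "salience"}
    if not required <= set(df.columns):
        raise ValueError(f"ratings CSV must have columns {sorted(required)}")
    if n_notes is None:
        n_notes = int(df["sonority_index"].max()) + 1 if len(df) else 0
    raters = sorted(df["rater_id"].astype(str).unique())
    out: dict[str, RatingSet] = {}
    for cat, sub in df.groupby("category"):
        mat = np.zeros((len(raters), n_notes))
        for _, row in sub.iterrows():
            i = raters.index(str(row["rater_id"]))
            mat[i, int(row["sonority_index"])] = float(row["salience"])
        out[str(cat)] = RatingSet(matrix=mat, rater_ids=list(raters), category=str(cat))
    return out
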