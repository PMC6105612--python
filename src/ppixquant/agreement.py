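"""Multi-rater agreement statistics for ordinal fluorescence grading.

Visual fluorescence intensity is graded on a 5-point ordinal scale
(0 = no fluorescence ... 4 = very high fluorescence).  With several raters
scoring the same items, agreement is summarised by:

* per-item modal agreement — fraction of raters giving the most frequent
  score for that item;
* overall pairwise agreement ``P_o`` — fraction of agreeing rater pairs
  pooled over all items;
* fixed-marginal (Fleiss-type) kappa — chance term ``P_e = sum_j p_j^2``
  from the observed category marginals;
* free-marginal kappa — chance term ``1/k`` assuming uniform use of the
  ``k`` categories.

The category space is fixed at k = 5 even when some categories go unused;
the free-marginal statistic depends on k, not on which categories appear.
All statistics are computed by explicit tallies (no algebraic shortcuts).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd


class DegenerateTableError(ValueError):
    """Raised when chance agreement is 1 and kappa is undefined."""


@dataclass(frozen=True)
class RatingTable:
    """Items x raters integer scores on a 0..k-1 ordinal scale."""

    scores: np.ndarray  # shape (items, raters)
    k: int = 5
    item_ids: tuple[str, ...] = ()
    rater_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        s = np.asarray(self.scores)
        object.__setattr__(self, "scores", s)
        if s.ndim != 2 or s.size == 0:
            raise ValueError("scores must be a non-empty 2D items x raters array")
        if not np.issubdtype(s.dtype, np.integer):
            raise ValueError("scores must be integers")
        if s.min() < 0 or s.max() >= self.k:
            raise ValueError(f"scores must lie in 0..{self.k - 1}")

    @property
    def n_items(self) -> int:
        return self.scores.shape[0]

    @property
    def n_raters(self) -> int:
        return self.scores.shape[1]

    @classmethod
    def from_csv(cls, path: str | Path, k: int = 5) -> "RatingTable":
        """Rows = items, columns = raters, integer cells; first column may be
        an item identifier."""
        df = pd.read_csv(path)
        first = df.columns[0]
        id_names = {"item", "id", "standard", "specimen", "sample"}
        if (first.strip().lower() in id_names
                or not np.issubdtype(df[first].dtype, np.number)):
            item_ids = tuple(str(v) for v in df[first])
            df = df.drop(columns=[first])
        else:
            item_ids = tuple(str(i + 1) for i in range(len(df)))
        return cls(scores=df.to_numpy(dtype=int), k=k, item_ids=item_ids,
                   rater_ids=tuple(df.columns))


def item_modal_agreement(row) -> float:
    """Percent of raters giving the item's most frequent score.

    Tied modes give the same maximal count, so the result is well defined.
    """
    row = np.asarray(row, dtype=int)
    if row.size < 2:
        raise ValueError("need at least 2 raters")
    counts = np.bincount(row)
    return 100.0 * counts.max() / row.size


def overall_pairwise_agreement(table: RatingTable) -> float:
    """``P_o``: fraction of agreeing rater pairs over all items (0..1)."""
    if table.n_raters < 2:
        raise ValueError("pairwise agreement needs >= 2 raters")
    agree = 0
    total = 0
    for row in table.scores:
        for a, b in combinations(row, 2):
            total += 1
            agree += int(a == b)
    return agree / total


def category_proportions(table: RatingTable) -> np.ndarray:
    """Overall proportion of ratings in each category 0..k-1."""
    counts = np.bincount(table.scores.ravel(), minlength=table.k)
    return counts / table.scores.size


def fleiss_kappa(table: RatingTable) -> float:
    """Fixed-marginal (Fleiss-type) kappa: ``(P_o - P_e) / (1 - P_e)`` with
    ``P_e`` from the observed category marginals.

    Raises
    ------
    DegenerateTableError
        All ratings in one category (``P_e`` = 1; kappa undefined).
    """
    p_o = overall_pairwise_agreement(table)
    p_e = float(np.sum(category_proportions(table) ** 2))
    if p_e >= 1.0:
        raise DegenerateTableError(
            "all ratings fall in a single category; fixed-marginal kappa undefined")
    return (p_o - p_e) / (1.0 - p_e)


def free_marginal_kappa(table: RatingTable) -> float:
    """Free-marginal kappa: ``(P_o - 1/k) / (1 - 1/k)``."""
    if table.k < 2:
        raise ValueError("free-marginal kappa needs k >= 2 categories")
    p_o = overall_pairwise_agreement(table)
    chance = 1.0 / table.k
    return (p_o - chance) / (1.0 - chance)


def intrarater_agreement(attempt1: RatingTable, attempt2: RatingTable
                         ) -> tuple[np.ndarray, float, float]:
    """Per-rater percent agreement between two grading attempts.

    Returns ``(per_rater_percent, mean, sample_sd)``.
    """
    if attempt1.scores.shape != attempt2.scores.shape:
        raise ValueError("attempts must have identical items x raters shape")
    equal = attempt1.scores == attempt2.scores
    per_rater = 100.0 * equal.mean(axis=0)
    sd = float(np.std(per_rater, ddof=1)) if per_rater.size > 1 else 0.0
    return per_rater, float(per_rater.mean()), sd


def agreement_report(table: RatingTable) -> dict:
    """All interrater summaries for one rating table (percent scale)."""
    p_o = overall_pairwise_agreement(table)
    return {
        "overall_pairwise_agreement_pct": round(100.0 * p_o, 1),
        "fleiss_kappa_pct": round(100.0 * fleiss_kappa(table), 1),
        "free_marginal_kappa_pct": round(100.0 * free_marginal_kappa(table), 1),
        "per_item_modal_agreement_pct": [
            round(item_modal_agreement(row), 1) for row in table.scores
        ],
        "n_items": table.n_items,
        "n_raters": table.n_raters,
        "k": table.k,
    }


# -- packaged fixtures -----------------------------------------------------

def _data_path(name: str):
    return resources.files("ppixquant.data").joinpath(name)


def load_benchmark_scores() -> RatingTable:
    """Second-attempt scores of 4 observers grading the 9 dye-in-polymer
    standards on the 0-4 scale (the packaged benchmark rating table)."""
    with resources.as_file(_data_path("interrater_scores.csv")) as p:
        return RatingTable.from_csv(p)


def load_benchmark_first_attempt() -> RatingTable:
    """Synthetic reconstruction of the observers' first grading attempt.

    Only the per-rater agreement counts with the second attempt are known
    (6, 5, 6 and 8 of 9 items); this table realises those counts against
    the benchmark second attempt with single-step score changes.
    """
    with resources.as_file(_data_path("intrarater_attempt1_synthetic.csv")) as p:
        return RatingTable.from_csv(p)


def load_grading_scale() -> pd.DataFrame:
    """The 0-4 visual fluorescence grading scale (score, definition)."""
    with resources.as_file(_data_path("grading_scale.csv")) as p:
        return pd.read_csv(p)
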