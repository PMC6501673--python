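"""Chi-square goodness-of-fit of collision tallies against checklist-derived
expected probabilities, Pearson residuals, and the binary disparity index.

A species' expected collision count is its share of the total checklist
tally times the total number of collisions.  Pearson residuals above +3 mark
over-represented species ("super colliders"), below -3 under-represented
ones ("collision avoiders"); residuals in [-3, 3] are excluded from the
binary index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DisparityResult",
    "expected_probs",
    "chi2_gof",
    "binarize",
    "disparity_from_tallies",
]

log = logging.getLogger(__name__)

MODES = ("count", "days")
_MODE_COLS = {
    "count": ("n_collisions", "n_checklists"),
    "days": ("n_collision_days", "n_checklist_days"),
}


@dataclass
class DisparityResult:
    """Per-species expected counts, residuals and categories, plus the
    global test statistic."""

    species: list[str]
    observed: np.ndarray
    expected: np.ndarray
    residuals: np.ndarray
    categories: list[str]
    chi2_statistic: float
    df: int
    p_value: float
    threshold: float = 3.0
    dropped_zero_expected: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species_id": self.species,
                "observed": self.observed.astype(int),
                "expected": self.expected,
                "residual": self.residuals,
                "category": self.categories,
            }
        )

    def binary_outcome(self) -> pd.Series:
        """1 for over-represented, 0 for under-represented; excluded dropped."""
        s = pd.Series(
            {sp: c for sp, c in zip(self.species, self.categories) if c != "excluded"}
        )
        return (s == "over").astype(int)


def expected_probs(tallies: Sequence[float]) -> np.ndarray:
    """Relative proportion of each species' checklist tally of the total.

    Raises if any tally is zero: a zero expected probability makes the
    goodness-of-fit cell undefined, so such species must be dropped or
    merged by the caller first.
    """
    t = np.asarray(tallies, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("tallies must be a non-empty 1-d sequence")
    if np.any(t < 0):
        raise ValueError("tallies must be non-negative")
    if np.any(t == 0):
        raise ValueError(
            "zero checklist tally: expected probability undefined; drop or merge first"
        )
    total = t.sum()
    return t / total


def chi2_gof(observed: Sequence[float], probs: Sequence[float]) -> DisparityResult:
    """Pearson chi-square goodness-of-fit with per-cell residuals.

    ``E_i = p_i * sum(O)``, ``r_i = (O_i - E_i)/sqrt(E_i)``, statistic
    ``sum(r_i^2)`` on ``k - 1`` degrees of freedom.
    """
    O = np.asarray(observed, dtype=float)
    p = np.asarray(probs, dtype=float)
    if O.shape != p.shape or O.ndim != 1:
        raise ValueError("observed and probs must be 1-d and aligned")
    if O.size < 2:
        raise ValueError("need at least 2 cells")
    if O.sum() <= 0:
        raise ValueError("total observed count must be positive")
    if not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("probabilities must sum to 1")
    E = p * O.sum()
    if np.any(E == 0):
        raise ValueError("zero expected count")
    r = (O - E) / np.sqrt(E)
    statistic = float(np.sum(r * r))
    df = O.size - 1
    p_value = float(stats.chi2.sf(statistic, df))
    species = [f"cell{i}" for i in range(O.size)]
    cats = [binarize(v) for v in r]
    return DisparityResult(species, O, E, r, cats, statistic, df, p_value)


def binarize(residual: float, threshold: float = 3.0) -> str:
    """Map a Pearson residual to over / under / excluded at +-threshold.

    Boundary values (|r| exactly equal to the threshold) are excluded:
    the cut-offs are strict inequalities.
    """
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    if residual > threshold:
        return "over"
    if residual < -threshold:
        return "under"
    return "excluded"


def disparity_from_tallies(
    table,
    season: str,
    mode: str = "days",
    threshold: float = 3.0,
) -> DisparityResult:
    """Run the goodness-of-fit test on one season and data-type mode of a
    :class:`~collide.tallies.TallyTable`.

    ``mode="count"`` compares n_collisions against n_checklists;
    ``mode="days"`` compares the unique-day variants.  Species with a zero
    checklist tally are dropped with a warning before the test.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    obs_col, exp_col = _MODE_COLS[mode]
    rows = table.rows(season)
    nonzero = rows[rows[exp_col] > 0]
    dropped = tuple(rows.index[rows[exp_col] == 0])
    if dropped:
        log.warning(
            "dropping %d species with zero %s tally: %s", len(dropped), exp_col, dropped
        )
    if len(nonzero) < 2:
        raise ValueError(f"fewer than 2 usable species for season {season!r}")
    p = expected_probs(nonzero[exp_col].to_numpy())
    res = chi2_gof(nonzero[obs_col].to_numpy(), p)
    res.species = list(nonzero.index)
    res.threshold = threshold
    res.categories = [binarize(v, threshold) for v in res.residuals]
    res.dropped_zero_expected = dropped
    return res
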