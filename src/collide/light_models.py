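"""Building-light analysis: nightly collision counts versus the 0-17
light score, stratified by a species trait (flight call by default),
fitted as a Poisson GLM and as an OLS of log mean counts per score, with a
species-count adjustment of the per-score means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data_model import NightRecord, SpeciesTraits

__all__ = [
    "LightFit",
    "LightAnalysisResult",
    "nightly_counts",
    "fit_poisson_light",
    "log_mean_regression",
    "adjusted_means",
    "analyze_light",
]

log = logging.getLogger(__name__)


@dataclass
class LightFit:
    slope: float
    intercept: float
    p_value: float
    n_nights: int
    model: str  # "poisson" | "logmean"


@dataclass
class LightAnalysisResult:
    stratum_var: str
    fits: dict[str, dict[str, LightFit]] = field(default_factory=dict)
    score_means: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for level, models in sorted(self.fits.items()):
            for model, f in sorted(models.items()):
                rows.append(
                    {
                        "stratum_var": self.stratum_var,
                        "stratum_level": level,
                        "model": model,
                        "slope": f.slope,
                        "intercept": f.intercept,
                        "p": f.p_value,
                        "n_nights": f.n_nights,
                    }
                )
        return pd.DataFrame(rows)


def nightly_counts(
    nights: Sequence[NightRecord],
    traits: Sequence[SpeciesTraits],
    stratum_var: str = "flight_call",
) -> pd.DataFrame:
    """Per-night collision counts summed within each level of a trait.

    Returns a frame with columns ``date``, ``light_score`` and one count
    column per trait level.  Only nights with a recorded light score enter
    (a :class:`NightRecord` always has one, so callers filtering raw data
    must drop unscored nights before building records).
    """
    level_of = {t.species_id: getattr(t, stratum_var) for t in traits}
    levels = sorted(set(level_of.values()))
    rows = []
    for night in nights:
        counts = dict.fromkeys(levels, 0)
        for sp, n in night.collisions_by_species:
            if sp not in level_of:
                raise ValueError(f"species {sp!r} missing from trait table")
            counts[level_of[sp]] += n
        rows.append({"date": night.date, "light_score": night.light_score, **counts})
    return pd.DataFrame(rows, columns=["date", "light_score", *levels])


def fit_poisson_light(
    counts: Sequence[float], scores: Sequence[float]
) -> LightFit:
    """Poisson GLM of nightly counts on light score: log E[count] = a + b*L."""
    counts = np.asarray(counts, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if counts.shape != scores.shape:
        raise ValueError("counts and scores must align")
    if len(np.unique(scores)) < 2:
        raise ValueError("need at least 2 distinct light scores")
    if counts.sum() == 0:
        raise ValueError("all counts are zero")
    X = sm.add_constant(scores)
    res = sm.GLM(counts, X, family=sm.families.Poisson()).fit()
    return LightFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        p_value=float(res.pvalues[1]),
        n_nights=len(counts),
        model="poisson",
    )


def log_mean_regression(
    counts: Sequence[float], scores: Sequence[float]
) -> LightFit:
    """OLS of log mean nightly count per light score on the score.

    Score levels with a zero mean are dropped with a warning (log
    undefined).
    """
    counts = np.asarray(counts, dtype=float)
    scores = np.asarray(scores, dtype=float)
    frame = pd.DataFrame({"score": scores, "count": counts})
    means = frame.groupby("score")["count"].mean()
    zero = means[means == 0]
    if len(zero):
        log.warning("dropping %d score levels with zero mean count", len(zero))
        means = means[means > 0]
    if len(means) < 2:
        raise ValueError("need at least 2 score levels with positive mean")
    x = means.index.to_numpy(float)
    y = np.log(means.to_numpy())
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    return LightFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        p_value=float(res.pvalues[1]) if len(means) > 2 else float("nan"),
        n_nights=len(counts),
        model="logmean",
    )


def adjusted_means(
    counts: Sequence[float],
    scores: Sequence[float],
    n_species: int,
) -> pd.Series:
    """Per-score mean of nightly counts divided by the stratum's species
    count (removes the species-richness artifact between strata)."""
    if not n_species > 0:
        raise ValueError("n_species must be positive")
    counts = np.asarray(counts, dtype=float) / n_species
    frame = pd.DataFrame({"score": np.asarray(scores), "adj": counts})
    return frame.groupby("score")["adj"].mean()


def analyze_light(
    nights: Sequence[NightRecord],
    traits: Sequence[SpeciesTraits],
    stratum_var: str = "flight_call",
) -> LightAnalysisResult:
    """Run both light models for every level of the stratifying trait."""
    table = nightly_counts(nights, traits, stratum_var)
    n_species = {}
    for t in traits:
        lvl = getattr(t, stratum_var)
        n_species[lvl] = n_species.get(lvl, 0) + 1
    result = LightAnalysisResult(stratum_var=stratum_var)
    mean_rows = []
    for level in [c for c in table.columns if c not in ("date", "light_score")]:
        counts = table[level].to_numpy(float)
        scores = table["light_score"].to_numpy(float)
        fits: dict[str, LightFit] = {}
        try:
            fits["poisson"] = fit_poisson_light(counts, scores)
        except ValueError as exc:
            log.warning("poisson fit skipped for %s=%s: %s", stratum_var, level, exc)
        try:
            fits["logmean"] = log_mean_regression(counts, scores)
        except ValueError as exc:
            log.warning("logmean fit skipped for %s=%s: %s", stratum_var, level, exc)
        result.fits[level] = fits
        raw = pd.DataFrame({"score": scores, "count": counts}).groupby("score")["count"].mean()
        adj = adjusted_means(counts, scores, n_species[level])
        for score in raw.index:
            mean_rows.append(
                {
                    "stratum_level": level,
                    "light_score": int(score),
                    "mean_count": raw.loc[score],
                    "log_mean_count": np.log(raw.loc[score]) if raw.loc[score] > 0 else np.nan,
                    "adjusted_mean_count": adj.loc[score],
                }
            )
    result.score_means = pd.DataFrame(mean_rows)
    return result
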