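"""Per-topic publication-trend modelling and forecasting.

Yearly counts per topic (zero-filled across the corpus year range) are fitted
with an ordinary least-squares linear trend, count ~ a + b * year, with 95%
prediction intervals from the t-distribution on n - 2 degrees of freedom.  An
optional single changepoint splits the fit into two segments, with forecasts
drawn from the post-changepoint segment.  The forecast slope between two
horizon years is (prediction_end - prediction_start) / span.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import spearmanr

from .corpus import CleanDocument
from .topics import TopicAssignment


@dataclass
class TopicYearSeries:
    topic_id: int
    years: np.ndarray  # strictly increasing, gap-free
    counts: np.ndarray

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.years) != len(self.counts):
            raise ValueError("years and counts must align")
        if len(self.years) > 1 and not (np.diff(self.years) > 0).all():
            raise ValueError("years must be strictly increasing")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")


@dataclass
class TrendForecast:
    topic_id: int
    segments: list  # [(start_year, statsmodels results), ...] in year order
    changepoint: int | None = None
    predicted: dict = field(default_factory=dict)  # year -> (point, lo95, hi95)

    @property
    def slope(self) -> float:
        """OLS per-year slope of the forecasting (last) segment."""
        return float(self.segments[-1][1].params[1])

    @property
    def intercept(self) -> float:
        return float(self.segments[-1][1].params[0])


def yearly_counts(
    assignment: TopicAssignment, docs: Sequence[CleanDocument]
) -> list[TopicYearSeries]:
    """Publication counts per topic-year, zero-filled over the corpus range.

    Includes the noise topic (-1) when present; totals across topics partition
    the corpus.
    """
    year_of = {d.pmid: d.year for d in docs}
    all_years = [year_of[p] for p in assignment.doc_ids if p in year_of]
    if not all_years:
        raise ValueError("no documents with years")
    lo, hi = min(all_years), max(all_years)
    years = np.arange(lo, hi + 1)
    series = []
    for topic in sorted(set(int(l) for l in assignment.labels)):
        counts = np.zeros(len(years))
        for pmid, lab in zip(assignment.doc_ids, assignment.labels):
            if int(lab) == topic and pmid in year_of:
                counts[year_of[pmid] - lo] += 1
        series.append(TopicYearSeries(topic_id=topic, years=years, counts=counts))
    return series


def _fit_segment(years: np.ndarray, counts: np.ndarray):
    X = sm.add_constant(years.astype(float))
    return sm.OLS(counts, X).fit()


def fit_trend(
    series: TopicYearSeries, changepoint: int | None = None
) -> TrendForecast:
    """OLS linear trend fit; optionally split at a configured changepoint year."""
    if len(series.years) < 3:
        raise ValueError("trend fit needs at least 3 observed years")
    if changepoint is None:
        segments = [(int(series.years[0]), _fit_segment(series.years, series.counts))]
    else:
        before = series.years < changepoint
        after = ~before
        if before.sum() < 3 or after.sum() < 3:
            raise ValueError("each changepoint segment needs at least 3 years")
        segments = [
            (int(series.years[0]), _fit_segment(series.years[before], series.counts[before])),
            (int(changepoint), _fit_segment(series.years[after], series.counts[after])),
        ]
    return TrendForecast(topic_id=series.topic_id, segments=segments,
                         changepoint=changepoint)


def forecast(fit: TrendForecast, horizon_years: Sequence[int]) -> pd.DataFrame:
    """Point forecasts with 95% prediction intervals for the given years.

    Years before the changepoint use the first segment; all later (and
    extrapolated) years use the last segment.  Intervals widen with distance
    from the observed mean year.
    """
    rows = []
    for year in horizon_years:
        results = fit.segments[0][1]
        for start, seg in fit.segments:
            if year >= start:
                results = seg
        X_new = np.array([[1.0, float(year)]])
        pred = results.get_prediction(X_new)
        frame = pred.summary_frame(alpha=0.05)
        point = float(frame["mean"].iloc[0])
        lo = float(frame["obs_ci_lower"].iloc[0])
        hi = float(frame["obs_ci_upper"].iloc[0])
        if not np.isfinite(lo) or not np.isfinite(hi):  # zero-residual fits
            lo = hi = point
        fit.predicted[int(year)] = (point, lo, hi)
        rows.append({"year": int(year), "pred": point, "lo95": lo, "hi95": hi})
    return pd.DataFrame(rows, columns=["year", "pred", "lo95", "hi95"])


def forecast_slope(pred_start: float, pred_end: float, span_years: int) -> float:
    """Per-year change in predicted counts between two horizon years."""
    if span_years < 1:
        raise ValueError("span_years must be >= 1")
    return (pred_end - pred_start) / span_years


def trend_summary(
    assignment: TopicAssignment,
    docs: Sequence[CleanDocument],
    horizon_start: int = 2026,
    horizon_end: int = 2029,
) -> pd.DataFrame:
    """Per-topic forecast table: last observation, horizon predictions, slope."""
    rows = []
    for series in yearly_counts(assignment, docs):
        observed = series.years[series.counts > 0]
        last_year = int(observed[-1]) if len(observed) else int(series.years[-1])
        last_count = float(series.counts[series.years == last_year][0])
        fit = fit_trend(series)
        fc = forecast(fit, [horizon_start, horizon_end])
        p_start = float(fc.loc[fc["year"] == horizon_start, "pred"].iloc[0])
        p_end = float(fc.loc[fc["year"] == horizon_end, "pred"].iloc[0])
        rows.append(
            {
                "topic_id": series.topic_id,
                "last_observed_year": last_year,
                "last_observed_count": last_count,
                f"pred_{horizon_start}": p_start,
                f"pred_{horizon_end}": p_end,
                "forecast_slope": forecast_slope(
                    p_start, p_end, horizon_end - horizon_start
                ),
            }
        )
    return pd.DataFrame(rows)


def novelty_slope_correlation(
    novelty: Sequence[float], slopes: Sequence[float]
) -> tuple[float, float]:
    """Spearman rank correlation between topic novelty and forecast slope.

    Reported descriptively (the association is exploratory, not a tested
    invariant).
    """
    rho, p = spearmanr(novelty, slopes)
    return float(rho), float(p)
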