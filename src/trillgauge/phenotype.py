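"""Male quality covariates: body condition, age class, aggression metrics.

Body condition is the standardized residual of weight regressed on tarsus
with linear day-of-year and time-of-day covariates.  Age classes follow
banding history: second-year (SY) males were banded as nestlings the
previous year, after-second-year (ASY) males were banded as adults in any
prior season; anything else is unknown.  Aggression comes from playback
event logs: song rate over the whole trial, and time within 5 m of the
speaker / flights across the speaker during song-bouts only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "body_condition",
    "aggression_metrics",
    "aggression_table",
    "code_age",
    "male_year_covariates",
]


def body_condition(
    records: pd.DataFrame,
    weight_col: str = "weight",
    tarsus_col: str = "tarsus",
    day_col: str = "capture_day",
    hour_col: str = "capture_hour",
    min_records: int = 10,
) -> pd.Series:
    """Standardized residual of ``weight ~ tarsus + day + hour``.

    Returns a Series aligned to ``records.index`` with mean 0 and SD 1 over
    the complete-case regression sample; rows with missing inputs get NaN.
    """
    cols = [weight_col, tarsus_col, day_col, hour_col]
    data = records[cols].astype(float)
    ok = data.notna().all(axis=1)
    if ok.sum() < min_records:
        raise ValueError(f"need >= {min_records} complete records, have {int(ok.sum())}")
    X = sm.add_constant(data.loc[ok, [tarsus_col, day_col, hour_col]], has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("degenerate condition regression design (constant predictor)")
    fit = sm.OLS(data.loc[ok, weight_col], X).fit()
    resid = fit.resid
    sd = resid.std(ddof=1)
    out = pd.Series(np.nan, index=records.index, name="condition")
    if sd <= 1e-10 * max(data.loc[ok, weight_col].std(ddof=1), 1.0):
        out.loc[ok] = 0.0  # perfect fit: no condition variation
    else:
        out.loc[ok] = (resid - resid.mean()) / sd
    return out


def aggression_metrics(events: pd.DataFrame, trial_duration: float | None = None):
    """Aggression scores for one playback trial.

    ``events`` has columns event_type (song | bout | position | crossing),
    t_start, t_end.  Song rate is over the entire trial; proportion of time
    within 5 m (``position`` intervals) and flights across the speaker
    (``crossing`` events) are averaged over song-bout windows only, since
    silent periods carry many zeros.

    Returns ``(song_rate_per_min, flights_per_bout, time_close_fraction)``.
    """
    bouts = events[events.event_type == "bout"]
    if bouts.empty:
        raise ValueError("trial has no song-bout windows")
    blen = (bouts.t_end - bouts.t_start).to_numpy(float)
    if np.any(blen <= 0):
        raise ValueError("zero-length song-bout window")
    if trial_duration is None:
        trial_duration = float(events.t_end.max())
    n_songs = int((events.event_type == "song").sum())
    song_rate = n_songs / (trial_duration / 60.0)

    pos = events[events.event_type == "position"]
    cross = events[events.event_type == "crossing"]
    close_frac, flights = [], []
    for _, b in bouts.iterrows():
        overlap = 0.0
        for _, pv in pos.iterrows():
            overlap += max(0.0, min(pv.t_end, b.t_end) - max(pv.t_start, b.t_start))
        close_frac.append(overlap / (b.t_end - b.t_start))
        flights.append(
            int(((cross.t_start >= b.t_start) & (cross.t_start < b.t_end)).sum())
        )
    return float(song_rate), float(np.mean(flights)), float(np.mean(close_frac))


def aggression_table(behavior: pd.DataFrame, trial_duration: float = 360.0) -> pd.DataFrame:
    """Per-trial aggression metrics for a whole behavior log."""
    rows = []
    for trial_id, ev in behavior.groupby("trial_id"):
        sr, fl, tc = aggression_metrics(ev, trial_duration)
        rows.append(
            {
                "trial_id": trial_id,
                "male_id": ev.male_id.iloc[0],
                "year": ev.year.iloc[0],
                "song_rate": sr,
                "flights": fl,
                "time_close": tc,
            }
        )
    return pd.DataFrame(rows)


def code_age(first_band_year, first_band_stage, observation_year) -> str:
    """SY / ASY / '' (unknown) from banding history.

    SY: banded as a nestling the previous year (first breeding season).
    ASY: banded as an adult in any previous season, or as a nestling more
    than one year ago.  Birds first banded in the observation year are of
    unknown age.  A banding year after the observation year is contradictory.
    """
    if pd.isna(first_band_year) or first_band_year == "":
        return ""
    y0, y = int(first_band_year), int(observation_year)
    if y0 > y:
        raise ValueError(f"banding year {y0} after observation year {y}")
    if first_band_stage == "nestling":
        return "SY" if y0 == y - 1 else ("ASY" if y0 < y - 1 else "")
    if first_band_stage == "adult":
        return "ASY" if y0 < y else ""
    raise ValueError(f"unknown banding stage {first_band_stage!r}")


def male_year_covariates(
    phenotype: pd.DataFrame,
    behavior: pd.DataFrame | None = None,
    collapse: str = "mean",
    recording_day: pd.Series | None = None,
) -> pd.DataFrame:
    """Reduce capture-level phenotype rows to one row per male-year.

    Size measures always collapse to the within-year mean.  Condition and
    the immune indices collapse per ``collapse``: ``"mean"``, ``"first"``
    (first capture of the year; the convention for success analyses), or
    ``"closest"`` (capture nearest the recording date, requires
    ``recording_day`` indexed by (male_id, year); the convention for song
    analyses).
    """
    ph = phenotype.copy()
    ph["condition"] = body_condition(ph)
    ph["age"] = [
        code_age(r.first_band_year, r.first_band_stage, r.year) for r in ph.itertuples()
    ]
    rows = []
    for (mid, year), grp in ph.groupby(["male_id", "year"]):
        grp = grp.sort_values("capture_day")
        if collapse == "first":
            pick = grp.iloc[0]
        elif collapse == "closest" and recording_day is not None:
            target = recording_day.get((mid, year), grp.capture_day.iloc[0])
            pick = grp.iloc[(grp.capture_day - target).abs().to_numpy().argmin()]
        else:
            pick = None
        rows.append(
            {
                "male_id": mid,
                "year": year,
                "tarsus": grp["tarsus"].mean(),
                "wing": grp["wing"].mean(),
                "tail": grp["tail"].mean(),
                "condition": (pick.condition if pick is not None else grp.condition.mean()),
                "hl_ratio": (pick.hl_ratio if pick is not None else grp.hl_ratio.mean()),
                "bactericidal": (
                    pick.bactericidal if pick is not None else grp.bactericidal.mean()
                ),
                "age": grp.age.iloc[0],
            }
        )
    out = pd.DataFrame(rows)
    if behavior is not None and len(behavior):
        agg = aggression_table(behavior)
        agg = agg.groupby(["male_id", "year"], as_index=False)[
            ["song_rate", "flights", "time_close"]
        ].mean()
        out = out.merge(agg, on=["male_id", "year"], how="left")
    return out
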