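"""Empirical-Bayes centered lagged predictors for the AR(1) models.

The AR models need their lagged predictors centered around estimated
means: the person trait level for the two-level model and the day mean
for the three-level model.  Both are taken from empirical-Bayes (BLUP)
quantities of the *empty* models fitted to all observed cases, which uses
all available information and shrinks noisy person/day means toward the
grand mean.

Six derived columns are produced:

* ``e_bi``       residual from the empty two-level model, y - (g00 + u0i)
* ``lev1pred``   within-day lag-1 of ``e_bi`` (the predictor y_{b-1,i} - mu_i)
* ``e_bdi``      residual from the empty three-level model,
                 y - (g000 + u00i + r0di)
* ``lev1predfor3l``  within-day lag-1 of ``e_bdi``
* ``r_0di``      EB day-level deviation, broadcast to all rows of its day
* ``lev2pred``   the previous day's ``r_0di`` within person

Lagging never crosses the night: the first beep of a day has no beep-level
predictor (the previous evening does not predict the next morning), and a
day whose entire previous day is unobserved has no day-level predictor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import mlm
from .panel_io import LongPanel

logger = logging.getLogger(__name__)

__all__ = [
    "LaggedFrame",
    "eb_residuals_2l",
    "within_day_lag",
    "day_residuals_3l",
    "person_day_lag",
    "build_predictors",
]

#: canonical column order, and the names used in CSV exports (matching the
#: conventional R workflow for these models)
DERIVED_COLUMNS = ("e_bi", "lev1pred", "e_bdi", "lev1predfor3l", "r_0di", "lev2pred")
_R_NAMES = {
    "e_bi": "e.bi",
    "e_bdi": "e.bdi",
    "r_0di": "r.0di",
    "lev1pred": "lev1pred",
    "lev1predfor3l": "lev1predfor3l",
    "lev2pred": "lev2pred",
}


@dataclass(frozen=True)
class LaggedFrame:
    """A panel augmented with EB residuals and centered lagged predictors."""

    data: pd.DataFrame
    fit_empty2: mlm.FitResult | None = None
    fit_empty3: mlm.FitResult | None = None
    degenerate_three_level: bool = False
    outcome_name: str = "y"

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path) -> None:
        df = self.data.rename(
            columns={"person": "Person", "day": "Day", "beep": "Beep",
                     "y": self.outcome_name, **_R_NAMES}
        )
        df.to_csv(path, index=False, na_rep="NA", float_format="%.17g")


def eb_residuals_2l(panel: LongPanel, fit: mlm.FitResult) -> pd.Series:
    """Beep-level residuals from the empty two-level fit.

    ``e_bi = y - (g00_hat + u0i_hat)`` for observed rows, with the EB/BLUP
    person deviation ``u0i_hat``; missing outcomes give missing residuals.
    """
    if fit.spec.family != "empty2":
        raise ValueError("fit must be an empty two-level model")
    df = panel.data
    panel_persons = set(df.loc[df["y"].notna(), "person"].unique())
    if not panel_persons <= set(fit.eb_person.index):
        raise ValueError("fit does not cover all persons with observed data")
    u0 = df["person"].map(fit.eb_person["intercept"])
    e = df["y"] - (fit.fixed["intercept"] + u0)
    return e.rename("e_bi")


def within_day_lag(column: pd.Series, panel: LongPanel) -> pd.Series:
    """Shift a row-aligned column back one beep within each (person, day).

    Row (i, d, b) receives the value at (i, d, b-1) when that row exists
    and its value is present; the first beep of every day, and any beep
    whose predecessor's value is missing, receive MISSING.  The lag never
    crosses a day boundary (the night interrupts the process).
    """
    df = panel.data
    if len(column) != len(df):
        raise ValueError("column is not row-aligned with the panel")
    col = pd.Series(np.asarray(column, dtype=float), index=df.index)
    grp = df.groupby(["person", "day"], sort=False)
    prev_val = col.groupby([df["person"], df["day"]], sort=False).shift(1)
    prev_beep = grp["beep"].shift(1)
    adjacent = prev_beep == (df["beep"] - 1)
    return prev_val.where(adjacent).rename(getattr(column, "name", None))


def day_residuals_3l(panel: LongPanel, fit: mlm.FitResult) -> pd.Series:
    """EB day-level deviations broadcast to every row of their day.

    Days with no observed outcome get MISSING.  Day effects are keyed on
    (person, day) pairs, so duplicate day labels across persons are safe.
    """
    if fit.spec.family != "empty3":
        raise ValueError("fit must be an empty three-level model")
    df = panel.data
    if fit.eb_day is None:
        raise ValueError("fit has no day-level effects")
    lookup = {(p, d): v for p, d, v in fit.eb_day.itertuples(index=False)}
    obs_days = {
        (p, d)
        for p, d in df.loc[df["y"].notna(), ["person", "day"]].itertuples(index=False)
    }
    missing_days = obs_days - set(lookup)
    if missing_days:
        raise ValueError(f"fit lacks day effects for observed days: {sorted(missing_days)[:5]}")
    vals = [
        lookup.get((p, d), np.nan)
        for p, d in df[["person", "day"]].itertuples(index=False)
    ]
    return pd.Series(vals, index=df.index, name="r_0di")


def person_day_lag(r_0di: pd.Series, panel: LongPanel) -> pd.Series:
    """The previous day's day-level deviation, within person.

    Each person's first recorded day gets MISSING, as does any day whose
    previous day (label d-1) is absent or entirely unobserved.  Persons
    are never mixed.
    """
    df = panel.data
    if len(r_0di) != len(df):
        raise ValueError("r_0di is not row-aligned with the panel")
    vals = np.asarray(r_0di, dtype=float)
    day_val: dict[tuple[int, int], float] = {}
    for (p, d), v in zip(df[["person", "day"]].itertuples(index=False), vals):
        if (p, d) not in day_val and not np.isnan(v):
            day_val[(p, d)] = v
    out = [
        day_val.get((p, d - 1), np.nan)
        for p, d in df[["person", "day"]].itertuples(index=False)
    ]
    return pd.Series(out, index=df.index, name="lev2pred")


def build_predictors(
    panel: LongPanel,
    *,
    three_level: bool = True,
    centering: str = "eb",
) -> LaggedFrame:
    """Fit the empty models on all observed cases and assemble the lagged
    centered predictors.

    ``centering="eb"`` (default) centers on empirical-Bayes estimates;
    ``centering="sample"`` is a sensitivity option using raw person and
    person-day sample means instead.  ``three_level=False`` skips the
    empty three-level fit (only ``e_bi``/``lev1pred`` are produced).

    A panel in which no person has two observed days cannot identify the
    day level; the three-level columns are then all-missing and the frame
    is flagged ``degenerate_three_level``.
    """
    if centering not in ("eb", "sample"):
        raise ValueError("centering must be 'eb' or 'sample'")
    df = panel.data.copy()
    fit2 = fit3 = None
    degenerate = False

    if centering == "eb":
        fit2 = mlm.fit(mlm.ModelSpec("empty2"), df)
        df["e_bi"] = eb_residuals_2l(panel, fit2)
    else:
        pm = df.groupby("person")["y"].transform("mean")
        df["e_bi"] = df["y"] - pm
    df["lev1pred"] = within_day_lag(df["e_bi"], panel)

    if three_level:
        obs = df[df["y"].notna()]
        multi_day = obs.groupby("person")["day"].nunique().max() if len(obs) else 0
        if multi_day < 2:
            degenerate = True
            logger.warning(
                "no person has two observed days; day level is unidentifiable "
                "and three-level predictors are set to missing"
            )
            for c in ("e_bdi", "lev1predfor3l", "r_0di", "lev2pred"):
                df[c] = np.nan
        elif centering == "eb":
            fit3 = mlm.fit(mlm.ModelSpec("empty3"), df)
            df["r_0di"] = day_residuals_3l(panel, fit3)
            u00 = df["person"].map(fit3.eb_person["intercept"])
            df["e_bdi"] = df["y"] - (fit3.fixed["intercept"] + u00 + df["r_0di"])
            df["lev1predfor3l"] = within_day_lag(df["e_bdi"], panel)
            df["lev2pred"] = person_day_lag(df["r_0di"], panel)
        else:
            pm = df.groupby("person")["y"].transform("mean")
            dm = df.groupby(["person", "day"])["y"].transform("mean")
            df["r_0di"] = dm - pm
            df["e_bdi"] = df["y"] - dm
            df["lev1predfor3l"] = within_day_lag(df["e_bdi"], panel)
            df["lev2pred"] = person_day_lag(df["r_0di"], panel)
    return LaggedFrame(
        data=df,
        fit_empty2=fit2,
        fit_empty3=fit3,
        degenerate_three_level=degenerate,
        outcome_name=panel.outcome_name,
    )
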