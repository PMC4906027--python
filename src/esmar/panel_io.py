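"""Long-format panel data for experience-sampling designs.

A panel holds one row per scheduled measurement occasion, indexed by
``person`` (1..Np), ``day`` (within person), and ``beep`` (within day).
Missing outcomes are explicit ``NaN`` values, never absent rows, so that
within-day and between-day lag rules can be applied unambiguously.

The canonical on-disk format is a comma-delimited CSV with a header
``Person,Day,Beep,<outcome>`` and the token ``NA`` (or an empty cell) for
missing outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

INDEX_COLS = ("person", "day", "beep")


class PanelFormatError(ValueError):
    """A file or frame does not have the required panel columns/values."""


class PanelIntegrityError(ValueError):
    """Duplicate (person, day, beep) triples or invalid index values."""


@dataclass(frozen=True)
class StudyDesign:
    """A balanced sampling design: persons x days/person x beeps/day."""

    n_persons: int
    n_days: int
    n_beeps: int

    def __post_init__(self) -> None:
        for name in ("n_persons", "n_days", "n_beeps"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")

    @property
    def n_obs(self) -> int:
        return self.n_persons * self.n_days * self.n_beeps


@dataclass(frozen=True)
class LongPanel:
    """An ordered long-format panel of (person, day, beep, y) occasions.

    ``data`` always carries the canonical columns ``person``, ``day``,
    ``beep`` (positive integers) and ``y`` (float, NaN = missing), sorted
    by person, then day, then beep.  ``outcome_name`` remembers the label
    used in external files.
    """

    data: pd.DataFrame
    outcome_name: str = "y"

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in (*INDEX_COLS, "y") if c not in df.columns]
        if missing:
            raise PanelFormatError(f"panel frame lacks columns {missing}")
        df = df.loc[:, [*INDEX_COLS, "y"]].copy()
        for c in INDEX_COLS:
            vals = df[c].to_numpy()
            as_int = np.asarray(vals, dtype=float)
            if not np.all(np.isfinite(as_int)) or np.any(as_int != np.round(as_int)):
                raise PanelIntegrityError(f"column {c!r} must hold integers")
            df[c] = as_int.astype(np.int64)
            if (df[c] < 1).any():
                raise PanelIntegrityError(f"column {c!r} must be >= 1 (1-based indices)")
        df["y"] = pd.to_numeric(df["y"], errors="raise").astype(float)
        df = df.sort_values(list(INDEX_COLS), kind="stable", ignore_index=True)
        if df.duplicated(list(INDEX_COLS)).any():
            dup = df[df.duplicated(list(INDEX_COLS))].iloc[0]
            raise PanelIntegrityError(
                f"duplicate occasion (person={dup['person']}, day={dup['day']}, "
                f"beep={dup['beep']})"
            )
        object.__setattr__(self, "data", df)

    # -- convenience ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_persons(self) -> int:
        return self.data["person"].nunique()

    def equals(self, other: "LongPanel") -> bool:
        return self.data.equals(other.data)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, outcome_name: str = "y") -> "LongPanel":
        """Build a panel from a frame with Person/Day/Beep/<outcome> columns.

        Column matching is case-insensitive for the index columns.  Rows
        are stably sorted into the canonical order.
        """
        lower = {c.lower(): c for c in frame.columns}
        rename = {}
        for c in INDEX_COLS:
            if c not in lower:
                raise PanelFormatError(f"required column {c!r} not found")
            rename[lower[c]] = c
        if outcome_name in frame.columns:
            rename[outcome_name] = "y"
        elif outcome_name.lower() in lower:
            rename[lower[outcome_name.lower()]] = "y"
        else:
            raise PanelFormatError(f"outcome column {outcome_name!r} not found")
        df = frame.rename(columns=rename)
        return cls(df, outcome_name=outcome_name)


def read_panel(path, outcome_name: str) -> LongPanel:
    """Read a long-format panel CSV.

    Requires columns ``Person``, ``Day``, ``Beep`` (any case) and the named
    outcome column.  ``NA`` and empty cells are treated as missing; any
    other non-numeric outcome token is a parse error.
    """
    try:
        df = pd.read_csv(path, keep_default_na=False, na_values=["NA", ""])
    except ValueError as exc:  # pragma: no cover - malformed csv
        raise PanelFormatError(f"cannot parse {path}: {exc}") from exc
    try:
        return LongPanel.from_frame(df, outcome_name=outcome_name)
    except (ValueError, TypeError) as exc:
        if isinstance(exc, (PanelFormatError, PanelIntegrityError)):
            raise
        raise PanelFormatError(f"non-numeric value in {path}: {exc}") from exc


def write_panel(panel: LongPanel, path) -> None:
    """Write a panel as CSV; round-trips bit-identically through read_panel."""
    df = panel.data.rename(
        columns={"person": "Person", "day": "Day", "beep": "Beep", "y": panel.outcome_name}
    )
    df.to_csv(path, index=False, na_rep="NA", float_format="%.17g")


def _lag_masks(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks: rows with a usable within-day lag-1 predecessor, and
    rows on a day whose previous day exists (for this person) with at least
    one observed outcome."""
    obs = df["y"].notna().to_numpy()
    grp = df.groupby(["person", "day"], sort=False)
    prev_beep = grp["beep"].shift(1)
    prev_obs = grp["y"].shift(1).notna().to_numpy()
    adjacent = (prev_beep.to_numpy() == df["beep"].to_numpy() - 1)
    has_lag = obs & prev_obs & np.where(np.isnan(prev_beep.to_numpy()), False, adjacent)

    day_any = df.assign(_obs=obs).groupby(["person", "day"], sort=False)["_obs"].any()
    observed_days = set(day_any.index[day_any])
    day_pred_ok = np.fromiter(
        ((p, d - 1) in observed_days
         for p, d in zip(df["person"].to_numpy(), df["day"].to_numpy())),
        dtype=bool,
        count=len(df),
    )
    return has_lag, day_pred_ok


def usable_case_counts(panel: LongPanel) -> tuple[int, int, int]:
    """Counts of rows usable by the empty, two-level AR, and three-level AR
    models: observed outcomes; those whose same-day previous beep is also
    observed; and those additionally preceded by an observed day (so the
    day-level lagged predictor exists).

    For a complete balanced design this gives
    (Np*Nd*Nb, Np*Nd*(Nb-1), Np*(Nd-1)*(Nb-1)).
    """
    df = panel.data
    obs = df["y"].notna().to_numpy()
    has_lag, day_pred_ok = _lag_masks(df)
    n_total = int(obs.sum())
    n_ar2 = int(has_lag.sum())
    n_ar3 = int((has_lag & day_pred_ok).sum())
    return n_total, n_ar2, n_ar3
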