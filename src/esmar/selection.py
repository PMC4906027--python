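"""Information-criterion selection of the number of levels.

Deciding between two- and three-level modeling via the day-level variance
test in empty models is unreliable: beep-level carry-over masquerades as
day-level variance.  The robust procedure compares the *autoregressive*
models by AIC (or BIC) instead: fit the two-level AR(1) model and the
three-level AR(1) variants, all without random-effect correlations, on
the identical case subset, and pick the criterion minimizer.  Three
levels are chosen iff a three-level family wins; exact ties break toward
the more parsimonious two-level structure.

Because the three-level AR model needs both a within-day and a
between-day lagged predictor, its usable case set is the smallest; every
compared model is therefore refitted on that common subset, while the
empty models used for EB centering are always fitted to all observed
cases first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import mlm
from .lagging import LaggedFrame, build_predictors
from .panel_io import LongPanel

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_MODEL_SET",
    "SelectionResult",
    "common_subset",
    "fit_model_set",
    "choose",
    "select_levels",
    "empirical_workflow",
]

#: the AR model set compared during level selection (uncorrelated randoms)
DEFAULT_MODEL_SET: tuple[mlm.ModelSpec, ...] = (
    mlm.ModelSpec("ar2"),
    mlm.ModelSpec("ar3_nobeta"),
    mlm.ModelSpec("ar3_fixedbeta"),
    mlm.ModelSpec("ar3_randombeta"),
)


@dataclass
class SelectionResult:
    """Per-model information criteria and the chosen level structure."""

    table: pd.DataFrame
    criterion: str
    chosen_family: str
    chosen_levels: int
    fits: dict[str, mlm.FitResult] = field(repr=False, default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def common_subset(lf: LaggedFrame) -> np.ndarray:
    """Row mask of the cases usable by the full three-level AR(1) model.

    Selects rows with an observed outcome and all three lagged predictors
    present; this is the smallest case set among the compared AR models,
    on which all of them must be estimated for a valid IC comparison.
    """
    df = lf.data
    for c in ("lev1pred", "lev1predfor3l", "lev2pred"):
        if c not in df.columns:
            raise ValueError(f"lagged frame lacks column {c!r}; build predictors first")
    mask = (
        df["y"].notna()
        & df["lev1pred"].notna()
        & df["lev1predfor3l"].notna()
        & df["lev2pred"].notna()
    ).to_numpy()
    if not mask.any():
        raise ValueError(
            "no cases support the three-level AR model (need >= 2 days with "
            ">= 2 beeps each per at least one person)"
        )
    return mask


def fit_model_set(
    lf: LaggedFrame,
    specs: tuple[mlm.ModelSpec, ...] = DEFAULT_MODEL_SET,
    mask: np.ndarray | None = None,
) -> tuple[dict[str, mlm.FitResult], list[str]]:
    """Fit every spec on the common-subset rows; non-converged fits are
    dropped with a recorded warning rather than failing the run."""
    if mask is None:
        mask = common_subset(lf)
    sub = lf.data.loc[mask]
    fits: dict[str, mlm.FitResult] = {}
    notes: list[str] = []
    for spec in specs:
        try:
            res = mlm.fit(spec, sub)
        except Exception as exc:  # noqa: BLE001 - recorded, not fatal
            notes.append(f"{spec.family}: fit failed ({exc})")
            logger.warning("fit of %s failed: %s", spec.family, exc)
            continue
        if not res.converged:
            notes.append(f"{spec.family}: did not converge; excluded from comparison")
            logger.warning("fit of %s did not converge; excluded", spec.family)
            continue
        fits[spec.family] = res
    n_obs = {f.n_obs for f in fits.values()}
    if len(n_obs) > 1:
        raise AssertionError(f"compared models used different case sets: {n_obs}")
    return fits, notes


def choose(fits: dict[str, mlm.FitResult], criterion: str) -> tuple[str, int]:
    """Argmin of the criterion; exact ties break toward fewer levels."""
    crit = criterion.lower()
    if crit not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")
    if not fits:
        raise mlm.ConvergenceError("no model in the set converged")
    vals = {fam: getattr(f, crit) for fam, f in fits.items()}
    best = min(vals.values())
    tied = [fam for fam, v in vals.items() if v <= best + 1e-9]
    tied.sort(key=lambda fam: (fits[fam].spec.n_levels, fam))
    fam = tied[0]
    return fam, fits[fam].spec.n_levels


def select_levels(
    panel: LongPanel | LaggedFrame,
    criterion: str = "aic",
    model_set: tuple[mlm.ModelSpec, ...] = DEFAULT_MODEL_SET,
) -> SelectionResult:
    """Run the recommended level-selection procedure on a panel.

    Builds EB-centered lagged predictors on the full data, restricts to
    the common case subset, fits the AR model set, and returns the
    criterion minimizer.  The empty models never participate: comparing
    empty models inherits the very day-variance artifact this procedure
    avoids.
    """
    lf = panel if isinstance(panel, LaggedFrame) else build_predictors(panel)
    if lf.degenerate_three_level:
        raise ValueError("panel cannot support three-level predictors (single day)")
    fits, notes = fit_model_set(lf, model_set)
    fam, levels = choose(fits, criterion)
    table = pd.DataFrame(
        [
            {
                "family": f.spec.family,
                "levels": f.spec.n_levels,
                "n_obs": f.n_obs,
                "loglik": f.loglik,
                "k": f.k_params,
                "aic": f.aic,
                "bic": f.bic,
                "converged": f.converged,
            }
            for f in fits.values()
        ]
    ).sort_values("family", ignore_index=True)
    return SelectionResult(
        table=table,
        criterion=criterion.lower(),
        chosen_family=fam,
        chosen_levels=levels,
        fits=fits,
        warnings=notes,
    )


def empirical_workflow(panel: LongPanel, criterion: str = "aic") -> dict:
    """The full recommended analysis path for one outcome, as a report.

    Centers predictors on all observed cases, compares the AR model set on
    the common subset, and returns the per-model IC table together with
    the selected model's complete estimates.
    """
    sel = select_levels(panel, criterion=criterion)
    chosen = sel.fits[sel.chosen_family]
    return {
        "criterion": sel.criterion,
        "table": sel.table.to_dict(orient="records"),
        "chosen_family": sel.chosen_family,
        "chosen_levels": sel.chosen_levels,
        "chosen_fit": chosen.to_dict(),
        "warnings": sel.warnings,
    }
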