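"""Generative models for nested experience-sampling series.

Two data-generating processes are provided:

* a two-level AR(1) process, in which each person has a trait level
  ``mu_i = gamma00 + u0i`` and a beep-to-beep inertia
  ``phi_i = gamma10 + u1i``, and each day's series restarts independently
  (the night interrupts the process, so the first beep of a day is not
  predicted by the previous evening);
* a three-level AR(1) process, in which day means follow an AR(1) across
  days within person (day-to-day inertia ``beta_i``), and beeps follow an
  AR(1) around the current day mean (beep inertia ``zeta_i``), again with
  independent restarts each morning.

Person-level deviations are jointly multivariate normal with configurable
correlations.  Sampled inertias are truncated into (-1, 1) so every
generated series is stationary; series are initialized from their
stationary distributions.

Random-number discipline: each person consumes an independent substream
spawned from the caller's generator, so enlarging ``n_persons`` never
reshuffles the data of earlier persons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel_io import LongPanel, StudyDesign

__all__ = [
    "TwoLevelARParams",
    "ThreeLevelARParams",
    "PersonEffects",
    "truncate_inertia",
    "draw_person_effects",
    "simulate_ar2",
    "simulate_ar3",
    "simulate_empty3",
]


def _check_sd(name: str, v: float) -> None:
    if not (np.isfinite(v) and v >= 0):
        raise ValueError(f"{name} must be a finite non-negative SD, got {v!r}")


def _check_corr(name: str, v: float) -> None:
    if not (np.isfinite(v) and abs(v) <= 1):
        raise ValueError(f"{name} must lie in [-1, 1], got {v!r}")


@dataclass(frozen=True)
class TwoLevelARParams:
    """Population parameters of the two-level AR(1) process.

    gamma00: mean trait level; gamma10: mean beep-level inertia;
    sd_u0/sd_u1: SDs of person deviations in trait level and inertia;
    sd_e: beep-level residual SD; r_u0u1: correlation of (u0i, u1i).
    """

    gamma00: float
    gamma10: float
    sd_u0: float
    sd_u1: float
    sd_e: float
    r_u0u1: float = 0.0

    def __post_init__(self) -> None:
        for n in ("sd_u0", "sd_u1", "sd_e"):
            _check_sd(n, getattr(self, n))
        _check_corr("r_u0u1", self.r_u0u1)

    @property
    def corr_matrix(self) -> np.ndarray:
        return np.array([[1.0, self.r_u0u1], [self.r_u0u1, 1.0]])

    @property
    def sds(self) -> np.ndarray:
        return np.array([self.sd_u0, self.sd_u1])


@dataclass(frozen=True)
class ThreeLevelARParams:
    """Population parameters of the three-level AR(1) process.

    gamma000: mean trait level; gamma010: mean day-level inertia;
    gamma100: mean beep-level inertia; sd_u00/sd_u01/sd_u10: SDs of the
    person deviations of these three quantities; sd_r: day-level residual
    SD; sd_e: beep-level residual SD; r_*: pairwise correlations of the
    person deviations.
    """

    gamma000: float
    gamma010: float
    gamma100: float
    sd_u00: float
    sd_u01: float
    sd_u10: float
    sd_r: float
    sd_e: float
    r_u00u01: float = 0.0
    r_u00u10: float = 0.0
    r_u01u10: float = 0.0

    def __post_init__(self) -> None:
        for n in ("sd_u00", "sd_u01", "sd_u10", "sd_r", "sd_e"):
            _check_sd(n, getattr(self, n))
        for n in ("r_u00u01", "r_u00u10", "r_u01u10"):
            _check_corr(n, getattr(self, n))
        if np.linalg.eigvalsh(self.corr_matrix).min() < -1e-10:
            raise ValueError("correlation matrix of person deviations is not PSD")

    @property
    def corr_matrix(self) -> np.ndarray:
        r1, r2, r3 = self.r_u00u01, self.r_u00u10, self.r_u01u10
        return np.array([[1.0, r1, r2], [r1, 1.0, r3], [r2, r3, 1.0]])

    @property
    def sds(self) -> np.ndarray:
        return np.array([self.sd_u00, self.sd_u01, self.sd_u10])


@dataclass(frozen=True)
class PersonEffects:
    """Per-person realized trait levels and (truncated) inertias.

    ``inertias`` has one column per autoregressive coefficient: (phi,) for
    the two-level process, (beta, zeta) for the three-level process.
    ``deviations`` holds the raw multivariate-normal draws before adding
    the population means and truncating.
    """

    mu: np.ndarray
    inertias: np.ndarray
    deviations: np.ndarray


def truncate_inertia(value):
    """Force autoregressive coefficients into (-1, 1).

    Values >= 1 become 0.99 and values <= -1 become -0.99; anything already
    inside the open unit interval is returned unchanged.  This keeps every
    sampled person-level AR(1) process stationary.
    """
    v = np.asarray(value, dtype=float)
    out = np.where(v >= 1.0, 0.99, np.where(v <= -1.0, -0.99, v))
    if np.isscalar(value) or np.ndim(value) == 0:
        return float(out)
    return out


def _corr_factor(corr: np.ndarray) -> np.ndarray:
    """A factor L with L L' = corr, tolerating singular (|r| = 1) matrices."""
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(corr)
        return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def _person_streams(rng: np.random.Generator, n: int) -> list[np.random.Generator]:
    return rng.spawn(n)


def draw_person_effects(params, n_persons: int, rng: np.random.Generator) -> PersonEffects:
    """Draw each person's trait level and inertia(s).

    Deviations are jointly multivariate normal with the parameter set's SDs
    and correlations; inertias are passed through :func:`truncate_inertia`.
    Each person uses an independent spawned substream (the same stream that
    later generates that person's series in the simulators).
    """
    streams = _person_streams(rng, n_persons)
    return _draw_effects_from_streams(params, streams)


def _draw_effects_from_streams(params, streams) -> PersonEffects:
    two_level = isinstance(params, TwoLevelARParams)
    L = params.sds[:, None] * _corr_factor(params.corr_matrix)
    k = L.shape[0]
    devs = np.empty((len(streams), k))
    for j, s in enumerate(streams):
        devs[j] = L @ s.standard_normal(k)
    if two_level:
        mu = params.gamma00 + devs[:, 0]
        inert = truncate_inertia(params.gamma10 + devs[:, 1])[:, None]
    else:
        mu = params.gamma000 + devs[:, 0]
        beta = truncate_inertia(params.gamma010 + devs[:, 1])
        zeta = truncate_inertia(params.gamma100 + devs[:, 2])
        inert = np.column_stack([beta, zeta])
    return PersonEffects(mu=mu, inertias=np.atleast_2d(inert), deviations=devs)


def _stationary_ar_matrix(
    s: np.random.Generator, nd: int, nb: int, phi: float, sd: float
) -> np.ndarray:
    """nd independent stationary AR(1) series of length nb (rows = days)."""
    eps = s.standard_normal((nd, nb))
    dev = np.empty((nd, nb))
    init_sd = sd / np.sqrt(1.0 - phi * phi) if sd > 0 else 0.0
    dev[:, 0] = eps[:, 0] * init_sd
    for b in range(1, nb):
        dev[:, b] = phi * dev[:, b - 1] + sd * eps[:, b]
    return dev


def _assemble(design: StudyDesign, y: np.ndarray, outcome_name: str) -> LongPanel:
    npn, nd, nb = design.n_persons, design.n_days, design.n_beeps
    df = pd.DataFrame(
        {
            "person": np.repeat(np.arange(1, npn + 1), nd * nb),
            "day": np.tile(np.repeat(np.arange(1, nd + 1), nb), npn),
            "beep": np.tile(np.arange(1, nb + 1), npn * nd),
            "y": y,
        }
    )
    return LongPanel(df, outcome_name=outcome_name)


def _thin(y: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate:
        y = y.copy()
        y[rng.random(y.shape[0]) < rate] = np.nan
    return y


def simulate_ar2(
    params: TwoLevelARParams,
    design: StudyDesign,
    rng: np.random.Generator,
    missing_rate: float = 0.0,
    outcome_name: str = "y",
) -> LongPanel:
    """Simulate a complete balanced panel from the two-level AR(1) process.

    Each day of each person is an independent stationary AR(1) series
    around the person's trait level: the first beep's deviation is drawn
    from N(0, sd_e^2 / (1 - phi_i^2)) and later beeps follow
    ``y_b = mu_i + phi_i (y_{b-1} - mu_i) + e``.  ``missing_rate`` applies
    optional MCAR thinning (default 0: complete data).
    """
    streams = _person_streams(rng, design.n_persons)
    eff = _draw_effects_from_streams(params, streams)
    nd, nb = design.n_days, design.n_beeps
    out = np.empty(design.n_obs)
    for j, s in enumerate(streams):
        phi = eff.inertias[j, 0]
        dev = _stationary_ar_matrix(s, nd, nb, phi, params.sd_e)
        out[j * nd * nb : (j + 1) * nd * nb] = (eff.mu[j] + dev).ravel()
        out[j * nd * nb : (j + 1) * nd * nb] = _thin(
            out[j * nd * nb : (j + 1) * nd * nb], missing_rate, s
        )
    return _assemble(design, out, outcome_name)


def simulate_ar3(
    params: ThreeLevelARParams,
    design: StudyDesign,
    rng: np.random.Generator,
    missing_rate: float = 0.0,
    outcome_name: str = "y",
) -> LongPanel:
    """Simulate a complete balanced panel from the three-level AR(1) process.

    Day means follow a stationary AR(1) across days within person
    (coefficient ``beta_i``, innovation SD ``sd_r``); conditional on its
    day mean, each day's beep series is an independent stationary AR(1)
    with coefficient ``zeta_i`` and innovation SD ``sd_e``.  With
    ``sd_r = 0``, ``gamma010 = 0`` and ``sd_u01 = 0`` the process reduces
    distributionally to :func:`simulate_ar2` with matched parameters.
    """
    streams = _person_streams(rng, design.n_persons)
    eff = _draw_effects_from_streams(params, streams)
    nd, nb = design.n_days, design.n_beeps
    out = np.empty(design.n_obs)
    for j, s in enumerate(streams):
        beta, zeta = eff.inertias[j]
        ed = s.standard_normal(nd)
        ddev = np.empty(nd)
        init_sd = params.sd_r / np.sqrt(1.0 - beta * beta) if params.sd_r > 0 else 0.0
        ddev[0] = ed[0] * init_sd
        for d in range(1, nd):
            ddev[d] = beta * ddev[d - 1] + params.sd_r * ed[d]
        bdev = _stationary_ar_matrix(s, nd, nb, zeta, params.sd_e)
        y = (eff.mu[j] + ddev)[:, None] + bdev
        out[j * nd * nb : (j + 1) * nd * nb] = _thin(y.ravel(), missing_rate, s)
    return _assemble(design, out, outcome_name)


def simulate_empty3(
    gamma000: float,
    sd_u00: float,
    sd_r: float,
    sd_e: float,
    design: StudyDesign,
    rng: np.random.Generator,
    missing_rate: float = 0.0,
    outcome_name: str = "y",
) -> LongPanel:
    """Simulate from the empty three-level model (no inertia at any level).

    Convenience wrapper over :func:`simulate_ar3` with all autoregressive
    coefficients and slope SDs fixed at zero: observations are
    ``gamma000 + u00i + r0di + e_bdi`` with independent normal terms.
    """
    params = ThreeLevelARParams(
        gamma000=gamma000,
        gamma010=0.0,
        gamma100=0.0,
        sd_u00=sd_u00,
        sd_u01=0.0,
        sd_u10=0.0,
        sd_r=sd_r,
        sd_e=sd_e,
    )
    return simulate_ar3(params, design, rng, missing_rate=missing_rate, outcome_name=outcome_name)
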