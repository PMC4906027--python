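"""Gaussian linear mixed models for nested ESM panels, fitted by ML.

The families implemented here are exactly the models used in two- vs
three-level AR(1) analysis of beep-level data:

========================  =============================  =========================
family                    fixed effects                  random effects
========================  =============================  =========================
``empty2``                intercept                      person intercept
``empty3``                intercept                      person + day intercepts
``ar2``                   intercept, lev1pred            person intercept + slope
``ar3_nobeta``            intercept, lev1predfor3l       person intercept + slope,
                                                         day intercept
``ar3_fixedbeta``         + lev2pred (fixed only)        as ar3_nobeta
``ar3_randombeta``        + lev2pred                     + person lev2pred slope
``ar3_fixedonly``         intercept, lev2pred,           person + day intercepts
                          lev1predfor3l                  (no random slopes)
========================  =============================  =========================

Person-level random effects are independent by default; ``correlated=True``
(available for ``ar2`` and ``ar3_randombeta``) estimates their full
covariance.  The day intercept is always independent of the person-level
effects.

Estimation maximizes the exact marginal Gaussian likelihood with the fixed
effects and the residual variance profiled out.  Writing the model for
person ``i`` as ``y_i = X_i b + U_i u_i + e_i`` with
``u_i ~ N(0, sigma^2 L L')`` and ``e_i ~ N(0, sigma^2 I)``, the Woodbury
identity reduces every likelihood quantity to the per-person Gram blocks
of ``[U_i, X_i, y_i]`` and the small matrix ``M_i = I + L' U_i'U_i L``,
so one likelihood evaluation costs O(q^3) per person with
``q = (#random slopes) + (#days)``.  The relative covariance factor ``L``
is optimized unconstrained; the likelihood depends on it only through
``L L'``, which keeps every proposal positive semi-definite and lets
boundary solutions (a variance estimated at zero) occur at finite
parameter values.  Boundary fits are flagged, not rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ModelSpec",
    "FitResult",
    "ConvergenceError",
    "fit",
    "marginal_loglik",
    "lrt",
    "wald",
]

_LOG2PI = float(np.log(2.0 * np.pi))

#: family -> (fixed columns, person-level random columns, day intercept?, levels)
FAMILY_DEFS: dict[str, tuple[tuple[str, ...], tuple[str, ...], bool, int]] = {
    "empty2": (("intercept",), ("intercept",), False, 2),
    "empty3": (("intercept",), ("intercept",), True, 3),
    "ar2": (("intercept", "lev1pred"), ("intercept", "lev1pred"), False, 2),
    "ar3_nobeta": (
        ("intercept", "lev1predfor3l"),
        ("intercept", "lev1predfor3l"),
        True,
        3,
    ),
    "ar3_fixedbeta": (
        ("intercept", "lev2pred", "lev1predfor3l"),
        ("intercept", "lev1predfor3l"),
        True,
        3,
    ),
    "ar3_randombeta": (
        ("intercept", "lev2pred", "lev1predfor3l"),
        ("intercept", "lev2pred", "lev1predfor3l"),
        True,
        3,
    ),
    "ar3_fixedonly": (
        ("intercept", "lev2pred", "lev1predfor3l"),
        ("intercept",),
        True,
        3,
    ),
}

_CORR_FAMILIES = {"ar2", "ar3_randombeta"}


class ConvergenceError(RuntimeError):
    """Raised when a fit cannot be used where convergence is mandatory."""


@dataclass(frozen=True)
class ModelSpec:
    """A model family plus the person-level random-correlation switch."""

    family: str
    correlated: bool = False

    def __post_init__(self) -> None:
        if self.family not in FAMILY_DEFS:
            raise ValueError(
                f"unknown family {self.family!r}; choose from {sorted(FAMILY_DEFS)}"
            )
        if self.correlated and self.family not in _CORR_FAMILIES:
            raise ValueError(
                f"correlated random effects are only meaningful for {_CORR_FAMILIES}"
            )

    @property
    def fixed_terms(self) -> tuple[str, ...]:
        return FAMILY_DEFS[self.family][0]

    @property
    def random_terms(self) -> tuple[str, ...]:
        return FAMILY_DEFS[self.family][1]

    @property
    def has_day_level(self) -> bool:
        return FAMILY_DEFS[self.family][2]

    @property
    def n_levels(self) -> int:
        return FAMILY_DEFS[self.family][3]

    @property
    def k_params(self) -> int:
        """Number of estimated parameters, counted as the fitting software
        counts them for AIC/BIC: fixed effects + variance/covariance
        components (including the day-level variance) + residual variance."""
        p_re = len(self.random_terms)
        n_g = p_re * (p_re + 1) // 2 if self.correlated else p_re
        return len(self.fixed_terms) + n_g + int(self.has_day_level) + 1


@dataclass
class FitResult:
    """Maximum-likelihood estimates for one fitted mixed model."""

    spec: ModelSpec
    fixed: dict[str, float]
    se: dict[str, float]
    sds: dict[str, float]  # person-level random SDs + "day" + "resid"
    corrs: dict[str, float]
    loglik: float
    n_obs: int
    k_params: int
    aic: float
    bic: float
    eb_person: pd.DataFrame
    eb_day: pd.DataFrame | None
    converged: bool
    boundary: bool
    resid: pd.Series = field(repr=False, default=None)
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "family": self.spec.family,
            "correlated": self.spec.correlated,
            "fixed": self.fixed,
            "se": self.se,
            "sds": self.sds,
            "corrs": self.corrs,
            "loglik": self.loglik,
            "n_obs": self.n_obs,
            "k_params": self.k_params,
            "aic": self.aic,
            "bic": self.bic,
            "converged": self.converged,
            "boundary": self.boundary,
        }


# ---------------------------------------------------------------------------
# data preparation


def _as_frame(data) -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        return data
    if hasattr(data, "data") and isinstance(data.data, pd.DataFrame):
        return data.data
    raise TypeError(f"cannot extract a data frame from {type(data)!r}")


class _Prepared:
    """Listwise-deleted, person-grouped design with per-person Gram blocks."""

    def __init__(self, spec: ModelSpec, df: pd.DataFrame):
        xcols, zcols, has_day, _ = FAMILY_DEFS[spec.family]
        need = {"person", "y", *(c for c in set(xcols + zcols) if c != "intercept")}
        if has_day:
            need.add("day")
        missing = need - set(df.columns)
        if missing:
            raise ValueError(f"model {spec.family!r} needs columns {sorted(missing)}")
        used = df.dropna(subset=[c for c in need if c != "person"]).copy()
        if not len(used):
            raise ValueError("no usable rows after listwise deletion")
        self.spec = spec
        self.index = used.index
        self.n = len(used)
        self.y = used["y"].to_numpy(float)

        def col(name, frame):
            if name == "intercept":
                return np.ones(len(frame))
            return frame[name].to_numpy(float)

        X = np.column_stack([col(c, used) for c in xcols])
        Z = np.column_stack([col(c, used) for c in zcols])
        # scale non-intercept columns to unit SD for optimizer conditioning
        self.x_scale = np.array(
            [1.0 if c == "intercept" else max(np.std(X[:, j]), 1e-12) for j, c in enumerate(xcols)]
        )
        self.z_scale = np.array(
            [1.0 if c == "intercept" else max(np.std(Z[:, j]), 1e-12) for j, c in enumerate(zcols)]
        )
        Xs = X / self.x_scale
        Zs = Z / self.z_scale

        persons = used["person"].to_numpy()
        self.person_ids, starts = np.unique(persons, return_index=True)
        order_ok = np.all(np.diff(persons) >= 0) if len(persons) else True
        if not order_ok:
            raise ValueError("rows must be sorted by person")
        bounds = np.r_[starts, len(used)]
        B = len(self.person_ids)
        p_re = len(zcols)
        self.p = len(xcols)
        self.p_re = p_re
        self.has_day = has_day

        self.day_codes: list[np.ndarray] = []
        self.day_labels: list[np.ndarray] = []
        nd = np.zeros(B, dtype=int)
        if has_day:
            days = used["day"].to_numpy()
            for i in range(B):
                sl = slice(bounds[i], bounds[i + 1])
                labels, codes = np.unique(days[sl], return_inverse=True)
                self.day_labels.append(labels)
                self.day_codes.append(codes)
                nd[i] = len(labels)
        self.nd = nd
        q = p_re + (int(nd.max()) if has_day else 0)
        self.q = q

        self.A = np.zeros((B, q, q))
        self.Cux = np.zeros((B, q, self.p))
        self.Cuy = np.zeros((B, q))
        self.Cxx = np.zeros((B, self.p, self.p))
        self.Cxy = np.zeros((B, self.p))
        self.Cyy = np.zeros(B)
        self.rows: list[slice] = []
        for i in range(B):
            sl = slice(bounds[i], bounds[i + 1])
            self.rows.append(sl)
            Zi, Xi, yi = Zs[sl], Xs[sl], self.y[sl]
            if has_day:
                D = np.zeros((Zi.shape[0], nd[i]))
                D[np.arange(Zi.shape[0]), self.day_codes[i]] = 1.0
                U = np.hstack([Zi, D])
            else:
                U = Zi
            qi = U.shape[1]
            self.A[i, :qi, :qi] = U.T @ U
            self.Cux[i, :qi] = U.T @ Xi
            self.Cuy[i, :qi] = U.T @ yi
            self.Cxx[i] = Xi.T @ Xi
            self.Cxy[i] = Xi.T @ yi
            self.Cyy[i] = yi @ yi
        self.Cxx_tot = self.Cxx.sum(axis=0)
        self.Cxy_tot = self.Cxy.sum(axis=0)
        self.Cyy_tot = self.Cyy.sum()
        self.Xs = Xs
        self.Zs = Zs
        self.xcols = xcols
        self.zcols = zcols

    # -- parameter vector layout -------------------------------------------
    @property
    def n_theta(self) -> int:
        p_re = self.p_re
        n_l = p_re * (p_re + 1) // 2 if self.spec.correlated else p_re
        return n_l + int(self.has_day)

    def lam_matrix(self, theta: np.ndarray) -> np.ndarray:
        """Dense (q, q) relative covariance factor for the stacked random
        effects [person effects, day intercepts]."""
        q, p_re = self.q, self.p_re
        lam = np.zeros((q, q))
        if self.spec.correlated:
            idx = np.tril_indices(p_re)
            Lz = np.zeros((p_re, p_re))
            Lz[idx] = theta[: len(idx[0])]
            lam[:p_re, :p_re] = Lz
            used = len(idx[0])
        else:
            lam[np.arange(p_re), np.arange(p_re)] = np.abs(theta[:p_re])
            used = p_re
        if self.has_day:
            d = np.arange(p_re, q)
            lam[d, d] = np.abs(theta[used])
        return lam

    def theta0(self) -> np.ndarray:
        x0 = np.full(self.n_theta, 0.5)
        if self.spec.correlated:
            idx = np.tril_indices(self.p_re)
            off = idx[0] != idx[1]
            x0[: len(idx[0])][off] = 0.0
        return x0

    # -- likelihood kernels -------------------------------------------------
    def _core(self, lam: np.ndarray):
        """Shared Woodbury pieces for a given relative factor."""
        M = np.eye(self.q) + lam.T @ self.A @ lam
        chol = np.linalg.cholesky(M)
        logdet = 2.0 * np.log(np.diagonal(chol, axis1=1, axis2=2)).sum()
        TX = lam.T @ self.Cux  # (B, q, p)
        Ty = self.Cuy @ lam  # (B, q)
        rhs = np.concatenate([TX, Ty[:, :, None]], axis=2)
        sol = np.linalg.solve(M, rhs)
        return M, logdet, TX, Ty, sol

    def profiled(self, theta: np.ndarray):
        """Profiled deviance pieces: (nll, beta_s, sigma2, extras)."""
        lam = self.lam_matrix(theta)
        M, logdet, TX, Ty, sol = self._core(lam)
        p = self.p
        XtVX = self.Cxx_tot - np.einsum("bqp,bqr->pr", TX, sol[:, :, :p])
        XtVy = self.Cxy_tot - np.einsum("bqp,bq->p", TX, sol[:, :, p])
        ytVy = self.Cyy_tot - np.einsum("bq,bq->", Ty, sol[:, :, p])
        try:
            beta = np.linalg.solve(XtVX, XtVy)
        except np.linalg.LinAlgError:
            beta = np.linalg.lstsq(XtVX, XtVy, rcond=None)[0]
        qf = ytVy - beta @ XtVy
        floor = max(1e-12 * self.Cyy_tot, 1e-300)
        qf = max(qf, floor)
        sigma2 = qf / self.n
        nll = 0.5 * (self.n * (_LOG2PI + np.log(sigma2) + 1.0) + logdet)
        return nll, beta, sigma2, (lam, M, XtVX)

    def nll(self, theta: np.ndarray) -> float:
        return self.profiled(theta)[0]

    def eb(self, lam: np.ndarray, M: np.ndarray, beta: np.ndarray):
        """EB/BLUP modes of the stacked random effects, in scaled units."""
        r_u = self.Cuy - self.Cux @ beta  # (B, q)
        t = np.einsum("qr,bq->br", lam, r_u)
        inner = np.linalg.solve(M, t[..., None])[..., 0]
        return np.einsum("qr,br->bq", lam, inner)

    def loglik_at(self, beta: np.ndarray, sd_e: float, lam_nat: np.ndarray) -> float:
        """Exact (non-profiled) marginal log-likelihood at natural values.

        ``lam_nat`` is the relative factor G^{1/2}/sd_e in *scaled* design
        units; ``beta`` likewise in scaled units.
        """
        M, logdet, TX, Ty, sol = self._core(lam_nat)
        r_u = self.Cuy - self.Cux @ beta
        rr = (
            self.Cyy
            - 2.0 * self.Cxy @ beta
            + np.einsum("p,bpr,r->b", beta, self.Cxx, beta)
        )
        t = np.einsum("qr,bq->br", lam_nat, r_u)
        inner = np.linalg.solve(M, t[..., None])[..., 0]
        quad = rr - np.einsum("bq,bq->b", t, inner)
        return float(
            -0.5 * (self.n * (_LOG2PI + 2.0 * np.log(sd_e)) + logdet + quad.sum() / sd_e**2)
        )


# ---------------------------------------------------------------------------
# public operations


def marginal_loglik(spec: ModelSpec, data, params: dict) -> float:
    """Exact marginal Gaussian log-likelihood at specified natural values.

    ``params`` holds ``fixed`` (term -> coefficient), ``sd`` (random term
    -> SD, plus ``"day"`` for three-level families), optional ``corr``
    ("a:b" -> correlation among person-level random effects), and
    ``sd_e``.  Rows with a missing outcome or predictor are removed first
    (listwise deletion).
    """
    prep = _Prepared(spec, _as_frame(data))
    sd_e = float(params["sd_e"])
    if sd_e <= 0:
        raise ValueError("sd_e must be positive")
    beta_raw = np.array([float(params["fixed"][c]) for c in prep.xcols])
    beta = beta_raw * prep.x_scale
    p_re = prep.p_re
    sds_raw = np.array([float(params["sd"].get(c, 0.0)) for c in prep.zcols])
    sds = sds_raw * prep.z_scale  # scaled-design units
    G = np.diag(sds**2)
    for key, r in (params.get("corr") or {}).items():
        a, b = key.split(":")
        ia, ib = prep.zcols.index(a), prep.zcols.index(b)
        G[ia, ib] = G[ib, ia] = r * sds[ia] * sds[ib]
    try:
        Lz = np.linalg.cholesky(G + 1e-300 * np.eye(p_re))
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(G)
        Lz = v @ np.diag(np.sqrt(np.clip(w, 0, None)))
    lam = np.zeros((prep.q, prep.q))
    lam[:p_re, :p_re] = Lz / sd_e
    if prep.has_day:
        d = np.arange(p_re, prep.q)
        lam[d, d] = float(params["sd"].get("day", 0.0)) / sd_e
    return prep.loglik_at(beta, sd_e, lam)


def fit(
    spec: ModelSpec,
    data,
    *,
    maxiter: int = 500,
    polish: bool = True,
    boundary_tol: float = 1e-4,
) -> FitResult:
    """Fit a mixed model by maximum likelihood (deterministic, ML not REML).

    Fixed effects and the residual variance are profiled out; the relative
    covariance factor is optimized by L-BFGS with a Nelder-Mead polish.
    Variance components may land on the zero boundary; such fits are
    returned with ``boundary=True``.  ``n_obs`` must exceed the parameter
    count.
    """
    prep = _Prepared(spec, _as_frame(data))
    k = spec.k_params
    if prep.n <= k:
        raise ValueError(f"{prep.n} usable cases cannot identify {k} parameters")

    x0 = prep.theta0()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = optimize.minimize(
            prep.nll,
            x0,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-13, "gtol": 1e-8},
        )
        best = res
        if polish:
            res2 = optimize.minimize(
                prep.nll,
                best.x,
                method="Nelder-Mead",
                options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 400 * prep.n_theta},
            )
            if res2.fun < best.fun:
                best = res2
    converged = bool(np.isfinite(best.fun)) and (res.success or best.fun <= res.fun)

    nll, beta_s, sigma2, (lam, M, XtVX) = prep.profiled(best.x)
    loglik = -nll
    sigma = float(np.sqrt(sigma2))

    beta = beta_s / prep.x_scale
    try:
        cov_s = sigma2 * np.linalg.inv(XtVX)
        se = np.sqrt(np.clip(np.diag(cov_s), 0, None)) / prep.x_scale
    except np.linalg.LinAlgError:
        se = np.full(prep.p, np.nan)

    # natural-scale variance components
    Lz = lam[: prep.p_re, : prep.p_re]
    G_s = sigma2 * (Lz @ Lz.T)
    D = np.diag(1.0 / prep.z_scale)
    G = D @ G_s @ D
    re_sds = np.sqrt(np.clip(np.diag(G), 0, None))
    sds = {c: float(s) for c, s in zip(prep.zcols, re_sds)}
    corrs: dict[str, float] = {}
    if spec.correlated:
        for i in range(prep.p_re):
            for j in range(i):
                denom = re_sds[i] * re_sds[j]
                corrs[f"{prep.zcols[j]}:{prep.zcols[i]}"] = (
                    float(G[i, j] / denom) if denom > 0 else np.nan
                )
    if prep.has_day:
        sds["day"] = float(sigma * lam[prep.p_re, prep.p_re]) if prep.q > prep.p_re else 0.0
    sds["resid"] = sigma

    boundary = bool(
        np.any(np.abs(np.diag(lam)[: prep.p_re]) < boundary_tol)
        or (prep.has_day and prep.q > prep.p_re and lam[prep.p_re, prep.p_re] < boundary_tol)
    )

    # EB/BLUP predictions and row-level residuals
    b = prep.eb(lam, M, beta_s)  # (B, q) scaled units
    b_person = b[:, : prep.p_re] / prep.z_scale
    eb_person = pd.DataFrame(b_person, index=pd.Index(prep.person_ids, name="person"),
                             columns=list(prep.zcols))
    eb_day = None
    if prep.has_day:
        recs = []
        for i, pid in enumerate(prep.person_ids):
            for code, lab in enumerate(prep.day_labels[i]):
                recs.append((pid, lab, b[i, prep.p_re + code]))
        eb_day = pd.DataFrame(recs, columns=["person", "day", "r_0di"])

    fitted = prep.Xs @ beta_s
    for i in range(len(prep.person_ids)):
        sl = prep.rows[i]
        fitted[sl] += prep.Zs[sl] @ b[i, : prep.p_re]
        if prep.has_day:
            fitted[sl] += b[i, prep.p_re + prep.day_codes[i]]
    resid = pd.Series(prep.y - fitted, index=prep.index, name="resid")

    aic = 2 * k - 2 * loglik
    bic = k * float(np.log(prep.n)) - 2 * loglik
    return FitResult(
        spec=spec,
        fixed={c: float(v) for c, v in zip(prep.xcols, beta)},
        se={c: float(v) for c, v in zip(prep.xcols, se)},
        sds=sds,
        corrs=corrs,
        loglik=float(loglik),
        n_obs=prep.n,
        k_params=k,
        aic=float(aic),
        bic=float(bic),
        eb_person=eb_person,
        eb_day=eb_day,
        converged=converged,
        boundary=boundary,
        resid=resid,
        message=getattr(best, "message", ""),
    )


def lrt(full: FitResult, constrained: FitResult) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested fits on identical rows.

    Returns (chi2, df, p) with the naive chi-square reference (no boundary
    correction), chi2 floored at zero.  Identical parameter counts give
    df = 0 and p = 1 by convention.
    """
    if full.n_obs != constrained.n_obs:
        raise ValueError(
            f"LRT requires identical case sets: {full.n_obs} vs {constrained.n_obs}"
        )
    df = full.k_params - constrained.k_params
    if df < 0:
        raise ValueError("'full' model has fewer parameters than 'constrained'")
    chi2 = max(0.0, 2.0 * (full.loglik - constrained.loglik))
    p = 1.0 if df == 0 else float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def wald(fit_result: FitResult, term: str) -> tuple[float, float]:
    """Wald z-test of a fixed effect: z = estimate/SE, two-sided normal p."""
    if term not in fit_result.fixed:
        raise KeyError(f"no fixed effect {term!r} in this fit")
    se = fit_result.se.get(term, np.nan)
    if not np.isfinite(se) or se <= 0:
        raise ConvergenceError(f"standard error for {term!r} unavailable or degenerate")
    z = fit_result.fixed[term] / se
    return float(z), float(2.0 * stats.norm.sf(abs(z)))
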