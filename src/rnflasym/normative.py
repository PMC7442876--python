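"""Per-location heteroscedastic Gaussian normative modeling.

At each of the 768 scanning locations the interocular difference ``d`` of a
subject with age ``a`` and signed radius difference ``r`` is modeled as

    d ~ Normal(mu(a, r), sigma(a, r)^2)
    mu(a, r)        = beta_mu . x_mu(a, r)
    log sigma(a, r) = beta_logsigma . x_sigma(a, r)

where both linear predictors draw terms from the basis
``(1, a, a^2, a^3, r, r^2, r^3)`` in centered and scaled covariates.  Each
of the six non-intercept terms can enter or leave either predictor, giving
``2^12 = 4096`` candidate models per location; the model minimizing the
Akaike information criterion is selected independently at every location,
and the 768 selected models form a queryable normative atlas.

Fitting maximizes the exact Gaussian likelihood by alternating an exact
weighted least-squares update of the mean coefficients with a step-halved
Fisher-scoring update of the log-sigma coefficients (the classic RS
algorithm for distributional regression).  Both steps are monotone in the
log-likelihood, so the iteration is deterministic and stable.

A lighter screening pass (:func:`screen_covariates`) fits the 4 x 4 grid of
{none, age, abs rd, both} linear mean/variance models per location and
labels the AIC-best combination, mirroring the first-stage covariate scan.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

from .profiles import N_LOCATIONS, DifferenceProfile, angle_to_index
from .pointwise import stack_deltas

__all__ = [
    "TermMask",
    "FitResult",
    "LocationModel",
    "Standardization",
    "NormativeAtlas",
    "ScreeningMap",
    "fit_gaussian_ls",
    "enumerate_candidates",
    "select_location_model",
    "fit_atlas",
    "screen_covariates",
    "predict_quantile",
]

N_BASIS_TERMS = 6  # age^1..3, rd^1..3
_AIC_TIE_TOL = 1e-8
TERM_NAMES = ("age1", "age2", "age3", "rd1", "rd2", "rd3")


@dataclass(frozen=True)
class TermMask:
    """Active optional terms of the mean and log-sigma predictors.

    Each tuple holds six booleans for ``(age^1, age^2, age^3, rd^1, rd^2,
    rd^3)``; intercepts are always implicitly present in both predictors.
    """

    mean_terms: tuple[bool, ...]
    sigma_terms: tuple[bool, ...]

    def __post_init__(self):
        if len(self.mean_terms) != N_BASIS_TERMS or len(self.sigma_terms) != N_BASIS_TERMS:
            raise ValueError("term masks must have 6 entries each")

    @property
    def n_active(self) -> int:
        return sum(self.mean_terms) + sum(self.sigma_terms)

    @property
    def n_params(self) -> int:
        return 2 + self.n_active

    def to_dict(self) -> dict:
        return {
            "mean_terms": [bool(b) for b in self.mean_terms],
            "sigma_terms": [bool(b) for b in self.sigma_terms],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TermMask":
        return cls(tuple(d["mean_terms"]), tuple(d["sigma_terms"]))


def enumerate_candidates(
    degree: int = 3,
    mean_terms: tuple[int, ...] | None = None,
    sigma_terms: tuple[int, ...] | None = None,
) -> list[TermMask]:
    """All candidate term masks in lexicographic bit order.

    By default every subset of the six optional mean terms crossed with
    every subset of the six optional sigma terms: 4096 masks.  ``degree``
    truncates both polynomial bases (degree 1 keeps only the linear age and
    rd terms, 16 masks); alternatively explicit basis-term indices (0..5,
    ordered age^1..3, rd^1..3) can be allowed per predictor.

    Order: masks enumerate as binary counting over the concatenated
    (mean, sigma) bit vector with the first allowed bit most significant,
    i.e. lexicographic over boolean tuples; the all-off (intercept-only)
    mask comes first.
    """
    if mean_terms is None:
        mean_terms = tuple(p for p in range(degree)) + tuple(3 + p for p in range(degree))
    if sigma_terms is None:
        sigma_terms = tuple(p for p in range(degree)) + tuple(3 + p for p in range(degree))
    out = []
    for bits in itertools.product((False, True), repeat=len(mean_terms) + len(sigma_terms)):
        mean = [False] * N_BASIS_TERMS
        sigma = [False] * N_BASIS_TERMS
        for j, idx in enumerate(mean_terms):
            mean[idx] = bits[j]
        for j, idx in enumerate(sigma_terms):
            sigma[idx] = bits[len(mean_terms) + j]
        out.append(TermMask(tuple(mean), tuple(sigma)))
    return out


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting


@dataclass
class FitResult:
    beta_mu: np.ndarray
    beta_logsigma: np.ndarray
    loglik: float
    aic: float
    converged: bool
    n_iter: int

    @property
    def k(self) -> int:
        return len(self.beta_mu) + len(self.beta_logsigma)


_LOG2PI = float(np.log(2.0 * np.pi))


def _loglik(eta: np.ndarray, r: np.ndarray) -> float:
    # sum of Normal(mu, e^eta) log-densities with residuals r = y - mu
    return float(-0.5 * len(r) * _LOG2PI - eta.sum() - 0.5 * np.sum((r * np.exp(-eta)) ** 2))


def _fit_core(y, Xm, Xs, gamma0, max_iter, tol):
    """Monotone RS iteration; returns (beta, gamma, loglik, converged, iters)."""
    F = 2.0 * (Xs.T @ Xs)  # expected information of the log-sigma block
    cho = linalg.cho_factor(F, check_finite=False)
    gamma = gamma0.copy()
    eta = np.clip(Xs @ gamma, -40.0, 40.0)
    beta = np.zeros(Xm.shape[1])
    ll = -np.inf
    for it in range(1, max_iter + 1):
        # exact WLS update of the mean block given sigma
        w = np.exp(-2.0 * eta)
        Xw = Xm * w[:, None]
        A = Xm.T @ Xw
        b = Xw.T @ y
        try:
            beta = linalg.solve(A, b, assume_a="pos", check_finite=False)
        except linalg.LinAlgError:
            beta = np.linalg.lstsq(Xm, y, rcond=None)[0]
        r = y - Xm @ beta
        ll_mid = _loglik(eta, r)
        # Fisher-scoring update of the log-sigma block, step-halved to
        # preserve monotonicity
        u = (r * np.exp(-eta)) ** 2 - 1.0
        step = linalg.cho_solve(cho, Xs.T @ u, check_finite=False)
        t = 1.0
        for _ in range(30):
            gamma_try = gamma + t * step
            eta_try = np.clip(Xs @ gamma_try, -40.0, 40.0)
            ll_try = _loglik(eta_try, r)
            if ll_try >= ll_mid - 1e-13:
                break
            t *= 0.5
        else:
            gamma_try, eta_try, ll_try = gamma, eta, ll_mid
        gamma, eta = gamma_try, eta_try
        if abs(ll_try - ll) < tol and it > 1:
            return beta, gamma, ll_try, True, it
        ll = ll_try
    return beta, gamma, ll, False, max_iter


try:  # JIT-compiled twin of _fit_core; same algorithm, same tolerances
    from numba import njit as _njit

    @_njit(cache=True)
    def _fit_core_jit(y, Xm, Xs, gamma0, max_iter, tol):  # pragma: no cover
        n = y.shape[0]
        F = 2.0 * (Xs.T @ Xs)
        gamma = gamma0.copy()
        eta = np.minimum(np.maximum(Xs @ gamma, -40.0), 40.0)
        beta = np.zeros(Xm.shape[1])
        c0 = -0.5 * n * _LOG2PI
        ll = -np.inf
        for it in range(1, max_iter + 1):
            w = np.exp(-2.0 * eta)
            A = Xm.T @ (Xm * w.reshape(n, 1))
            b = Xm.T @ (w * y)
            beta = np.linalg.solve(A, b)
            r = y - Xm @ beta
            re = r * np.exp(-eta)
            ll_mid = c0 - eta.sum() - 0.5 * (re**2).sum()
            u = re**2 - 1.0
            step = np.linalg.solve(F, Xs.T @ u)
            t = 1.0
            accepted = False
            gamma_try, eta_try, ll_try = gamma, eta, ll_mid
            for _h in range(30):
                gamma_try = gamma + t * step
                eta_try = np.minimum(np.maximum(Xs @ gamma_try, -40.0), 40.0)
                re2 = r * np.exp(-eta_try)
                ll_try = c0 - eta_try.sum() - 0.5 * (re2**2).sum()
                if ll_try >= ll_mid - 1e-13:
                    accepted = True
                    break
                t *= 0.5
            if not accepted:
                gamma_try, eta_try, ll_try = gamma, eta, ll_mid
            gamma, eta = gamma_try, eta_try
            if it > 1 and abs(ll_try - ll) < tol:
                return beta, gamma, ll_try, True, it
            ll = ll_try
        return beta, gamma, ll, False, max_iter

    _HAVE_JIT = True
except ImportError:  # pragma: no cover
    _HAVE_JIT = False


def _run_core(y, Xm, Xs, gamma0, max_iter, tol):
    if _HAVE_JIT:
        try:
            return _fit_core_jit(
                np.ascontiguousarray(y),
                np.ascontiguousarray(Xm),
                np.ascontiguousarray(Xs),
                np.ascontiguousarray(gamma0),
                max_iter,
                tol,
            )
        except Exception:  # singular system etc. -> numpy path decides
            pass
    return _fit_core(y, Xm, Xs, gamma0, max_iter, tol)


def fit_gaussian_ls(
    y: np.ndarray,
    X_mu: np.ndarray,
    X_sigma: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> FitResult:
    """Maximum-likelihood Gaussian location-scale fit.

    ``mean = X_mu @ beta_mu`` and ``sigma = exp(X_sigma @ beta_logsigma)``;
    both design matrices must carry their own intercept column.  The fit is
    deterministic: ordinary-least-squares initialization, monotone
    alternating updates, and a single deterministically jittered restart if
    the first pass fails to converge.  ``aic = 2k - 2 loglik`` with ``k``
    the total number of coefficients.
    """
    y = np.asarray(y, dtype=float)
    X_mu = np.atleast_2d(np.asarray(X_mu, dtype=float))
    X_sigma = np.atleast_2d(np.asarray(X_sigma, dtype=float))
    n = len(y)
    if X_mu.shape[0] != n or X_sigma.shape[0] != n:
        raise ValueError("design matrices must have one row per observation")
    k = X_mu.shape[1] + X_sigma.shape[1]
    if n < k:
        raise ValueError(f"need n >= {k} observations for {k} parameters, got {n}")
    if np.all(y == y[0]):
        raise ValueError("y has zero variance; the Gaussian MLE is degenerate")

    try:
        beta0 = linalg.solve(X_mu.T @ X_mu, X_mu.T @ y, assume_a="pos", check_finite=False)
    except linalg.LinAlgError:
        beta0 = np.linalg.lstsq(X_mu, y, rcond=None)[0]
    resid = y - X_mu @ beta0
    mse = float(np.mean(resid**2))
    if mse < 1e-24:
        raise ValueError("mean model fits y exactly; the sigma MLE is degenerate")
    sd0 = np.sqrt(mse)
    if np.all(X_sigma[:, 0] == 1.0):
        gamma0 = np.zeros(X_sigma.shape[1])
        gamma0[0] = np.log(sd0)
    else:
        gamma0 = np.linalg.lstsq(X_sigma, np.full(n, np.log(sd0)), rcond=None)[0]

    beta, gamma, ll, converged, iters = _run_core(y, X_mu, X_sigma, gamma0, max_iter, tol)
    if not converged:
        jitter = 0.05 * np.where(np.arange(len(gamma0)) % 2 == 0, 1.0, -1.0)
        beta2, gamma2, ll2, conv2, it2 = _run_core(
            y, X_mu, X_sigma, gamma0 + jitter, max_iter, tol
        )
        if conv2 or ll2 > ll:
            beta, gamma, ll, converged, iters = beta2, gamma2, ll2, conv2, iters + it2
    aic = 2.0 * k - 2.0 * ll
    return FitResult(beta, gamma, ll, aic, converged, iters)


# ---------------------------------------------------------------------------
# Covariate standardization and basis construction


@dataclass(frozen=True)
class Standardization:
    """Centering/scaling constants and training ranges of the covariates."""

    age_center: float
    age_scale: float
    rd_center: float
    rd_scale: float
    age_min: float = -np.inf
    age_max: float = np.inf
    rd_min: float = -np.inf
    rd_max: float = np.inf

    def __post_init__(self):
        for name in ("age_center", "age_scale", "rd_center", "rd_scale"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.age_scale <= 0 or self.rd_scale <= 0:
            raise ValueError("standardization scales must be > 0")

    @classmethod
    def from_cohort(cls, ages: np.ndarray, rds: np.ndarray) -> "Standardization":
        ages = np.asarray(ages, dtype=float)
        rds = np.asarray(rds, dtype=float)
        return cls(
            age_center=float(ages.mean()),
            age_scale=float(ages.std()) or 1.0,
            rd_center=float(rds.mean()),
            rd_scale=float(rds.std()) or 1.0,
            age_min=float(ages.min()),
            age_max=float(ages.max()),
            rd_min=float(rds.min()),
            rd_max=float(rds.max()),
        )

    def transform(self, age, rd) -> tuple[np.ndarray, np.ndarray]:
        a = (np.asarray(age, dtype=float) - self.age_center) / self.age_scale
        r = (np.asarray(rd, dtype=float) - self.rd_center) / self.rd_scale
        return a, r

    def in_range(self, age, rd) -> bool:
        return bool(
            np.all((age >= self.age_min) & (age <= self.age_max))
            and np.all((rd >= self.rd_min) & (rd <= self.rd_max))
        )

    def to_dict(self) -> dict:
        return {
            "age_center": self.age_center,
            "age_scale": self.age_scale,
            "rd_center": self.rd_center,
            "rd_scale": self.rd_scale,
            "age_min": self.age_min,
            "age_max": self.age_max,
            "rd_min": self.rd_min,
            "rd_max": self.rd_max,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Standardization":
        return cls(**{k: float(v) for k, v in d.items()})


def full_basis(age_std: np.ndarray, rd_std: np.ndarray) -> np.ndarray:
    """Design basis ``[1, a, a^2, a^3, r, r^2, r^3]`` (n x 7)."""
    a = np.asarray(age_std, dtype=float)
    r = np.asarray(rd_std, dtype=float)
    one = np.ones_like(a)
    return np.column_stack([one, a, a * a, a**3, r, r * r, r**3])


def _design_columns(mask_half: tuple[bool, ...]) -> np.ndarray:
    return np.concatenate(([0], 1 + np.flatnonzero(mask_half)))


# ---------------------------------------------------------------------------
# Per-location selection


@dataclass
class LocationModel:
    """AIC-selected Gaussian location-scale model for one retinal location."""

    location: int
    mask: TermMask
    beta_mu: np.ndarray
    beta_logsigma: np.ndarray
    loglik: float
    aic: float
    converged: bool
    n: int
    n_nonconverged_candidates: int = 0
    fallback: bool = False  # intercept-only fallback (no candidate converged)

    def predict(self, age_std, rd_std) -> tuple[np.ndarray, np.ndarray]:
        basis = full_basis(np.atleast_1d(age_std), np.atleast_1d(rd_std))
        mu = basis[:, _design_columns(self.mask.mean_terms)] @ self.beta_mu
        eta = basis[:, _design_columns(self.mask.sigma_terms)] @ self.beta_logsigma
        return mu, np.exp(eta)

    def to_dict(self) -> dict:
        return {
            "location": self.location,
            **self.mask.to_dict(),
            "beta_mu": list(map(float, self.beta_mu)),
            "beta_logsigma": list(map(float, self.beta_logsigma)),
            "loglik": float(self.loglik),
            "aic": float(self.aic),
            "converged": bool(self.converged),
            "n": int(self.n),
            "n_nonconverged_candidates": int(self.n_nonconverged_candidates),
            "fallback": bool(self.fallback),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LocationModel":
        return cls(
            location=int(d["location"]),
            mask=TermMask.from_dict(d),
            beta_mu=np.asarray(d["beta_mu"], dtype=float),
            beta_logsigma=np.asarray(d["beta_logsigma"], dtype=float),
            loglik=float(d["loglik"]),
            aic=float(d["aic"]),
            converged=bool(d["converged"]),
            n=int(d["n"]),
            n_nonconverged_candidates=int(d.get("n_nonconverged_candidates", 0)),
            fallback=bool(d.get("fallback", False)),
        )


def select_location_model(
    y: np.ndarray,
    age_std: np.ndarray,
    rd_std: np.ndarray,
    candidates: list[TermMask] | None = None,
    location: int = 0,
) -> LocationModel:
    """Fit every candidate mask and return the converged fit of minimal AIC.

    Covariates must already be standardized with the atlas constants.  AIC
    ties (within 1e-8) break toward fewer parameters, then enumeration
    order.  Non-converged candidates are skipped and counted; if none
    converges a ``RuntimeError`` is raised.
    """
    if candidates is None:
        candidates = enumerate_candidates()
    y = np.asarray(y, dtype=float)
    basis = full_basis(age_std, rd_std)
    if y.shape[0] != basis.shape[0]:
        raise ValueError("y and covariates must have equal length")

    best = None
    best_mask = None
    n_noncon = 0
    for mask in candidates:
        Xm = basis[:, _design_columns(mask.mean_terms)]
        Xs = basis[:, _design_columns(mask.sigma_terms)]
        try:
            fit = fit_gaussian_ls(y, Xm, Xs)
        except (ValueError, linalg.LinAlgError):
            n_noncon += 1
            continue
        if not fit.converged:
            n_noncon += 1
            continue
        if best is None or fit.aic < best.aic - _AIC_TIE_TOL or (
            fit.aic <= best.aic + _AIC_TIE_TOL and fit.k < best.k
        ):
            best, best_mask = fit, mask
    if best is None:
        raise RuntimeError(f"no candidate converged at location {location}")
    return LocationModel(
        location=location,
        mask=best_mask,
        beta_mu=best.beta_mu,
        beta_logsigma=best.beta_logsigma,
        loglik=best.loglik,
        aic=best.aic,
        converged=True,
        n=len(y),
        n_nonconverged_candidates=n_noncon,
    )


# ---------------------------------------------------------------------------
# Atlas


_INTERCEPT_ONLY = TermMask((False,) * 6, (False,) * 6)
ATLAS_FORMAT_VERSION = "1.0"
CONVENTION_TAG = "TSNIT-768/OS-minus-OD"


@dataclass
class NormativeAtlas:
    """768 per-location normative models plus covariate standardization."""

    models: list[LocationModel]
    standardization: Standardization
    convention: str = CONVENTION_TAG
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.models) != N_LOCATIONS:
            raise ValueError(f"atlas must hold exactly {N_LOCATIONS} models")

    def predict_musigma(self, angle_deg: float, age: float, rd: float):
        """Normative mean and SD (um) at an angle for given covariates.

        The angle is mapped to the nearest grid location.  Covariates
        outside the training range trigger an extrapolation warning.
        """
        if not self.standardization.in_range(np.asarray(age), np.asarray(rd)):
            warnings.warn(
                "covariates outside the atlas training range; extrapolating",
                UserWarning,
                stacklevel=2,
            )
        model = self.models[angle_to_index(angle_deg)]
        a, r = self.standardization.transform(age, rd)
        mu, sigma = model.predict(a, r)
        return float(mu[0]), float(sigma[0])

    def predict_quantile(self, angle_deg: float, age: float, rd: float, p: float) -> float:
        if not 0.0 < p < 1.0:
            raise ValueError(f"p must lie in (0, 1), got {p!r}")
        mu, sigma = self.predict_musigma(angle_deg, age, rd)
        return mu + sigma * float(stats.norm.ppf(p))

    def profile_musigma(self, age: float, rd: float) -> tuple[np.ndarray, np.ndarray]:
        """(mu, sigma) arrays over all 768 locations for one covariate pair."""
        a, r = self.standardization.transform(age, rd)
        mus = np.empty(N_LOCATIONS)
        sigmas = np.empty(N_LOCATIONS)
        for i, model in enumerate(self.models):
            mu, sigma = model.predict(a, r)
            mus[i], sigmas[i] = mu[0], sigma[0]
        return mus, sigmas

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format_version": ATLAS_FORMAT_VERSION,
            "convention": self.convention,
            "standardization": self.standardization.to_dict(),
            "metadata": self.metadata,
            "models": [m.to_dict() for m in self.models],
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "NormativeAtlas":
        return cls(
            models=[LocationModel.from_dict(m) for m in d["models"]],
            standardization=Standardization.from_dict(d["standardization"]),
            convention=d.get("convention", CONVENTION_TAG),
            metadata=d.get("metadata", {}),
        )

    @classmethod
    def load(cls, path) -> "NormativeAtlas":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _intercept_only_model(y, basis, location) -> LocationModel:
    fit = fit_gaussian_ls(y, basis[:, :1], basis[:, :1])
    return LocationModel(
        location=location,
        mask=_INTERCEPT_ONLY,
        beta_mu=fit.beta_mu,
        beta_logsigma=fit.beta_logsigma,
        loglik=fit.loglik,
        aic=fit.aic,
        converged=fit.converged,
        n=len(y),
        fallback=True,
    )


def fit_atlas(
    diffs: list[DifferenceProfile],
    candidates: list[TermMask] | None = None,
    locations: list[int] | None = None,
    n_jobs: int = 1,
    metadata: dict | None = None,
) -> NormativeAtlas:
    """Fit the 768-location normative atlas on a QC-passed cohort.

    Standardization constants are computed from the cohort; each location is
    then model-selected independently (order-independent, parallelizable via
    joblib when ``n_jobs != 1``).  ``locations`` restricts full selection to
    a subset of locations, the remainder receiving intercept-only fits — the
    atlas always carries all 768 models.  Locations where no candidate
    converges fall back to the intercept-only fit and are flagged.
    """
    deltas = stack_deltas(diffs)
    n = deltas.shape[0]
    if n < 100:
        warnings.warn(f"atlas fitted on only {n} subjects; norms will be noisy", UserWarning)
    ages = np.array([d.age for d in diffs])
    rds = np.array([d.rd for d in diffs])
    std = Standardization.from_cohort(ages, rds)
    a, r = std.transform(ages, rds)
    basis = full_basis(a, r)
    if candidates is None:
        candidates = enumerate_candidates()
    selected = set(range(N_LOCATIONS)) if locations is None else set(locations)

    def _fit_one(i: int) -> LocationModel:
        y = deltas[:, i]
        if i not in selected:
            return _intercept_only_model(y, basis, i)
        try:
            return select_location_model(y, a, r, candidates, location=i)
        except (RuntimeError, ValueError):
            return _intercept_only_model(y, basis, i)

    if n_jobs != 1:
        from joblib import Parallel, delayed

        models = Parallel(n_jobs=n_jobs)(delayed(_fit_one)(i) for i in range(N_LOCATIONS))
    else:
        models = [_fit_one(i) for i in range(N_LOCATIONS)]
    meta = {"n_subjects": int(n), "n_candidates": len(candidates)}
    if metadata:
        meta.update(metadata)
    return NormativeAtlas(models=list(models), standardization=std, metadata=meta)


def predict_quantile(
    atlas: NormativeAtlas, angle_deg: float, age: float, rd: float, p: float
) -> float:
    """Normative quantile ``mu + sigma * z_p`` at a location (module-level
    convenience mirroring :meth:`NormativeAtlas.predict_quantile`)."""
    return atlas.predict_quantile(angle_deg, age, rd, p)


# ---------------------------------------------------------------------------
# Stage-1 screening


_SCREEN_LABELS = ("none", "age", "abs_rd", "both")


@dataclass
class ScreeningMap:
    """Per-location labels of which covariates the AIC prefers.

    Linear-terms-only scan with age and the absolute radius difference as
    regressors: for each location the 4 x 4 grid of {none, age, abs_rd,
    both} mean/variance models is fitted and the AIC-best combination
    recorded.
    """

    mean_effect: list[str]
    var_effect: list[str]

    def __post_init__(self):
        if len(self.mean_effect) != N_LOCATIONS or len(self.var_effect) != N_LOCATIONS:
            raise ValueError("screening map must cover all 768 locations")

    def counts(self) -> dict:
        return {
            "mean": {lab: self.mean_effect.count(lab) for lab in _SCREEN_LABELS},
            "var": {lab: self.var_effect.count(lab) for lab in _SCREEN_LABELS},
        }


def screen_covariates(diffs: list[DifferenceProfile]) -> ScreeningMap:
    """First-stage linear screen of age and absolute radius difference."""
    deltas = stack_deltas(diffs)
    ages = np.array([d.age for d in diffs])
    abs_rds = np.array([d.abs_rd for d in diffs])
    a = (ages - ages.mean()) / (ages.std() or 1.0)
    r = (abs_rds - abs_rds.mean()) / (abs_rds.std() or 1.0)
    one = np.ones_like(a)
    designs = {
        "none": one[:, None],
        "age": np.column_stack([one, a]),
        "abs_rd": np.column_stack([one, r]),
        "both": np.column_stack([one, a, r]),
    }
    mean_lab, var_lab = [], []
    for i in range(N_LOCATIONS):
        y = deltas[:, i]
        best = (np.inf, None, None)
        for ml in _SCREEN_LABELS:
            for vl in _SCREEN_LABELS:
                try:
                    fit = fit_gaussian_ls(y, designs[ml], designs[vl])
                except (ValueError, linalg.LinAlgError):
                    continue
                if fit.converged and fit.aic < best[0] - _AIC_TIE_TOL:
                    best = (fit.aic, ml, vl)
        if best[1] is None:
            best = (np.nan, "none", "none")
        mean_lab.append(best[1])
        var_lab.append(best[2])
    return ScreeningMap(mean_lab, var_lab)
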