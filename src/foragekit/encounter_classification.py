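"""Behavioral-state classification of patch encounters.

Two per-encounter posteriors are estimated: the probability that an
encounter was an exploitation, ``p(y=1|z)``, from a regularized
two-component Gaussian mixture on (log duration, log mean on-patch
velocity); and the probability that the patch was sensed, ``p(v=1|w)``,
from a replicate-averaged semi-supervised quadratic discriminant on three
velocity features.  A smoothed-bootstrap critical-bandwidth test checks
bimodality before mixture fitting, and encounters whose onset was not
recorded get their sensing posterior by marginalizing the discriminant
over the censored features.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.linalg import solve_triangular
from sklearn.mixture import GaussianMixture
from sklearn.model_selection import KFold

from .errors import (ConfigurationError, DegenerateDataError,
                     InsufficientDataError, NumericalError)

__all__ = [
    "SilvermanResult",
    "ExploitPosterior",
    "SensingPosterior",
    "QDAModel",
    "pc1_project",
    "rot_bandwidth",
    "critical_bandwidth",
    "silverman_test",
    "fit_exploit_gmm",
    "qda_fit_predict",
    "classify_sensing",
    "marginalize_censored",
    "exclude_low_sensing",
    "compose_three_way",
    "kde_mode_count",
]

KDE_GRID_POINTS = 1024


# ---------------------------------------------------------------------------
# PC1 projection and KDE machinery
# ---------------------------------------------------------------------------

def pc1_project(z_matrix: np.ndarray) -> np.ndarray:
    """Project mean-centered rows onto the first principal component.

    The sign is fixed so the loading on the first column (log duration)
    is positive.
    """
    z = np.asarray(z_matrix, dtype=float)
    if z.ndim != 2 or z.shape[0] < 3:
        raise DegenerateDataError("need a 2-D matrix with >= 3 rows")
    zc = z - z.mean(axis=0)
    u, s, vt = np.linalg.svd(zc, full_matrices=False)
    if s[0] <= 0:
        raise DegenerateDataError("rank-0 data: all rows identical")
    v1 = vt[0]
    if v1[0] < 0:
        v1 = -v1
    return zc @ v1


def _kde_on_grid(data: np.ndarray, h: float,
                 grid_points: int = KDE_GRID_POINTS) -> tuple[np.ndarray, np.ndarray]:
    grid = np.linspace(data.min() - 3 * h, data.max() + 3 * h, grid_points)
    u = (grid[:, None] - data[None, :]) / h
    dens = np.exp(-0.5 * u * u).sum(axis=1) / (data.size * h * math.sqrt(2 * math.pi))
    return grid, dens


def kde_mode_count(data: np.ndarray, h: float,
                   grid_points: int = KDE_GRID_POINTS) -> int:
    """Number of strict interior local maxima of the Gaussian KDE on a grid."""
    _, dens = _kde_on_grid(np.asarray(data, dtype=float), h, grid_points)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] > dens[2:])
    return int(interior.sum())


def rot_bandwidth(scores: np.ndarray, d: int = 1) -> float:
    """Rule-of-thumb bandwidth sigma * (4 / ((d+2) n))^(1/(d+4))."""
    x = np.asarray(scores, dtype=float)
    if x.size < 2:
        raise DegenerateDataError("need n >= 2")
    sigma = float(np.std(x, ddof=1))
    if sigma == 0:
        raise DegenerateDataError("zero variance")
    n = x.size
    return sigma * (4.0 / ((d + 2) * n)) ** (1.0 / (d + 4))


def critical_bandwidth(scores: np.ndarray, j: int = 1,
                       rel_tol: float = 1e-4,
                       grid_points: int = KDE_GRID_POINTS,
                       max_iter: int = 200) -> float:
    """Smallest Gaussian-KDE bandwidth at which the sample has <= j modes.

    Bisection between a bandwidth with more than j modes and one with at
    most j; mode counts are strict local maxima on a fixed fine grid.
    """
    x = np.asarray(scores, dtype=float)
    if x.size < 2 or np.ptp(x) == 0:
        raise DegenerateDataError("zero-spread input has no critical bandwidth")
    h_hi = rot_bandwidth(x)
    it = 0
    while kde_mode_count(x, h_hi, grid_points) > j:
        h_hi *= 2.0
        it += 1
        if it > 60:
            raise NumericalError("no unimodal bandwidth found below 2^60 * ROT")
    h_lo = h_hi / 2.0
    it = 0
    while kde_mode_count(x, h_lo, grid_points) <= j:
        h_hi = h_lo
        h_lo /= 2.0
        it += 1
        if it > 60:
            # <= j modes at arbitrarily small bandwidth (e.g. j >= n)
            return h_lo
    it = 0
    while (h_hi - h_lo) / h_hi > rel_tol:
        mid = 0.5 * (h_hi + h_lo)
        if kde_mode_count(x, mid, grid_points) <= j:
            h_hi = mid
        else:
            h_lo = mid
        it += 1
        if it > max_iter:
            raise NumericalError(
                f"critical bandwidth bisection did not converge: "
                f"[{h_lo:.6g}, {h_hi:.6g}] after {max_iter} iterations")
    return h_hi


@dataclass(frozen=True)
class SilvermanResult:
    critical_bandwidth: float
    rot_bandwidth: float
    p_value: float
    n_bootstrap: int
    modes_tested: int
    n_exceed: int
    method: str


def silverman_test(scores: np.ndarray, j: int = 1, B: int = 2000, *,
                   seed: int, method: str = "critical_bandwidth",
                   grid_points: int = KDE_GRID_POINTS) -> SilvermanResult:
    """Critical-bandwidth bimodality test with smoothed bootstrap.

    Each replicate resamples the scores with replacement and adds
    rescaled Gaussian noise ``(z* + h* eps) / sqrt(1 + (h*/sigma)^2)``.
    A replicate exceeds the observed statistic when its critical
    bandwidth is at least ``h*`` - equivalently (and by default computed
    as, since it avoids a bisection per replicate) when its KDE at
    bandwidth ``h*`` still has more than ``j`` modes.  Set
    ``method='explicit'`` to recompute every replicate's critical
    bandwidth instead.  p = (exceed + 1) / (B + 1).
    """
    if method not in ("critical_bandwidth", "explicit"):
        raise ConfigurationError(f"unknown method: {method!r}")
    if B < 100:
        warnings.warn("B < 100 gives coarse p-value resolution", stacklevel=2)
    x = np.asarray(scores, dtype=float)
    rng = np.random.default_rng(seed)
    h_star = critical_bandwidth(x, j, grid_points=grid_points)
    h_rot = rot_bandwidth(x)
    sigma = float(np.std(x, ddof=1))
    shrink = math.sqrt(1.0 + (h_star / sigma) ** 2)
    n = x.size
    exceed = 0
    for _ in range(B):
        z = x[rng.integers(0, n, n)]
        zt = (z + h_star * rng.standard_normal(n)) / shrink
        if method == "explicit":
            if np.ptp(zt) == 0:
                continue
            if critical_bandwidth(zt, j, grid_points=grid_points) >= h_star:
                exceed += 1
        else:
            if kde_mode_count(zt, h_star, grid_points) > j:
                exceed += 1
    p = (exceed + 1) / (B + 1)
    return SilvermanResult(h_star, h_rot, p, B, j, exceed, method)


# ---------------------------------------------------------------------------
# exploit / explore GMM
# ---------------------------------------------------------------------------

@dataclass
class ExploitPosterior:
    posteriors: np.ndarray            # p(y=1 | z) per encounter
    means: np.ndarray                 # (2, d), row 1 = exploit component
    covariances: np.ndarray
    weights: np.ndarray
    alpha: float
    posterior_variance: float
    cv_table: pd.DataFrame | None = None


def _posterior_exploit(gmm: GaussianMixture, z: np.ndarray) -> np.ndarray:
    # exploit component = larger mean log-duration (column 0)
    comp = int(np.argmax(gmm.means_[:, 0]))
    return gmm.predict_proba(z)[:, comp]


def fit_exploit_gmm(z_matrix: np.ndarray,
                    alpha_grid: Sequence[float] = (0.005, 0.01, 0.025, 0.05, 0.1),
                    n_folds: int = 5, seed: int = 0) -> ExploitPosterior:
    """Two-component GMM on (log duration, log velocity) with the diagonal
    regularization ``alpha`` chosen to minimize held-out posterior
    variance ``sum p (1 - p)``; the exploit component is the one with the
    larger mean log duration."""
    z = np.asarray(z_matrix, dtype=float)
    if z.ndim != 2 or z.shape[0] < 10:
        raise InsufficientDataError("need >= 10 encounters for the mixture")
    alphas = [float(a) for a in alpha_grid]
    if not alphas or any(a <= 0 for a in alphas):
        raise ConfigurationError("alpha_grid must contain positive values")

    rng = np.random.default_rng(seed)
    cv_rows = []
    if len(alphas) > 1:
        folds = list(KFold(n_folds, shuffle=True,
                           random_state=int(rng.integers(2**31))).split(z))
        for a in alphas:
            score = 0.0
            for tr, te in folds:
                gmm = _fit_gmm(z[tr], a, int(rng.integers(2**31)))
                p = _posterior_exploit(gmm, z[te])
                score += float(np.sum(p * (1.0 - p)))
            cv_rows.append({"alpha": a, "heldout_posterior_variance": score})
        cv = pd.DataFrame(cv_rows)
        best = float(cv.loc[cv["heldout_posterior_variance"].idxmin(), "alpha"])
    else:
        cv = None
        best = alphas[0]

    gmm = _fit_gmm(z, best, int(rng.integers(2**31)))
    p = _posterior_exploit(gmm, z)
    order = np.argsort(gmm.means_[:, 0])   # row 1 = exploit
    return ExploitPosterior(
        posteriors=p, means=gmm.means_[order],
        covariances=gmm.covariances_[order], weights=gmm.weights_[order],
        alpha=best, posterior_variance=float(np.sum(p * (1.0 - p))),
        cv_table=cv)


def _fit_gmm(z: np.ndarray, alpha: float, seed: int) -> GaussianMixture:
    gmm = GaussianMixture(n_components=2, covariance_type="full",
                          reg_covar=alpha, n_init=10,
                          init_params="k-means++", tol=1e-8, max_iter=500,
                          random_state=seed).fit(z)
    if not gmm.converged_:
        raise NumericalError("EM did not converge across restarts")
    return gmm


# ---------------------------------------------------------------------------
# soft-weighted QDA
# ---------------------------------------------------------------------------

@dataclass
class QDAModel:
    """Gaussian class-conditional classifier with soft-weighted moments."""

    means: np.ndarray        # (2, d)
    covariances: np.ndarray  # (2, d, d)
    priors: np.ndarray       # (2,)
    _chol: np.ndarray = field(init=False, repr=False)
    _logdet: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        chol = np.stack([np.linalg.cholesky(c) for c in self.covariances])
        self._chol = chol
        self._logdet = 2.0 * np.log(
            np.stack([np.diag(c) for c in chol])).sum(axis=1)

    def log_density(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        d = X.shape[1]
        out = np.empty((X.shape[0], 2))
        for c in range(2):
            diff = X - self.means[c]
            y = solve_triangular(self._chol[c], diff.T, lower=True).T
            maha = np.sum(y * y, axis=1)
            out[:, c] = -0.5 * (maha + self._logdet[c] + d * math.log(2 * math.pi))
        return out

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """p(class 1 | x)."""
        logd = self.log_density(X) + np.log(self.priors)[None, :]
        m = logd.max(axis=1, keepdims=True)
        w = np.exp(logd - m)
        return w[:, 1] / w.sum(axis=1)


def qda_fit_predict(features: np.ndarray, labels_soft: np.ndarray,
                    ridge: float = 1e-9) -> QDAModel:
    """Fit QDA with soft class weights; ``labels_soft`` is p(class 1).

    Class moments are weighted: weighted means, weighted unbiased
    covariances (denominator sum(w) - 1 so that 0/1 weights reproduce
    textbook QDA), priors proportional to total class weight.  A singular
    weighted covariance is ridge-regularized with a warning.
    """
    X = np.asarray(features, dtype=float)
    q = np.asarray(labels_soft, dtype=float)
    if X.ndim != 2 or X.shape[0] != q.size:
        raise InsufficientDataError("features and labels must align")
    d = X.shape[1]
    W = np.column_stack([1.0 - q, q])
    totals = W.sum(axis=0)
    if np.any(totals < d + 1):
        raise InsufficientDataError(
            f"each class needs total soft weight >= {d + 1}; got {totals}")
    means = np.empty((2, d))
    covs = np.empty((2, d, d))
    for c in range(2):
        w = W[:, c]
        mu = (w[:, None] * X).sum(axis=0) / totals[c]
        diff = X - mu
        cov = (w[:, None, None] * (diff[:, :, None] * diff[:, None, :])
               ).sum(axis=0) / (totals[c] - 1.0)
        means[c] = mu
        covs[c] = cov
    priors = totals / totals.sum()
    for c in range(2):
        try:
            np.linalg.cholesky(covs[c])
        except np.linalg.LinAlgError:
            bump = max(ridge, 1e-8) * (np.trace(covs[c]) / d + 1.0)
            warnings.warn(f"singular class-{c} covariance; adding ridge {bump:g}",
                          stacklevel=2)
            covs[c] = covs[c] + bump * np.eye(d)
    return QDAModel(means, covs, priors)


# ---------------------------------------------------------------------------
# semi-supervised sensing classification
# ---------------------------------------------------------------------------

@dataclass
class SensingPosterior:
    p_sense: np.ndarray                # replicate-averaged p(v=1|w) per row
    marginalized: np.ndarray           # bool per row
    replicate_models: list             # QDAModel per replicate
    n_replicates: int
    quality: dict = field(default_factory=dict)


def _self_train_qda(W: np.ndarray, labeled_mask: np.ndarray,
                    labels: np.ndarray, tol: float = 1e-6,
                    max_iter: int = 100) -> QDAModel:
    """Soft self-training: unlabeled rows enter each refit with weight
    equal to their current posterior; stop when total posterior variance
    moves by less than ``tol``."""
    q = np.where(labeled_mask, labels, 0.5).astype(float)
    unl = ~labeled_mask
    prev_var = np.inf
    model = None
    for _ in range(max_iter):
        model = qda_fit_predict(W, q)
        if not np.any(unl):
            break
        p = model.predict_proba(W[unl])
        q[unl] = p
        var = float(np.sum(p * (1.0 - p)))
        if abs(prev_var - var) < tol:
            break
        prev_var = var
    assert model is not None
    return model


def classify_sensing(encounters: pd.DataFrame, exploit_posteriors: np.ndarray,
                     n_replicates: int = 1000, *, seed: int,
                     marginalize: bool = True,
                     feature_cols: Sequence[str] = ("s_k", "t_k", "u_k"),
                     ) -> SensingPosterior:
    """Replicate-averaged semi-supervised QDA sensing posterior.

    Density-0 encounters are fixed negatives; per replicate, positives
    are drawn as Bernoulli(p(y=1|z)) among positive-density encounters,
    the self-training QDA is run, and all uncensored encounters are
    scored.  Start-censored encounters (biased deceleration features) are
    excluded from fitting and, when ``marginalize`` is set, receive
    posteriors marginalized over (t_k, u_k) given s_k.
    """
    df = encounters.reset_index(drop=True)
    W = df.loc[:, list(feature_cols)].to_numpy(dtype=float)
    p_y = np.asarray(exploit_posteriors, dtype=float)
    if len(df) != p_y.size:
        raise InsufficientDataError("exploit posteriors must align with encounters")
    neg = (df["density"].to_numpy() == 0)
    censored = df["start_censored"].to_numpy(dtype=bool) if "start_censored" in df \
        else np.zeros(len(df), dtype=bool)
    if not neg.any():
        raise InsufficientDataError(
            "no density-0 encounters: cannot seed negative labels")
    if float(p_y[~neg].sum()) == 0.0:
        raise InsufficientDataError(
            "all exploit posteriors are 0: no positive labels can be drawn")

    usable = ~censored
    rng = np.random.default_rng(seed)
    acc = np.zeros(len(df))
    models: list[QDAModel] = []
    n_ok = 0
    for _ in range(n_replicates):
        draw = rng.uniform(size=len(df)) < p_y
        pos = draw & ~neg & usable
        if not pos.any():
            continue
        labeled = (pos | neg) & usable
        labels = pos.astype(float)
        try:
            model = _self_train_qda(W[usable], labeled[usable], labels[usable])
        except InsufficientDataError:
            continue
        acc[usable] += model.predict_proba(W[usable])
        models.append(model)
        n_ok += 1
    if n_ok == 0:
        raise InsufficientDataError("no replicate produced positive labels")
    p_sense = acc / n_ok
    p_sense[~usable] = np.nan

    marg_flags = np.zeros(len(df), dtype=bool)
    if marginalize and censored.any():
        def posterior_fn(pts: np.ndarray) -> np.ndarray:
            return np.mean([m.predict_proba(pts) for m in models], axis=0)
        W_ok = W[usable]
        for i in np.nonzero(censored)[0]:
            p_sense[i] = marginalize_censored(posterior_fn, W_ok, W[i, 0])
            marg_flags[i] = True

    quality = {
        "false_positive_rate_density0": float(np.nanmean(p_sense[neg & usable] > 0.5))
        if (neg & usable).any() else float("nan"),
        "n_replicates_used": n_ok,
    }
    return SensingPosterior(p_sense, marg_flags, models, n_ok, quality)


def marginalize_censored(posterior_fn: Callable[[np.ndarray], np.ndarray],
                         uncensored_features: np.ndarray, s_k: float,
                         atol: float = 1e-4) -> float:
    """Marginal sensing probability p(v=1|s) for a censored encounter.

    Numerically integrates the posterior against a kernel estimate of
    p(t, u | s) built from uncensored (s, t, u) rows: product Gaussian
    kernels with rule-of-thumb bandwidths, conditioned by weighting each
    kernel by its s-distance to ``s_k``.  Degenerate (zero-bandwidth)
    dimensions collapse to point masses.  Result clipped to [0, 1].
    """
    F = np.asarray(uncensored_features, dtype=float)
    if F.ndim != 2 or F.shape[1] != 3 or F.shape[0] < 2:
        raise InsufficientDataError("need uncensored (s, t, u) rows")
    n = F.shape[0]
    sds = F.std(axis=0, ddof=1)
    factor = (4.0 / ((3 + 2) * n)) ** (1.0 / (3 + 4))
    hs, ht, hu = sds * factor

    if hs > 0:
        logw = -0.5 * ((s_k - F[:, 0]) / hs) ** 2
        logw -= logw.max()
        w = np.exp(logw)
    else:
        w = np.ones(n)
    if w.sum() < 1e-12 * n:
        warnings.warn("no uncensored encounters near s_k; "
                      "falling back to the unconditional joint", stacklevel=2)
        w = np.ones(n)
    w = w / w.sum()

    def post(t: float, u: float) -> float:
        return float(posterior_fn(np.array([[s_k, t, u]]))[0])

    tiny = 1e-12
    if ht < tiny and hu < tiny:
        vals = posterior_fn(np.column_stack(
            [np.full(n, s_k), F[:, 1], F[:, 2]]))
        return float(np.clip(np.dot(w, vals), 0.0, 1.0))

    t_lo, t_hi = F[:, 1].min() - 5 * ht, F[:, 1].max() + 5 * ht
    u_lo, u_hi = F[:, 2].min() - 5 * hu, F[:, 2].max() + 5 * hu

    if ht < tiny or hu < tiny:
        # one censored dimension is a point mass: 1-D quadrature
        if ht < tiny:
            def integrand(u: float) -> float:
                dens = np.exp(-0.5 * ((u - F[:, 2]) / hu) ** 2) / (
                    hu * math.sqrt(2 * math.pi))
                return float(np.dot(w, dens * np.array(
                    [post(ti, u) for ti in F[:, 1]])))
            val, _ = integrate.quad(integrand, u_lo, u_hi, epsabs=atol)
        else:
            def integrand(t: float) -> float:
                dens = np.exp(-0.5 * ((t - F[:, 1]) / ht) ** 2) / (
                    ht * math.sqrt(2 * math.pi))
                return float(np.dot(w, dens * np.array(
                    [post(t, ui) for ui in F[:, 2]])))
            val, _ = integrate.quad(integrand, t_lo, t_hi, epsabs=atol)
        return float(np.clip(val, 0.0, 1.0))

    def integrand(u: float, t: float) -> float:
        dens = (np.exp(-0.5 * ((t - F[:, 1]) / ht) ** 2) *
                np.exp(-0.5 * ((u - F[:, 2]) / hu) ** 2))
        dens /= 2 * math.pi * ht * hu
        return post(t, u) * float(np.dot(w, dens))

    val, _ = integrate.dblquad(integrand, t_lo, t_hi, u_lo, u_hi,
                               epsabs=atol, epsrel=1e-3)
    return float(np.clip(val, 0.0, 1.0))


def exclude_low_sensing(encounters: pd.DataFrame, p_sense: np.ndarray,
                        threshold: float = 0.05) -> pd.DataFrame:
    """Drop near-miss encounters: midpoint never entered AND p(sense) < threshold."""
    entered = encounters["midpoint_entered"].to_numpy(dtype=bool)
    drop = (~entered) & (np.asarray(p_sense) < threshold)
    return encounters.loc[~drop].reset_index(drop=True)


def compose_three_way(p_sense: np.ndarray, p_exploit: np.ndarray) -> pd.DataFrame:
    """Search / sample / exploit probabilities from the two posteriors."""
    ps = np.asarray(p_sense, dtype=float)
    pe = np.asarray(p_exploit, dtype=float)
    return pd.DataFrame({
        "p_search": 1.0 - ps,
        "p_sample": ps * (1.0 - pe),
        "p_exploit": ps * pe,
    })
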