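"""Soft-label logistic model of the per-encounter exploit decision.

The response is a classifier posterior q_k in [0, 1] rather than a binary
outcome; maximizing sum q ln p + (1 - q) ln(1 - p) with
p = logistic(beta . x) is equivalent to minimizing the per-encounter KL
divergence from the posterior to the model probability.  Covariates are
the log relative density of the current patch (rho_k), hours off food
since the last exploitation (tau_s), the log densities of the previous
encounter (rho_h) and of the last exploited patch (rho_e), and optionally
hours since transfer (tau_t).  Inference combines probabilistic encounter
inclusion (Bernoulli draws from the sensing posterior, with covariates
rebuilt on the retained sequence) with a hierarchical bootstrap over
worms.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import (ConfigurationError, FittingError, InputDataError,
                     InsufficientDataError, SeparationError)

__all__ = [
    "COVARIATE_COLUMNS",
    "GLMFit",
    "BootstrapEnsemble",
    "StrainComparison",
    "build_covariates",
    "encounter_sample",
    "worm_bootstrap",
    "fit_soft_logistic",
    "soft_log_likelihood",
    "bic",
    "model_select",
    "bootstrap_ensemble",
    "shuffle_null",
    "coefficient_test",
    "fit_ridge",
    "cv_lambda",
    "strain_compare",
    "simulate_first_exploit",
    "predict_surface",
    "compare_likelihood",
]

COVARIATE_COLUMNS = ["rho_k", "tau_s", "rho_h", "rho_e"]
FULL_SPEC = ("rho_k", "tau_s", "rho_h", "rho_e")


def _logistic(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta, dtype=float)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


# ---------------------------------------------------------------------------
# covariate construction and resampling
# ---------------------------------------------------------------------------

def build_covariates(encounters: pd.DataFrame, acclimation_density: float,
                     include_tau_t: bool = False,
                     on_zero_density: str = "drop",
                     pseudo_density: float | None = None,
                     realized: str = "threshold",
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Sequential covariates per worm from a time-ordered encounter table.

    Expects columns worm_id, entry_s, exit_s, density, q (soft exploit
    label) and optionally p_sense.  Per worm, rho_k = ln density; rho_h is
    the previous encounter's log density (initialized at the acclimation
    log density); rho_e is the last realized-exploit log density (same
    initialization); tau_s is hours spent off patch since the last
    realized exploitation (first encounter: total time elapsed off
    patch); tau_t is hours since recording start.  A realized exploit is
    q >= 0.5 by default, or a Bernoulli(q) draw when
    ``realized='bernoulli'`` (requires ``rng``).

    Density-0 rows are dropped by default (they only seed the sensing
    classifier's negatives); ``on_zero_density`` may instead be
    ``'pseudo'`` (replace 0 by ``pseudo_density``) or ``'error'``.
    """
    if acclimation_density <= 0:
        raise InputDataError("acclimation_density must be > 0")
    if realized not in ("threshold", "bernoulli"):
        raise ConfigurationError(f"unknown realized mode: {realized!r}")
    if realized == "bernoulli" and rng is None:
        raise ConfigurationError("realized='bernoulli' requires an rng")
    df = encounters.copy()
    dens = df["density"].to_numpy(dtype=float)
    if np.any(dens <= 0):
        if on_zero_density == "drop":
            df = df.loc[dens > 0]
        elif on_zero_density == "pseudo":
            if pseudo_density is None or pseudo_density <= 0:
                raise InputDataError(
                    "on_zero_density='pseudo' requires a positive pseudo_density")
            df = df.copy()
            df.loc[df["density"] <= 0, "density"] = pseudo_density
        else:
            raise InputDataError("non-positive density in encounter table")

    ln_accl = math.log(acclimation_density)
    out_rows = []
    for worm, grp in df.groupby("worm_id", sort=True):
        grp = grp.sort_values("entry_s")
        rho_h = ln_accl
        rho_e = ln_accl
        off_accum_s = 0.0
        prev_exit = 0.0
        for idx, (_, row) in enumerate(grp.iterrows()):
            off_accum_s += max(row["entry_s"] - prev_exit, 0.0)
            rec = dict(row)
            rec.update(worm_id=worm, encounter=idx,
                       rho_k=math.log(row["density"]),
                       tau_s=off_accum_s / 3600.0,
                       rho_h=rho_h, rho_e=rho_e)
            if include_tau_t:
                rec["tau_t"] = row["entry_s"] / 3600.0
            out_rows.append(rec)
            q = float(row["q"])
            exploited = (q >= 0.5 if realized == "threshold"
                         else bool(rng.uniform() < q))
            rho_h = math.log(row["density"])
            if exploited:
                rho_e = rho_h
                off_accum_s = 0.0
            prev_exit = row["exit_s"]
    return pd.DataFrame(out_rows).reset_index(drop=True)


def encounter_sample(encounters: pd.DataFrame, acclimation_density: float,
                     n_sets: int = 100, *, seed: int, rebuild: bool = True,
                     **build_kwargs) -> list[pd.DataFrame]:
    """Probabilistic inclusion of sensed encounters, n_sets replicates.

    Per replicate, each encounter is retained with probability
    ``p_sense``; covariates are rebuilt on the retained sequence so that
    time spent in dropped (non-responding) encounters counts as off-patch
    search time.  ``rebuild=False`` keeps the covariates already stored
    on the table (only sensible when they were built consistently, e.g.
    for covariate-level benchmarks with p_sense = 1).
    """
    if "p_sense" not in encounters:
        raise InputDataError("encounter table lacks a p_sense column")
    rng = np.random.default_rng(seed)
    ps = encounters["p_sense"].to_numpy(dtype=float)
    out = []
    for _ in range(n_sets):
        keep = rng.uniform(size=len(encounters)) < ps
        sub = encounters.loc[keep]
        if len(sub) == 0 or not rebuild:
            out.append(sub.copy())
            continue
        out.append(build_covariates(sub, acclimation_density, **build_kwargs))
    return out


def worm_bootstrap(dataset: pd.DataFrame, n_sets: int = 500, *,
                   seed: int) -> list[pd.DataFrame]:
    """Hierarchical bootstrap: resample whole worms with replacement.

    Each replicate samples the original number of worms; a worm drawn
    twice contributes its rows twice (tagged with a fresh boot_worm id).
    """
    worms = np.array(sorted(dataset["worm_id"].unique()))
    if worms.size < 2:
        warnings.warn("fewer than 2 worms: bootstrap replicates are degenerate",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    base = dataset.reset_index(drop=True)
    row_idx = {w: np.asarray(g, dtype=np.intp)
               for w, g in base.groupby("worm_id").indices.items()}
    out = []
    for _ in range(n_sets):
        picks = rng.choice(worms, size=worms.size, replace=True)
        chunks = [row_idx[w] for w in picks]
        rep = base.iloc[np.concatenate(chunks)].reset_index(drop=True)
        rep["boot_worm"] = np.repeat(np.arange(worms.size),
                                     [c.size for c in chunks])
        out.append(rep)
    return out


# ---------------------------------------------------------------------------
# soft-label logistic fitting
# ---------------------------------------------------------------------------

@dataclass
class GLMFit:
    beta: np.ndarray                     # original scale, intercept first
    spec: tuple[str, ...]
    log_likelihood: float
    n: int
    lambda_: float = 0.0
    converged: bool = True
    names: tuple[str, ...] = field(default_factory=tuple)

    def coef(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return X @ self.beta


def _design(dataset: pd.DataFrame, spec: Sequence[str]) -> tuple[np.ndarray, np.ndarray, tuple]:
    missing = [c for c in spec if c not in dataset.columns]
    if missing:
        raise InputDataError(f"dataset lacks covariates: {missing}")
    X = np.column_stack([np.ones(len(dataset))] +
                        [dataset[c].to_numpy(dtype=float) for c in spec])
    q = dataset["q"].to_numpy(dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise InputDataError("soft labels must lie in [0, 1]")
    return X, q, ("intercept", *spec)


def soft_log_likelihood(beta: np.ndarray, X: np.ndarray, q: np.ndarray) -> float:
    """sum q ln p + (1-q) ln(1-p) at p = logistic(X beta)."""
    eta = X @ beta
    # ln p = -log1p(exp(-eta)); ln(1-p) = -eta - log1p(exp(-eta))
    sp = np.logaddexp(0.0, -eta)
    return float(np.sum(-q * sp + (1.0 - q) * (-eta - sp)))


def _newton_soft(X: np.ndarray, q: np.ndarray, lam: float = 0.0,
                 tol: float = 1e-8, max_iter: int = 100
                 ) -> tuple[np.ndarray, bool]:
    """Damped Newton on the standardized design; lam penalizes non-intercept
    coefficients as lam * ||beta||^2 (subtracted from the log-likelihood)."""
    n, p = X.shape
    pen = np.ones(p)
    pen[0] = 0.0
    beta = np.zeros(p)

    def obj(b):
        return soft_log_likelihood(b, X, q) - lam * float(np.sum(pen * b * b))

    f = obj(beta)
    for _ in range(max_iter):
        eta = X @ beta
        mu = _logistic(eta)
        grad = X.T @ (q - mu) - 2.0 * lam * pen * beta
        if np.max(np.abs(grad)) < tol:
            return beta, True
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        H = (X * w[:, None]).T @ X + 2.0 * lam * np.diag(pen)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        t = 1.0
        for _ in range(50):
            cand = beta + t * step
            fc = obj(cand)
            if fc >= f - 1e-12:
                beta, f = cand, fc
                break
            t *= 0.5
        else:
            break
    eta = X @ beta
    mu = _logistic(eta)
    grad = X.T @ (q - mu) - 2.0 * lam * pen * beta
    return beta, bool(np.max(np.abs(grad)) < 1e-6)


def _fit_core(dataset: pd.DataFrame, spec: Sequence[str],
              lam: float) -> GLMFit:
    X, q, names = _design(dataset, spec)
    n, p = X.shape
    if n < p:
        raise InsufficientDataError(f"{n} rows cannot identify {p} coefficients")
    if np.linalg.matrix_rank(X) < p:
        sds = X[:, 1:].std(axis=0)
        bad = [names[i + 1] for i in range(p - 1) if sds[i] == 0]
        raise FittingError(
            f"design matrix is rank deficient; suspect columns: {bad or 'correlated covariates'}")

    # standardize covariate columns for conditioning
    mu = X[:, 1:].mean(axis=0)
    sd = X[:, 1:].std(axis=0)
    sd[sd == 0] = 1.0
    Xs = X.copy()
    Xs[:, 1:] = (X[:, 1:] - mu) / sd
    lam_std = lam  # penalty applies on the standardized scale

    beta_s, ok = _newton_soft(Xs, q, lam_std)
    if not ok:
        res = optimize.minimize(
            lambda b: -(soft_log_likelihood(b, Xs, q)
                        - lam_std * float(np.sum(b[1:] ** 2))),
            beta_s, method="BFGS", options={"maxiter": 500, "gtol": 1e-8})
        beta_s, ok = res.x, res.success
    if lam == 0.0 and np.max(np.abs(beta_s)) > 30.0:
        raise SeparationError(
            "coefficients diverging: data are (quasi-)separated; use ridge "
            "regularization (fit_ridge)")
    if not ok and lam == 0.0:
        raise SeparationError(
            "soft logistic fit did not converge; data may be separated - "
            "consider ridge regularization")

    beta = np.empty_like(beta_s)
    beta[1:] = beta_s[1:] / sd
    beta[0] = beta_s[0] - float(np.dot(beta_s[1:], mu / sd))
    ll = soft_log_likelihood(beta, X, q)
    return GLMFit(beta=beta, spec=tuple(spec), log_likelihood=ll, n=n,
                  lambda_=lam, converged=ok, names=names)


def fit_soft_logistic(dataset: pd.DataFrame,
                      spec: Sequence[str] = FULL_SPEC) -> GLMFit:
    """Maximize the soft-label logistic likelihood for the chosen covariates.

    Covariates are standardized internally; coefficients are reported on
    the original scale.  Raises on rank deficiency or separation.
    """
    if len(dataset) == 0:
        raise InsufficientDataError("empty dataset")
    return _fit_core(dataset, spec, lam=0.0)


def fit_ridge(dataset: pd.DataFrame, spec: Sequence[str],
              lambda_: float) -> GLMFit:
    """Soft logistic fit with an L2 penalty on the standardized non-intercept
    coefficients: objective = log-likelihood - lambda * ||beta||^2."""
    if lambda_ < 0:
        raise ConfigurationError("lambda must be >= 0")
    if len(dataset) == 0:
        raise InsufficientDataError("empty dataset")
    return _fit_core(dataset, spec, lam=lambda_)


def cv_lambda(dataset: pd.DataFrame, spec: Sequence[str],
              grid: Sequence[float], n_folds: int = 5, *,
              seed: int) -> tuple[float, pd.DataFrame]:
    """Pick lambda maximizing the mean held-out soft log-likelihood.

    Ties break toward the smaller lambda.  Returns (lambda*, CV table).
    """
    grid = sorted(float(g) for g in grid)
    if not grid:
        raise ConfigurationError("empty lambda grid")
    from sklearn.model_selection import KFold
    folds = list(KFold(n_folds, shuffle=True, random_state=seed)
                 .split(np.arange(len(dataset))))
    rows = []
    for lam in grid:
        lls = []
        for tr, te in folds:
            fit = _fit_core(dataset.iloc[tr], spec, lam=lam)
            Xte, qte, _ = _design(dataset.iloc[te], spec)
            lls.append(soft_log_likelihood(fit.beta, Xte, qte) / len(te))
        rows.append({"lambda": lam, "mean_heldout_ll": float(np.mean(lls))})
    table = pd.DataFrame(rows)
    best = table.loc[table["mean_heldout_ll"].idxmax(), "lambda"]
    # idxmax returns the first maximum; grid is sorted ascending -> smallest
    return float(best), table


# ---------------------------------------------------------------------------
# model selection and hypothesis tests
# ---------------------------------------------------------------------------

def bic(fit: GLMFit) -> float:
    """-2 log-likelihood + p ln n (lower is better)."""
    p = len(fit.beta)
    return -2.0 * fit.log_likelihood + p * math.log(fit.n)


def model_select(dataset: pd.DataFrame,
                 specs: Sequence[Sequence[str]]) -> pd.DataFrame:
    """Fit each spec on the same rows and rank by BIC (ascending)."""
    rows = []
    for sp in specs:
        fit = fit_soft_logistic(dataset, sp)
        rows.append({"spec": tuple(sp), "n_params": len(fit.beta),
                     "log_likelihood": fit.log_likelihood, "bic": bic(fit)})
    out = pd.DataFrame(rows).sort_values("bic", kind="stable").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


@dataclass
class BootstrapEnsemble:
    betas: np.ndarray           # (replicates, coefficients)
    names: tuple[str, ...]
    provenance: list            # (encounter_set, worm_set) per replicate

    @property
    def mean(self) -> np.ndarray:
        return self.betas.mean(axis=0)

    @property
    def sd(self) -> np.ndarray:
        return self.betas.std(axis=0, ddof=1)

    def ci(self, level: float = 0.95) -> np.ndarray:
        a = (1.0 - level) / 2.0
        return np.quantile(self.betas, [a, 1.0 - a], axis=0)

    def summary(self) -> pd.DataFrame:
        lo, hi = self.ci()
        return pd.DataFrame({"coefficient": self.names, "mean": self.mean,
                             "sd": self.sd, "ci_lo": lo, "ci_hi": hi})


def bootstrap_ensemble(encounters: pd.DataFrame, acclimation_density: float,
                       spec: Sequence[str] = FULL_SPEC,
                       n_encounter_sets: int = 100, n_worm_sets: int = 500,
                       *, seed: int, lambda_: float = 0.0, rebuild: bool = True,
                       **build_kwargs) -> BootstrapEnsemble:
    """Full inference ensemble: encounter sampling x worm bootstrap.

    Produces ``n_encounter_sets * n_worm_sets`` replicate fits.  Each
    encounter-sampled dataset is built once, then worm-bootstrapped.
    """
    ss = np.random.SeedSequence(seed)
    s_enc, s_worm = ss.spawn(2)
    enc_sets = encounter_sample(encounters, acclimation_density,
                                n_encounter_sets, seed=s_enc, rebuild=rebuild,
                                **build_kwargs)
    worm_seeds = s_worm.spawn(n_encounter_sets)
    betas = []
    prov = []
    for e_idx, (enc_df, wseed) in enumerate(zip(enc_sets, worm_seeds)):
        if len(enc_df) == 0:
            raise InsufficientDataError(
                "encounter-sampled replicate is empty; sensing posteriors too low")
        reps = worm_bootstrap(enc_df, n_worm_sets, seed=wseed)
        for w_idx, rep in enumerate(reps):
            fit = _fit_core(rep, spec, lam=lambda_)
            betas.append(fit.beta)
            prov.append((e_idx, w_idx))
    names = ("intercept", *spec)
    return BootstrapEnsemble(np.array(betas), names, prov)


def shuffle_null(dataset: pd.DataFrame, spec: Sequence[str],
                 n_shuffles: int, *, seed: int) -> BootstrapEnsemble:
    """Null coefficient ensemble: refit after permuting the soft labels."""
    rng = np.random.default_rng(seed)
    betas = []
    for i in range(n_shuffles):
        shuffled = dataset.copy()
        shuffled["q"] = rng.permutation(dataset["q"].to_numpy())
        betas.append(fit_soft_logistic(shuffled, spec).beta)
    return BootstrapEnsemble(np.array(betas), ("intercept", *spec),
                             [("shuffle", i) for i in range(n_shuffles)])


def coefficient_test(ensemble: BootstrapEnsemble,
                     adjust: str = "bonferroni") -> pd.DataFrame:
    """Two-tailed one-sample bootstrap test per coefficient.

    p = 2 min[P(beta <= 0), P(beta >= 0)] over replicates, floored at
    2/B (the ensemble's resolution), then Bonferroni-adjusted across
    coefficients by default.
    """
    B, p = ensemble.betas.shape
    if B < 100:
        warnings.warn("fewer than 100 replicates: coarse p-value resolution",
                      stacklevel=2)
    raw = np.empty(p)
    for jcol in range(p):
        b = ensemble.betas[:, jcol]
        raw[jcol] = 2.0 * min(float(np.mean(b <= 0)), float(np.mean(b >= 0)))
    floored = np.maximum(raw, 2.0 / B)
    if adjust == "bonferroni":
        adj = np.minimum(floored * p, 1.0)
    elif adjust == "none":
        adj = floored
    else:
        raise ConfigurationError(f"unknown adjustment: {adjust!r}")
    return pd.DataFrame({"coefficient": ensemble.names, "p_raw": floored,
                         "p_adjusted": np.minimum(adj, 1.0),
                         "at_resolution_floor": raw < 2.0 / B})


class StrainComparison(NamedTuple):
    table: pd.DataFrame


DENSITY_COEFS = ("rho_k", "rho_h", "rho_e")


def strain_compare(ensemble_mutant: BootstrapEnsemble,
                   ensemble_wt: BootstrapEnsemble,
                   density_coefs: Sequence[str] = DENSITY_COEFS,
                   two_tailed_literal: bool = False) -> StrainComparison:
    """Z test of ensemble means: Z = (mu_mut - mu_wt) / sqrt(sd_m^2 + sd_w^2).

    Density coefficients get a left-tailed normal p; the rest two-tailed
    2 Phi(-|Z|) (or the literal single-tail Phi(-|Z|) variant).
    Benjamini-Hochberg adjustment across coefficients.
    """
    if ensemble_mutant.names != ensemble_wt.names:
        raise ConfigurationError("ensembles have mismatched coefficient specs")
    mu_m, sd_m = ensemble_mutant.mean, ensemble_mutant.sd
    mu_w, sd_w = ensemble_wt.mean, ensemble_wt.sd
    pooled = np.sqrt(sd_m**2 + sd_w**2)
    if np.any(pooled == 0):
        raise ConfigurationError("zero pooled variance: Z undefined")
    Z = (mu_m - mu_w) / pooled
    ps = np.empty_like(Z)
    tails = []
    for i, name in enumerate(ensemble_wt.names):
        if name in density_coefs:
            ps[i] = stats.norm.cdf(Z[i])
            tails.append("left")
        else:
            ps[i] = (stats.norm.cdf(-abs(Z[i])) if two_tailed_literal
                     else 2.0 * stats.norm.cdf(-abs(Z[i])))
            tails.append("two")
    adj = _benjamini_hochberg(ps)
    return StrainComparison(pd.DataFrame({
        "coefficient": ensemble_wt.names, "Z": Z, "tail": tails,
        "p": ps, "p_bh": adj}))


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


# ---------------------------------------------------------------------------
# derived predictions
# ---------------------------------------------------------------------------

def simulate_first_exploit(probability_sequences: Iterable[np.ndarray],
                           n_draws: int, *, seed: int
                           ) -> tuple[np.ndarray, float]:
    """Distribution of the encounter index of the first exploitation.

    For each worm's ordered probability sequence, draws Bernoulli chains
    and records the 1-based index of the first success; sequences that end
    without a success contribute to the censored mass.  Returns
    (pmf over encounter index, censored_mass), pooled across sequences.
    """
    rng = np.random.default_rng(seed)
    seqs = [np.asarray(s, dtype=float) for s in probability_sequences]
    kept = [s for s in seqs if s.size > 0]
    if len(kept) < len(seqs):
        warnings.warn(f"skipped {len(seqs) - len(kept)} empty sequence(s)",
                      stacklevel=2)
    if not kept:
        raise InsufficientDataError("no non-empty probability sequences")
    max_len = max(s.size for s in kept)
    counts = np.zeros(max_len)
    censored = 0
    total = 0
    for s in kept:
        draws = rng.uniform(size=(n_draws, s.size)) < s[None, :]
        any_hit = draws.any(axis=1)
        first = np.argmax(draws, axis=1)
        idx, cts = np.unique(first[any_hit], return_counts=True)
        counts[idx] += cts
        censored += int((~any_hit).sum())
        total += n_draws
    return counts / total, censored / total


def predict_surface(fit: GLMFit, axis1: str, grid_axis1: np.ndarray,
                    grid_rho_k: np.ndarray,
                    fixed_values: dict[str, float] | None = None) -> np.ndarray:
    """Exploitation-probability grid over (rho_k, axis1).

    ``axis1`` is one of rho_h / rho_e.  Covariates in the fit's spec that
    are neither rho_k nor axis1 are held at ``fixed_values`` (required
    for each).  If axis1 is absent from the spec the surface is constant
    along it.  Returns an array of shape (len(grid_rho_k), len(grid_axis1)).
    """
    if axis1 not in ("rho_h", "rho_e"):
        raise ConfigurationError("axis1 must be rho_h or rho_e")
    fixed = dict(fixed_values or {})
    for name in fixed:
        if name not in fit.spec:
            raise ConfigurationError(f"fixed covariate {name!r} not in fit spec")
    g1 = np.asarray(grid_rho_k, dtype=float)
    g2 = np.asarray(grid_axis1, dtype=float)
    K, A = np.meshgrid(g1, g2, indexing="ij")
    eta = np.full(K.shape, fit.beta[0])
    for i, name in enumerate(fit.spec, start=1):
        if name == "rho_k":
            eta += fit.beta[i] * K
        elif name == axis1:
            eta += fit.beta[i] * A
        else:
            if name not in fixed:
                raise ConfigurationError(
                    f"covariate {name!r} needs a fixed value")
            eta += fit.beta[i] * fixed[name]
    return _logistic(eta)


class LikelihoodComparison(NamedTuple):
    statistic: float
    df: int
    p_value: float
    ll_full: float
    ll_reduced: float


def compare_likelihood(fit_full: GLMFit, fit_reduced: GLMFit,
                       holdout: pd.DataFrame | None = None
                       ) -> LikelihoodComparison:
    """Likelihood-ratio comparison of nested soft-logistic fits.

    With ``holdout`` given, both fits are evaluated on that dataset with
    coefficients held fixed (out-of-sample comparison); otherwise the
    stored training log-likelihoods are compared.  The chi-square
    reference uses df = difference in parameter count.
    """
    if not set(fit_reduced.spec) <= set(fit_full.spec):
        raise ConfigurationError("reduced spec is not nested in the full spec")
    if holdout is not None:
        Xf, qf, _ = _design(holdout, fit_full.spec)
        Xr, qr, _ = _design(holdout, fit_reduced.spec)
        ll_f = soft_log_likelihood(fit_full.beta, Xf, qf)
        ll_r = soft_log_likelihood(fit_reduced.beta, Xr, qr)
    else:
        if fit_full.n != fit_reduced.n:
            raise ConfigurationError("fits were made on different row sets")
        ll_f, ll_r = fit_full.log_likelihood, fit_reduced.log_likelihood
    df = len(fit_full.beta) - len(fit_reduced.beta)
    stat = 2.0 * (ll_f - ll_r)
    p = 1.0 if df == 0 else float(stats.chi2.sf(max(stat, 0.0), df))
    return LikelihoodComparison(stat, df, p, ll_f, ll_r)
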