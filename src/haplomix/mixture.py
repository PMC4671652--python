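"""Two-class Poisson mixture over per-gene PTV counts.

The count x_g of rare truncating variants in gene g is modelled as a
two-component Poisson mixture: with probability f_hi the gene is intolerant
to heterozygous truncation (HI) and x_g ~ Poisson(lambda_HI(g)); otherwise
(HS) x_g ~ Poisson(lambda_HS(g)). The per-gene means come from either the
relative-rate model (A: parameters f_hi and noise fraction e) or the
synonymous-anchored model (B: parameters f_hi and class scales s_HI, s_HS).

Parameters are estimated by least squares between the model's marginal
cumulative count distribution and the empirical one, minimized with the
Nelder-Mead simplex (a maximum-likelihood fitter is provided for method
comparison). Uncertainty comes from refitting on gene-resampling bootstrap
replicates. Estimators follow the scikit-learn protocol (``fit``,
``predict_proba``, trailing-underscore fitted attributes).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logit
from sklearn.base import BaseEstimator

from .baseline import (
    ExpectedCounts,
    expected_counts_model_a,
    expected_counts_model_b,
    fit_synonymous_scale,
)
from .catalog import Catalog

_LOGIT_CLIP = 1e-9


# ---------------------------------------------------------------------------
# Poisson primitives


def poisson_log_pmf(k: np.ndarray | int, lam: np.ndarray | float) -> np.ndarray:
    """log Poisson pmf, with the convention Poisson(0, 0) = 1."""
    k = np.asarray(k, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if np.any(k < 0) or np.any(k != np.floor(k)):
        raise ValueError("k must be a nonnegative integer")
    if np.any(lam < 0):
        raise ValueError("lambda must be nonnegative")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = k * np.log(lam) - lam - gammaln(k + 1.0)
    # lam == 0: pmf is 1 at k=0, 0 elsewhere
    out = np.where(lam == 0, np.where(k == 0, 0.0, -np.inf), out)
    return out


def poisson_pmf(k, lam) -> np.ndarray | float:
    """Poisson pmf computed stably in log space."""
    res = np.exp(poisson_log_pmf(k, lam))
    return float(res) if np.ndim(res) == 0 else res


def _avg_mixture_cdf_numpy(k_max: int, lam_hi: np.ndarray, lam_hs: np.ndarray,
                           f_hi: float) -> np.ndarray:
    pmf_hi = np.exp(-lam_hi)
    pmf_hs = np.exp(-lam_hs)
    cdf_hi = pmf_hi.copy()
    cdf_hs = pmf_hs.copy()
    out = np.empty(k_max + 1)
    out[0] = f_hi * cdf_hi.mean() + (1.0 - f_hi) * cdf_hs.mean()
    for k in range(1, k_max + 1):
        pmf_hi *= lam_hi / k
        pmf_hs *= lam_hs / k
        cdf_hi += pmf_hi
        cdf_hs += pmf_hs
        out[k] = f_hi * cdf_hi.mean() + (1.0 - f_hi) * cdf_hs.mean()
    return out


try:  # JIT kernel for the optimizer's hot loop; numpy path is the reference
    from numba import njit

    @njit(cache=True)
    def _avg_mixture_cdf_jit(k_max, lam_hi, lam_hs, f_hi):  # pragma: no cover
        n = lam_hi.size
        out = np.zeros(k_max + 1)
        w_hi = f_hi / n
        w_hs = (1.0 - f_hi) / n
        for g in range(n):
            p_hi = np.exp(-lam_hi[g])
            p_hs = np.exp(-lam_hs[g])
            c_hi = p_hi
            c_hs = p_hs
            out[0] += w_hi * c_hi + w_hs * c_hs
            for k in range(1, k_max + 1):
                p_hi *= lam_hi[g] / k
                p_hs *= lam_hs[g] / k
                c_hi += p_hi
                c_hs += p_hs
                out[k] += w_hi * c_hi + w_hs * c_hs
        return out

    def _avg_mixture_cdf(k_max, lam_hi, lam_hs, f_hi):
        return _avg_mixture_cdf_jit(
            int(k_max),
            np.ascontiguousarray(lam_hi, dtype=np.float64),
            np.ascontiguousarray(lam_hs, dtype=np.float64),
            float(f_hi),
        )

except ImportError:  # pragma: no cover
    _avg_mixture_cdf = _avg_mixture_cdf_numpy

_avg_mixture_cdf.__doc__ = """Gene-averaged mixture CDF F(k) for k = 0..k_max.

Uses the pmf recurrence pmf(k+1) = pmf(k) * lam / (k+1); exp(-lam)
underflows to 0 only for lam > ~745, where the true CDF on this grid is
itself below double precision.
"""


def marginal_count_pmf(
    k: int, f_hi: float, expected: ExpectedCounts
) -> float:
    """P(X = k): the gene-averaged mixture pmf of the per-gene count."""
    per_gene = f_hi * poisson_pmf(k, expected.lambda_hi) + (
        1.0 - f_hi
    ) * poisson_pmf(k, expected.lambda_hs)
    return float(np.mean(per_gene))


def empirical_cdf(observed_counts: np.ndarray, k_max: int) -> np.ndarray:
    """F_emp(k) = fraction of genes with count <= k, k = 0..k_max."""
    observed_counts = np.asarray(observed_counts)
    if observed_counts.size == 0:
        raise ValueError("observed_counts must be nonempty")
    hist = np.bincount(observed_counts, minlength=k_max + 1)[: k_max + 1]
    return np.cumsum(hist) / observed_counts.size


def cdf_objective(
    f_hi: float,
    expected: ExpectedCounts,
    observed_counts: np.ndarray,
    k_max: int | None = None,
) -> float:
    """Sum of squared differences between model and empirical count CDFs,
    on the unweighted grid k = 0 .. max observed count."""
    observed_counts = np.asarray(observed_counts)
    if k_max is None:
        k_max = int(observed_counts.max())
    f_emp = empirical_cdf(observed_counts, k_max)
    f_model = _avg_mixture_cdf(k_max, expected.lambda_hi, expected.lambda_hs, f_hi)
    return float(np.sum((f_model - f_emp) ** 2))


# ---------------------------------------------------------------------------
# Parameter containers


@dataclass
class MixtureParams:
    """Fitted mixture parameters; exactly the set matching model_tag."""

    model_tag: str  # "A", "A_no_noise" or "B"
    f_hi: float
    e: float | None = None
    s_hi: float | None = None
    s_hs: float | None = None

    def __post_init__(self) -> None:
        if self.model_tag == "A_no_noise":
            self.e = 0.0
        if self.model_tag in ("A", "A_no_noise"):
            if self.e is None or self.s_hi is not None or self.s_hs is not None:
                raise ValueError("model A carries (f_hi, e) only")
        elif self.model_tag == "B":
            if self.s_hi is None or self.s_hs is None or self.e is not None:
                raise ValueError("model B carries (f_hi, s_hi, s_hs) only")
            if self.s_hi > self.s_hs:
                raise ValueError("identifiability requires s_hi <= s_hs")
        else:
            raise ValueError(f"unknown model_tag {self.model_tag!r}")

    def as_dict(self) -> dict:
        d = {"model_tag": self.model_tag, "f_hi": self.f_hi}
        if self.e is not None:
            d["e"] = self.e
        if self.s_hi is not None:
            d["s_hi"] = self.s_hi
            d["s_hs"] = self.s_hs
        return d


@dataclass
class BootstrapResult:
    replicates: pd.DataFrame  # one row per successful replicate
    ci95: dict[str, tuple[float, float]]
    n_boot: int
    n_failures: int
    seed: int


@dataclass
class MixtureFit:
    params: MixtureParams
    objective: float
    converged: bool
    n_evals: int
    seed: int = 0
    V: int | None = None
    M: float | None = None
    bootstrap: BootstrapResult | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "params": self.params.as_dict(),
            "objective": self.objective,
            "converged": self.converged,
            "n_evals": self.n_evals,
            "seed": self.seed,
            "V": self.V,
            "M": self.M,
        }
        if self.bootstrap is not None:
            payload["bootstrap"] = {
                "n_boot": self.bootstrap.n_boot,
                "n_failures": self.bootstrap.n_failures,
                "ci95": {k: list(v) for k, v in self.bootstrap.ci95.items()},
            }
        Path(path).write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# Estimators


class _TruncationMixtureBase(BaseEstimator):
    """Shared Nelder-Mead machinery for both expected-count models."""

    def __init__(
        self,
        method: str = "cdf_ls",
        f_starts: tuple[float, ...] = (0.05, 0.1, 0.2, 0.3, 0.4),
        tol: float = 1e-8,
        xatol: float = 1e-6,
        max_evals: int = 10_000,
        random_state: int = 0,
    ):
        self.method = method
        self.f_starts = f_starts
        self.tol = tol
        self.xatol = xatol
        self.max_evals = max_evals
        self.random_state = random_state

    # subclass hooks ------------------------------------------------------
    def _unpack(self, x: np.ndarray) -> MixtureParams:  # pragma: no cover
        raise NotImplementedError

    def _pack_starts(self) -> list[np.ndarray]:  # pragma: no cover
        raise NotImplementedError

    def _expected(self, params: MixtureParams) -> ExpectedCounts:  # pragma: no cover
        raise NotImplementedError

    # ---------------------------------------------------------------------
    def _objective_fn(self, observed: np.ndarray) -> Callable[[np.ndarray], float]:
        if self.method == "cdf_ls":
            k_max = int(observed.max())
            f_emp = empirical_cdf(observed, k_max)

            def obj(x: np.ndarray) -> float:
                p = self._unpack(x)
                exp = self._expected(p)
                f_model = _avg_mixture_cdf(
                    k_max, exp.lambda_hi, exp.lambda_hs, p.f_hi
                )
                return float(np.sum((f_model - f_emp) ** 2))

        elif self.method == "mle":

            def obj(x: np.ndarray) -> float:
                p = self._unpack(x)
                exp = self._expected(p)
                lp_hi = poisson_log_pmf(observed, exp.lambda_hi)
                lp_hs = poisson_log_pmf(observed, exp.lambda_hs)
                m = np.maximum(lp_hi, lp_hs)
                m = np.where(np.isfinite(m), m, 0.0)
                mix = p.f_hi * np.exp(lp_hi - m) + (1 - p.f_hi) * np.exp(
                    lp_hs - m
                )
                ll = np.sum(np.log(np.maximum(mix, 1e-300)) + m)
                return float(-ll)

        else:
            raise ValueError(f"method must be cdf_ls or mle, got {self.method!r}")
        return obj

    def _fit_transformed(self, observed: np.ndarray) -> tuple[np.ndarray, float, bool, int]:
        obj = self._objective_fn(observed)
        best: tuple[np.ndarray, float, bool, int] | None = None
        n_evals = 0
        max_per_start = max(self.max_evals // max(len(self._pack_starts()), 1), 200)
        for x0 in self._pack_starts():
            res = minimize(
                obj,
                x0,
                method="Nelder-Mead",
                options={
                    "fatol": self.tol,
                    "xatol": self.xatol,
                    "maxfev": max_per_start,
                },
            )
            n_evals += res.nfev
            cand = (res.x, float(res.fun), bool(res.success), n_evals)
            if best is None or cand[1] < best[1] - 1e-15:
                best = cand
            elif abs(cand[1] - best[1]) <= 1e-15:
                # tie: keep the lower f_hi (first packed coordinate is logit f)
                if cand[0][0] < best[0][0]:
                    best = cand
        assert best is not None
        return best[0], best[1], best[2], n_evals

    # sklearn surface -----------------------------------------------------
    def predict_proba(self, X: Catalog | np.ndarray | None = None) -> np.ndarray:
        """Posterior class probabilities per gene, columns (HS, HI)."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "f_hi_")
        observed = (
            self._observed_
            if X is None
            else (
                X.included["o_ptv"].to_numpy(int)
                if isinstance(X, Catalog)
                else np.asarray(X, dtype=int)
            )
        )
        post_hi = _posterior_hi_values(
            self.f_hi_, self.lambda_hi_, self.lambda_hs_, observed
        )
        return np.column_stack([1.0 - post_hi, post_hi])

    def predict(self, X: Catalog | np.ndarray | None = None) -> np.ndarray:
        """Most probable class per gene: 1 for intolerant (HI), else 0."""
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


class ModelAMixture(_TruncationMixtureBase):
    """Relative-rate mixture: parameters f_hi and the noise fraction e.

    ``noise=False`` fixes e = 0 (the single-parameter first-stage design in
    which intolerant genes are never observed truncated).
    """

    def __init__(
        self,
        noise: bool = True,
        method: str = "cdf_ls",
        f_starts: tuple[float, ...] = (0.05, 0.1, 0.2, 0.3, 0.4),
        e_start: float = 0.05,
        tol: float = 1e-8,
        xatol: float = 1e-6,
        max_evals: int = 10_000,
        random_state: int = 0,
    ):
        super().__init__(
            method=method,
            f_starts=f_starts,
            tol=tol,
            xatol=xatol,
            max_evals=max_evals,
            random_state=random_state,
        )
        self.noise = noise
        self.e_start = e_start

    @property
    def model_tag(self) -> str:
        return "A" if self.noise else "A_no_noise"

    def _unpack(self, x: np.ndarray) -> MixtureParams:
        f_hi = float(expit(x[0]))
        e = float(expit(x[1])) if self.noise else 0.0
        if self.noise:
            return MixtureParams(model_tag="A", f_hi=f_hi, e=e)
        return MixtureParams(model_tag="A_no_noise", f_hi=f_hi)

    def _pack_starts(self) -> list[np.ndarray]:
        starts = []
        for f0 in self.f_starts:
            f0 = float(np.clip(f0, _LOGIT_CLIP, 1 - _LOGIT_CLIP))
            if self.noise:
                starts.append(np.array([logit(f0), logit(self.e_start)]))
            else:
                starts.append(np.array([logit(f0)]))
        return starts

    def _expected(self, params: MixtureParams) -> ExpectedCounts:
        q = self._q_
        e = params.e if params.e is not None else 0.0
        lam_hi = self._V_ * e * q
        lam_hs = lam_hi + self._V_ * (1.0 - e) * q / (1.0 - params.f_hi)
        return ExpectedCounts(lambda_hi=lam_hi, lambda_hs=lam_hs, model_tag="A")

    def fit(self, X: Catalog, y=None, V: int | None = None) -> "ModelAMixture":
        """Fit on a catalog's included genes; V defaults to the observed
        PTV total of the catalog."""
        return self.fit_arrays(
            X.included["p_trunc"].to_numpy(float),
            X.included["o_ptv"].to_numpy(int),
            V=V,
        )

    def fit_arrays(
        self, p_trunc: np.ndarray, observed: np.ndarray, V: int | None = None
    ) -> "ModelAMixture":
        """Array-level fit core (used by the bootstrap's hot loop)."""
        observed = np.asarray(observed, dtype=int)
        p_trunc = np.asarray(p_trunc, dtype=float)
        total = p_trunc.sum()
        if total <= 0:
            raise ValueError("sum of p_trunc must be > 0")
        self._q_ = p_trunc / total
        self._V_ = int(V) if V is not None else int(observed.sum())
        self._observed_ = observed
        x, obj, ok, n_evals = self._fit_transformed(observed)
        params = self._unpack(x)
        self.f_hi_ = params.f_hi
        self.e_ = params.e if self.noise else 0.0
        self.V_ = self._V_
        self.objective_ = obj
        self.converged_ = ok
        self.n_evals_ = n_evals
        exp = self._expected(params)
        self.lambda_hi_ = exp.lambda_hi
        self.lambda_hs_ = exp.lambda_hs
        return self

    def _params(self) -> MixtureParams:
        if self.noise:
            return MixtureParams(model_tag="A", f_hi=self.f_hi_, e=self.e_)
        return MixtureParams(model_tag="A_no_noise", f_hi=self.f_hi_)


class ModelBMixture(_TruncationMixtureBase):
    """Synonymous-anchored mixture: parameters f_hi, s_hi, s_hs.

    The scale M (expected variants per unit mutation rate) is taken from the
    no-intercept synonymous regression unless supplied. The class scales are
    optimized in log space; the returned fit is relabelled if needed so that
    s_hi <= s_hs.
    """

    def __init__(
        self,
        method: str = "cdf_ls",
        f_starts: tuple[float, ...] = (0.05, 0.1, 0.2, 0.3, 0.4),
        tol: float = 1e-8,
        xatol: float = 1e-6,
        max_evals: int = 10_000,
        random_state: int = 0,
    ):
        super().__init__(
            method=method,
            f_starts=f_starts,
            tol=tol,
            xatol=xatol,
            max_evals=max_evals,
            random_state=random_state,
        )

    model_tag = "B"

    def _unpack(self, x: np.ndarray) -> MixtureParams:
        f_hi = float(expit(x[0]))
        s_a, s_b = float(np.exp(x[1])), float(np.exp(x[2]))
        if s_a > s_b:  # relabel: swap classes
            s_a, s_b = s_b, s_a
            f_hi = 1.0 - f_hi
        return MixtureParams(model_tag="B", f_hi=f_hi, s_hi=s_a, s_hs=s_b)

    def _pack_starts(self) -> list[np.ndarray]:
        s_hs0 = max(self._s_moment_, 1e-6)
        s_hi0 = max(0.1 * s_hs0, 1e-8)
        return [
            np.array(
                [
                    logit(np.clip(f0, _LOGIT_CLIP, 1 - _LOGIT_CLIP)),
                    np.log(s_hi0),
                    np.log(s_hs0),
                ]
            )
            for f0 in self.f_starts
        ]

    def _expected(self, params: MixtureParams) -> ExpectedCounts:
        neutral = self._neutral_
        return ExpectedCounts(
            lambda_hi=neutral * params.s_hi,
            lambda_hs=neutral * params.s_hs,
            model_tag="B",
            expected_neutral=neutral,
        )

    def fit(self, X: Catalog, y=None, M: float | None = None) -> "ModelBMixture":
        if M is None:
            M = fit_synonymous_scale(X).M
        return self.fit_arrays(
            X.included["p_trunc"].to_numpy(float),
            X.included["o_ptv"].to_numpy(int),
            M=M,
        )

    def fit_arrays(
        self, p_trunc: np.ndarray, observed: np.ndarray, M: float
    ) -> "ModelBMixture":
        """Array-level fit core (used by the bootstrap's hot loop)."""
        observed = np.asarray(observed, dtype=int)
        self._neutral_ = M * np.asarray(p_trunc, dtype=float)
        # moment start for the dominant class scale
        self._s_moment_ = float(observed.mean() / max(self._neutral_.mean(), 1e-300))
        self._observed_ = observed
        x, obj, ok, n_evals = self._fit_transformed(observed)
        params = self._unpack(x)
        self.f_hi_ = params.f_hi
        self.s_hi_ = params.s_hi
        self.s_hs_ = params.s_hs
        self.M_ = float(M)
        self.objective_ = obj
        self.converged_ = ok
        self.n_evals_ = n_evals
        exp = self._expected(params)
        self.lambda_hi_ = exp.lambda_hi
        self.lambda_hs_ = exp.lambda_hs
        self.expected_neutral_ = exp.expected_neutral
        return self

    def _params(self) -> MixtureParams:
        return MixtureParams(
            model_tag="B", f_hi=self.f_hi_, s_hi=self.s_hi_, s_hs=self.s_hs_
        )


def _make_estimator(model_tag: str, method: str = "cdf_ls", **options):
    if model_tag == "A":
        return ModelAMixture(noise=True, method=method, **options)
    if model_tag in ("A0", "A_no_noise"):
        return ModelAMixture(noise=False, method=method, **options)
    if model_tag == "B":
        return ModelBMixture(method=method, **options)
    raise ValueError(f"unknown model_tag {model_tag!r}")


def _fit_to_result(est, seed: int = 0) -> MixtureFit:
    return MixtureFit(
        params=est._params(),
        objective=est.objective_,
        converged=est.converged_,
        n_evals=est.n_evals_,
        seed=seed,
        V=getattr(est, "V_", None),
        M=getattr(est, "M_", None),
    )


def fit_cdf_ls(
    catalog: Catalog,
    model_tag: str = "A",
    V_or_M: float | None = None,
    **options,
) -> MixtureFit:
    """Least-squares CDF fit (the default estimation method)."""
    est = _make_estimator(model_tag, method="cdf_ls", **options)
    if isinstance(est, ModelAMixture):
        est.fit(catalog, V=V_or_M)
    else:
        est.fit(catalog, M=V_or_M)
    return _fit_to_result(est)


def fit_mle(
    catalog: Catalog,
    model_tag: str = "A",
    V_or_M: float | None = None,
    **options,
) -> MixtureFit:
    """Maximum-likelihood fit over the same parameter space; provided for
    method comparison, not the default."""
    est = _make_estimator(model_tag, method="mle", **options)
    if isinstance(est, ModelAMixture):
        est.fit(catalog, V=V_or_M)
    else:
        est.fit(catalog, M=V_or_M)
    return _fit_to_result(est)


def bootstrap_fit(
    catalog: Catalog,
    model_tag: str = "A",
    V_or_M: float | None = None,
    n_boot: int = 500,
    seed: int = 0,
    method: str = "cdf_ls",
    point_fit: MixtureFit | None = None,
    **options,
) -> BootstrapResult:
    """Gene-resampling bootstrap of the mixture fit.

    Each replicate resamples the included genes with replacement (carrying
    rates and counts), recomputes V (model A) or M (model B) on the
    replicate, and refits. Refits warm-start from the point estimate with a
    single simplex start and a looser x-tolerance (replicates feed a
    percentile CI, not a point estimate); failures are excluded and counted.
    """
    inc = catalog.included
    p_trunc = inc["p_trunc"].to_numpy(float)
    p_syn = inc["p_syn"].to_numpy(float)
    o_syn = inc["o_syn"].to_numpy(float)
    observed = inc["o_ptv"].to_numpy(int)
    n = len(observed)
    if point_fit is None:
        point_fit = fit_cdf_ls(catalog, model_tag, V_or_M, **options)
    p = point_fit.params
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    n_failures = 0
    options = {**options, "xatol": options.get("xatol", 1e-4)}
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            est = _make_estimator(model_tag, method=method, **options)
            est.f_starts = (p.f_hi,)
            if isinstance(est, ModelAMixture):
                if est.noise:
                    est.e_start = max(p.e, 1e-6)
                est.fit_arrays(p_trunc[idx], observed[idx])
            else:
                denom = float(np.sum(p_syn[idx] ** 2))
                if denom <= 0:
                    raise ZeroDivisionError("degenerate synonymous rates")
                M_rep = float(np.sum(o_syn[idx] * p_syn[idx]) / denom)
                est.fit_arrays(p_trunc[idx], observed[idx], M=M_rep)
            rep = est._params().as_dict()
            rep.pop("model_tag")
            if not np.isfinite(est.objective_):
                raise FloatingPointError("non-finite objective")
            rows.append(rep)
        except Exception:  # noqa: BLE001 — replicate failures are data, not bugs
            n_failures += 1
    reps = pd.DataFrame(rows)
    ci95 = {
        col: (
            float(np.percentile(reps[col], 2.5)),
            float(np.percentile(reps[col], 97.5)),
        )
        for col in reps.columns
    }
    return BootstrapResult(
        replicates=reps, ci95=ci95, n_boot=n_boot, n_failures=n_failures, seed=seed
    )


# ---------------------------------------------------------------------------
# Posteriors


def _posterior_hi_values(
    f_hi: float, lam_hi: np.ndarray, lam_hs: np.ndarray, observed: np.ndarray
) -> np.ndarray:
    lp_hi = poisson_log_pmf(observed, lam_hi)
    lp_hs = poisson_log_pmf(observed, lam_hs)
    if f_hi <= 0.0:
        return np.zeros_like(lp_hi)
    if f_hi >= 1.0:
        return np.ones_like(lp_hi)
    m = np.maximum(lp_hi, lp_hs)
    m = np.where(np.isfinite(m), m, 0.0)
    num = f_hi * np.exp(lp_hi - m)
    den = num + (1.0 - f_hi) * np.exp(lp_hs - m)
    return num / den


def posterior_hi(
    fit: MixtureFit, expected: ExpectedCounts, catalog: Catalog
) -> pd.DataFrame:
    """Per-gene posterior probability of intolerance, sorted descending.

    Columns mirror the per-gene report: gene, observed PTVs, the neutral
    expectation (model B) and the class-conditional means, and the posterior.
    """
    inc = catalog.included
    observed = inc["o_ptv"].to_numpy(int)
    post = _posterior_hi_values(
        fit.params.f_hi, expected.lambda_hi, expected.lambda_hs, observed
    )
    neutral = (
        expected.expected_neutral
        if expected.expected_neutral is not None
        else expected.lambda_hs
    )
    df = pd.DataFrame(
        {
            "gene": inc["gene"].to_numpy(),
            "observed_ptv": observed,
            "expected_ptv": neutral,
            "lambda_hi": expected.lambda_hi,
            "lambda_hs": expected.lambda_hs,
            "posterior_hi": post,
        }
    )
    return df.sort_values(
        "posterior_hi", ascending=False, kind="mergesort"
    ).reset_index(drop=True)


def expected_counts_for_fit(catalog: Catalog, fit: MixtureFit) -> ExpectedCounts:
    """Rebuild the per-gene expected counts implied by a fit on a catalog."""
    p = fit.params
    if p.model_tag in ("A", "A_no_noise"):
        V = fit.V if fit.V is not None else catalog.total_ptv()
        return expected_counts_model_a(catalog, V, p.e or 0.0, p.f_hi)
    M = fit.M if fit.M is not None else fit_synonymous_scale(catalog).M
    return expected_counts_model_b(catalog, M, p.s_hi, p.s_hs)
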