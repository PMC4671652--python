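"""Neutral baselines: the synonymous scale M and per-gene expected PTV counts.

Model A works with *relative* rates: the observed PTV total V is split into a
noise fraction e spread over all genes and a signal fraction 1-e confined to
haplosufficient (HS) genes. Model B anchors *absolute* expectations in the
synonymous spectrum: a no-intercept regression of observed synonymous counts
on synonymous rates yields the scale M, and class multipliers s_HI <= s_HS
convert the neutral expectation M*p_trunc into class-conditional means.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .catalog import Catalog

logger = logging.getLogger(__name__)


@dataclass
class SynonymousScaleFit:
    """No-intercept least-squares slope of o_syn on p_syn, with residuals."""

    M: float
    residuals: np.ndarray
    residual_sd: float
    dropped_genes: list[str] = field(default_factory=list)
    n_passes: int = 1

    def to_json(self, path: str | Path) -> None:
        payload = {
            "M": self.M,
            "residual_sd": self.residual_sd,
            "dropped_genes": self.dropped_genes,
            "n_passes": self.n_passes,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


@dataclass
class ExpectedCounts:
    """Per-gene Poisson means under the intolerant (HI) and tolerant (HS)
    classes, aligned to the catalog's included genes."""

    lambda_hi: np.ndarray
    lambda_hs: np.ndarray
    model_tag: str  # "A" or "B"
    expected_neutral: np.ndarray | None = None  # model B: M * p_trunc

    def __post_init__(self) -> None:
        if self.lambda_hi.shape != self.lambda_hs.shape:
            raise ValueError("lambda arrays must be aligned")
        if not (np.isfinite(self.lambda_hi).all() and np.isfinite(self.lambda_hs).all()):
            raise ValueError("expected counts must be finite")


def fit_synonymous_scale(catalog: Catalog) -> SynonymousScaleFit:
    """Estimate M by no-intercept least squares of o_syn on p_syn.

    The intercept is omitted because a gene with zero synonymous mutation
    rate is expected to show zero synonymous variants. Closed form:
    M = sum(o_syn * p_syn) / sum(p_syn**2).
    """
    inc = catalog.included
    p = inc["p_syn"].to_numpy(float)
    o = inc["o_syn"].to_numpy(float)
    denom = float(np.sum(p * p))
    if denom <= 0:
        raise ValueError("all p_syn are zero; synonymous scale undefined")
    M = float(np.sum(o * p) / denom)
    residuals = o - M * p
    sd = float(np.std(residuals, ddof=1)) if len(residuals) > 1 else 0.0
    return SynonymousScaleFit(M=M, residuals=residuals, residual_sd=sd)


def synonymous_deviation_filter(
    catalog: Catalog,
    fit: SynonymousScaleFit | None = None,
    k_sd: float = 3.0,
    side: str = "both",
) -> tuple[Catalog, SynonymousScaleFit]:
    """Exclude genes whose synonymous counts deviate from expectation.

    Genes whose regression residual lies more than ``k_sd`` standard
    deviations from the residual mean are marked not included (a coverage
    heuristic: genes sequenced too shallowly or too deeply relative to their
    rate). ``side`` selects two-sided (default), "high" or "low" deviations.
    M is refit once on the surviving genes.
    """
    if side not in ("both", "high", "low"):
        raise ValueError(f"side must be both, high or low, got {side!r}")
    out = catalog.copy()
    inc_mask = out.genes["included"].to_numpy(bool)
    if inc_mask.sum() < 3:
        logger.warning("fewer than 3 included genes; deviation filter skipped")
        fit = fit or fit_synonymous_scale(out)
        out.provenance.append("synonymous deviation filter skipped (<3 genes)")
        return out, fit
    if fit is None:
        fit = fit_synonymous_scale(out)
    res = fit.residuals
    mu, sd = float(np.mean(res)), float(np.std(res, ddof=1))
    if sd == 0 or not np.isfinite(k_sd):
        out.provenance.append(
            f"synonymous deviation filter: no genes excluded (k_sd={k_sd})"
        )
        return out, fit
    centered = res - mu
    if side == "both":
        deviant = np.abs(centered) > k_sd * sd
    elif side == "high":
        deviant = centered > k_sd * sd
    else:
        deviant = centered < -k_sd * sd
    inc_idx = np.flatnonzero(inc_mask)
    dropped_idx = inc_idx[deviant]
    dropped = out.genes.iloc[dropped_idx]["gene"].tolist()
    out.genes.iloc[dropped_idx, out.genes.columns.get_loc("included")] = False
    refit = fit_synonymous_scale(out)
    refit.dropped_genes = dropped
    refit.n_passes = 2
    out.provenance.append(
        f"synonymous deviation filter ({side}, k_sd={k_sd}): "
        f"excluded {len(dropped)} genes; M {fit.M:.6g} -> {refit.M:.6g}"
    )
    return out, refit


def expected_counts_model_a(
    catalog: Catalog, V: int, e: float, f_hi: float
) -> ExpectedCounts:
    """Class-conditional expected PTV counts under the relative-rate model.

    With q_g the relative truncation rate over included genes:
    lambda_HI = V*e*q_g (noise only); lambda_HS adds the signal share
    V*(1-e)*q_g/(1-f_hi), using the identification that HS genes carry a
    fraction 1-f_hi of the total rate mass.
    """
    if V < 0:
        raise ValueError("V must be nonnegative")
    if not (0.0 <= e <= 1.0):
        raise ValueError("noise fraction e must lie in [0, 1]")
    if not (0.0 <= f_hi < 1.0) and not (f_hi == 1.0 and e == 1.0):
        raise ValueError("f_hi must lie in [0, 1); f_hi=1 only with e=1")
    q = catalog.relative_rates()
    lam_hi = V * e * q
    if e == 1.0:
        lam_hs = lam_hi.copy()
    else:
        lam_hs = lam_hi + V * (1.0 - e) * q / (1.0 - f_hi)
    return ExpectedCounts(lambda_hi=lam_hi, lambda_hs=lam_hs, model_tag="A")


def expected_counts_model_b(
    catalog: Catalog, M: float, s_hi: float, s_hs: float
) -> ExpectedCounts:
    """Class-conditional expected PTV counts anchored in the synonymous scale.

    lambda_class = M * p_trunc * s_class; the neutral expectation M * p_trunc
    (s=1) is exposed for observed-vs-expected reporting.
    """
    if M <= 0:
        raise ValueError("M must be positive")
    if s_hi < 0 or s_hs < 0:
        raise ValueError("class scales must be nonnegative")
    p = catalog.included["p_trunc"].to_numpy(float)
    neutral = M * p
    return ExpectedCounts(
        lambda_hi=neutral * s_hi,
        lambda_hs=neutral * s_hs,
        model_tag="B",
        expected_neutral=neutral,
    )
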