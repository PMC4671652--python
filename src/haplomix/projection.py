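"""Model-derived accumulation curves and the first-hit conditional.

Under the fitted relative-rate model, the expected number of distinct genes
observed truncated after v cumulative PTVs decomposes into an intolerant
(HI) component fed only by noise and a tolerant (HS) component fed by noise
plus genuine de novo signal. The conditional probability that a gene newly
observed truncated is intolerant is the ratio of the derivatives of those
components; it rises with v because tolerant genes saturate first.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import Catalog


@dataclass
class ProjectionCurve:
    v_grid: np.ndarray
    total: np.ndarray
    hi_component: np.ndarray
    hs_component: np.ndarray
    conditional_hi: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "v": self.v_grid,
                "total": self.total,
                "hi": self.hi_component,
                "hs": self.hs_component,
                "conditional_hi": self.conditional_hi,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _rates(catalog: Catalog, e: float, f_hi: float):
    q = catalog.relative_rates()
    rate_hi = e * q  # per-PTV hit rate of an HI gene (noise only)
    rate_hs = q * (e + (1.0 - e) / (1.0 - f_hi))
    return q, rate_hi, rate_hs


def predicted_gene_accumulation(
    catalog: Catalog, f_hi: float, e: float, v_grid: np.ndarray
) -> ProjectionCurve:
    """Expected distinct truncated genes vs cumulative PTVs, by class.

    Poisson thinning: after v variants a gene with per-variant hit rate r is
    truncated with probability 1 - exp(-v r). Components weight genes by
    their class prior (f_hi and 1 - f_hi).
    """
    if not (0.0 <= f_hi < 1.0):
        raise ValueError("f_hi must lie in [0, 1)")
    if not (0.0 <= e <= 1.0):
        raise ValueError("e must lie in [0, 1]")
    v_grid = np.asarray(v_grid, dtype=float)
    _, rate_hi, rate_hs = _rates(catalog, e, f_hi)
    v = v_grid[:, None]
    hi = f_hi * np.sum(-np.expm1(-v * rate_hi[None, :]), axis=1)
    hs = (1.0 - f_hi) * np.sum(-np.expm1(-v * rate_hs[None, :]), axis=1)
    cond = conditional_first_hit_probability(catalog, f_hi, e, v_grid)
    return ProjectionCurve(
        v_grid=v_grid,
        total=hi + hs,
        hi_component=hi,
        hs_component=hs,
        conditional_hi=cond,
    )


def conditional_first_hit_probability(
    catalog: Catalog, f_hi: float, e: float, v_grid: np.ndarray
) -> np.ndarray:
    """P(gene is intolerant | gene newly observed truncated at v PTVs).

    Ratio of the analytic derivatives of the class accumulation components:
    d/dv of sum_g w_class (1 - exp(-v r_g)) = sum_g w_class r_g exp(-v r_g).
    Beyond saturation (denominator underflows) the value is 1 by convention
    when e > 0; with e = 0 no intolerant gene is ever discovered and the
    curve is identically 0.
    """
    v_grid = np.asarray(v_grid, dtype=float)
    _, rate_hi, rate_hs = _rates(catalog, e, f_hi)
    if e == 0.0:
        return np.zeros_like(v_grid)
    v = v_grid[:, None]
    d_hi = f_hi * np.sum(rate_hi[None, :] * np.exp(-v * rate_hi[None, :]), axis=1)
    d_hs = (1.0 - f_hi) * np.sum(
        rate_hs[None, :] * np.exp(-v * rate_hs[None, :]), axis=1
    )
    denom = d_hi + d_hs
    with np.errstate(invalid="ignore", divide="ignore"):
        cond = np.where(denom > 0, d_hi / np.maximum(denom, 1e-300), 1.0)
    return cond


def crossing_point(
    catalog: Catalog,
    f_hi: float,
    e: float,
    level: float = 0.5,
    v_max: int = 1_000_000,
) -> float:
    """Smallest v at which the first-hit conditional reaches ``level``,
    located by bisection on the analytic curve."""
    if e == 0.0:
        raise ValueError("conditional is identically 0 when e = 0")
    lo, hi = 0.0, float(v_max)
    f = lambda v: conditional_first_hit_probability(  # noqa: E731
        catalog, f_hi, e, np.array([v])
    )[0]
    if f(hi) < level:
        raise ValueError(f"conditional does not reach {level} by v={v_max}")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if f(mid) < level:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_accumulation(
    catalog: Catalog,
    f_hi: float,
    e: float,
    v_grid: np.ndarray,
    n_reps: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Monte Carlo oracle for the analytic curves.

    Simulates the generative process variant by variant: with probability e
    a noise variant lands on any gene (proportionally to q), otherwise a
    real variant lands on a tolerant gene. Gene classes are drawn
    Bernoulli(f_hi) per replicate. Returns per-v means of the total and
    per-class distinct-gene counts.
    """
    v_grid = np.asarray(v_grid, dtype=np.int64)
    q = catalog.relative_rates()
    n = len(q)
    rng = np.random.default_rng(seed)
    tot = np.zeros((n_reps, len(v_grid)))
    hi_c = np.zeros((n_reps, len(v_grid)))
    for r in range(n_reps):
        z = rng.random(n) < f_hi  # True = intolerant
        q_hs = np.where(z, 0.0, q)
        q_hs_sum = q_hs.sum()
        if q_hs_sum == 0 and e < 1.0:
            raise ValueError("no tolerant gene with positive rate while e < 1")
        counts = np.zeros(n, dtype=np.int64)
        prev = 0
        for j, v in enumerate(v_grid):
            m = int(v - prev)
            if m > 0:
                n_noise = rng.binomial(m, e)
                if n_noise:
                    counts += rng.multinomial(n_noise, q)
                if m - n_noise:
                    counts += rng.multinomial(m - n_noise, q_hs / q_hs_sum)
                prev = int(v)
            hit = counts > 0
            tot[r, j] = hit.sum()
            hi_c[r, j] = (hit & z).sum()
    return pd.DataFrame(
        {
            "v": v_grid,
            "total": tot.mean(axis=0),
            "hi": hi_c.mean(axis=0),
            "hs": (tot - hi_c).mean(axis=0),
        }
    )
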