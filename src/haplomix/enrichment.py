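"""Gene-set characterization: one-tailed hypergeometric tests with BH-FDR.

Used to ask whether a selection of genes (e.g. those never observed
truncated) over- or under-represents annotated pathways. Overlaps are
counted within the analysis universe; both directions are tested per set
and adjusted jointly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom


@dataclass
class GeneSetTest:
    set_name: str
    universe_size: int
    set_size: int
    selection_size: int
    overlap: int
    direction: str  # "enrichment" or "depletion"
    p_value: float
    p_adjusted: float | None = None
    significant: bool | None = None


def hypergeometric_test(
    universe_size: int,
    set_size: int,
    selection_size: int,
    overlap: int,
    direction: str = "enrichment",
) -> float:
    """One-tailed hypergeometric p-value.

    Enrichment: P(X >= overlap); depletion: P(X <= overlap), where X counts
    set members among ``selection_size`` draws without replacement from a
    universe containing ``set_size`` set members.
    """
    if not (
        0 <= set_size <= universe_size
        and 0 <= selection_size <= universe_size
        and 0 <= overlap <= min(set_size, selection_size)
    ):
        raise ValueError("inconsistent hypergeometric counts")
    if overlap < max(0, set_size + selection_size - universe_size):
        raise ValueError("overlap below feasible minimum")
    rv = hypergeom(universe_size, set_size, selection_size)
    if direction == "enrichment":
        return float(rv.sf(overlap - 1))
    if direction == "depletion":
        return float(rv.cdf(overlap))
    raise ValueError(f"direction must be enrichment or depletion, got {direction!r}")


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, output in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """GMT-style file: one set per line, ``name<TAB>gene1<TAB>gene2...``.

    A second column holding a description URL (classic GMT) is tolerated:
    any field containing '://' or equal to 'na' directly after the name is
    skipped.
    """
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        name, members = fields[0], fields[1:]
        if members and ("://" in members[0] or members[0].lower() == "na"):
            members = members[1:]
        sets[name] = set(members)
    return sets


def test_gene_sets(
    selection: Iterable[str],
    sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    min_set_size: int = 100,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Test every sufficiently large set in both directions, BH-adjusted.

    Sets are intersected with the universe before sizing; sets smaller than
    ``min_set_size`` (after intersection) are skipped. BH is applied jointly
    across all tests performed; rows are flagged significant at ``fdr``.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    selection = set(selection) & universe
    results: list[GeneSetTest] = []
    for name, members in sets.items():
        inset = set(members) & universe
        if len(inset) < min_set_size:
            continue
        overlap = len(inset & selection)
        for direction in ("enrichment", "depletion"):
            p = hypergeometric_test(
                len(universe), len(inset), len(selection), overlap, direction
            )
            results.append(
                GeneSetTest(
                    set_name=name,
                    universe_size=len(universe),
                    set_size=len(inset),
                    selection_size=len(selection),
                    overlap=overlap,
                    direction=direction,
                    p_value=p,
                )
            )
    if not results:
        return pd.DataFrame(
            columns=[
                "set_name", "universe_size", "set_size", "selection_size",
                "overlap", "direction", "p_value", "p_adjusted", "significant",
            ]
        )
    # guard against p underflowing to exactly 0 for extreme overlaps
    adj = bh_adjust([max(r.p_value, 1e-300) for r in results])
    for r, a in zip(results, adj):
        r.p_adjusted = float(a)
        r.significant = bool(a <= fdr)
    df = pd.DataFrame([vars(r) for r in results])
    df.attrs["adjustment"] = "BH joint across all tests (both directions)"
    return df.sort_values(["p_adjusted", "set_name"]).reset_index(drop=True)
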