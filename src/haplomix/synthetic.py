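"""Seeded generators of gene catalogs and variant tables.

The generator emulates the statistical structure the inference assumes: a
catalog of ~16,000 genes with heavy-tailed relative mutation rates, a latent
Bernoulli(f_hi) intolerance label per gene, multinomial PTV counts with a
noise fraction e (relative-rate model) or Poisson counts with class scales
(synonymous-anchored model), and Poisson synonymous counts. Everything is
bit-reproducible under a seed, and the emitted variant tables round-trip
through the catalog module.

Defaults describe the study regime: 16,000 genes, V = 40,000 PTVs, log10
truncation rates Normal(-4.8, 0.4) — a spread at which ~74% of genes
receive at least one PTV under neutral assignment — and synonymous rates a
lognormal multiple (median 3x) of the truncation rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import Catalog, GeneRecord

DEFAULT_RATE_PARAMS = {
    "log10_loc": -4.8,
    "log10_spread": 0.4,
    "syn_ratio_log_mean": float(np.log(3.0)),
    "syn_ratio_log_sd": 0.3,
}


@dataclass
class SyntheticTruth:
    """Ground truth saved alongside every synthetic dataset."""

    n_genes: int
    seed: int
    f_hi: float | None = None
    e: float | None = None
    s_hi: float | None = None
    s_hs: float | None = None
    M: float | None = None
    V: int | None = None
    z: np.ndarray | None = None  # True = intolerant
    rate_distribution: str = (
        "log10 p_trunc ~ Normal(loc, spread); p_syn = p_trunc * LogNormal"
    )

    def to_json(self, path: str | Path) -> None:
        payload = {
            k: v
            for k, v in vars(self).items()
            if k != "z" and v is not None
        }
        if self.z is not None:
            payload["n_hi"] = int(self.z.sum())
            payload["hi_genes"] = np.flatnonzero(self.z).tolist()
        Path(path).write_text(json.dumps(payload, indent=2))


def generate_catalog(
    n_genes: int = 16_000,
    rate_params: dict | None = None,
    seed: int = 0,
) -> Catalog:
    """Draw a gene catalog with heavy-tailed rates and zeroed counts."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rp = dict(DEFAULT_RATE_PARAMS)
    if rate_params:
        rp.update(rate_params)
    rng = np.random.default_rng(seed)
    log10_pt = rng.normal(rp["log10_loc"], rp["log10_spread"], n_genes)
    p_trunc = 10.0 ** log10_pt
    ratio = rng.lognormal(rp["syn_ratio_log_mean"], rp["syn_ratio_log_sd"], n_genes)
    p_syn = p_trunc * ratio
    records = [
        GeneRecord(gene_id=f"G{i:05d}", p_trunc=float(pt), p_syn=float(ps))
        for i, (pt, ps) in enumerate(zip(p_trunc, p_syn))
    ]
    return Catalog.from_records(
        records,
        provenance=[
            f"synthetic catalog: n_genes={n_genes}, seed={seed}, "
            f"rate_params={rp}"
        ],
    )


def assign_labels(catalog: Catalog, f_hi: float, seed: int = 0) -> np.ndarray:
    """Latent intolerance labels z_g ~ Bernoulli(f_hi); True = intolerant."""
    if not (0.0 <= f_hi < 1.0):
        raise ValueError("f_hi must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    return rng.random(len(catalog.genes)) < f_hi


def simulate_counts_model_a(
    catalog: Catalog,
    f_hi: float = 0.25,
    e: float = 0.10,
    V: int = 40_000,
    seed: int = 0,
    z: np.ndarray | None = None,
) -> tuple[Catalog, SyntheticTruth]:
    """Fill o_ptv under the relative-rate generative model.

    Exactly round(V*e) noise variants are assigned multinomially over all
    genes proportionally to p_trunc, and the remaining V - round(V*e) real
    variants over tolerant genes only, so sum(o_ptv) = V holds exactly.
    Synonymous counts are drawn Poisson with a scale matching the PTV yield
    so the catalog is complete. All genes are marked included.
    """
    rng = np.random.default_rng(seed)
    out = catalog.copy()
    p = out.genes["p_trunc"].to_numpy(float)
    if z is None:
        z = rng.random(len(p)) < f_hi
    q = p / p.sum()
    n_noise = int(round(V * e))
    q_hs = np.where(z, 0.0, p)
    if q_hs.sum() == 0 and n_noise < V:
        raise ValueError("no tolerant gene with positive rate while e < 1")
    counts = np.zeros(len(p), dtype=np.int64)
    if n_noise:
        counts += rng.multinomial(n_noise, q)
    if V - n_noise:
        counts += rng.multinomial(V - n_noise, q_hs / q_hs.sum())
    p_syn = out.genes["p_syn"].to_numpy(float)
    # synonymous yield at a scale comparable to the PTV yield per unit rate
    M_syn = V / p.sum()
    o_syn = rng.poisson(M_syn * p_syn)
    out.genes["o_ptv"] = counts
    out.genes["o_ptv_severe"] = 0
    out.genes["o_syn"] = o_syn
    out.genes["o_any"] = counts + o_syn
    out.genes["included"] = True
    out.provenance.append(
        f"model A counts: f_hi={f_hi}, e={e}, V={V}, seed={seed}"
    )
    truth = SyntheticTruth(
        n_genes=len(p), seed=seed, f_hi=f_hi, e=e, V=V, z=z
    )
    return out, truth


def simulate_counts_model_b(
    catalog: Catalog,
    f_hi: float = 0.25,
    s_hi: float = 0.1,
    s_hs: float = 1.0,
    M: float = 1e5,
    seed: int = 0,
    z: np.ndarray | None = None,
) -> tuple[Catalog, SyntheticTruth]:
    """Fill o_ptv and o_syn under the synonymous-anchored generative model.

    o_ptv(g) ~ Poisson(M * p_trunc * s_class(g)); o_syn(g) ~
    Poisson(M * p_syn); independent across genes.
    """
    if M <= 0:
        raise ValueError("M must be positive")
    rng = np.random.default_rng(seed)
    out = catalog.copy()
    p_t = out.genes["p_trunc"].to_numpy(float)
    p_s = out.genes["p_syn"].to_numpy(float)
    if z is None:
        z = rng.random(len(p_t)) < f_hi
    s = np.where(z, s_hi, s_hs)
    o_ptv = rng.poisson(M * p_t * s)
    o_syn = rng.poisson(M * p_s)
    out.genes["o_ptv"] = o_ptv
    out.genes["o_ptv_severe"] = 0
    out.genes["o_syn"] = o_syn
    out.genes["o_any"] = o_ptv + o_syn
    out.genes["included"] = True
    out.provenance.append(
        f"model B counts: f_hi={f_hi}, s_hi={s_hi}, s_hs={s_hs}, M={M}, "
        f"seed={seed}"
    )
    truth = SyntheticTruth(
        n_genes=len(p_t), seed=seed, f_hi=f_hi, s_hi=s_hi, s_hs=s_hs, M=M, z=z
    )
    return out, truth


def emit_variant_table(
    catalog: Catalog,
    allele_number: int = 23_092,
    decoy_fraction: float = 0.0,
    severe_fraction: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Expand per-gene counts into a variant table the catalog module reads.

    Each counted PTV becomes one record (alternating stop-gain/frameshift)
    and each synonymous count one synonymous record. Allele counts follow
    1 + Geometric(0.5), so most variants are singletons and all are rare at
    the default allele number. ``decoy_fraction`` adds common (AF >= 1%)
    stop-gain decoys that the rare filter must remove, and
    ``severe_fraction`` flags that share of PTVs as severe.

    Round-trip guarantee: filter_variants(mode="rare") followed by
    aggregate_counts reproduces the catalog's o_ptv and o_syn exactly.
    """
    rng = np.random.default_rng(seed)
    rows: list[tuple] = []

    def rare_ac() -> int:
        ac = 1 + rng.geometric(0.5) - 1  # support {1, 2, ...}, mostly 1
        return int(min(ac, max(int(0.01 * allele_number) - 1, 1)))

    for _, g in catalog.genes.iterrows():
        for i in range(int(g["o_ptv"])):
            cons = "stop_gained" if i % 2 == 0 else "frameshift_variant"
            severe = bool(rng.random() < severe_fraction)
            rows.append((g["gene"], cons, rare_ac(), allele_number, severe))
        for _ in range(int(g["o_syn"])):
            rows.append(
                (g["gene"], "synonymous_variant", rare_ac(), allele_number, False)
            )
    n_decoys = int(round(decoy_fraction * len(rows)))
    gene_ids = catalog.genes["gene"].to_numpy()
    for _ in range(n_decoys):
        gene = gene_ids[rng.integers(len(gene_ids))]
        ac = int(allele_number * rng.uniform(0.01, 0.5))
        rows.append((gene, "stop_gained", max(ac, int(0.01 * allele_number)),
                     allele_number, False))
    df = pd.DataFrame(rows, columns=["gene", "consequence", "AC", "AN", "severe"])
    return df


def write_dataset(
    out_dir: str | Path,
    catalog: Catalog,
    truth: SyntheticTruth,
    variants: pd.DataFrame | None = None,
) -> None:
    """Write rate table, optional variant table, and the truth sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    catalog.genes[["gene", "p_syn", "p_trunc"]].to_csv(
        out / "rates.tsv", sep="\t", index=False
    )
    catalog.to_tsv(out / "catalog.tsv")
    if variants is not None:
        variants.to_csv(out / "variants.tsv", sep="\t", index=False)
    truth.to_json(out / "truth.json")
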