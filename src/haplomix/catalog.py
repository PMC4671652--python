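"""Gene catalogs and variant tables.

A *catalog* pairs per-gene de novo mutation rates (relative probabilities of
a truncating or synonymous mutation, Samocha-style) with per-gene counts of
observed rare variants. Only rate ratios enter downstream models, so the
absolute scale of the rate columns is irrelevant as long as it is shared.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GENE_COLUMNS = [
    "gene",
    "p_trunc",
    "p_syn",
    "o_ptv",
    "o_ptv_severe",
    "o_syn",
    "o_any",
    "included",
]


class Consequence(str, Enum):
    STOP_GAIN = "stop_gain"
    FRAMESHIFT = "frameshift"
    SPLICE_SITE = "splice_site"
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    OTHER = "other"


# SnpEff / VEP / SO vocabulary -> internal classes. Unknown terms fall
# through to OTHER; the mapping is total by construction.
_STOP_TERMS = {
    "stop_gained",
    "stop_gain",
    "nonsense",
    "stop_gained_variant",
}
_FRAMESHIFT_TERMS = {
    "frameshift",
    "frameshift_variant",
    "frame_shift_ins",
    "frame_shift_del",
}
_SPLICE_TERMS = {
    "splice_donor_variant",
    "splice_acceptor_variant",
    "splice_site",
    "splice_donor",
    "splice_acceptor",
}
_SYN_TERMS = {
    "synonymous_variant",
    "synonymous",
    "synonymous_coding",
    "silent",
}
_MISSENSE_TERMS = {
    "missense_variant",
    "missense",
    "non_synonymous_coding",
    "nonsynonymous",
}


def classify_consequence(term: str, include_splice: bool = False) -> Consequence:
    """Map an annotation consequence term to an internal class.

    ``include_splice`` does not change the class assignment, only whether
    :func:`is_ptv` treats splice-site variants as protein-truncating.
    """
    t = term.strip().lower().replace("&", ",").split(",")[0]
    if t in _STOP_TERMS:
        return Consequence.STOP_GAIN
    if t in _FRAMESHIFT_TERMS or t.startswith("frameshift"):
        return Consequence.FRAMESHIFT
    if t in _SPLICE_TERMS:
        return Consequence.SPLICE_SITE
    if t in _SYN_TERMS:
        return Consequence.SYNONYMOUS
    if t in _MISSENSE_TERMS:
        return Consequence.MISSENSE
    return Consequence.OTHER


def is_ptv(consequence: Consequence, include_splice: bool = False) -> bool:
    """Protein-truncating predicate: stop-gain or frameshift, plus
    splice-site when ``include_splice`` is set."""
    if consequence in (Consequence.STOP_GAIN, Consequence.FRAMESHIFT):
        return True
    return include_splice and consequence is Consequence.SPLICE_SITE


@dataclass
class GeneRecord:
    """Rates and observed counts for one gene."""

    gene_id: str
    p_trunc: float
    p_syn: float
    o_ptv: int = 0
    o_ptv_severe: int = 0
    o_syn: int = 0
    o_any: int = 0
    included: bool = True

    def __post_init__(self) -> None:
        if self.p_trunc < 0 or self.p_syn < 0:
            raise ValueError(f"negative mutation rate for {self.gene_id}")
        if not (self.o_ptv_severe <= self.o_ptv <= self.o_any):
            raise ValueError(
                f"inconsistent counts for {self.gene_id}: "
                f"severe={self.o_ptv_severe} ptv={self.o_ptv} any={self.o_any}"
            )


@dataclass
class VariantRecord:
    """One (variant, gene) annotation."""

    gene_id: str
    consequence: Consequence
    allele_count: int
    allele_number: int
    severe: bool = False
    genotype_counts: tuple[int, int, int] | None = None  # (hom_ref, het, hom_alt)

    def __post_init__(self) -> None:
        if self.allele_count < 1:
            raise ValueError("allele_count must be >= 1")
        if self.allele_number < 1:
            raise ValueError("allele_number must be >= 1")

    @property
    def allele_frequency(self) -> float:
        return self.allele_count / self.allele_number


@dataclass
class Catalog:
    """Ordered collection of genes with counts, backed by a DataFrame."""

    genes: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = set(GENE_COLUMNS) - set(self.genes.columns)
        if missing:
            raise ValueError(f"catalog missing columns: {sorted(missing)}")
        if self.genes["gene"].duplicated().any():
            dups = self.genes.loc[self.genes["gene"].duplicated(), "gene"]
            raise ValueError(f"duplicate gene ids: {sorted(set(dups))[:5]}")

    @property
    def n_genes(self) -> int:
        """Number of included genes."""
        return int(self.genes["included"].sum())

    @property
    def included(self) -> pd.DataFrame:
        return self.genes.loc[self.genes["included"]]

    def relative_rates(self) -> np.ndarray:
        """q_g = p_trunc / sum(p_trunc) over included genes."""
        p = self.included["p_trunc"].to_numpy(float)
        total = p.sum()
        if total <= 0:
            raise ValueError("sum of p_trunc over included genes must be > 0")
        return p / total

    def total_ptv(self) -> int:
        """Total observed PTVs V over included genes."""
        return int(self.included["o_ptv"].sum())

    def copy(self) -> "Catalog":
        return Catalog(self.genes.copy(), list(self.provenance))

    def to_tsv(self, path: str | Path) -> None:
        self.genes[GENE_COLUMNS].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Catalog":
        df = pd.read_csv(path, sep="\t")
        df["included"] = df["included"].astype(bool)
        return cls(df, provenance=[f"loaded from {path}"])

    @classmethod
    def from_records(
        cls, records: Iterable[GeneRecord], provenance: Sequence[str] = ()
    ) -> "Catalog":
        rows = [
            (r.gene_id, r.p_trunc, r.p_syn, r.o_ptv, r.o_ptv_severe, r.o_syn,
             r.o_any, r.included)
            for r in records
        ]
        df = pd.DataFrame(rows, columns=GENE_COLUMNS)
        return cls(df, provenance=list(provenance))


def read_rate_table(path: str | Path, scale_mode: str = "linear") -> list[GeneRecord]:
    """Read a per-gene mutation-rate TSV.

    Accepts either separate ``p_stop``/``p_frameshift`` columns (summed into
    p_trunc) or a single ``p_trunc`` column, alongside ``p_syn``. With
    ``scale_mode="log10"`` rate columns are de-logged first.
    """
    if scale_mode not in ("linear", "log10"):
        raise ValueError(f"scale_mode must be linear or log10, got {scale_mode!r}")
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip() for c in df.columns]
    if "gene" not in df.columns or "p_syn" not in df.columns:
        raise ValueError("rate table requires 'gene' and 'p_syn' columns")
    if "p_trunc" in df.columns:
        rate_cols = ["p_syn", "p_trunc"]
    elif {"p_stop", "p_frameshift"} <= set(df.columns):
        rate_cols = ["p_syn", "p_stop", "p_frameshift"]
    else:
        raise ValueError(
            "rate table requires either 'p_trunc' or both 'p_stop' and "
            "'p_frameshift' columns"
        )
    for c in rate_cols:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    n_before = len(df)
    df = df.dropna(subset=rate_cols)
    df = df[np.isfinite(df[rate_cols]).all(axis=1)]
    n_dropped = n_before - len(df)
    if scale_mode == "log10":
        for c in rate_cols:
            df[c] = 10.0 ** df[c]
    if (df[rate_cols] < 0).any().any():
        raise ValueError("negative linear mutation rates in rate table")
    if df["gene"].duplicated().any():
        dups = sorted(set(df.loc[df["gene"].duplicated(), "gene"]))
        raise ValueError(f"duplicate gene ids in rate table: {dups[:5]}")
    if n_dropped:
        logger.info("read_rate_table: dropped %d rows with missing rates", n_dropped)
    p_trunc = (
        df["p_trunc"]
        if "p_trunc" in rate_cols
        else df["p_stop"] + df["p_frameshift"]
    )
    records = [
        GeneRecord(gene_id=str(g), p_trunc=float(pt), p_syn=float(ps))
        for g, pt, ps in zip(df["gene"], p_trunc, df["p_syn"])
    ]
    return records


def _variant_from_tsv_row(row: pd.Series) -> VariantRecord:
    an = int(row["AN"])
    if an == 0:
        raise ValueError("AN=0: allele number must be positive")
    gt = None
    if {"hom_ref", "het", "hom_alt"} <= set(row.index) and not pd.isna(row["het"]):
        gt = (int(row["hom_ref"]), int(row["het"]), int(row["hom_alt"]))
    return VariantRecord(
        gene_id=str(row["gene"]),
        consequence=classify_consequence(str(row["consequence"])),
        allele_count=int(row["AC"]),
        allele_number=an,
        severe=bool(row.get("severe", False)),
        genotype_counts=gt,
    )


def read_variant_table(path: str | Path, format: str = "tsv") -> list[VariantRecord]:
    """Read a variant table as a list of (variant, gene) records.

    TSV columns: ``gene, consequence, AC, AN, severe[, hom_ref, het, hom_alt]``.
    VCF: per-record ``AC``/``AN`` INFO fields and a ``CSQ``-style or ``GENE``/
    ``CONSEQUENCE`` annotation; multi-gene annotations yield one record per
    gene.
    """
    if format == "tsv":
        df = pd.read_csv(path, sep=None, engine="python")
        required = {"gene", "consequence", "AC", "AN"}
        if not required <= set(df.columns):
            raise ValueError(f"variant TSV requires columns {sorted(required)}")
        if "severe" not in df.columns:
            df["severe"] = False
        return [_variant_from_tsv_row(row) for _, row in df.iterrows()]
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"format must be tsv or vcf, got {format!r}")


def _read_vcf(path: str | Path) -> list[VariantRecord]:
    from cyvcf2 import VCF

    records: list[VariantRecord] = []
    vcf = VCF(str(path))
    for v in vcf:
        ac = v.INFO.get("AC")
        an = v.INFO.get("AN")
        if ac is None or an is None:
            raise ValueError(f"VCF record at {v.CHROM}:{v.POS} lacks AC/AN")
        if isinstance(ac, tuple):
            ac = ac[0]
        an = int(an)
        if an == 0:
            raise ValueError(f"AN=0 at {v.CHROM}:{v.POS}")
        ann = v.INFO.get("ANN") or v.INFO.get("CSQ")
        severe = bool(v.INFO.get("SEVERE", 0))
        if ann is None:
            continue
        # SnpEff ANN: Allele|Annotation|Impact|Gene|... — one entry per gene
        for entry in str(ann).split(","):
            fields = entry.split("|")
            if len(fields) < 4:
                continue
            term, gene = fields[1], fields[3]
            records.append(
                VariantRecord(
                    gene_id=gene,
                    consequence=classify_consequence(term),
                    allele_count=int(ac),
                    allele_number=an,
                    severe=severe,
                )
            )
    return records


def hwe_exact_p(hom_ref: int, het: int, hom_alt: int) -> float:
    """Exact Hardy-Weinberg test p-value conditioned on allele count.

    Sums the probabilities of all heterozygote counts (at fixed sample size
    and minor-allele count) no more probable than the observed one. Computed
    with exact integer arithmetic; feasible because the distribution over het
    counts has at most ``n_minor/2 + 1`` support points.
    """
    if min(hom_ref, het, hom_alt) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = hom_ref + het + hom_alt
    if n == 0:
        return 1.0
    n_alt = 2 * hom_alt + het
    n_minor = min(n_alt, 2 * n - n_alt)
    # weight(h) proportional to n! 2^h / (n_aa! n_ab! n_bb!); use log-gamma
    hs = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_minor = (n_minor - hs) // 2
    hom_major = n - hs - hom_minor
    from scipy.special import gammaln

    logw = (
        hs * math.log(2.0)
        - gammaln(hom_minor + 1)
        - gammaln(hs + 1)
        - gammaln(hom_major + 1)
    )
    logw -= logw.max()
    w = np.exp(logw)
    probs = w / w.sum()
    obs = probs[hs == het]
    if obs.size == 0:  # impossible het count given allele total
        return 1.0
    return float(probs[probs <= obs[0] * (1 + 1e-12)].sum())


@dataclass
class FilterReport:
    n_input: int
    n_kept: int
    n_removed_frequency: int = 0
    n_removed_hwe: int = 0
    n_without_genotypes: int = 0
    mode: str = "rare"


def filter_variants(
    variants: Sequence[VariantRecord],
    mode: str = "rare",
    hwe_alpha: float = 1e-8,
) -> tuple[list[VariantRecord], FilterReport]:
    """Frequency and Hardy-Weinberg filtering.

    mode="rare" keeps allele frequency strictly below 1%; "singleton" keeps
    allele count 1; "all" keeps everything. HWE filtering applies only to
    variants carrying genotype counts.
    """
    if mode not in ("rare", "singleton", "all"):
        raise ValueError(f"mode must be rare, singleton or all, got {mode!r}")
    report = FilterReport(n_input=len(variants), n_kept=0, mode=mode)
    kept: list[VariantRecord] = []
    for v in variants:
        if mode == "rare" and not (v.allele_frequency < 0.01):
            report.n_removed_frequency += 1
            continue
        if mode == "singleton" and v.allele_count != 1:
            report.n_removed_frequency += 1
            continue
        if v.genotype_counts is not None:
            if hwe_exact_p(*v.genotype_counts) < hwe_alpha:
                report.n_removed_hwe += 1
                continue
        else:
            report.n_without_genotypes += 1
        kept.append(v)
    if report.n_without_genotypes == len(variants) and variants:
        logger.warning("no genotype counts available; HWE filter skipped")
    report.n_kept = len(kept)
    return kept, report


def aggregate_counts(
    genes: Sequence[GeneRecord],
    variants: Sequence[VariantRecord],
    include_splice: bool = False,
) -> Catalog:
    """Aggregate filtered variants into per-gene counts.

    Each variant record counts once regardless of carrier number (a rare
    variant is treated as a single de novo mutational event). Genes absent
    from the rate table are dropped with a warning. A gene is included when
    its rates are available and it carries at least one variant of any class.
    """
    by_gene = {g.gene_id: g for g in genes}
    for g in by_gene.values():
        g.o_ptv = g.o_ptv_severe = g.o_syn = g.o_any = 0
    n_unknown = 0
    for v in variants:
        g = by_gene.get(v.gene_id)
        if g is None:
            n_unknown += 1
            continue
        g.o_any += 1
        if is_ptv(v.consequence, include_splice):
            g.o_ptv += 1
            if v.severe:
                g.o_ptv_severe += 1
        elif v.consequence is Consequence.SYNONYMOUS:
            g.o_syn += 1
    if n_unknown:
        logger.warning(
            "aggregate_counts: %d variant records in genes without rates dropped",
            n_unknown,
        )
    for g in by_gene.values():
        g.included = g.o_any >= 1
    prov = [
        f"aggregated {len(variants)} variant records into {len(by_gene)} genes",
        f"{n_unknown} records dropped (gene not in rate table)",
        "inclusion: rates available and >=1 variant of any class",
    ]
    return Catalog.from_records(by_gene.values(), provenance=prov)
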