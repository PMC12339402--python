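"""Gene-to-domain assignment, domain taxonomy and expression statistics.

A gene belongs to a mark's domains when >= 90% (configurable) of its body
overlaps the domain union. Combining per-mark memberships gives a domain
class per gene: in naive mES cells, LADs carry lamin B1, LAP2B and H3K9me2
together, while KODs carry H3K9me2 without the lamina markers. Expression
(TPM) and differential-expression calls are then summarized per class, and
class enrichment of differential genes is tested with a two-sided Fisher's
exact test.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .config import Config
from .core import DomainSet, GenomicInterval, merge_intervals, union_bp

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Class schemes

@dataclass(frozen=True)
class DomainClassScheme:
    """Maps boolean membership patterns over a mark set to class names.

    ``patterns`` must partition the full 2^m pattern space; unnamed
    residual patterns get systematic "+"-joined names.
    """

    marks: Tuple[str, ...]
    patterns: Mapping[Tuple[bool, ...], str]

    def __post_init__(self) -> None:
        expected = set(itertools.product([False, True], repeat=len(self.marks)))
        if set(self.patterns) != expected:
            missing = expected - set(self.patterns)
            raise ValueError(f"patterns do not partition 2^m space; missing {missing}")

    def classify(self, membership: Mapping[str, bool]) -> str:
        key = tuple(bool(membership[m]) for m in self.marks)
        return self.patterns[key]

    @property
    def class_names(self) -> List[str]:
        return sorted(set(self.patterns.values()))


def _systematic_name(marks: Sequence[str], pattern: Sequence[bool]) -> str:
    on = [m for m, p in zip(marks, pattern) if p]
    return "+".join(on) if on else "non-LAD"


def mes_scheme() -> DomainClassScheme:
    """Naive mES cell taxonomy over (LB1, LAP2B, H3K9me2).

    LAD = all three marks; "LB1+LAP2B" = both lamina marks without H3K9me2;
    KOD = H3K9me2 only; non-LAD = none. Residual patterns keep systematic
    names.
    """
    marks = ("LB1", "LAP2B", "H3K9me2")
    patterns = {}
    for pat in itertools.product([False, True], repeat=3):
        lb1, lap2b, k9me2 = pat
        if lb1 and lap2b and k9me2:
            name = "LAD"
        elif lb1 and lap2b:
            name = "LB1+LAP2B"
        elif k9me2 and not lb1 and not lap2b:
            name = "KOD"
        elif not any(pat):
            name = "non-LAD"
        else:
            name = _systematic_name(marks, pat)
        patterns[pat] = name
    return DomainClassScheme(marks, patterns)


def generic_scheme(marks: Sequence[str]) -> DomainClassScheme:
    """Systematic taxonomy over an arbitrary mark set: "+"-joined names for
    each pattern, non-LAD for the empty pattern."""
    marks = tuple(marks)
    patterns = {
        pat: _systematic_name(marks, pat)
        for pat in itertools.product([False, True], repeat=len(marks))
    }
    return DomainClassScheme(marks, patterns)


def epilc_scheme() -> DomainClassScheme:
    """EpiLC taxonomy over (LB1, H3K9me2) only: LAD = both, LB1-only,
    KOD = H3K9me2 only, non-LAD = neither."""
    marks = ("LB1", "H3K9me2")
    patterns = {
        (True, True): "LAD",
        (True, False): "LB1-only",
        (False, True): "KOD",
        (False, False): "non-LAD",
    }
    return DomainClassScheme(marks, patterns)


# ---------------------------------------------------------------------------
# Coverage and class assignment

def gene_domain_coverage(gene: GenomicInterval, domains: DomainSet) -> float:
    """Fraction of the gene body covered by the union of a mark's domains."""
    if len(gene) == 0:
        raise ValueError("zero-length gene")
    covered = sum(gene.overlap(iv) for iv in merge_intervals(domains.intervals))
    return covered / len(gene)


def assign_classes(
    genes: Sequence[GenomicInterval],
    domain_sets: Mapping[str, DomainSet],
    scheme: DomainClassScheme,
    config: Optional[Config] = None,
    biotypes: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Build the per-gene table: coverage and membership per mark, class.

    Membership uses >= config.gene_overlap_fraction (default 0.90) against
    the domain union of each mark. Returns one row per gene with columns
    gene_id, chrom, start, end, biotype, cov_<mark>, in_<mark>,
    domain_class.
    """
    config = config or Config()
    missing = [m for m in scheme.marks if m not in domain_sets]
    if missing:
        raise KeyError(f"domain sets missing for marks: {missing}")
    frac = config.gene_overlap_fraction
    rows = []
    for i, gene in enumerate(genes):
        gid = gene.label if gene.label is not None else f"gene_{i}"
        row: dict = {
            "gene_id": gid, "chrom": gene.chrom,
            "start": gene.start, "end": gene.end,
            "biotype": (biotypes or {}).get(gid, "protein_coding"),
        }
        membership = {}
        for mark in scheme.marks:
            cov = gene_domain_coverage(gene, domain_sets[mark])
            row[f"cov_{mark}"] = cov
            membership[mark] = cov >= frac
            row[f"in_{mark}"] = membership[mark]
        row["domain_class"] = scheme.classify(membership)
        rows.append(row)
    table = pd.DataFrame(rows)
    logger.info(
        "assign_classes: %d genes, overlap fraction %.2f, classes %s",
        len(table), frac,
        dict(table["domain_class"].value_counts()) if len(table) else {},
    )
    return table


# ---------------------------------------------------------------------------
# Overlap accounting (UpSet-style)

def overlap_accounting(
    domain_sets: Mapping[str, DomainSet]
) -> pd.DataFrame:
    """Partition the covered genome by mark-membership pattern; Mb each.

    Returns one row per boolean pattern with any mass, columns
    <mark> (bool per mark), pattern (systematic name), mb. The rows sum to
    the union coverage of all marks.
    """
    marks = list(domain_sets)
    # breakpoint sweep per chromosome
    mass_bp: Dict[Tuple[bool, ...], int] = {}
    chroms = sorted(
        {iv.chrom for ds in domain_sets.values() for iv in ds.intervals}
    )
    for chrom in chroms:
        per_mark = {
            m: merge_intervals(
                [iv for iv in domain_sets[m].intervals if iv.chrom == chrom]
            )
            for m in marks
        }
        points = sorted(
            {p for ivs in per_mark.values() for iv in ivs for p in (iv.start, iv.end)}
        )
        starts = {
            m: np.array([iv.start for iv in ivs])
            for m, ivs in per_mark.items()
        }
        ends = {m: np.array([iv.end for iv in ivs]) for m, ivs in per_mark.items()}
        for a, b in zip(points[:-1], points[1:]):
            pattern = tuple(
                bool(
                    len(starts[m])
                    and (j := np.searchsorted(starts[m], a, side="right") - 1) >= 0
                    and ends[m][j] > a
                )
                for m in marks
            )
            if any(pattern):
                mass_bp[pattern] = mass_bp.get(pattern, 0) + (b - a)
    rows = []
    for pattern, bp in sorted(mass_bp.items(), reverse=True):
        row = {m: p for m, p in zip(marks, pattern)}
        row["pattern"] = _systematic_name(marks, pattern)
        row["mb"] = bp / 1e6
        rows.append(row)
    return pd.DataFrame(rows, columns=[*marks, "pattern", "mb"])


# ---------------------------------------------------------------------------
# Expression and differential expression

def expressed_proportion(
    table: pd.DataFrame, domain_class: str, config: Optional[Config] = None
) -> float:
    """Fraction of a class's genes that are expressed (TPM strictly > 5 by
    default; >= with config.tpm_ge). Empty class -> NaN, with a warning."""
    config = config or Config()
    sub = table[table["domain_class"] == domain_class]
    if len(sub) == 0:
        logger.warning("expressed_proportion: no genes in class %r", domain_class)
        return float("nan")
    if "tpm" not in sub.columns:
        raise KeyError("table lacks a 'tpm' column")
    t = config.tpm_expressed
    expressed = sub["tpm"] >= t if config.tpm_ge else sub["tpm"] > t
    return float(expressed.mean())


def classify_degs(
    de_table: pd.DataFrame,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
) -> pd.Series:
    """Call each gene up/down/unchanged from log2FC and adjusted p.

    up: log2FC strictly > log2(fc_threshold) and p_adj strictly < alpha;
    down symmetric; everything else (including NaN p) unchanged.
    """
    for col in ("log2fc", "padj"):
        if col not in de_table.columns:
            raise KeyError(f"DE table lacks column {col!r}")
    cut = math.log2(fc_threshold)
    lfc, p = de_table["log2fc"], de_table["padj"]
    sig = p < alpha
    status = pd.Series("unchanged", index=de_table.index, name="de_status")
    status[(lfc > cut) & sig] = "up"
    status[(lfc < -cut) & sig] = "down"
    return status


# ---------------------------------------------------------------------------
# Fisher's exact test (two-sided, fixed-margin enumeration)

def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> Tuple[float, float]:
    """Odds ratio and two-sided exact p for the 2x2 table [[a, b], [c, d]].

    p sums hypergeometric probabilities of all tables with the observed
    margins whose probability is <= the observed table's (with a 1e-12
    relative slack for floating-point ties). Zero cells give odds ratios of
    0 or inf; a zero margin gives p = 1 by convention.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
        if a * d == 0 and b * c == 0:
            odds = float("nan")
    else:
        odds = (a * d) / (b * c)
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        logger.info("fisher_exact_two_sided: zero margin, p = 1 by convention")
        return odds, 1.0
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, r1, c1)
    p_obs = hypergeom.pmf(a, n, r1, c1)
    p = float(pmf[pmf <= p_obs * (1 + 1e-12)].sum())
    if p > 1 - 1e-12:  # full support included; absorb float summation error
        p = 1.0
    return odds, min(p, 1.0)


@dataclass(frozen=True)
class EnrichmentResult:
    """Fisher-test result for differential genes within one domain class."""

    domain_class: str
    direction: str
    deg_in_class: int
    deg_out_class: int
    nondeg_in_class: int
    nondeg_out_class: int
    odds_ratio: float
    p_value: float


def deg_class_enrichment(
    table: pd.DataFrame, domain_class: str, direction: str = "up"
) -> EnrichmentResult:
    """Two-sided Fisher's exact test of DEG enrichment in a domain class.

    Rows of the 2x2 table: DEG (of the given direction) vs non-DEG; columns:
    in vs out of the class. The gene universe is every row of the table.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    is_deg = (table["de_status"] == direction).to_numpy()
    in_class = (table["domain_class"] == domain_class).to_numpy()
    a = int(np.sum(is_deg & in_class))
    b = int(np.sum(is_deg & ~in_class))
    c = int(np.sum(~is_deg & in_class))
    d = int(np.sum(~is_deg & ~in_class))
    odds, p = fisher_exact_two_sided(a, b, c, d)
    return EnrichmentResult(domain_class, direction, a, b, c, d, odds, p)


# ---------------------------------------------------------------------------
# mES -> EpiLC transitions

TRANSITION_LABELS = ("cLAD", "cKOD", "newKOD", "LAD->LB1", "non-LAD", "other")


def transition_classes(
    table_mes: pd.DataFrame, table_epilc: pd.DataFrame
) -> pd.DataFrame:
    """Label each gene's domain-class path from naive mES cells to EpiLCs.

    cLAD / cKOD / non-LAD: same class in both states; newKOD: non-LAD into
    KOD; "LAD->LB1": LAD into an LB1-only domain. Anything else is kept
    under "other" rather than forced into a named path.
    """
    mes = table_mes.set_index("gene_id")["domain_class"]
    epi = table_epilc.set_index("gene_id")["domain_class"]
    only_mes = sorted(set(mes.index) - set(epi.index))
    only_epi = sorted(set(epi.index) - set(mes.index))
    if only_mes or only_epi:
        raise ValueError(
            f"gene universes differ; missing from EpiLC table: {only_mes[:10]}, "
            f"missing from mES table: {only_epi[:10]}"
        )

    def label(gene: str) -> str:
        m, e = mes[gene], epi[gene]
        if m == "LAD" and e == "LAD":
            return "cLAD"
        if m == "KOD" and e == "KOD":
            return "cKOD"
        if m == "non-LAD" and e == "KOD":
            return "newKOD"
        if m == "LAD" and e == "LB1-only":
            return "LAD->LB1"
        if m == "non-LAD" and e == "non-LAD":
            return "non-LAD"
        return "other"

    out = pd.DataFrame(
        {
            "gene_id": mes.index,
            "class_mes": mes.to_numpy(),
            "class_epilc": epi.reindex(mes.index).to_numpy(),
        }
    )
    out["transition"] = [label(g) for g in out["gene_id"]]
    return out
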