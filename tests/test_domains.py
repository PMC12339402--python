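"""Gene classification, overlap accounting, DEG calls and Fisher's test."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact as scipy_fisher

from ladkit.config import Config
from ladkit.core import DomainSet, GenomicInterval, union_bp
from ladkit.domains import (
    assign_classes,
    classify_degs,
    deg_class_enrichment,
    epilc_scheme,
    expressed_proportion,
    fisher_exact_two_sided,
    gene_domain_coverage,
    generic_scheme,
    mes_scheme,
    overlap_accounting,
    transition_classes,
)

from conftest import random_disjoint_intervals


def ds(mark, ivs):
    return DomainSet(mark=mark, intervals=ivs)


class TestCoverage:
    def test_ninety_percent_boundary_is_member(self, config):
        gene = GenomicInterval("chr1", 0, 1000, "g")
        exactly = gene_domain_coverage(gene, ds("m", [GenomicInterval("chr1", 0, 900)]))
        below = gene_domain_coverage(gene, ds("m", [GenomicInterval("chr1", 0, 899)]))
        assert exactly == 0.9
        assert exactly >= config.gene_overlap_fraction       # member
        assert below == 0.899
        assert not below >= config.gene_overlap_fraction     # not a member

    def test_coverage_is_against_domain_union(self):
        gene = GenomicInterval("chr1", 0, 1000, "g")
        split = ds("m", [GenomicInterval("chr1", 0, 500),
                         GenomicInterval("chr1", 600, 1000)])
        assert gene_domain_coverage(gene, split) == 0.9

    def test_matches_per_base_oracle(self, rng, small_genome):
        for _ in range(100):
            chrom = "chr1"
            L = small_genome[chrom]
            start = int(rng.integers(0, L - 2000))
            gene = GenomicInterval(chrom, start, start + int(rng.integers(500, 2000)))
            domains = ds("m", random_disjoint_intervals(rng, small_genome))
            cover = np.zeros(L, dtype=bool)
            for iv in domains.intervals:
                if iv.chrom == chrom:
                    cover[iv.start:iv.end] = True
            expected = cover[gene.start:gene.end].mean()
            assert gene_domain_coverage(gene, domains) == pytest.approx(
                expected, abs=1e-12)

    def test_zero_length_gene_rejected(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 5, 5)


class TestSchemes:
    def test_mes_named_patterns(self):
        s = mes_scheme()
        assert s.classify({"LB1": True, "LAP2B": True, "H3K9me2": True}) == "LAD"
        assert s.classify({"LB1": True, "LAP2B": True, "H3K9me2": False}) == "LB1+LAP2B"
        assert s.classify({"LB1": False, "LAP2B": False, "H3K9me2": True}) == "KOD"
        assert s.classify({"LB1": False, "LAP2B": False, "H3K9me2": False}) == "non-LAD"

    def test_patterns_partition_space(self):
        for scheme in (mes_scheme(), epilc_scheme(), generic_scheme(("a", "b"))):
            assert len(scheme.patterns) == 2 ** len(scheme.marks)


class TestAssignClasses:
    def _domains(self):
        lad = [GenomicInterval("chr1", 0, 50_000)]
        return {
            "LB1": ds("LB1", lad),
            "LAP2B": ds("LAP2B", list(lad)),
            "H3K9me2": ds("H3K9me2", [GenomicInterval("chr1", 0, 50_000),
                                      GenomicInterval("chr1", 70_000, 90_000)]),
        }

    def test_full_coverage_classes(self):
        genes = [
            GenomicInterval("chr1", 10_000, 20_000, "lad_gene"),
            GenomicInterval("chr1", 72_000, 80_000, "kod_gene"),
            GenomicInterval("chr1", 92_000, 95_000, "free_gene"),
        ]
        table = assign_classes(genes, self._domains(), mes_scheme())
        got = dict(zip(table["gene_id"], table["domain_class"]))
        assert got == {"lad_gene": "LAD", "kod_gene": "KOD",
                       "free_gene": "non-LAD"}

    def test_classes_partition_gene_universe(self, rng, small_genome):
        genes = [
            GenomicInterval("chr1", int(s), int(s) + 3_000, f"g{i}")
            for i, s in enumerate(rng.integers(0, 90_000, size=200))
        ]
        domain_sets = {
            m: ds(m, random_disjoint_intervals(rng, small_genome))
            for m in ("LB1", "LAP2B", "H3K9me2")
        }
        table = assign_classes(genes, domain_sets, mes_scheme())
        assert table["domain_class"].notna().all()
        assert table["domain_class"].value_counts().sum() == 200

    def test_raising_threshold_shrinks_membership(self, rng, small_genome):
        genes = [
            GenomicInterval("chr1", int(s), int(s) + 3_000, f"g{i}")
            for i, s in enumerate(rng.integers(0, 90_000, size=100))
        ]
        domain_sets = {"m": ds("m", random_disjoint_intervals(rng, small_genome))}
        scheme = generic_scheme(("m",))
        t90 = assign_classes(genes, domain_sets, scheme,
                             Config(gene_overlap_fraction=0.90))
        t95 = assign_classes(genes, domain_sets, scheme,
                             Config(gene_overlap_fraction=0.95))
        assert (t95["in_m"] <= t90["in_m"]).all()

    def test_missing_mark_rejected(self):
        with pytest.raises(KeyError, match="missing"):
            assign_classes([GenomicInterval("chr1", 0, 10, "g")],
                           {"LB1": ds("LB1", [])}, mes_scheme())


class TestOverlapAccounting:
    def test_identical_sets_single_pattern(self):
        ivs = [GenomicInterval("chr1", 0, 1_000_000)]
        table = overlap_accounting({"A": ds("A", ivs), "B": ds("B", list(ivs))})
        assert len(table) == 1
        assert table.iloc[0]["pattern"] == "A+B"
        assert table.iloc[0]["mb"] == 1.0

    def test_disjoint_sets_two_patterns(self):
        table = overlap_accounting({
            "A": ds("A", [GenomicInterval("chr1", 0, 500_000)]),
            "B": ds("B", [GenomicInterval("chr1", 600_000, 800_000)]),
        })
        got = dict(zip(table["pattern"], table["mb"]))
        assert got == {"A": 0.5, "B": 0.2}

    def test_patterns_sum_to_union(self, rng, small_genome):
        domain_sets = {
            m: ds(m, random_disjoint_intervals(rng, small_genome))
            for m in ("A", "B", "C")
        }
        table = overlap_accounting(domain_sets)
        all_ivs = [iv for d in domain_sets.values() for iv in d.intervals]
        assert table["mb"].sum() * 1e6 == pytest.approx(union_bp(all_ivs))


class TestExpression:
    def _table(self, tpms, cls="LAD"):
        return pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(len(tpms))],
            "domain_class": cls,
            "tpm": tpms,
        })

    def test_all_silent(self):
        assert expressed_proportion(self._table([0.0, 0.0, 0.0]), "LAD") == 0.0

    def test_boundary_tpm_five_not_expressed(self):
        assert expressed_proportion(self._table([5.0, 5.0]), "LAD") == 0.0
        cfg = Config(tpm_ge=True)
        assert expressed_proportion(self._table([5.0, 5.0]), "LAD", cfg) == 1.0

    def test_empty_class_flagged_not_zero(self):
        assert math.isnan(expressed_proportion(self._table([1.0]), "KOD"))

    def test_matches_count_and_divide_oracle(self, rng):
        tpms = rng.lognormal(1.5, 1.0, 500)
        got = expressed_proportion(self._table(tpms), "LAD")
        assert got == sum(1 for t in tpms if t > 5) / 500


class TestClassifyDegs:
    def test_boundary_semantics(self):
        table = pd.DataFrame({
            "log2fc": [1.0, 3.0, -2.0, 1.5, 2.0],
            "padj": [0.01, 0.04, 0.01, 0.05, np.nan],
        })
        got = list(classify_degs(table, fc_threshold=2, alpha=0.05))
        # log2FC exactly 1.0 at fc=2 is unchanged (strict >); p exactly
        # alpha is unchanged (strict <); NaN p never significant
        assert got == ["unchanged", "up", "down", "unchanged", "unchanged"]

    def test_counts_match_brute_force(self, rng):
        table = pd.DataFrame({
            "log2fc": rng.normal(0, 2, 1_000),
            "padj": rng.uniform(0, 1, 1_000),
        })
        got = classify_degs(table, 2, 0.05)
        brute_up = sum(
            1 for f, p in zip(table["log2fc"], table["padj"])
            if f > 1.0 and p < 0.05)
        brute_down = sum(
            1 for f, p in zip(table["log2fc"], table["padj"])
            if f < -1.0 and p < 0.05)
        assert (got == "up").sum() == brute_up
        assert (got == "down").sum() == brute_down
        assert (got == "unchanged").sum() == 1_000 - brute_up - brute_down

    def test_missing_columns_rejected(self):
        with pytest.raises(KeyError):
            classify_degs(pd.DataFrame({"log2fc": [1.0]}), 2, 0.05)


def exact_fisher_p(a, b, c, d):
    """Independent rational-arithmetic enumeration of the two-sided p."""
    n, r1, c1 = a + b + c + d, a + b, a + c

    def table_weight(x):
        # number of ways: C(r1, x) * C(n - r1, c1 - x)
        return math.comb(r1, x) * math.comb(n - r1, c1 - x)

    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    w_obs = table_weight(a)
    total = math.comb(n, c1)
    acc = sum(table_weight(x) for x in range(lo, hi + 1)
              if table_weight(x) <= w_obs)
    return acc / total


class TestFisher:
    def test_symmetric_table(self):
        odds, p = fisher_exact_two_sided(5, 5, 5, 5)
        assert odds == 1.0 and p == 1.0

    def test_perfect_association(self):
        odds, p = fisher_exact_two_sided(10, 0, 0, 10)
        assert odds == math.inf
        assert p == pytest.approx(exact_fisher_p(10, 0, 0, 10), rel=1e-12)
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_zero_margin_convention(self):
        _, p = fisher_exact_two_sided(0, 0, 3, 7)
        assert p == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(40):
            a, b, c, d = rng.integers(0, 11, size=4)
            if a + b + c + d == 0:
                continue
            _, p = fisher_exact_two_sided(int(a), int(b), int(c), int(d))
            assert p == pytest.approx(exact_fisher_p(a, b, c, d), rel=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_agrees_with_scipy(self, seed):
        rng = np.random.default_rng(100 + seed)
        a, b, c, d = (int(v) for v in rng.integers(1, 30, size=4))
        _, p = fisher_exact_two_sided(a, b, c, d)
        assert p == pytest.approx(
            scipy_fisher([[a, b], [c, d]]).pvalue, rel=1e-7)

    def test_transpose_symmetry(self, rng):
        for _ in range(20):
            a, b, c, d = (int(v) for v in rng.integers(0, 15, size=4))
            if (a + b) * (a + c) == 0:
                continue
            _, p1 = fisher_exact_two_sided(a, b, c, d)
            _, p2 = fisher_exact_two_sided(a, c, b, d)
            assert p1 == pytest.approx(p2, rel=1e-12)


class TestEnrichment:
    def test_counts_and_result(self):
        table = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(20)],
            "domain_class": ["LAD"] * 10 + ["non-LAD"] * 10,
            "de_status": ["up"] * 8 + ["unchanged"] * 2
                          + ["unchanged"] * 9 + ["up"],
        })
        r = deg_class_enrichment(table, "LAD", "up")
        assert (r.deg_in_class, r.deg_out_class,
                r.nondeg_in_class, r.nondeg_out_class) == (8, 1, 2, 9)
        assert r.odds_ratio == pytest.approx(36.0)
        assert 0 < r.p_value < 0.05


class TestTransitions:
    def _tables(self):
        mes = pd.DataFrame({
            "gene_id": ["a", "b", "c", "d", "e", "f"],
            "domain_class": ["LAD", "KOD", "non-LAD", "LAD", "non-LAD", "KOD"],
        })
        epilc = pd.DataFrame({
            "gene_id": ["a", "b", "c", "d", "e", "f"],
            "domain_class": ["LAD", "KOD", "KOD", "LB1-only", "non-LAD", "LAD"],
        })
        return mes, epilc

    def test_named_paths(self):
        table = transition_classes(*self._tables())
        got = dict(zip(table["gene_id"], table["transition"]))
        assert got == {"a": "cLAD", "b": "cKOD", "c": "newKOD",
                       "d": "LAD->LB1", "e": "non-LAD", "f": "other"}

    def test_labels_partition_universe(self):
        table = transition_classes(*self._tables())
        assert len(table) == 6
        assert table["transition"].notna().all()

    def test_mismatched_universe_rejected(self):
        mes, epilc = self._tables()
        with pytest.raises(ValueError, match="universes differ"):
            transition_classes(mes, epilc.iloc[:-1])
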