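import numpy as np
import pytest

from raescan.ase_io import GenomicInterval
from raescan.genome_context import (
    arm_position_compare,
    assign_genes_to_domains,
    contingency_enrichment,
    density_split,
    domain_enrichment,
    merge_intervals,
    regulatory_complexity,
    strand_overlap_flags,
)


def iv(chrom, start, end, strand=".", id=""):
    return GenomicInterval(chrom, start, end, strand, id or f"{chrom}:{start}-{end}")


class TestAssignGenesToDomains:
    def test_one_bp_overlap_maps(self):
        mapping = assign_genes_to_domains(
            [iv("chr1", 100, 200, id="g")], [iv("chr1", 150, 400, id="d")]
        )
        assert mapping == {"g": ["d"]}

    def test_half_open_abutment_unmapped(self):
        mapping = assign_genes_to_domains(
            [iv("chr1", 100, 150, id="g")], [iv("chr1", 150, 400, id="d")]
        )
        assert mapping == {}

    def test_spanning_gene_counted_in_both(self):
        mapping = assign_genes_to_domains(
            [iv("chr1", 90, 210, id="g")],
            [iv("chr1", 0, 100, id="d1"), iv("chr1", 100, 300, id="d2")],
        )
        assert sorted(mapping["g"]) == ["d1", "d2"]

    def test_chromosome_mismatch(self):
        mapping = assign_genes_to_domains(
            [iv("chr2", 100, 200, id="g")], [iv("chr1", 0, 1000, id="d")]
        )
        assert mapping == {}


def planted_domain_setup():
    """8 RAE + 2 biallelic genes in one domain on a 92/898 background."""
    genes, labels = [], {}
    # background genes on chr2, outside any domain
    for i in range(92):
        genes.append(iv("chr2", i * 1000, i * 1000 + 500, id=f"bg_rae{i}"))
        labels[f"bg_rae{i}"] = "RAE"
    for i in range(898):
        genes.append(iv("chr2", (i + 100) * 1000, (i + 100) * 1000 + 500,
                        id=f"bg_bial{i}"))
        labels[f"bg_bial{i}"] = "Biallelic"
    for i in range(8):
        genes.append(iv("chr1", 100 + i * 10, 105 + i * 10, id=f"in_rae{i}"))
        labels[f"in_rae{i}"] = "RAE"
    for i in range(2):
        genes.append(iv("chr1", 300 + i * 10, 305 + i * 10, id=f"in_bial{i}"))
        labels[f"in_bial{i}"] = "Biallelic"
    domains = [iv("chr1", 0, 1000, id="planted")]
    return genes, labels, domains


class TestDomainEnrichment:
    def test_planted_domain_flagged(self):
        genes, labels, domains = planted_domain_setup()
        mapping = assign_genes_to_domains(genes, domains)
        results, merged = domain_enrichment(mapping, labels, domains)
        (res,) = results
        assert res.unit_id == "planted"
        assert res.odds_ratio == pytest.approx((8 * 898) / (2 * 92), rel=1e-12)
        assert res.significant
        assert len(merged) == 1

    def test_background_ratio_domain_not_flagged(self):
        genes, labels = [], {}
        for i in range(100):
            lab = "RAE" if i % 10 == 0 else "Biallelic"  # 10% RAE everywhere
            chrom = "chr1" if i < 50 else "chr2"
            genes.append(iv(chrom, i * 100, i * 100 + 50, id=f"g{i}"))
            labels[f"g{i}"] = lab
        domains = [iv("chr1", 0, 10000, id="d")]
        mapping = assign_genes_to_domains(genes, domains)
        results, merged = domain_enrichment(mapping, labels, domains)
        (res,) = results
        assert res.odds_ratio == pytest.approx(1.0, abs=0.1)
        assert abs(res.pearson_residuals).max() < 0.2
        assert not res.significant
        assert merged == []

    def test_domain_without_classified_genes_skipped(self):
        genes = [iv("chr1", 0, 10, id="g")]
        labels = {"g": "RAE", "other": "Biallelic"}
        domains = [iv("chr1", 0, 100, id="d1"), iv("chr1", 5000, 6000, id="d2")]
        mapping = assign_genes_to_domains(genes, domains)
        results, _ = domain_enrichment(mapping, labels, domains)
        assert [r.unit_id for r in results] == ["d1"]  # d2 has no genes at all

    def test_order_invariance(self):
        genes, labels, domains = planted_domain_setup()
        domains = domains + [iv("chr1", 2000, 3000, id="empty")]
        m1 = assign_genes_to_domains(genes, domains)
        m2 = assign_genes_to_domains(list(reversed(genes)), list(reversed(domains)))
        r1, _ = domain_enrichment(m1, labels, domains)
        r2, _ = domain_enrichment(m2, labels, domains)
        assert [(r.unit_id, r.p_value) for r in r1] == [
            (r.unit_id, r.p_value) for r in r2
        ]


class TestMergeIntervals:
    def test_overlapping_union(self):
        merged = merge_intervals([iv("chr1", 0, 100), iv("chr1", 50, 150)])
        assert [(m.start, m.end) for m in merged] == [(0, 150)]

    def test_disjoint_sorted(self):
        merged = merge_intervals(
            [iv("chr1", 500, 600), iv("chr1", 0, 100), iv("chr2", 10, 20)]
        )
        assert [(m.chrom, m.start, m.end) for m in merged] == [
            ("chr1", 0, 100), ("chr1", 500, 600), ("chr2", 10, 20)
        ]


class TestStrandOverlapFlags:
    def test_opposite_strand_pair(self):
        flags = strand_overlap_flags(
            [iv("chr1", 100, 200, "+", "A"), iv("chr1", 150, 250, "-", "B")]
        )
        assert flags["A"]["opposite_overlap"] and flags["B"]["opposite_overlap"]
        assert not flags["A"]["same_overlap"]

    def test_same_strand_pair(self):
        flags = strand_overlap_flags(
            [iv("chr1", 100, 200, "+", "A"), iv("chr1", 150, 250, "+", "B")]
        )
        assert flags["A"]["same_overlap"] and not flags["A"]["opposite_overlap"]

    def test_half_open_abutment_no_overlap(self):
        flags = strand_overlap_flags(
            [iv("chr1", 100, 200, "+", "A"), iv("chr1", 200, 300, "-", "B")]
        )
        assert not flags["A"]["opposite_overlap"]
        assert not flags["B"]["opposite_overlap"]

    def test_unknown_strand_excluded(self):
        with pytest.warns(UserWarning, match="unknown strand"):
            flags = strand_overlap_flags(
                [iv("chr1", 0, 10, ".", "dot"), iv("chr1", 5, 15, "+", "A")]
            )
        assert "dot" not in flags


class TestContingencyEnrichment:
    def test_balanced_table_null(self):
        flags = {}
        labels = {}
        k = 0
        for flag in (True, False):
            for lab in ("RAE", "Biallelic"):
                for _ in range(25):
                    flags[f"g{k}"] = flag
                    labels[f"g{k}"] = lab
                    k += 1
        res = contingency_enrichment(flags, labels)
        assert res.p_value == pytest.approx(1.0)
        assert np.allclose(res.pearson_residuals, 0.0)

    def test_hand_computed_chi2(self):
        # table [[30,10],[10,30]]: E = 20 everywhere, chi2 = 4 * 100/20 = 20
        flags, labels = {}, {}
        k = 0
        for n, flag, lab in [(30, True, "RAE"), (10, True, "Biallelic"),
                             (10, False, "RAE"), (30, False, "Biallelic")]:
            for _ in range(n):
                flags[f"g{k}"] = flag
                labels[f"g{k}"] = lab
                k += 1
        res = contingency_enrichment(flags, labels)
        from scipy import stats
        assert res.table.tolist() == [[30, 10], [10, 30]]
        assert -2 * np.log(res.p_value) > 0  # p from chi2 sf
        assert res.p_value == pytest.approx(float(stats.chi2.sf(20.0, 1)), rel=1e-9)
        # residuals: (30-20)/sqrt(20)
        assert res.pearson_residuals[0, 0] == pytest.approx(10 / np.sqrt(20))

    def test_residual_signs(self):
        flags, labels = {}, {}
        k = 0
        for n, flag, lab in [(40, True, "RAE"), (10, True, "Biallelic"),
                             (10, False, "RAE"), (40, False, "Biallelic")]:
            for _ in range(n):
                flags[f"g{k}"] = flag
                labels[f"g{k}"] = lab
                k += 1
        res = contingency_enrichment(flags, labels)
        assert res.pearson_residuals[0, 0] > 0  # observed > expected
        assert res.pearson_residuals[0, 1] < 0

    def test_swap_invariance(self):
        flags, labels = {}, {}
        k = 0
        counts = [(30, True, "RAE"), (10, True, "Biallelic"),
                  (12, False, "RAE"), (28, False, "Biallelic")]
        for n, flag, lab in counts:
            for _ in range(n):
                flags[f"g{k}"] = flag
                labels[f"g{k}"] = lab
                k += 1
        res = contingency_enrichment(flags, labels)
        swapped_flags = {g: not f for g, f in flags.items()}
        swapped_labels = {g: ("Biallelic" if l == "RAE" else "RAE")
                          for g, l in labels.items()}
        res2 = contingency_enrichment(swapped_flags, swapped_labels)
        assert res2.odds_ratio == pytest.approx(res.odds_ratio, rel=1e-12)
        assert res2.p_value == pytest.approx(res.p_value, rel=1e-12)

    def test_zero_margin_named(self):
        flags = {"a": True, "b": False}
        labels = {"a": "RAE", "b": "RAE"}
        with pytest.raises(ValueError, match="Biallelic"):
            contingency_enrichment(flags, labels)


class TestDensitySplit:
    def test_even_count_split(self):
        out = density_split({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0})
        assert out == {"a": "low", "b": "low", "c": "high", "d": "high"}

    def test_exact_median_goes_low(self):
        with pytest.warns(UserWarning, match="median"):
            out = density_split({"a": 1.0, "b": 2.0, "c": 3.0})
        assert out["b"] == "low"

    def test_density_normalisation_contract(self):
        # per-bp density = count / length: doubling length halves density
        count, length = 10.0, 500.0
        assert count / (2 * length) == (count / length) / 2

    def test_identical_values_error(self):
        with pytest.raises(ValueError, match="identical"):
            density_split({"a": 1.0, "b": 1.0})

    def test_every_non_tied_gene_assigned(self, rng):
        values = {f"g{i}": float(v) for i, v in enumerate(rng.normal(size=101))}
        out = density_split(values)
        med = np.median(list(values.values()))
        n_tie = sum(1 for v in values.values() if v == med)
        n_high = sum(1 for s in out.values() if s == "high")
        n_low = len(out) - n_high
        assert len(out) == 101
        assert abs(n_high - n_low) <= n_tie + 1


class TestRegulatoryComplexity:
    def test_maximal_gene_scores_one(self):
        metrics = {f"g{i}": [i, i, i, i] for i in range(5)}
        scores = regulatory_complexity(metrics)
        assert scores["g4"] == 1.0
        assert scores["g0"] == 0.0

    def test_median_gene_scores_half(self):
        metrics = {f"g{i}": [i, i, i, i] for i in range(5)}
        assert regulatory_complexity(metrics)["g2"] == 0.5

    def test_permutation_invariance(self, rng):
        metrics = {f"g{i}": list(rng.normal(size=4)) for i in range(20)}
        a = regulatory_complexity(metrics)
        items = list(metrics.items())
        rng.shuffle(items)
        b = regulatory_complexity(dict(items))
        assert a == b

    def test_monotone_transform_invariance(self, rng):
        metrics = {f"g{i}": list(rng.uniform(0.1, 5, size=4)) for i in range(20)}
        a = regulatory_complexity(metrics)
        transformed = {
            g: [np.log(v[0]), v[1] ** 3, 10 * v[2] + 2, np.exp(v[3])]
            for g, v in metrics.items()
        }
        b = regulatory_complexity(transformed)
        for g in a:
            assert a[g] == pytest.approx(b[g])

    def test_missing_metric_excluded(self):
        metrics = {"a": [1, 2, 3, 4], "b": [2, 3, 4, 5], "c": [1, 2, np.nan, 4]}
        with pytest.warns(UserWarning, match="missing"):
            scores = regulatory_complexity(metrics)
        assert "c" not in scores


class TestArmPositionCompare:
    SIZES = {"chr1": 1000}

    def test_end_proximal_metric_zero(self):
        pos, _, _ = arm_position_compare(
            [iv("chr1", 0, 2)], [iv("chr1", 499, 501)], self.SIZES
        )
        assert pos[0] == pytest.approx(0.001)

    def test_center_metric_half(self):
        _, pos_b, _ = arm_position_compare(
            [iv("chr1", 0, 2)], [iv("chr1", 499, 501)], self.SIZES
        )
        assert pos_b[0] == pytest.approx(0.5)

    def test_planted_separation_significant(self, rng):
        near_ends = [iv("chr1", int(s), int(s) + 10)
                     for s in rng.integers(0, 50, size=30)]
        near_center = [iv("chr1", int(s), int(s) + 10)
                       for s in rng.integers(450, 520, size=30)]
        _, _, p = arm_position_compare(near_ends, near_center, self.SIZES)
        assert p < 0.01

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError, match="past chromosome end"):
            arm_position_compare([iv("chr1", 900, 1100)], [iv("chr1", 0, 10)],
                                 self.SIZES)

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(KeyError):
            arm_position_compare([iv("chrX", 0, 10)], [iv("chr1", 0, 10)],
                                 self.SIZES)
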