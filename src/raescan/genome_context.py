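"""Genomic-context statistics for classified gene sets.

Covers: assignment of genes to topological domains (>= 1 bp overlap,
half-open coordinates), per-domain 2x2 chi-squared enrichment of RAE vs
biallelic genes with BH correction and interval-union merging of significant
domains, sense/antisense gene-overlap flags, generic contingency enrichment
with Pearson residuals, median density splits, percentile-rank regulatory
complexity scores, and a chromosome-arm positional comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from raescan.ase_io import GenomicInterval
from raescan.overdispersion import bh_adjust

__all__ = [
    "EnrichmentResult",
    "assign_genes_to_domains",
    "domain_enrichment",
    "strand_overlap_flags",
    "contingency_enrichment",
    "density_split",
    "regulatory_complexity",
    "arm_position_compare",
    "merge_intervals",
]


@dataclass
class EnrichmentResult:
    """2x2 enrichment of a unit (domain or category) for RAE vs biallelic."""

    unit_id: str
    table: np.ndarray  # rows: in/out (or flag true/false); cols: RAE/Biallelic
    odds_ratio: float
    p_value: float
    q_value: float = float("nan")
    pearson_residuals: np.ndarray | None = None
    significant: bool = False


def _odds_ratio(t: np.ndarray) -> float:
    a, b = float(t[0, 0]), float(t[0, 1])
    c, d = float(t[1, 0]), float(t[1, 1])
    if b * c == 0.0:
        return float("inf") if a * d > 0 else float("nan")
    return (a * d) / (b * c)


def _chi2_table(t: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Pearson chi-squared (no continuity correction) with residuals."""
    t = np.asarray(t, dtype=float)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("contingency table has an empty margin")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    if (expected < 5).any():
        warnings.warn(
            "expected count < 5 in a contingency cell; consider an exact test"
        )
    chi2 = float(((t - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=(t.shape[0] - 1) * (t.shape[1] - 1)))
    residuals = (t - expected) / np.sqrt(expected)
    return chi2, p, residuals


def assign_genes_to_domains(
    genes: Sequence[GenomicInterval], domains: Sequence[GenomicInterval]
) -> dict[str, list[str]]:
    """Map each gene ID to every domain ID it overlaps by >= 1 bp.

    Genes overlapping no domain are absent from the mapping.  A gene spanning
    several domains is mapped to all of them.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for d in domains:
        by_chrom.setdefault(d.chrom, []).append(d)
    for lst in by_chrom.values():
        lst.sort(key=lambda d: d.start)
    mapping: dict[str, list[str]] = {}
    for g in genes:
        hits = [
            d.id
            for d in by_chrom.get(g.chrom, ())
            if d.start < g.end and g.start < d.end
        ]
        if hits:
            mapping[g.id] = hits
    return mapping


def domain_enrichment(
    mapping: Mapping[str, Sequence[str]],
    labels: Mapping[str, str],
    domains: Sequence[GenomicInterval],
    fdr: float = 0.10,
    min_or: float = 1.5,
) -> tuple[list[EnrichmentResult], list[GenomicInterval]]:
    """Per-domain RAE vs biallelic enrichment with BH correction.

    ``labels`` maps gene IDs to 'RAE' or 'Biallelic' (X-linked, imprinted and
    HLA genes must be excluded by the caller).  Each domain's 2x2 table
    crosses in-domain/out-of-domain with RAE/Biallelic, counted over all
    labelled genes.  Domains are significant iff BH q < ``fdr`` and
    odds ratio >= ``min_or``; significant domains are merged by interval
    union per chromosome.
    """
    labelled = {g: c for g, c in labels.items() if c in ("RAE", "Biallelic")}
    total_rae = sum(1 for c in labelled.values() if c == "RAE")
    total_bial = len(labelled) - total_rae
    domain_by_id = {d.id: d for d in domains}
    genes_in_domain: dict[str, set[str]] = {}
    for gene, dom_ids in mapping.items():
        if gene not in labelled:
            continue
        for did in dom_ids:
            genes_in_domain.setdefault(did, set()).add(gene)

    results: list[EnrichmentResult] = []
    for d in sorted(domain_by_id):
        members = genes_in_domain.get(d, set())
        if not members:
            continue  # no classified genes in this domain
        in_rae = sum(1 for g in members if labelled[g] == "RAE")
        in_bial = len(members) - in_rae
        table = np.array(
            [[in_rae, in_bial], [total_rae - in_rae, total_bial - in_bial]],
            dtype=np.int64,
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, p, residuals = _chi2_table(table)
        except ValueError:
            continue  # empty margin: domain not testable
        results.append(
            EnrichmentResult(
                unit_id=d,
                table=table,
                odds_ratio=_odds_ratio(table),
                p_value=p,
                pearson_residuals=residuals,
            )
        )
    if results:
        q = bh_adjust(np.clip([r.p_value for r in results], 1e-300, 1.0))
        for r, qv in zip(results, q):
            r.q_value = float(qv)
            r.significant = bool(qv < fdr and r.odds_ratio >= min_or)
    merged = merge_intervals(
        [domain_by_id[r.unit_id] for r in results if r.significant]
    )
    return results, merged


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union-merge overlapping/abutting intervals per chromosome; output is
    sorted and disjoint."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: x.start)
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(
                    GenomicInterval(chrom, cur_start, cur_end, ".", f"{chrom}:{cur_start}-{cur_end}")
                )
                cur_start, cur_end = iv.start, iv.end
        out.append(
            GenomicInterval(chrom, cur_start, cur_end, ".", f"{chrom}:{cur_start}-{cur_end}")
        )
    return out


def strand_overlap_flags(
    genes: Sequence[GenomicInterval],
) -> dict[str, dict[str, bool]]:
    """Per-gene booleans for >= 1 bp overlap with another locus, split into
    opposite-strand (+/-) and same-strand (+/+ or -/-) overlaps.

    Genes with unknown strand are excluded with a warning.
    """
    stranded = [g for g in genes if g.strand in ("+", "-")]
    skipped = len(genes) - len(stranded)
    if skipped:
        warnings.warn(f"excluding {skipped} genes with unknown strand")
    flags = {
        g.id: {"opposite_overlap": False, "same_overlap": False} for g in stranded
    }
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for g in stranded:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom_genes in by_chrom.values():
        chrom_genes.sort(key=lambda g: g.start)
        for i, a in enumerate(chrom_genes):
            for b in chrom_genes[i + 1 :]:
                if b.start >= a.end:
                    break
                key = "same_overlap" if a.strand == b.strand else "opposite_overlap"
                flags[a.id][key] = True
                flags[b.id][key] = True
    return flags


def contingency_enrichment(
    flags: Mapping[str, bool], labels: Mapping[str, str], unit_id: str = ""
) -> EnrichmentResult:
    """Pearson chi-squared independence test of a boolean gene annotation
    against the RAE/Biallelic labels, with Pearson residuals
    ``(O - E)/sqrt(E)`` giving direction and magnitude.

    Table rows are flag True/False; columns are RAE/Biallelic.
    """
    genes = [g for g in labels if labels[g] in ("RAE", "Biallelic") and g in flags]
    table = np.zeros((2, 2), dtype=np.int64)
    for g in genes:
        row = 0 if flags[g] else 1
        col = 0 if labels[g] == "RAE" else 1
        table[row, col] += 1
    if (table.sum(axis=0) == 0).any():
        empty = "RAE" if table[:, 0].sum() == 0 else "Biallelic"
        raise ValueError(f"no genes in class {empty!r}")
    if (table.sum(axis=1) == 0).any():
        empty = "flag=True" if table[0].sum() == 0 else "flag=False"
        raise ValueError(f"empty category: {empty}")
    chi2, p, residuals = _chi2_table(table)
    return EnrichmentResult(
        unit_id=unit_id,
        table=table,
        odds_ratio=_odds_ratio(table),
        p_value=p,
        pearson_residuals=residuals,
    )


def density_split(values: Mapping[str, float]) -> dict[str, str]:
    """Split genes into 'high'/'low' around the median of a per-bp density.

    Values strictly below the median are 'low', strictly above are 'high';
    exact-median ties fold into 'low' (logged).
    """
    if len(values) < 2:
        raise ValueError("need >= 2 genes to split")
    vals = np.array(list(values.values()), dtype=float)
    if np.ptp(vals) == 0.0:
        raise ValueError("all density values identical; no split possible")
    med = float(np.median(vals))
    out = {g: ("high" if v > med else "low") for g, v in values.items()}
    n_ties = sum(1 for v in values.values() if v == med)
    if n_ties:
        warnings.warn(f"{n_ties} genes exactly at the median assigned to 'low'")
    return out


def regulatory_complexity(
    metrics: Mapping[str, Sequence[float]],
) -> dict[str, float]:
    """Median-of-percentile-ranks regulatory complexity score in [0, 1].

    ``metrics`` maps gene ID to its four metric values (chromatin-state
    kinds, per-bp state density, mean promoter-contact count per tissue,
    enhancer count).  Each metric column is percentile-ranked across genes
    (average rank for ties, min -> 0, max -> 1); the score is the median of
    the four percentiles.  Genes with any missing metric are excluded.
    """
    complete = {
        g: np.asarray(v, dtype=float)
        for g, v in metrics.items()
        if len(v) == 4 and np.isfinite(np.asarray(v, dtype=float)).all()
    }
    n_dropped = len(metrics) - len(complete)
    if n_dropped:
        warnings.warn(f"excluding {n_dropped} genes with missing metrics")
    if len(complete) < 2:
        raise ValueError("need >= 2 genes with complete metrics")
    genes = sorted(complete)
    mat = np.vstack([complete[g] for g in genes])
    n = mat.shape[0]
    pct = np.column_stack(
        [(stats.rankdata(mat[:, j], method="average") - 1.0) / (n - 1.0) for j in range(4)]
    )
    scores = np.median(pct, axis=1)
    return {g: float(s) for g, s in zip(genes, scores)}


def arm_position_compare(
    domains_a: Sequence[GenomicInterval],
    domains_b: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
) -> tuple[np.ndarray, np.ndarray, float]:
    """Compare the relative end-proximal positioning of two interval sets.

    The position metric for an interval is
    ``min(mid, size - mid) / size`` in [0, 0.5] — 0 at a chromosome end,
    0.5 at the exact centre.  Returns the two metric vectors and the
    Kruskal-Wallis rank-test p-value.
    """

    def positions(domains: Sequence[GenomicInterval]) -> np.ndarray:
        vals = []
        for d in domains:
            if d.chrom not in chrom_sizes:
                raise KeyError(f"chromosome {d.chrom!r} not in chrom_sizes")
            size = chrom_sizes[d.chrom]
            if d.end > size:
                raise ValueError(
                    f"interval {d.id!r} extends past chromosome end ({d.end} > {size})"
                )
            mid = d.midpoint
            vals.append(min(mid, size - mid) / size)
        return np.array(vals, dtype=float)

    pos_a = positions(domains_a)
    pos_b = positions(domains_b)
    _, p = stats.kruskal(pos_a, pos_b)
    return pos_a, pos_b, float(p)


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Flatten EnrichmentResults into a TSV-ready table."""
    rows = []
    for r in results:
        rows.append(
            {
                "unit_id": r.unit_id,
                "n11": int(r.table[0, 0]),
                "n12": int(r.table[0, 1]),
                "n21": int(r.table[1, 0]),
                "n22": int(r.table[1, 1]),
                "odds_ratio": r.odds_ratio,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "residual_11": float(r.pearson_residuals[0, 0])
                if r.pearson_residuals is not None
                else float("nan"),
                "significant": r.significant,
            }
        )
    return pd.DataFrame(rows)
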