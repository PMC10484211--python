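"""Population-level aggregation of per-individual RAE calls.

Per-gene significance frequencies across a cohort are standardised into Z
scores over a combined autosomal + XCI reference set; sensitivity/specificity
curves against the XCI positive controls give an empirical Z threshold for
the RAE class; classifications replicated independently in the male and
female cohorts yield high-confidence catalogs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PopulationSummary",
    "ThresholdResult",
    "ReplicationResult",
    "summarize_population",
    "z_scores",
    "derive_threshold",
    "classify_genes",
    "replicate_hc",
    "factor_regression",
]

CLASS_RAE = "RAE"
CLASS_BIALLELIC = "Biallelic"
CLASS_NC = "NotCategorized"
CLASS_UNTESTED = "Untested"

SUMMARY_COLUMNS = [
    "gene_id",
    "n_tested",
    "n_significant",
    "frequency",
    "z",
    "class_label",
]


@dataclass
class PopulationSummary:
    gene_id: str
    n_tested: int
    n_significant: int
    frequency: float
    z: float = float("nan")
    class_label: str = CLASS_UNTESTED


@dataclass
class ThresholdResult:
    """Empirical Z threshold from sensitivity/specificity convergence."""

    z_rae: float
    z_biallelic: float = 0.0
    sensitivity_curve: list[tuple[float, float]] = field(default_factory=list)
    specificity_curve: list[tuple[float, float]] = field(default_factory=list)
    sensitivity_at_threshold: float = float("nan")
    specificity_at_threshold: float = float("nan")
    separable: bool = True

    def curves_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "z": [z for z, _ in self.sensitivity_curve],
                "sensitivity": [s for _, s in self.sensitivity_curve],
                "specificity": [s for _, s in self.specificity_curve],
            }
        )


@dataclass
class ReplicationResult:
    hc_rae: set[str]
    hc_biallelic: set[str]
    chi2: float
    p_value: float
    n_shared: int


def _normalize_calls(
    calls: Mapping[str, pd.DataFrame] | Iterable[tuple[str, pd.DataFrame]],
) -> list[tuple[str, pd.DataFrame]]:
    items = list(calls.items()) if isinstance(calls, Mapping) else list(calls)
    ids = [i for i, _ in items]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate individual IDs: {dupes}")
    if not items:
        raise ValueError("no per-individual call tables supplied")
    return items


def summarize_population(
    calls: Mapping[str, pd.DataFrame] | Iterable[tuple[str, pd.DataFrame]],
    min_individuals: int = 10,
) -> pd.DataFrame:
    """Aggregate per-individual significance tables into per-gene counts.

    Each call table needs ``gene_id`` and ``significant`` columns (the output
    of :func:`raescan.overdispersion.call_individual`).  A gene is *tested*
    in an individual if it appears in that individual's table.  Genes tested
    in fewer than ``min_individuals`` individuals are labelled Untested.
    """
    items = _normalize_calls(calls)
    tested: dict[str, int] = {}
    signif: dict[str, int] = {}
    for _, frame in items:
        genes = frame["gene_id"].to_numpy()
        sig = frame["significant"].to_numpy(dtype=bool)
        for g, s in zip(genes, sig):
            tested[g] = tested.get(g, 0) + 1
            if s:
                signif[g] = signif.get(g, 0) + 1
    gene_ids = sorted(tested)
    n_tested = np.array([tested[g] for g in gene_ids])
    n_sig = np.array([signif.get(g, 0) for g in gene_ids])
    out = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "n_tested": n_tested,
            "n_significant": n_sig,
            "frequency": n_sig / n_tested,
            "z": np.nan,
            "class_label": np.where(
                n_tested < min_individuals, CLASS_UNTESTED, CLASS_NC
            ),
        }
    )
    return out[SUMMARY_COLUMNS]


def z_scores(summaries: pd.DataFrame, combined_set: Iterable[str]) -> pd.DataFrame:
    """Standardise frequencies into Z scores.

    The mean and population (ddof=0) standard deviation are computed over
    ``combined_set`` (the autosomal + XCI reference genes); every gene with a
    frequency — including genes outside the set — receives a Z on that scale.
    Untested genes keep z = NaN.
    """
    combined = set(combined_set)
    tested = summaries["class_label"] != CLASS_UNTESTED
    known = set(summaries.loc[tested, "gene_id"])
    missing = combined - known
    if missing:
        raise ValueError(
            f"{len(missing)} combined-set genes absent from the tested summaries "
            f"(e.g. {sorted(missing)[:3]})"
        )
    ref = summaries.loc[
        tested & summaries["gene_id"].isin(combined), "frequency"
    ].to_numpy()
    if ref.size < 2:
        raise ValueError("combined set must contain >= 2 tested genes")
    mean_f = float(ref.mean())
    sd_f = float(ref.std(ddof=0))
    if sd_f == 0.0:
        raise ValueError("combined-set frequencies are degenerate (sd = 0)")
    out = summaries.copy()
    out.loc[tested, "z"] = (out.loc[tested, "frequency"] - mean_f) / sd_f
    return out


def derive_threshold(
    summaries: pd.DataFrame,
    positives: Iterable[str],
    negatives: Iterable[str],
) -> ThresholdResult:
    """Derive the RAE Z cutoff where sensitivity and specificity converge.

    Over the grid of all observed Z values of the two sets,
    ``sensitivity(z)`` is the fraction of positives (XCI controls) with
    ``Z >= z`` and ``specificity(z)`` the fraction of negatives with
    ``Z < z``; the threshold is the smallest grid value minimising
    ``|sensitivity - specificity|``.
    """
    positives = set(positives)
    negatives = set(negatives)
    if not positives or not negatives:
        raise ValueError("positives and negatives must both be non-empty")
    z_map = summaries.set_index("gene_id")["z"]
    z_pos = z_map.reindex(sorted(positives)).to_numpy(dtype=float)
    z_neg = z_map.reindex(sorted(negatives)).to_numpy(dtype=float)
    if np.isnan(z_pos).any() or np.isnan(z_neg).any():
        raise ValueError("all positives and negatives must have Z scores")
    grid = np.unique(np.concatenate([z_pos, z_neg]))
    sens = (z_pos[None, :] >= grid[:, None]).mean(axis=1)
    spec = (z_neg[None, :] < grid[:, None]).mean(axis=1)
    best = int(np.argmin(np.abs(sens - spec)))  # first index = smallest z on ties
    result = ThresholdResult(
        z_rae=float(grid[best]),
        sensitivity_curve=list(zip(grid.tolist(), sens.tolist())),
        specificity_curve=list(zip(grid.tolist(), spec.tolist())),
        sensitivity_at_threshold=float(sens[best]),
        specificity_at_threshold=float(spec[best]),
    )
    if sens[best] + spec[best] <= 1.1:
        result.separable = False
        warnings.warn(
            "positive and negative Z distributions are barely separable "
            f"(sens={sens[best]:.2f}, spec={spec[best]:.2f} at threshold)"
        )
    return result


def classify_genes(
    summaries: pd.DataFrame,
    thresholds: ThresholdResult,
    biallelic_inclusive: bool = True,
) -> pd.DataFrame:
    """Assign RAE / Biallelic / NotCategorized labels from Z scores.

    RAE iff ``z >= z_rae``; Biallelic iff ``z <= 0`` (or strictly ``< 0``
    with ``biallelic_inclusive=False``); everything else NotCategorized.
    Untested genes are left untouched.
    """
    out = summaries.copy()
    tested = out["class_label"] != CLASS_UNTESTED
    z = out["z"].to_numpy(dtype=float)
    if np.isnan(z[tested.to_numpy()]).any():
        raise ValueError("Z scores must be filled before classification")
    rae = z >= thresholds.z_rae
    bial = (z <= thresholds.z_biallelic) if biallelic_inclusive else (
        z < thresholds.z_biallelic
    )
    labels = np.full(len(out), CLASS_NC, dtype=object)
    labels[bial] = CLASS_BIALLELIC
    labels[rae] = CLASS_RAE  # RAE wins if z_rae <= 0 ever overlaps
    out.loc[tested, "class_label"] = labels[tested.to_numpy()]
    return out


def replicate_hc(
    female_classes: pd.DataFrame, male_classes: pd.DataFrame
) -> ReplicationResult:
    """Intersect classifications from the two sex cohorts.

    hc-RAE is the set of genes labelled RAE in both cohorts; hc-Biallelic
    likewise.  A chi-squared test of independence on the female x male class
    contingency (over genes tested in both) quantifies reproducibility.
    Genes tested in only one cohort cannot replicate and are ignored.
    """
    f = female_classes.set_index("gene_id")["class_label"]
    m = male_classes.set_index("gene_id")["class_label"]
    f = f[f != CLASS_UNTESTED]
    m = m[m != CLASS_UNTESTED]
    shared = f.index.intersection(m.index)
    if len(shared) == 0:
        raise ValueError("no genes tested in both cohorts")
    hc_rae = set(shared[(f[shared] == CLASS_RAE) & (m[shared] == CLASS_RAE)])
    hc_bial = set(
        shared[(f[shared] == CLASS_BIALLELIC) & (m[shared] == CLASS_BIALLELIC)]
    )
    table = pd.crosstab(f[shared], m[shared])
    if table.shape[0] > 1 and table.shape[1] > 1:
        chi2, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    else:
        chi2, p = 0.0, 1.0
    return ReplicationResult(
        hc_rae=hc_rae,
        hc_biallelic=hc_bial,
        chi2=float(chi2),
        p_value=float(p),
        n_shared=int(len(shared)),
    )


def factor_regression(gene_scores, factor) -> tuple[float, float]:
    """Simple OLS of a test statistic on a technical/biological factor.

    Returns (R-squared, slope p-value).  Used per individual (factor vs
    q-values) and at population level (factor vs Z scores).
    """
    y = np.asarray(gene_scores, dtype=float)
    x = np.asarray(factor, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("gene_scores and factor must be equal-length vectors")
    if y.size < 3:
        raise ValueError("need at least 3 points for regression")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0.0:
        raise ValueError("factor has zero variance")
    fit = stats.linregress(x, y)
    return float(fit.rvalue**2), float(fit.pvalue)
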