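"""Synthetic cohorts and the biallelic null-simulation FDR estimate.

``generate_cohort`` emulates the allelic-expression subtypes the test must
distinguish: balanced biallelic genes (binomial, p = 0.5), cis-skewed genes
(binomial with a gene-specific p shared across tissues and individuals),
imprinted-like genes (binomial with p near 0 or 1, consistent direction),
RAE genes (beta-binomial with a gene-specific intra-class correlation rho,
drawn independently per tissue), and an optional XCI-like positive-control
stratum present only in females.

``simulate_null_counts`` implements the biallelic null: the observed totals
``N`` are kept and haplotype-A counts are redrawn as Binomial(N, 0.5);
``estimate_fdr`` runs the full per-individual test on such null data to
measure the empirical false discovery rate.

RNG streams are split hierarchically (cohort -> individual -> gene) with
``numpy.random.SeedSequence`` so that enlarging a cohort never perturbs
existing draws.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from raescan.ase_io import AlleleCountTable
from raescan.overdispersion import call_individual

__all__ = [
    "SyntheticCohortSpec",
    "XciStratumSpec",
    "Cohort",
    "FdrEstimate",
    "generate_cohort",
    "simulate_null_counts",
    "estimate_fdr",
]

CLASS_NAMES = ("biallelic_balanced", "biallelic_skewed", "imprinted_like", "rae")


@dataclass
class XciStratumSpec:
    """XCI-like positive-control genes: present only in female tables, with
    high overdispersion in a ``penetrance`` fraction of individuals."""

    n_genes: int = 40
    rho: float = 0.8
    penetrance: float = 0.9


@dataclass
class SyntheticCohortSpec:
    """Generative parameters for a ground-truth-labelled cohort."""

    n_individuals: int = 20
    n_genes: int = 200
    seed: int = 0
    frac_female: float = 0.5
    tissue_count_range: tuple[int, int] = (5, 30)
    depth_median: float = 100.0
    depth_sigma: float = 0.6
    min_depth_floor: int = 1
    class_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "biallelic_balanced": 0.75,
            "biallelic_skewed": 0.10,
            "imprinted_like": 0.05,
            "rae": 0.10,
        }
    )
    skew_p_range: tuple[float, float] = (0.6, 0.8)
    rae_rho_range: tuple[float, float] = (0.4, 0.8)
    rae_mode: str = "dynamic"  # or "clonal"
    xci_like: XciStratumSpec | None = None

    def __post_init__(self) -> None:
        if self.n_individuals < 1 or self.n_genes < 1:
            raise ValueError("n_individuals and n_genes must be positive")
        missing = set(self.class_proportions) - set(CLASS_NAMES)
        if missing:
            raise ValueError(f"unknown class names: {sorted(missing)}")
        total = sum(self.class_proportions.get(c, 0.0) for c in CLASS_NAMES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions must sum to 1, got {total}")
        if any(v < 0 for v in self.class_proportions.values()):
            raise ValueError("class proportions must be non-negative")
        lo, hi = self.tissue_count_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid tissue_count_range")
        if self.rae_mode not in ("dynamic", "clonal"):
            raise ValueError("rae_mode must be 'dynamic' or 'clonal'")

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticCohortSpec":
        d = json.loads(text)
        if d.get("xci_like") is not None:
            d["xci_like"] = XciStratumSpec(**d["xci_like"])
        for key in ("tissue_count_range", "skew_p_range", "rae_rho_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class Cohort:
    tables: list[AlleleCountTable]
    truth: pd.DataFrame  # gene_id, class, param
    spec: SyntheticCohortSpec

    @property
    def sex_map(self) -> dict[str, str]:
        return {t.individual_id: t.sex for t in self.tables}

    def xci_gene_ids(self) -> list[str]:
        return list(self.truth.loc[self.truth["class"] == "xci_like", "gene_id"])


def _draw_depths(rng: np.random.Generator, spec: SyntheticCohortSpec, size: int) -> np.ndarray:
    n = rng.lognormal(mean=np.log(spec.depth_median), sigma=spec.depth_sigma, size=size)
    return np.maximum(np.round(n).astype(np.int64), spec.min_depth_floor)


def _draw_gene_counts(
    rng: np.random.Generator,
    cls: str,
    param: float,
    N: np.ndarray,
    mode: str,
) -> np.ndarray:
    if cls in ("biallelic_balanced", "biallelic_skewed", "imprinted_like"):
        p = 0.5 if cls == "biallelic_balanced" else param
        return rng.binomial(N, p)
    # beta-binomial with mu = 0.5, intra-class correlation rho = param
    rho = param
    if mode == "clonal":
        # one allele effectively fixed per tissue; rho controls how extreme
        hi = 0.5 + 0.5 * np.sqrt(rho)
        q = np.where(rng.random(N.size) < 0.5, hi, 1.0 - hi)
    else:
        t = (1.0 - rho) / rho
        q = rng.beta(0.5 * t, 0.5 * t, size=N.size)
    return rng.binomial(N, q)


def generate_cohort(spec: SyntheticCohortSpec) -> Cohort:
    """Generate a labelled cohort of phased allele-count tables.

    Gene-level parameters (class, skew p, imprint direction, rho) are fixed
    across individuals; tissue counts and depths are redrawn per individual.
    XCI-like genes receive data only in female tables.
    """
    root = np.random.SeedSequence(spec.seed)
    ss_genes, ss_cohort = root.spawn(2)

    n_auto = spec.n_genes
    probs = [spec.class_proportions.get(c, 0.0) for c in CLASS_NAMES]
    classes = []
    params = np.zeros(n_auto)
    # one stream per gene so enlarging the cohort appends, never reshuffles
    for i, seq in enumerate(ss_genes.spawn(n_auto)):
        grng = np.random.default_rng(seq)
        cls = str(grng.choice(CLASS_NAMES, p=probs))
        classes.append(cls)
        if cls == "biallelic_balanced":
            params[i] = 0.5
        elif cls == "biallelic_skewed":
            p = grng.uniform(*spec.skew_p_range)
            # either haplotype may carry the skew
            params[i] = p if grng.random() < 0.5 else 1.0 - p
        elif cls == "imprinted_like":
            params[i] = 0.98 if grng.random() < 0.5 else 0.02
        else:
            params[i] = grng.uniform(*spec.rae_rho_range)

    gene_ids = [f"GENE{i:05d}" for i in range(n_auto)]
    all_classes = list(classes)
    all_params = list(params)
    if spec.xci_like is not None:
        for k in range(spec.xci_like.n_genes):
            gene_ids.append(f"XCI{k:04d}")
            all_classes.append("xci_like")
            all_params.append(spec.xci_like.rho)
    n_genes = len(gene_ids)

    n_female = int(round(spec.frac_female * spec.n_individuals))
    sexes = ["female"] * n_female + ["male"] * (spec.n_individuals - n_female)
    ind_ids = [
        f"{'F' if s == 'female' else 'M'}{i:04d}" for i, s in enumerate(sexes)
    ]
    lo_t, hi_t = spec.tissue_count_range
    tissues = [f"tissue_{j:02d}" for j in range(hi_t)]

    ind_seqs = ss_cohort.spawn(spec.n_individuals)
    tables: list[AlleleCountTable] = []
    for ind, sex, seq in zip(ind_ids, sexes, ind_seqs):
        gene_seqs = seq.spawn(n_genes)
        X = np.zeros((n_genes, hi_t), dtype=np.int64)
        N = np.zeros((n_genes, hi_t), dtype=np.int64)
        missing = np.ones((n_genes, hi_t), dtype=bool)
        for g in range(n_genes):
            cls = all_classes[g]
            if cls == "xci_like" and sex != "female":
                continue
            rng = np.random.default_rng(gene_seqs[g])
            n_t = int(rng.integers(lo_t, hi_t + 1))
            cols = rng.choice(hi_t, size=n_t, replace=False)
            depths = _draw_depths(rng, spec, n_t)
            if cls == "xci_like":
                if rng.random() < spec.xci_like.penetrance:
                    counts = _draw_gene_counts(
                        rng, "rae", all_params[g], depths, spec.rae_mode
                    )
                else:
                    counts = rng.binomial(depths, 0.5)
            else:
                counts = _draw_gene_counts(
                    rng, cls, all_params[g], depths, spec.rae_mode
                )
            X[g, cols] = counts
            N[g, cols] = depths
            missing[g, cols] = False
        tables.append(
            AlleleCountTable(
                individual_id=ind,
                sex=sex,
                genes=list(gene_ids),
                tissues=list(tissues),
                X=X,
                N=N,
                missing=missing,
            )
        )
    truth = pd.DataFrame(
        {"gene_id": gene_ids, "class": all_classes, "param": all_params}
    )
    return Cohort(tables=tables, truth=truth, spec=spec)


def simulate_null_counts(
    observed: AlleleCountTable, seed: int, p: float | str = 0.5
) -> AlleleCountTable:
    """Biallelic null resample of an observed table.

    Keeps every observed total ``N`` (and the missingness mask) and redraws
    the haplotype-A count as Binomial(N, p) per cell; the second haplotype is
    ``N - X`` by construction.  ``p='observed'`` uses each gene's pooled
    p-hat instead of the default 0.5.
    """
    rng = np.random.default_rng(seed)
    obs = ~observed.missing
    X = np.zeros_like(observed.X)
    if isinstance(p, str):
        if p != "observed":
            raise ValueError("p must be a probability or 'observed'")
        totals = np.where(obs, observed.N, 0).sum(axis=1)
        hapA = np.where(obs, observed.X, 0).sum(axis=1)
        with np.errstate(invalid="ignore"):
            p_gene = np.where(totals > 0, hapA / np.maximum(totals, 1), 0.5)
        P = np.broadcast_to(p_gene[:, None], observed.N.shape)
    else:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p must be in [0, 1], got {p}")
        P = np.full(observed.N.shape, float(p))
    X[obs] = rng.binomial(observed.N[obs], P[obs])
    return AlleleCountTable(
        individual_id=observed.individual_id,
        sex=observed.sex,
        genes=list(observed.genes),
        tissues=list(observed.tissues),
        X=X,
        N=observed.N.copy(),
        missing=observed.missing.copy(),
    )


@dataclass
class FdrEstimate:
    """Null-simulation false discovery rates, with the observed cohort's
    significant fractions for contrast."""

    fdr_grid: tuple[float, ...]
    false_rate_mean: dict[float, float]
    false_rate_sd: dict[float, float]
    false_rate_p05_mean: float
    false_rate_p05_sd: float
    observed_rate: dict[float, float]
    n_reps: int
    n_individuals: int
    per_individual: pd.DataFrame | None = None


def estimate_fdr(
    observed_cohort: Sequence[AlleleCountTable],
    n_reps: int = 1,
    fdr_grid: Sequence[float] = (0.05, 0.10),
    seed: int = 0,
    null_p: float | str = 0.5,
) -> FdrEstimate:
    """Empirical FDR by biallelic null simulation.

    For each individual and each rep, the observed totals are resampled under
    the binomial null and the full per-individual test (LRT + BH) is rerun;
    the fraction of genes falsely significant at each q cutoff — and at raw
    p < 0.05 — is averaged across individuals and reps.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tables = list(observed_cohort)
    if not tables:
        raise ValueError("empty cohort")
    root = np.random.SeedSequence(seed)
    seeds = root.spawn(len(tables) * n_reps)
    rows = []
    for i, table in enumerate(tables):
        obs_calls = call_individual(table)
        n_genes = len(obs_calls)
        for rep in range(n_reps):
            child = seeds[i * n_reps + rep]
            sim = simulate_null_counts(
                table, seed=int(child.generate_state(1)[0]), p=null_p
            )
            calls = call_individual(sim)
            row = {
                "individual_id": table.individual_id,
                "rep": rep,
                "n_genes": n_genes,
                "p05_rate": float((calls["p_value"] < 0.05).mean()),
            }
            for q in fdr_grid:
                row[f"q{q}_rate"] = float((calls["q_value"] < q).mean())
                row[f"observed_q{q}_rate"] = float((obs_calls["q_value"] < q).mean())
            rows.append(row)
    per = pd.DataFrame(rows)
    return FdrEstimate(
        fdr_grid=tuple(fdr_grid),
        false_rate_mean={q: float(per[f"q{q}_rate"].mean()) for q in fdr_grid},
        false_rate_sd={q: float(per[f"q{q}_rate"].std(ddof=0)) for q in fdr_grid},
        false_rate_p05_mean=float(per["p05_rate"].mean()),
        false_rate_p05_sd=float(per["p05_rate"].std(ddof=0)),
        observed_rate={q: float(per[f"observed_q{q}_rate"].mean()) for q in fdr_grid},
        n_reps=n_reps,
        n_individuals=len(tables),
        per_individual=per,
    )
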