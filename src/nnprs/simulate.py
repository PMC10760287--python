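"""Synthetic cohorts with LD-block structure and PRS-driven case status.

Real imputed-biobank genotypes are emulated with a Gaussian-copula haplotype
model: each haplotype's alleles derive from a latent standard-normal vector
with equicorrelation ``rho`` inside a block (identity across blocks and for
blockless SNPs), thresholded at the minor-allele-frequency quantile, and a
genotype is the sum of two independent haplotypes.  A correlated block stands
in for HLA-DQ-style linkage: it is what lets a network recover a removed SNP
from its retained partners.

Disease labels are drawn from a logistic model in the standardized PRS, with
the intercept solved so the cohort hits a target prevalence; the slope
``beta`` sets the achievable case/population AUC.  The train/validation/test
split procedure (case holdout, then 70/15/15 with floor/floor/remainder
rounding) is implemented here as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .prs import (
    HLA_BLOCK_ID,
    GenotypeMatrix,
    PRSDefinition,
    evaluate_prs,
    template_block_snps,
)


@dataclass(frozen=True)
class SnpSpec:
    snp_id: str
    effect_allele: str
    maf: float
    block_id: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(f"maf must lie in (0, 0.5], got {self.maf}")


@dataclass(frozen=True)
class BlockSpec:
    block_id: str
    rho: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho < 1.0):
            raise ValueError(f"rho must lie in [0, 1), got {self.rho}")


@dataclass
class CohortSplits:
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    case_test_idx: dict[str, np.ndarray] = field(default_factory=dict)


def simulate_genotypes(
    n: int,
    snps: list[SnpSpec],
    blocks: list[BlockSpec] | None = None,
    seed: int = 0,
) -> GenotypeMatrix:
    """Draw ``n`` genotypes under the Gaussian-copula haplotype model."""
    if n < 1:
        raise ValueError("n must be >= 1")
    blocks = blocks or []
    rho_of = {b.block_id: b.rho for b in blocks}
    for s in snps:
        if s.block_id is not None and s.block_id not in rho_of:
            raise ValueError(f"SNP {s.snp_id} references undefined block {s.block_id!r}")

    rng = np.random.default_rng(seed)
    p = len(snps)
    thresholds = norm.ppf([s.maf for s in snps])
    genotype = np.zeros((n, p), dtype=float)
    block_cols: dict[str | None, list[int]] = {}
    for j, s in enumerate(snps):
        block_cols.setdefault(s.block_id, []).append(j)

    for _hap in range(2):
        z = rng.standard_normal((n, p))
        for block_id, cols in block_cols.items():
            if block_id is None:
                continue
            rho = rho_of[block_id]
            if rho > 0.0:
                shared = rng.standard_normal((n, 1))
                z[:, cols] = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * z[:, cols]
        genotype += z < thresholds
    return GenotypeMatrix(
        values=genotype,
        snp_ids=[s.snp_id for s in snps],
        effect_alleles=[s.effect_allele for s in snps],
    )


def assign_disease(
    scores: np.ndarray,
    beta: float,
    prevalence_target: float,
    seed: int = 0,
    tol: float = 1e-4,
) -> np.ndarray:
    """Bernoulli case labels with P(case|score) = logistic(alpha + beta·z(score)).

    ``alpha`` is solved by bisection so the mean case probability matches
    ``prevalence_target`` within ``tol``.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if not (0.0 < prevalence_target < 1.0):
        raise ValueError("prevalence_target must lie in (0, 1)")
    scores = np.asarray(scores, dtype=float)
    sd = scores.std()
    z = (scores - scores.mean()) / sd if sd > 0 else np.zeros_like(scores)

    lo, hi = -50.0, 50.0
    for _ in range(200):
        alpha = 0.5 * (lo + hi)
        prev = expit(alpha + beta * z).mean()
        if abs(prev - prevalence_target) <= tol:
            break
        if prev < prevalence_target:
            lo = alpha
        else:
            hi = alpha
    else:
        raise ValueError("target prevalence unattainable with this score distribution")
    rng = np.random.default_rng(seed)
    return rng.random(scores.shape[0]) < expit(alpha + beta * z)


def split_cohort(
    n_total: int,
    case_sets: dict[str, np.ndarray] | None = None,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> CohortSplits:
    """Hold out every case sample into its case test set(s), then split the
    remaining m samples into floor(f_train·m) / floor(f_val·m) / remainder.

    A sample may belong to several case sets (overlapping diagnoses); it is
    then held out once but appears in each of its case test sets.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    case_sets = case_sets or {}
    case_test: dict[str, np.ndarray] = {}
    is_case = np.zeros(n_total, dtype=bool)
    for name, idx in case_sets.items():
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        idx = np.unique(idx.astype(int))
        if idx.size and (idx.min() < 0 or idx.max() >= n_total):
            raise ValueError(f"case set {name!r} indexes outside 0..{n_total - 1}")
        case_test[name] = idx
        is_case[idx] = True

    rest = np.flatnonzero(~is_case)
    m = rest.size
    if m == 0:
        raise ValueError("no samples left after case holdout")
    n_train = int(np.floor(fractions[0] * m))
    n_val = int(np.floor(fractions[1] * m))
    perm = np.random.default_rng(seed).permutation(m)
    shuffled = rest[perm]
    return CohortSplits(
        train_idx=np.sort(shuffled[:n_train]),
        val_idx=np.sort(shuffled[n_train : n_train + n_val]),
        test_idx=np.sort(shuffled[n_train + n_val :]),
        case_test_idx=case_test,
    )


# ---------------------------------------------------------------------------
# End-to-end cohort convenience
# ---------------------------------------------------------------------------


@dataclass
class Cohort:
    """A simulated study: genotypes, ground-truth scores, labels and splits."""

    genotypes: GenotypeMatrix
    prs: PRSDefinition
    scores: np.ndarray
    case_labels: np.ndarray
    splits: CohortSplits

    @property
    def n_samples(self) -> int:
        return self.genotypes.n_samples

    def X(self, idx: np.ndarray) -> np.ndarray:
        return self.genotypes.values[idx]

    def y(self, idx: np.ndarray) -> np.ndarray:
        return self.scores[idx]


def snp_specs_for_prs(
    prs: PRSDefinition,
    rho: float = 0.9,
    maf_range: tuple[float, float] = (0.1, 0.5),
    seed: int = 0,
) -> tuple[list[SnpSpec], list[BlockSpec]]:
    """SnpSpecs for a template PRS: its designated block SNPs share one
    equicorrelated block, all other SNPs are independent; MAFs drawn from
    ``maf_range``."""
    try:
        block_ids = set(template_block_snps(prs.name))
    except ValueError:
        block_ids = set()
    rng = np.random.default_rng(seed)
    specs = [
        SnpSpec(
            snp_id=s,
            effect_allele=a,
            maf=float(rng.uniform(*maf_range)),
            block_id=HLA_BLOCK_ID if s in block_ids else None,
        )
        for s, a in zip(prs.snp_ids, prs.effect_alleles)
    ]
    blocks = [BlockSpec(HLA_BLOCK_ID, rho)] if block_ids else []
    return specs, blocks


def simulate_cohort(
    prs: PRSDefinition,
    n: int,
    seed: int = 0,
    rho: float = 0.9,
    beta: float = 1.5,
    prevalence: float = 0.01,
    case_set_name: str = "cases",
) -> Cohort:
    """Simulate genotypes under the template's LD structure, score them with
    the PRS, draw case labels, hold cases out and split the rest 70/15/15."""
    specs, blocks = snp_specs_for_prs(prs, rho=rho, seed=seed)
    genotypes = simulate_genotypes(n, specs, blocks, seed=seed + 1)
    scores = evaluate_prs(genotypes, prs)
    labels = assign_disease(scores, beta=beta, prevalence_target=prevalence, seed=seed + 2)
    splits = split_cohort(n, {case_set_name: labels}, seed=seed + 3)
    return Cohort(genotypes=genotypes, prs=prs, scores=scores, case_labels=labels, splits=splits)


def save_cohort(cohort: Cohort, prefix: str | Path) -> None:
    """Write genotypes, scores, labels and split index files (one index per line)."""
    from .prs import write_genotypes

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    write_genotypes(cohort.genotypes, f"{prefix}.genotypes.tsv")
    np.savetxt(f"{prefix}.scores.txt", cohort.scores, fmt="%.17g")
    np.savetxt(f"{prefix}.labels.txt", cohort.case_labels.astype(int), fmt="%d")
    s = cohort.splits
    np.savetxt(f"{prefix}.train.idx", s.train_idx, fmt="%d")
    np.savetxt(f"{prefix}.val.idx", s.val_idx, fmt="%d")
    np.savetxt(f"{prefix}.test.idx", s.test_idx, fmt="%d")
    for name, idx in s.case_test_idx.items():
        np.savetxt(f"{prefix}.case_{name}.idx", idx, fmt="%d")
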