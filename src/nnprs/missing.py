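"""Missing-SNP compensation experiments.

SNPs are removed in a seeded permutation; at each evaluated step a linear
predictor, a standard MLP and an autoencoder (composed with the full-SNP MLP
as AE-MLP) are retrained from scratch on the retained SNPs, with the PRS
computed from the *full* SNP set as the label.  The baseline is the PRS
evaluated directly on the reduced SNP set.  Test-set Spearman/RMSE against
the full-SNP PRS and case-vs-population AUC, all with bootstrap CIs, are
reported per step.

The leave-one-SNP-out analysis trains one autoencoder per SNP on the other
SNPs and reports the Pearson correlation between predicted and actual values
of the held-out SNP on the test split — the per-SNP predictability map that
explains when the MLP can beat the reduced PRS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .metrics import MetricReport, auc, bootstrap_ci, pearson, rmse, spearman_rank
from .nets import (
    AE_DEFAULT_CONFIG,
    TrainConfig,
    build_autoencoder,
    build_mlp,
    fit_linear,
    predict_ae_mlp,
    train_autoencoder,
    train_regressor,
)
from .prs import GenotypeMatrix, PRSDefinition, evaluate_prs
from .simulate import Cohort


@dataclass
class SubsetSpec:
    """A removal permutation and the nested retained-SNP index sets.

    ``retained_sets[j]`` holds the column indices still present after ``j``
    removals; step 0 is the full SNP set and each step removes exactly one
    more SNP, following ``removal_order``.
    """

    removal_order: np.ndarray
    retained_sets: list[np.ndarray]
    restrict_to: np.ndarray | None = None

    def __post_init__(self) -> None:
        for j in range(1, len(self.retained_sets)):
            prev, cur = self.retained_sets[j - 1], self.retained_sets[j]
            if len(cur) != len(prev) - 1 or not set(cur).issubset(set(prev)):
                raise ValueError("retained sets must be nested and shrink by 1 per step")

    @property
    def n_steps(self) -> int:
        return len(self.retained_sets) - 1


def make_removal_permutation(
    snp_ids: list[str],
    seed: int = 0,
    restrict_to: list[str] | None = None,
) -> SubsetSpec:
    """Uniform random removal permutation over the eligible SNP pool.

    With ``restrict_to`` only those SNPs are ever removed (e.g. the
    HLA-DQ-like block), so the permutation has at most that many steps.
    """
    p = len(snp_ids)
    all_idx = np.arange(p)
    if restrict_to is None:
        pool = all_idx
        restrict = None
    else:
        missing = set(restrict_to) - set(snp_ids)
        if missing:
            raise ValueError(f"restrict_to contains unknown SNPs: {sorted(missing)}")
        pos = {s: i for i, s in enumerate(snp_ids)}
        restrict = np.asarray(sorted(pos[s] for s in restrict_to))
        pool = restrict
    order = np.random.default_rng(seed).permutation(pool)
    retained = [all_idx.copy()]
    for j in range(len(order)):
        removed = set(order[: j + 1].tolist())
        retained.append(np.asarray([i for i in all_idx if i not in removed]))
    return SubsetSpec(removal_order=order, retained_sets=retained, restrict_to=restrict)


def prs_on_reduced(
    genotypes: GenotypeMatrix, prs: PRSDefinition, retained: np.ndarray
) -> np.ndarray:
    """The PRS evaluated without the removed SNPs: their additive
    contribution is zero (dosage set to 0) and any interaction term touching
    a removed SNP contributes zero."""
    cols = genotypes.column_order(prs.snp_ids)
    keep = set(np.asarray(retained).tolist())
    values = genotypes.values[:, cols].copy()
    removed_positions = [i for i in range(prs.n_snps) if i not in keep]
    values[:, removed_positions] = 0.0
    removed = set(removed_positions)
    reduced = PRSDefinition(
        name=prs.name + "_reduced",
        snp_ids=list(prs.snp_ids),
        effect_alleles=list(prs.effect_alleles),
        additive_weights=prs.additive_weights.copy(),
        interactions=[
            t for t in prs.interactions if t.index_a not in removed and t.index_b not in removed
        ],
        intercept=prs.intercept,
    )
    reduced_geno = GenotypeMatrix(
        values=values,
        snp_ids=list(prs.snp_ids),
        effect_alleles=list(prs.effect_alleles),
    )
    return evaluate_prs(reduced_geno, reduced)


@dataclass
class SubsetResult:
    step: int
    n_retained: int
    metrics: dict[str, dict[str, MetricReport]]  # method -> metric name -> report
    predictions: dict[str, np.ndarray] = field(default_factory=dict)


METHODS = ("prs_reduced", "linear", "mlp", "ae_mlp")


def default_eval_steps(n_steps: int, every: int = 5) -> list[int]:
    """Every ``every``-th removal step plus both endpoints."""
    steps = sorted(set(range(0, n_steps + 1, every)) | {0, n_steps})
    return steps


def _reports(
    pred: np.ndarray,
    y_ref: np.ndarray,
    case_scores: np.ndarray | None,
    n_boot: int,
    seed: int,
) -> dict[str, MetricReport]:
    out = {
        "spearman": bootstrap_ci(
            spearman_rank, (pred, y_ref), metric_name="spearman", n_boot=n_boot, seed=seed
        ),
        "rmse": bootstrap_ci(rmse, (pred, y_ref), metric_name="rmse", n_boot=n_boot, seed=seed),
    }
    if case_scores is not None:
        out["auc"] = bootstrap_ci(
            auc, (case_scores, pred), metric_name="auc",
            n_boot=n_boot, seed=seed, stratified=True,
        )
    return out


def run_subset_experiment(
    cohort: Cohort,
    subset: SubsetSpec,
    steps_to_eval: list[int] | None = None,
    cfg: TrainConfig | None = None,
    ae_cfg: TrainConfig | None = None,
    n_boot: int = 200,
    seed: int = 0,
    keep_predictions: bool = False,
) -> list[SubsetResult]:
    """Retrain linear/MLP/AE per retained-SNP subset and score all methods.

    The full-SNP MLP (needed by every AE-MLP composition) is trained once at
    step 0.  Labels are always the full-SNP PRS; metrics are computed on the
    test split, and AUC compares the held-out case set against the
    population test set when the cohort has one.
    """
    prs = cohort.prs
    cfg = cfg or TrainConfig()
    ae_cfg = ae_cfg or replace(AE_DEFAULT_CONFIG, max_epochs=cfg.max_epochs,
                               patience=cfg.patience, eval_every=cfg.eval_every)
    steps = steps_to_eval if steps_to_eval is not None else default_eval_steps(subset.n_steps)
    s = cohort.splits
    cols_full = cohort.genotypes.column_order(prs.snp_ids)
    X_all = cohort.genotypes.values[:, cols_full]
    y = cohort.scores
    tr, va, te = s.train_idx, s.val_idx, s.test_idx
    case_idx = None
    if s.case_test_idx:
        case_idx = next(iter(s.case_test_idx.values()))

    mlp_full = build_mlp(prs.n_snps, seed=cfg.seed, input_snp_ids=list(prs.snp_ids))
    train_regressor(mlp_full, X_all[tr], y[tr], X_all[va], y[va], cfg)

    results = []
    for step in steps:
        retained = subset.retained_sets[step]
        if retained.size == 0:
            warnings.warn(f"step {step} retains no SNPs; skipped")
            continue
        Xs = X_all[:, retained]
        retained_ids = [prs.snp_ids[i] for i in retained]

        preds: dict[str, np.ndarray] = {}
        case_preds: dict[str, np.ndarray] = {}

        preds["prs_reduced"] = prs_on_reduced(cohort.genotypes, prs, retained)

        lin = fit_linear(Xs[tr], y[tr])
        preds["linear"] = lin.predict(Xs)

        if step == 0:
            mlp = mlp_full
        else:
            mlp = build_mlp(retained.size, seed=cfg.seed + step,
                            input_snp_ids=retained_ids)
            train_regressor(mlp, Xs[tr], y[tr], Xs[va], y[va], cfg)
        preds["mlp"] = mlp.predict(Xs)

        ae = build_autoencoder(retained.size, prs.n_snps, seed=ae_cfg.seed + step,
                               input_snp_ids=retained_ids, output_names=list(prs.snp_ids))
        train_autoencoder(ae, Xs[tr], X_all[tr], Xs[va], X_all[va], ae_cfg)
        preds["ae_mlp"] = predict_ae_mlp(ae, mlp_full, Xs)

        metrics = {}
        for method, pred in preds.items():
            case_scores = pred[case_idx] if case_idx is not None else None
            metrics[method] = _reports(pred[te], y[te], case_scores, n_boot, seed)
        res = SubsetResult(step=step, n_retained=int(retained.size), metrics=metrics)
        if keep_predictions:
            res.predictions = {m: p[te] for m, p in preds.items()}
        results.append(res)
    return results


@dataclass
class LeaveOneOutResult:
    snp_id: str
    r: float
    degenerate: bool = False


def leave_one_out_predictability(
    cohort: Cohort,
    cfg: TrainConfig | None = None,
    snp_subset: list[str] | None = None,
) -> list[LeaveOneOutResult]:
    """Per-SNP autoencoder predictability: for each SNP, train an AE on the
    remaining SNPs and report the test-split Pearson correlation between its
    predicted and actual values.  A constant (degenerate-variance) column is
    reported as r = 0 with a flag."""
    prs = cohort.prs
    cfg = cfg or AE_DEFAULT_CONFIG
    cols = cohort.genotypes.column_order(prs.snp_ids)
    X = cohort.genotypes.values[:, cols]
    s = cohort.splits
    tr, va, te = s.train_idx, s.val_idx, s.test_idx
    targets = snp_subset if snp_subset is not None else list(prs.snp_ids)
    pos = {sid: i for i, sid in enumerate(prs.snp_ids)}

    out = []
    for sid in targets:
        i = pos[sid]
        keep = np.asarray([j for j in range(prs.n_snps) if j != i])
        ae = build_autoencoder(keep.size, prs.n_snps, seed=cfg.seed + i,
                               input_snp_ids=[prs.snp_ids[j] for j in keep],
                               output_names=list(prs.snp_ids))
        train_autoencoder(ae, X[tr][:, keep], X[tr], X[va][:, keep], X[va], cfg)
        actual = X[te][:, i]
        if actual.std() == 0.0:
            out.append(LeaveOneOutResult(snp_id=sid, r=0.0, degenerate=True))
            continue
        predicted = ae.forward(X[te][:, keep])[:, i]
        out.append(LeaveOneOutResult(snp_id=sid, r=pearson(predicted, actual)))
    return out


def results_to_rows(results: list[SubsetResult]) -> list[dict]:
    """Flatten to tidy rows (step, method, metric, estimate, ci_lo, ci_hi)."""
    rows = []
    for res in results:
        for method, reports in res.metrics.items():
            for metric, rep in reports.items():
                rows.append({
                    "step": res.step, "n_retained": res.n_retained,
                    "method": method, "metric": metric,
                    "estimate": rep.estimate, "ci_lo": rep.ci_low, "ci_hi": rep.ci_high,
                })
    return rows
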