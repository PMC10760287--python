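"""Model-variant catalogue for probing performance limits.

With a fixed retained-SNP subset, a family of MLP variants is trained on the
same task as the standard model (``Orig``): a hyperparameter grid search,
four capacity variants (shallower/deeper/wider), a skip-connection model
whose input is passed unweighted to the last hidden layer, and a model whose
input is expanded with all pairwise products.  If none of them beats the
standard MLP, the performance ceiling is evidence of an information limit in
the inputs rather than a modelling limit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .metrics import MetricReport, pearson
from .missing import SubsetSpec, _reports
from .nets import (
    STANDARD_HIDDEN,
    NetworkSpec,
    TrainConfig,
    TrainedNetwork,
    build_mlp,
    train_regressor,
)
from .simulate import Cohort

VARIANT_NAMES = (
    "Orig", "Hyperparams", "Capacity1", "Capacity2", "Capacity3", "Capacity4",
    "Skip", "Pairwise",
)

HYPERPARAM_GRID = {"learning_rate": (1e-3, 1e-4, 1e-5), "batch_size": (5, 20, 100)}


def expand_pairwise(x: np.ndarray) -> np.ndarray:
    """Append all pairwise products: (x_1..x_p, x_1x_2, x_1x_3, …, x_{p-1}x_p).

    Output length p + p(p-1)/2; products ordered lexicographically by (i, j),
    i < j.  Accepts a single vector or a samples × p matrix.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    p = X.shape[1]
    iu, ju = np.triu_indices(p, k=1)
    out = np.hstack([X, X[:, iu] * X[:, ju]])
    return out[0] if single else out


def pairwise_width(p: int) -> int:
    return p + p * (p - 1) // 2


@dataclass
class VariantPlan:
    name: str
    spec: NetworkSpec
    config: TrainConfig
    config_grid: list[TrainConfig] | None = None  # Hyperparams only
    expand_input: bool = False  # Pairwise only


def make_variant(
    name: str,
    input_width: int,
    base_config: TrainConfig | None = None,
    grid: dict | None = None,
) -> VariantPlan:
    """Build the network spec and training configuration of one catalogue
    variant for ``input_width`` retained SNPs."""
    base = base_config or TrainConfig()
    if name in ("Orig", "Capacity1"):
        spec = NetworkSpec(input_width, STANDARD_HIDDEN)
    elif name == "Hyperparams":
        spec = NetworkSpec(input_width, STANDARD_HIDDEN)
        grid = grid or HYPERPARAM_GRID
        configs = [
            replace(base, learning_rate=lr, batch_size=bs)
            for lr in grid["learning_rate"]
            for bs in grid["batch_size"]
        ]
        return VariantPlan(name=name, spec=spec, config=base, config_grid=configs)
    elif name == "Capacity2":
        spec = NetworkSpec(input_width, (200,))
    elif name == "Capacity3":
        spec = NetworkSpec(input_width, (55, 50, 40, 30, 25, 15, 5))
    elif name == "Capacity4":
        spec = NetworkSpec(input_width, (200, 160, 120, 90, 70, 50, 10))
    elif name == "Skip":
        spec = NetworkSpec(input_width, STANDARD_HIDDEN, skip_input_to_last_hidden=True)
    elif name == "Pairwise":
        spec = NetworkSpec(pairwise_width(input_width), STANDARD_HIDDEN)
        return VariantPlan(name=name, spec=spec, config=base, expand_input=True)
    else:
        raise ValueError(f"unknown variant {name!r}; choose from {VARIANT_NAMES}")
    return VariantPlan(name=name, spec=spec, config=base)


def ensemble_average(predictions: list[np.ndarray]) -> np.ndarray:
    """Elementwise arithmetic mean of the model predictions."""
    if not predictions:
        raise ValueError("need at least one prediction vector")
    stack = np.vstack([np.asarray(p, dtype=float).ravel() for p in predictions])
    return stack.mean(axis=0)


def _train_plan(plan: VariantPlan, Xtr, ytr, Xv, yv, seed: int) -> TrainedNetwork:
    if plan.expand_input:
        Xtr, Xv = expand_pairwise(Xtr), expand_pairwise(Xv)
    if plan.config_grid:
        best = None
        for k, cfg in enumerate(plan.config_grid):
            net = build_mlp(plan.spec.input_width, plan.spec.hidden_widths,
                            seed=seed + k,
                            skip_input_to_last_hidden=plan.spec.skip_input_to_last_hidden)
            train_regressor(net, Xtr, ytr, Xv, yv, replace(cfg, seed=seed + k))
            val = float(np.mean((net.predict(Xv) - yv) ** 2))
            if best is None or val < best[0]:
                best = (val, net)
        return best[1]
    net = build_mlp(plan.spec.input_width, plan.spec.hidden_widths, seed=seed,
                    skip_input_to_last_hidden=plan.spec.skip_input_to_last_hidden)
    train_regressor(net, Xtr, ytr, Xv, yv, replace(plan.config, seed=seed))
    return net


@dataclass
class VariantStudy:
    metrics: dict[str, dict[str, MetricReport]]  # variant -> metric -> report
    predictions: dict[str, np.ndarray]  # variant -> test-split predictions
    agreement_with_orig: dict[str, float]  # Pearson r of predictions vs Orig
    ensemble: dict[str, MetricReport]


def run_variant_study(
    cohort: Cohort,
    subset: SubsetSpec,
    step: int,
    cfg: TrainConfig | None = None,
    variants: tuple[str, ...] = VARIANT_NAMES,
    grid: dict | None = None,
    n_boot: int = 200,
    seed: int = 0,
) -> VariantStudy:
    """Train every catalogue variant on one retained-SNP subset and compare.

    All variants share the train/validation/test splits and the full-SNP PRS
    label; reports are Spearman/RMSE against the label plus case AUC, with
    bootstrap CIs, alongside per-variant prediction agreement with ``Orig``
    and the metrics of the ensemble (mean of all variant predictions).
    """
    prs = cohort.prs
    cfg = cfg or TrainConfig()
    retained = subset.retained_sets[step]
    cols = cohort.genotypes.column_order(prs.snp_ids)
    X = cohort.genotypes.values[:, cols][:, retained]
    y = cohort.scores
    s = cohort.splits
    tr, va, te = s.train_idx, s.val_idx, s.test_idx
    case_idx = next(iter(s.case_test_idx.values())) if s.case_test_idx else None

    metrics: dict[str, dict[str, MetricReport]] = {}
    preds: dict[str, np.ndarray] = {}
    for i, name in enumerate(variants):
        plan = make_variant(name, retained.size, base_config=cfg, grid=grid)
        net = _train_plan(plan, X[tr], y[tr], X[va], y[va], seed=cfg.seed + 100 * i)
        X_eval = expand_pairwise(X) if plan.expand_input else X
        full_pred = net.predict(X_eval)
        preds[name] = full_pred[te]
        case_scores = full_pred[case_idx] if case_idx is not None else None
        metrics[name] = _reports(full_pred[te], y[te], case_scores, n_boot, seed)

    agreement = {
        name: pearson(preds[name], preds["Orig"])
        for name in preds if name != "Orig"
    }
    ens = ensemble_average(list(preds.values()))
    ensemble_reports = _reports(ens, y[te], None, n_boot, seed)
    return VariantStudy(
        metrics=metrics, predictions=preds,
        agreement_with_orig=agreement, ensemble=ensemble_reports,
    )
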