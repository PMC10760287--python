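"""Canonical scaled-down study recipes.

The headline experiments were originally run on a ~487k-sample biobank;
these functions re-run their synthetic analogues at desk scale with fixed
cohort sizes and training lengths, so results are comparable across
machines and reproducible from a single seed.

Training length: learning rate and batch size follow the published training
setup (1e-4 / 5 for score regression, 5e-5 / 5 for the autoencoder); epoch
counts are not published, so each recipe trains until validation MSE stops
improving under a generous cap chosen to reach the convergence plateau at
its cohort size.
"""

from __future__ import annotations

from dataclasses import dataclass

from .metrics import rmse, spearman_rank
from .nets import TrainConfig, build_mlp, train_regressor
from .prs import make_template_prs
from .simulate import simulate_cohort

# study-scale training configuration for PRS recreation: published
# hyperparameters, convergence-plateau epoch cap (see docs/methods.md)
RECREATION_CONFIG = TrainConfig(
    learning_rate=1e-4, batch_size=5, max_epochs=80, patience=15, eval_every=2000
)


@dataclass
class RecreationResult:
    template: str
    n_samples: int
    n_train: int
    spearman: float
    rmse: float
    iterations: int


def prs_recreation_study(
    template: str,
    n: int,
    seed: int = 1,
    cfg: TrainConfig | None = None,
) -> RecreationResult:
    """Recreate a template PRS with the standard MLP and measure test-split
    fidelity.

    Simulates an ``n``-sample cohort under the template's LD structure
    (rho = 0.9 on its designated block), holds out cases, splits 70/15/15,
    trains the standard MLP on the full SNP set with the programmed PRS as
    the label, and reports Spearman and RMSE between MLP predictions and the
    true score on the test split.
    """
    prs = make_template_prs(template, seed=seed)
    cohort = simulate_cohort(prs, n, seed=seed)
    s = cohort.splits
    cfg = cfg or RECREATION_CONFIG
    cfg = TrainConfig(**{**cfg.__dict__, "seed": seed})
    net = build_mlp(prs.n_snps, seed=seed, input_snp_ids=list(prs.snp_ids))
    train_regressor(net, cohort.X(s.train_idx), cohort.y(s.train_idx),
                    cohort.X(s.val_idx), cohort.y(s.val_idx), cfg)
    pred = net.predict(cohort.X(s.test_idx))
    return RecreationResult(
        template=template,
        n_samples=n,
        n_train=int(s.train_idx.size),
        spearman=spearman_rank(pred, cohort.y(s.test_idx)),
        rmse=rmse(pred, cohort.y(s.test_idx)),
        iterations=int(net.history[-1]["iteration"]),
    )
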