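"""Training-set-size sweep: how much data does PRS recreation need?

Retrains the standard MLP on nested subsamples of the training split and
reports case AUC, Spearman and RMSE on the fixed test split with bootstrap
CIs.  Performance typically degrades only modestly until the training set
falls into the low thousands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import MetricReport
from .missing import _reports
from .nets import TrainConfig, build_mlp, train_regressor
from .simulate import Cohort


@dataclass
class SweepResult:
    size: int
    metrics: dict[str, MetricReport]


def training_size_sweep(
    cohort: Cohort,
    sizes: list[int],
    cfg: TrainConfig | None = None,
    n_boot: int = 200,
    seed: int = 0,
) -> list[SweepResult]:
    """Train the standard MLP on the first ``size`` samples of a fixed
    shuffle of the training split, for each requested size (nested subsets),
    evaluating on the unchanged validation and test splits."""
    prs = cohort.prs
    cfg = cfg or TrainConfig()
    s = cohort.splits
    cols = cohort.genotypes.column_order(prs.snp_ids)
    X = cohort.genotypes.values[:, cols]
    y = cohort.scores
    rng = np.random.default_rng(seed)
    shuffled_train = s.train_idx[rng.permutation(s.train_idx.size)]
    case_idx = next(iter(s.case_test_idx.values())) if s.case_test_idx else None

    results = []
    for size in sizes:
        if size < 1 or size > shuffled_train.size:
            raise ValueError(f"size {size} outside 1..{shuffled_train.size}")
        tr = shuffled_train[:size]
        net = build_mlp(prs.n_snps, seed=cfg.seed, input_snp_ids=list(prs.snp_ids))
        train_regressor(net, X[tr], y[tr], X[s.val_idx], y[s.val_idx], cfg)
        pred = net.predict(X)
        case_scores = pred[case_idx] if case_idx is not None else None
        results.append(
            SweepResult(size=size, metrics=_reports(pred[s.test_idx], y[s.test_idx],
                                                    case_scores, n_boot, seed))
        )
    return results
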