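"""Compensate for missing SNPs with retrained models.

Removes SNPs from a 67-SNP score's correlated (HLA-DQ-like) block in a
random permutation and, at selected steps, retrains a linear predictor, a
standard MLP and an autoencoder+MLP composition on the retained SNPs with
the full-SNP PRS as the label.  The baseline is the PRS evaluated without
the removed SNPs.  Because block SNPs are mutually predictable through LD,
the networks recover much of the lost interaction signal and beat the
reduced PRS; linear reweighting recovers less.
"""

import nnprs
from nnprs.missing import make_removal_permutation, run_subset_experiment
from nnprs.nets import TrainConfig

prs = nnprs.make_template_prs("T1D67-like", seed=1)
cohort = nnprs.simulate_cohort(prs, 20_000, seed=1)
block = nnprs.template_block_snps("T1D67-like")
subset = make_removal_permutation(prs.snp_ids, seed=1, restrict_to=block)

results = run_subset_experiment(
    cohort, subset, steps_to_eval=[5, 10, 13],
    cfg=TrainConfig(max_epochs=20, patience=6, seed=1), n_boot=100, seed=1,
)

print("test-split Spearman vs the full 67-SNP PRS "
      "(removals confined to the 14-SNP correlated block):")
print(f"{'removed':>8} {'reduced PRS':>12} {'linear':>8} {'MLP':>8} {'AE-MLP':>8}")
for r in results:
    m = {k: r.metrics[k]["spearman"].estimate for k in r.metrics}
    print(f"{67 - r.n_retained:>8} {m['prs_reduced']:>12.4f} {m['linear']:>8.4f} "
          f"{m['mlp']:>8.4f} {m['ae_mlp']:>8.4f}")
print("MLP and AE-MLP track each other and sit well above the reduced PRS: "
      "the networks impute the removed block SNPs from their retained LD "
      "partners (once the last partner goes, nothing is recoverable and all "
      "methods collapse to the reduced PRS)")
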