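"""Export a trained network as a plain-text bundle and score with matrix
arithmetic only.

The bundle holds the ordered SNP list and, per layer, an activation tag, the
weight matrix and the bias row, all as decimal text.  Any tool that can do
multiply-add and max can evaluate it; here the bundle's own forward pass is
checked against the in-memory network.
"""

import numpy as np

import nnprs

prs = nnprs.make_template_prs("T1D10-like", seed=3)
cohort = nnprs.simulate_cohort(prs, 5_000, seed=7)
s = cohort.splits
net = nnprs.build_mlp(prs.n_snps, seed=0, input_snp_ids=list(prs.snp_ids))
nnprs.train_regressor(net, cohort.X(s.train_idx), cohort.y(s.train_idx),
                      cohort.X(s.val_idx), cohort.y(s.val_idx),
                      nnprs.TrainConfig(max_epochs=5, seed=0))

bundle = nnprs.export_network(net, "model.nnprs.txt")
print("wrote model.nnprs.txt:",
      [f"{w.shape[0]}x{w.shape[1]}" for w in bundle.weights], "layers")

X = cohort.X(s.test_idx)[:100]
text_scores = nnprs.forward_from_text(bundle, X).ravel()
mem_scores = net.predict(X)
print(f"max |text forward − framework forward| over 100 samples: "
      f"{np.max(np.abs(text_scores - mem_scores)):.2e}")
print("the text file alone reproduces the model: ship the file, not the code")
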