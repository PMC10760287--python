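#!/usr/bin/env python3
"""Minimal standalone evaluator for nnprs text bundles.

Deliberately shares no code with the nnprs package and uses no numerical
library: plain-Python lists, loops, multiply-add and max.  This is the
portability demonstration — anything that can do matrix arithmetic can score
samples from the text file alone.

Usage:
    python eval_bundle_minimal.py BUNDLE.txt < inputs.tsv > scores.tsv

Each input line is one sample: tab- or space-separated effect-allele counts
ordered as in the bundle's [SNPS] section.  One output line per sample with
one score per output neuron.
"""

import math
import sys


def parse_bundle(path):
    with open(path, encoding="utf-8") as fh:
        body = [ln.strip() for ln in fh if ln.strip() and not ln.strip().startswith("#")]
    assert body[0].startswith("nnprs-export"), "not an nnprs text bundle"
    n_snps = 0
    layers = []  # (matrix rows, bias, activation, concat_input)
    i = 1
    section = None
    while i < len(body):
        line = body[i]
        if line == "[SNPS]":
            section = "snps"
        elif line == "[OUTPUTS]":
            section = "outputs"
        elif line.startswith("[LAYER"):
            fields = line.strip("[]").split()
            rows, cols, tag = int(fields[2]), int(fields[3]), fields[4]
            concat = len(fields) == 6 and fields[5] == "concat_input"
            mat = [[float(v) for v in body[i + 1 + r].split()] for r in range(rows)]
            bias = [float(v) for v in body[i + 1 + rows].split()]
            assert all(len(row) == cols for row in mat) and len(bias) == cols
            layers.append((mat, bias, tag, concat))
            i += 1 + rows
            section = None
        elif section == "snps":
            n_snps += 1
        i += 1
    return n_snps, layers


def activate(z, tag):
    if tag == "relu":
        return [max(0.0, v) for v in z]
    if tag == "linear":
        return z
    if tag == "sigmoid_times_two":
        return [2.0 / (1.0 + math.exp(-v)) for v in z]
    raise ValueError("unknown activation " + tag)


def forward(layers, v0):
    v = list(v0)
    for mat, bias, tag, concat in layers:
        if concat:
            v = v + list(v0)
        z = []
        for j in range(len(bias)):
            acc = bias[j]
            for i in range(len(v)):
                acc += v[i] * mat[i][j]
            z.append(acc)
        v = activate(z, tag)
    return v


def main():
    if len(sys.argv) != 2:
        sys.exit(__doc__)
    n_snps, layers = parse_bundle(sys.argv[1])
    for line in sys.stdin:
        if not line.strip():
            continue
        v0 = [float(v) for v in line.split()]
        assert len(v0) == n_snps, "input length does not match the SNP block"
        print("\t".join(repr(v) for v in forward(layers, v0)))


if __name__ == "__main__":
    main()
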