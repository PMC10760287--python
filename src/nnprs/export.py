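"""Portable plain-text serialisation of trained networks.

A trained model is nothing but ordered (matrix, bias) pairs, activation tags
and the SNP list with effect alleles, so it can be stored as a line-oriented
UTF-8 text file and evaluated anywhere matrix arithmetic exists — other
languages, other decades, even a spreadsheet.  Values are written with 17
significant digits, which round-trips IEEE doubles exactly.

Format (``#`` starts a comment):

    nnprs-export 1
    [SNPS]
    snp_id <TAB> effect_allele          # one line per input SNP, in order
    [OUTPUTS]                            # optional: names of output columns
    name
    [LAYER k rows cols activation]       # k from 1; activation relu|linear|
    row of `cols` space-separated values #   sigmoid_times_two; a trailing
    ... (`rows` rows) ...                #   `concat_input` flag marks a layer
    bias row (`cols` values)             #   fed concat(prev output, input)

The forward pass is v_l = act_l(v_{l-1} · M_l + b_l) applied layer by layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .nets import NetworkSpec, TrainedNetwork, _apply_activation

FORMAT_HEADER = "nnprs-export 1"


@dataclass
class ExportBundle:
    """Parsed text bundle: SNP block plus ordered layer blocks."""

    format_version: int
    snp_block: list[tuple[str, str]]  # (snp_id, effect_allele)
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    activations: list[str]
    concat_input: list[bool]
    output_names: list[str] = field(default_factory=list)

    @property
    def n_inputs(self) -> int:
        return len(self.snp_block)

    def to_network(self) -> TrainedNetwork:
        skip = any(self.concat_input)
        if skip and (len(self.concat_input) < 1 or not self.concat_input[-1]):
            raise ValueError("concat_input is only supported on the final layer")
        hidden = tuple(w.shape[1] for w in self.weights[:-1])
        spec = NetworkSpec(
            input_width=self.n_inputs,
            hidden_widths=hidden,
            output_width=self.weights[-1].shape[1],
            output_activation=self.activations[-1],
            skip_input_to_last_hidden=skip,
        )
        return TrainedNetwork(
            spec=spec,
            weights=[w.copy() for w in self.weights],
            biases=[b.copy() for b in self.biases],
            input_snp_ids=[s for s, _ in self.snp_block],
            output_names=list(self.output_names) or None,
        )


def export_network(net: TrainedNetwork, path: str | Path) -> ExportBundle:
    """Write ``net`` to ``path`` as a text bundle and return the bundle."""
    snp_ids = net.input_snp_ids or [f"snp{i}" for i in range(net.spec.input_width)]
    alleles = ["?"] * len(snp_ids)
    lines = [FORMAT_HEADER, "# trained PRS network; forward pass: v_l = act(v_{l-1} M_l + b_l)"]
    lines.append("[SNPS]")
    for s, a in zip(snp_ids, alleles):
        lines.append(f"{s}\t{a}")
    if net.output_names:
        lines.append("[OUTPUTS]")
        lines.extend(net.output_names)
    acts = net.spec.activations
    for k, (w, b) in enumerate(zip(net.weights, net.biases), start=1):
        tag = acts[k - 1]
        concat = net.spec.skip_input_to_last_hidden and k == net.n_layers
        header = f"[LAYER {k} {w.shape[0]} {w.shape[1]} {tag}" + (" concat_input]" if concat else "]")
        lines.append(header)
        for row in w:
            lines.append(" ".join(f"{v:.17g}" for v in row))
        lines.append(" ".join(f"{v:.17g}" for v in b))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
    return load_bundle(path)


class BundleParseError(ValueError):
    pass


def load_bundle(path: str | Path) -> ExportBundle:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    body = [ln.strip() for ln in lines if ln.strip() and not ln.strip().startswith("#")]
    if not body or not body[0].startswith("nnprs-export"):
        raise BundleParseError("missing nnprs-export header")
    version = int(body[0].split()[1])

    snp_block: list[tuple[str, str]] = []
    output_names: list[str] = []
    weights, biases, activations, concat_flags = [], [], [], []
    i = 1
    section = None
    while i < len(body):
        line = body[i]
        if line == "[SNPS]":
            section = "snps"
            i += 1
        elif line == "[OUTPUTS]":
            section = "outputs"
            i += 1
        elif line.startswith("[LAYER"):
            fields = line.strip("[]").split()
            if len(fields) not in (5, 6):
                raise BundleParseError(f"malformed layer header: {line}")
            _, _k, rows, cols, tag = fields[:5]
            rows, cols = int(rows), int(cols)
            concat_flags.append(len(fields) == 6 and fields[5] == "concat_input")
            block = body[i + 1 : i + 2 + rows]
            if len(block) != rows + 1:
                raise BundleParseError(f"layer block truncated at line {i}")
            mat = np.array([[float(v) for v in r.split()] for r in block[:-1]])
            bias = np.array([float(v) for v in block[-1].split()])
            if mat.shape != (rows, cols) or bias.shape != (cols,):
                raise BundleParseError(
                    f"layer shape mismatch: header says {rows}x{cols}, body is {mat.shape}"
                )
            if tag not in ("relu", "linear", "sigmoid_times_two"):
                raise BundleParseError(f"unknown activation {tag!r}")
            weights.append(mat)
            biases.append(bias)
            activations.append(tag)
            i += 2 + rows
            section = None
        elif section == "snps":
            parts = line.split("\t")
            snp_block.append((parts[0], parts[1] if len(parts) > 1 else "?"))
            i += 1
        elif section == "outputs":
            output_names.append(line)
            i += 1
        else:
            raise BundleParseError(f"unexpected line outside any section: {line!r}")

    if not weights:
        raise BundleParseError("bundle contains no layers")
    if weights[0].shape[0] != len(snp_block):
        raise BundleParseError(
            f"SNP count {len(snp_block)} does not match first matrix rows {weights[0].shape[0]}"
        )
    for k in range(1, len(weights)):
        expect = weights[k - 1].shape[1] + (len(snp_block) if concat_flags[k] else 0)
        if weights[k].shape[0] != expect:
            raise BundleParseError(f"matrix dimensions do not chain at layer {k + 1}")
    return ExportBundle(
        format_version=version, snp_block=snp_block,
        weights=weights, biases=biases, activations=activations,
        concat_input=concat_flags, output_names=output_names,
    )


def forward_from_text(bundle: ExportBundle, v0: np.ndarray) -> np.ndarray:
    """Evaluate the bundle on input row(s) ``v0`` (ordered per its SNP block)
    using only matrix arithmetic: v_l = act_l(v_{l-1} · M_l + b_l)."""
    v = np.atleast_2d(np.asarray(v0, dtype=float))
    if v.shape[1] != bundle.n_inputs:
        raise ValueError(f"input length {v.shape[1]} != SNP block size {bundle.n_inputs}")
    x0 = v
    for mat, bias, tag, concat in zip(
        bundle.weights, bundle.biases, bundle.activations, bundle.concat_input
    ):
        if concat:
            v = np.hstack([v, x0])
        v = _apply_activation(v @ mat + bias, tag)
    out = v
    if np.asarray(v0).ndim == 1:
        out = out[0]
        if out.shape == (1,):
            return float(out[0])
    return out
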