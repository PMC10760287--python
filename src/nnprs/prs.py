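"""Polygenic risk score definitions and evaluation.

A PRS here is an intercept plus an additive part (weight times effect-allele
count per SNP) plus pairwise interaction terms.  Interactions come in two
modes: ``product`` (weight · g_a · g_b, for dosage-product scores) and
``state_indicator`` (weight · 1{g_a = s_a and g_b = s_b}), the form HLA
interaction scores take, where specific genotype combinations such as the
DR3/DR4 heterozygote carry their own weight.

These formulas are the ground-truth labels for all network training; the
module also reads and writes them as tab-delimited weight files and ships
seeded structural templates standing in for published T1D/Celiac scores.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

_MODES = ("product", "state_indicator")
TEMPLATE_NAMES = ("T1D10-like", "T1D30-like", "T1D67-like", "CD42-like")


@dataclass(frozen=True)
class InteractionTerm:
    """A pairwise term between the SNPs at positions ``index_a`` and ``index_b``."""

    index_a: int
    index_b: int
    mode: str
    weight: float
    required_state_a: int | None = None
    required_state_b: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"unknown interaction mode {self.mode!r}")
        if self.index_a == self.index_b:
            raise ValueError("interaction must reference two distinct SNPs")
        if self.mode == "state_indicator":
            for s in (self.required_state_a, self.required_state_b):
                if s not in (0, 1, 2):
                    raise ValueError(
                        "state_indicator requires genotype states in {0, 1, 2}"
                    )


@dataclass
class PRSDefinition:
    """Weights and interaction terms of one polygenic risk score."""

    name: str
    snp_ids: list[str]
    effect_alleles: list[str]
    additive_weights: np.ndarray
    interactions: list[InteractionTerm] = field(default_factory=list)
    intercept: float = 0.0

    def __post_init__(self) -> None:
        self.additive_weights = np.asarray(self.additive_weights, dtype=float)
        if len(self.snp_ids) != len(set(self.snp_ids)):
            raise ValueError("duplicate SNP ids in PRS definition")
        if self.additive_weights.shape != (len(self.snp_ids),):
            raise ValueError("additive_weights must have one entry per SNP")
        if len(self.effect_alleles) != len(self.snp_ids):
            raise ValueError("effect_alleles must have one entry per SNP")
        p = len(self.snp_ids)
        for t in self.interactions:
            if not (0 <= t.index_a < p and 0 <= t.index_b < p):
                raise ValueError(
                    f"interaction ({t.index_a},{t.index_b}) outside SNP range 0..{p - 1}"
                )

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


@dataclass
class GenotypeMatrix:
    """Samples × SNPs effect-allele counts, values in [0, 2].

    Missing entries are recorded in ``missing_mask`` and held at 0 in
    ``values``, mirroring the pre-processing convention of setting missing
    dosages to zero before training and scoring.
    """

    values: np.ndarray
    snp_ids: list[str]
    effect_alleles: list[str]
    missing_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be a 2-D array")
        if self.values.shape[1] != len(self.snp_ids):
            raise ValueError("one column per SNP id required")
        if len(self.effect_alleles) != len(self.snp_ids):
            raise ValueError("one effect allele per SNP id required")
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.values.shape:
                raise ValueError("missing_mask shape must match values")
        self.values[self.missing_mask] = 0.0
        if np.any(~np.isfinite(self.values)):
            raise ValueError("genotype values must be finite (mask missing entries)")
        if self.values.min(initial=0.0) < 0.0 or self.values.max(initial=0.0) > 2.0:
            raise ValueError("genotype values must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def column_order(self, snp_ids: list[str]) -> np.ndarray:
        """Column indices matching ``snp_ids``; raises naming any absent SNP."""
        pos = {s: i for i, s in enumerate(self.snp_ids)}
        idx = []
        for s in snp_ids:
            if s not in pos:
                raise KeyError(f"SNP {s!r} required by the PRS is absent from the genotypes")
            idx.append(pos[s])
        return np.asarray(idx, dtype=int)


def evaluate_prs(genotypes: GenotypeMatrix, prs: PRSDefinition) -> np.ndarray:
    """Score every sample: intercept + Σ w_i·g_i + Σ interaction contributions.

    Columns are reconciled by SNP id, not position.  Fractional (imputed)
    dosages are accepted; a ``state_indicator`` term matches after rounding
    the two dosages to the nearest integer genotype.
    """
    cols = genotypes.column_order(prs.snp_ids)
    g = genotypes.values[:, cols]
    scores = prs.intercept + g @ prs.additive_weights
    if prs.interactions:
        g_round = np.rint(g)
        for t in prs.interactions:
            if t.mode == "product":
                scores = scores + t.weight * g[:, t.index_a] * g[:, t.index_b]
            else:
                hit = (g_round[:, t.index_a] == t.required_state_a) & (
                    g_round[:, t.index_b] == t.required_state_b
                )
                scores = scores + t.weight * hit
    if not np.all(np.isfinite(scores)):
        raise ValueError("non-finite PRS scores")
    return scores


# ---------------------------------------------------------------------------
# Weight-file round trip
#
# Tab-delimited text: a `#name` header line, then one `A` line per SNP
# (A <tab> snp_id <tab> effect_allele <tab> weight) and one `I` line per
# interaction (I <tab> snp_a <tab> snp_b <tab> mode <tab> state_a <tab>
# state_b <tab> weight), `.` for unused state fields.
# ---------------------------------------------------------------------------


def write_prs_definition(prs: PRSDefinition, path: str | Path) -> None:
    lines = [f"#{prs.name}"]
    if prs.intercept != 0.0:
        lines.append(f"C\t{prs.intercept!r}")
    for s, a, w in zip(prs.snp_ids, prs.effect_alleles, prs.additive_weights):
        lines.append(f"A\t{s}\t{a}\t{float(w)!r}")
    for t in prs.interactions:
        sa = "." if t.required_state_a is None else str(t.required_state_a)
        sb = "." if t.required_state_b is None else str(t.required_state_b)
        lines.append(
            f"I\t{prs.snp_ids[t.index_a]}\t{prs.snp_ids[t.index_b]}\t{t.mode}\t{sa}\t{sb}\t{t.weight!r}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


class PRSParseError(ValueError):
    pass


def load_prs_definition(path: str | Path) -> PRSDefinition:
    name = Path(path).stem
    snp_ids: list[str] = []
    effect_alleles: list[str] = []
    weights: list[float] = []
    inter_rows: list[tuple[int, list[str]]] = []
    intercept = 0.0
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if lineno == 1 or not snp_ids:
                name = line[1:].strip() or name
            continue
        parts = line.split("\t")
        try:
            if parts[0] == "A":
                if len(parts) != 4:
                    raise ValueError("expected A<TAB>snp<TAB>allele<TAB>weight")
                snp_ids.append(parts[1])
                effect_alleles.append(parts[2])
                weights.append(float(parts[3]))
            elif parts[0] == "I":
                if len(parts) != 7:
                    raise ValueError("expected 7 tab-separated fields on I line")
                inter_rows.append((lineno, parts))
            elif parts[0] == "C":
                intercept = float(parts[1])
            else:
                raise ValueError(f"unknown record type {parts[0]!r}")
        except (ValueError, IndexError) as exc:
            raise PRSParseError(f"{path}:{lineno}: {exc}") from exc

    index = {s: i for i, s in enumerate(snp_ids)}
    interactions = []
    for lineno, parts in inter_rows:
        _, sa, sb, mode, st_a, st_b, w = parts
        if sa not in index or sb not in index:
            missing = sa if sa not in index else sb
            raise PRSParseError(f"{path}:{lineno}: interaction references unknown SNP {missing!r}")
        if mode not in _MODES:
            raise PRSParseError(f"{path}:{lineno}: unknown mode {mode!r}")
        try:
            ra = None if st_a == "." else int(st_a)
            rb = None if st_b == "." else int(st_b)
            term = InteractionTerm(
                index_a=index[sa], index_b=index[sb], mode=mode,
                weight=float(w), required_state_a=ra, required_state_b=rb,
            )
        except ValueError as exc:
            raise PRSParseError(f"{path}:{lineno}: {exc}") from exc
        interactions.append(term)
    return PRSDefinition(
        name=name, snp_ids=snp_ids, effect_alleles=effect_alleles,
        additive_weights=np.asarray(weights), interactions=interactions,
        intercept=intercept,
    )


# ---------------------------------------------------------------------------
# Structural templates
#
# The published T1D/Celiac weight tables are not reprinted here; these
# templates reproduce their *structure* — SNP counts, an HLA-like correlated
# block, and state-indicator interaction terms concentrated on that block —
# with weights drawn reproducibly from a seed.  Real published weights are
# supplied through the weight-file loader instead.
# ---------------------------------------------------------------------------

_TEMPLATE_LAYOUT = {
    # (n_snps, block_size, n_state_indicator_terms)
    "T1D10-like": (10, 2, 1),
    "T1D30-like": (30, 2, 1),
    "T1D67-like": (67, 14, 10),
    "CD42-like": (42, 10, 6),
}
_ALLELES = ("A", "C", "G", "T")
HLA_BLOCK_ID = "hla_dq"


def template_block_snps(template: str) -> list[str]:
    """SNP ids of the designated correlated (HLA-DQ-like) block of a template."""
    n, block, _ = _layout(template)
    stem = template.split("-")[0].lower()
    return [f"{stem}_hladq{i:02d}" for i in range(block)]


def _layout(template: str) -> tuple[int, int, int]:
    if template not in _TEMPLATE_LAYOUT:
        raise ValueError(f"unknown template {template!r}; choose from {TEMPLATE_NAMES}")
    return _TEMPLATE_LAYOUT[template]


def make_template_prs(template: str, seed: int = 0) -> PRSDefinition:
    """Build a structural stand-in PRS: additive weights on every SNP plus
    state-indicator interactions confined to the correlated block.

    T1D10-like and T1D30-like carry exactly one interaction term (their
    published counterparts key on a single DR3/DR4-style pair); T1D67-like and
    CD42-like carry a set of them spread over the block.
    """
    n, block, n_terms = _layout(template)
    rng = np.random.default_rng(seed)
    stem = template.split("-")[0].lower()
    snp_ids = template_block_snps(template) + [
        f"{stem}_snp{i:02d}" for i in range(block, n)
    ]
    effect_alleles = list(rng.choice(_ALLELES, size=n))
    weights = rng.uniform(0.02, 0.6, size=n)

    interactions: list[InteractionTerm] = []
    seen: set[tuple[int, int, int, int]] = set()
    while len(interactions) < n_terms:
        a, b = sorted(rng.choice(block, size=2, replace=False))
        # heterozygote-pair states dominate, as in DR3/DR4-style terms
        sa, sb = rng.choice([1, 1, 1, 2], size=2)
        key = (int(a), int(b), int(sa), int(sb))
        if key in seen:
            continue
        seen.add(key)
        interactions.append(
            InteractionTerm(
                index_a=int(a), index_b=int(b), mode="state_indicator",
                required_state_a=int(sa), required_state_b=int(sb),
                weight=float(rng.uniform(1.0, 3.5)),
            )
        )
    return PRSDefinition(
        name=template, snp_ids=snp_ids, effect_alleles=effect_alleles,
        additive_weights=weights, interactions=interactions,
    )


# ---------------------------------------------------------------------------
# Genotype input formats
# ---------------------------------------------------------------------------

_PLINK_META = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")


def read_genotypes(path: str | Path, sep: str = "\t") -> GenotypeMatrix:
    """Read a genotype matrix from delimited text.

    Two layouts are recognised: a plain samples × SNPs table whose header
    row holds SNP ids, and PLINK ``--recode A`` raw files where six metadata
    columns precede ``SNP_ALLELE`` count columns and NA marks missingness.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if list(df.columns[:6]) == list(_PLINK_META):
        geno = df.iloc[:, 6:]
        snp_ids, alleles = [], []
        for c in geno.columns:
            snp, _, allele = c.rpartition("_")
            if not snp:
                snp, allele = c, "?"
            snp_ids.append(snp)
            alleles.append(allele)
    else:
        geno = df
        snp_ids = [str(c) for c in df.columns]
        alleles = ["?"] * len(snp_ids)
    values = geno.to_numpy(dtype=float)
    mask = ~np.isfinite(values)
    values = np.where(mask, 0.0, values)
    return GenotypeMatrix(
        values=values, snp_ids=snp_ids, effect_alleles=alleles, missing_mask=mask
    )


def write_genotypes(genotypes: GenotypeMatrix, path: str | Path) -> None:
    buf = io.StringIO()
    buf.write("\t".join(genotypes.snp_ids) + "\n")
    vals = genotypes.values.copy()
    out = vals.astype(object)
    out[genotypes.missing_mask] = "NA"
    for row in out:
        buf.write("\t".join(str(v) for v in row) + "\n")
    Path(path).write_text(buf.getvalue())
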