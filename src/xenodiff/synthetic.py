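"""Synthetic two-class expression matrices with planted structure.

The generator emulates the statistical shape of a single-cell qPCR
(Biomark-style) comparison between original human tumor cells and their
patient-derived xenograft (PDX) counterparts: 831 cells (174 human, 657
PDX), 69 continuous log-scale gene features, a minority of genes carrying a
class-dependent mean shift, optionally a few genes carrying joint
threshold-rule structure, and missing values completely at random. Every
downstream stage (ranking, forward selection, rule learning) is testable
against the emitted ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .data_io import ExpressionMatrix
from .errors import ParameterError


@dataclass(frozen=True)
class PlantedRule:
    """A planted conjunction of threshold conditions implying a class.

    ``conditions`` is a tuple of ``(gene_index, op, threshold)`` with
    ``op`` in {">=", "<="}; within ``target_class``, a ``fraction`` of cells
    are generated to satisfy the full conjunction, while cells of the other
    class violate at least one condition (so the rule's precision is ~1).
    """

    conditions: tuple
    target_class: str
    fraction: float = 0.9


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study.

    Defaults mirror the study shape the generator emulates: 831 cells at a
    174:657 human:PDX imbalance, 69 genes, 15 informative genes shifted by
    1.5 within-class standard deviations in the human class.
    """

    n_cells: int = 831
    n_genes: int = 69
    class_counts: dict = field(default_factory=lambda: {"human": 174, "pdx": 657})
    informative_genes: int = 15
    effect_size: float = 1.5
    rule_genes: tuple = ()  # tuple of PlantedRule
    baseline_mean: float = 2.0
    baseline_sd: float = 1.0
    missing_rate: float = 0.0
    correlation_blocks: tuple = ()  # tuples of gene indices sharing a factor
    block_strength: float = 0.5
    clip: tuple | None = None  # e.g. (-3.0, 14.0)
    seed: int = 0

    def validate(self) -> None:
        if sum(self.class_counts.values()) != self.n_cells:
            raise ParameterError("class_counts must sum to n_cells")
        if len(self.class_counts) != 2:
            raise ParameterError("exactly two classes are supported")
        n_rule_genes = len({g for r in self.rule_genes for g, _, _ in r.conditions})
        if self.informative_genes + n_rule_genes > self.n_genes:
            raise ParameterError(
                "informative plus rule genes exceed n_genes "
                f"({self.informative_genes} + {n_rule_genes} > {self.n_genes})"
            )
        if not 0 <= self.missing_rate < 1:
            raise ParameterError("missing_rate must be in [0, 1)")
        if self.informative_genes < 0 or self.n_genes < 1 or self.n_cells < 2:
            raise ParameterError("degenerate matrix dimensions")


@dataclass
class GroundTruth:
    """What was planted: which genes are informative, and the realized rules."""

    informative_gene_ids: list
    planted_rules: list
    effect_sizes: dict  # gene_id -> mean shift (in expression units)

    def to_json(self, path) -> None:
        payload = {
            "informative_gene_ids": self.informative_gene_ids,
            "planted_rules": [asdict(r) for r in self.planted_rules],
            "effect_sizes": self.effect_sizes,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


#: Margin (in units of baseline_sd) kept clear of a planted threshold so the
#: boundary is recoverable but not ambiguous.
RULE_MARGIN = 0.05


def _sample_rule_value(rng, op: str, thr: float, satisfy: bool, sd: float):
    """Exponentially decaying mass on the satisfying or violating side."""
    off = (RULE_MARGIN + rng.exponential(1.0)) * sd
    sign = 1.0 if (op == ">=") == satisfy else -1.0
    return thr + sign * off


def generate(spec: SyntheticSpec) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw one matrix + ground truth from the spec; seed-deterministic."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    classes = list(spec.class_counts)
    labels = np.repeat(classes, [spec.class_counts[c] for c in classes])
    n, p = spec.n_cells, spec.n_genes
    minority = min(classes, key=lambda c: spec.class_counts[c])

    values = rng.normal(spec.baseline_mean, spec.baseline_sd, size=(n, p))

    for block in spec.correlation_blocks:
        factor = rng.normal(0.0, spec.baseline_sd, size=n)
        for g in block:
            values[:, g] += spec.block_strength * factor

    # reserve rule genes first, then informative genes from what remains
    rule_gene_idx = sorted({g for r in spec.rule_genes for g, _, _ in r.conditions})
    free = [g for g in range(p) if g not in rule_gene_idx]
    informative = free[: spec.informative_genes]

    shift = spec.effect_size * spec.baseline_sd
    is_minority = labels == minority
    for g in informative:
        values[is_minority, g] += shift

    for rule in spec.rule_genes:
        in_class = labels == rule.target_class
        idx_in = np.nonzero(in_class)[0]
        n_sat = int(round(rule.fraction * len(idx_in)))
        sat = rng.permutation(idx_in)[:n_sat]
        sat_set = set(sat.tolist())
        for i in np.nonzero(in_class)[0]:
            satisfy_all = i in sat_set
            for g, op, thr in rule.conditions:
                values[i, g] = _sample_rule_value(rng, op, thr, satisfy_all, spec.baseline_sd)
        # other class: violate one randomly chosen condition, rest free
        for i in np.nonzero(~in_class)[0]:
            g_v, op_v, thr_v = rule.conditions[rng.integers(len(rule.conditions))]
            for g, op, thr in rule.conditions:
                values[i, g] = _sample_rule_value(
                    rng, op, thr, satisfy=(g != g_v), sd=spec.baseline_sd
                )

    if spec.clip is not None:
        np.clip(values, spec.clip[0], spec.clip[1], out=values)

    mask = rng.random(size=(n, p)) < spec.missing_rate
    values = np.where(mask, np.nan, values)

    gene_ids = [f"g{j + 1}" for j in range(p)]
    cell_ids = [f"c{i + 1}" for i in range(n)]

    truth = GroundTruth(
        informative_gene_ids=[gene_ids[g] for g in informative],
        planted_rules=list(spec.rule_genes),
        effect_sizes={gene_ids[g]: float(shift) for g in informative},
    )
    matrix = ExpressionMatrix(
        values, cell_ids, gene_ids, labels, mask,
        provenance={"synthetic": {"seed": spec.seed, "n_cells": n, "n_genes": p}},
    )
    return matrix, truth
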