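"""Mapping gene expression onto reactions through GPR rules.

A gene-protein-reaction (GPR) rule is a boolean expression over gene ids
(``and`` / ``or`` / parentheses).  Expression values (log2 scale) are mapped
to reactions by recursive evaluation: an AND node (enzyme complex) takes the
minimum of its children -- the complex is limited by its scarcest subunit --
and an OR node (isoenzymes) takes the maximum -- the strongest isoform
carries the reaction.  An ``or_mode="sum"`` variant adds isoenzyme
contributions instead.

Genes without a measurement leave their leaf undefined: undefined children
are skipped at OR nodes and propagate undefinedness through AND nodes.

Two condition profiles are compared by the per-reaction ratio
``numerator/denominator - 1`` and by a two-sample Kolmogorov-Smirnov test on
the gene-level values.
"""

from __future__ import annotations

import ast
import logging
import math
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .model import MetabolicModel

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionProfile",
    "ReactionExpression",
    "GPRParseError",
    "log_transform",
    "read_expression_tsv",
    "reaction_expression",
    "expression_ratio",
    "ks_two_sample",
    "gpr_genes",
]


class GPRParseError(ValueError):
    pass


@dataclass(frozen=True)
class ExpressionProfile:
    """Per-gene expression values for one condition, on the log2 scale."""

    condition: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        for g, v in self.values.items():
            if not g:
                raise ValueError("empty gene id in expression profile")
            if not math.isfinite(v):
                raise ValueError(f"non-finite expression value for gene {g!r}")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": list(self.values), "value": list(self.values.values())}
        )


@dataclass(frozen=True)
class ReactionExpression:
    """Per-reaction expression derived from a profile via GPR rules.

    ``values`` holds a value for every reaction whose rule could be
    evaluated; ``missing`` lists reactions whose GPR has no measured gene
    (or no GPR at all).  ``coverage`` is the fraction of each rule's genes
    that had data.
    """

    condition: str
    values: dict[str, float]
    missing: tuple[str, ...] = ()
    coverage: dict[str, float] = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"reaction_id": list(self.values), "expression": list(self.values.values())}
        )


def log_transform(raw: dict[str, float], condition: str = "") -> ExpressionProfile:
    """log2-transform raw (positive) intensities into a profile."""
    out = {}
    for g, v in raw.items():
        if not v > 0:
            raise ValueError(f"gene {g!r}: non-positive raw intensity {v!r}")
        out[g] = math.log2(v)
    return ExpressionProfile(condition=condition, values=out)


def read_expression_tsv(path, condition: str = "", log2: bool = False) -> ExpressionProfile:
    """Read a (gene_id, value) TSV; ``log2=True`` applies the transform."""
    df = pd.read_csv(path, sep="\t")
    raw = dict(zip(df["gene_id"].astype(str), df["value"].astype(float)))
    if log2:
        return log_transform(raw, condition)
    return ExpressionProfile(condition=condition, values=raw)


# ---------------------------------------------------------------------------
# GPR parsing/evaluation.  Parsing is delegated to cobra's GPR class, which
# handles the BiGG grammar (and/or, parentheses, odd gene identifiers).
# ---------------------------------------------------------------------------

def _parse_gpr(rule: str):
    from cobra.core.gene import GPR

    try:
        gpr = GPR.from_string(rule)
    except Exception as exc:  # noqa: BLE001
        raise GPRParseError(f"cannot parse GPR rule {rule!r}: {exc}") from exc
    if gpr.body is None:
        raise GPRParseError(f"empty GPR rule {rule!r}")
    return gpr


def gpr_genes(rule: str) -> set[str]:
    """The set of gene ids appearing in a GPR rule string."""
    return set(_parse_gpr(rule).genes)


def _eval_node(node, values: dict[str, float], or_mode: str) -> float | None:
    if isinstance(node, ast.Name):
        return values.get(node.id)
    if isinstance(node, ast.BoolOp):
        children = [_eval_node(c, values, or_mode) for c in node.values]
        if isinstance(node.op, ast.And):
            if any(c is None for c in children):
                return None
            return min(children)
        defined = [c for c in children if c is not None]
        if not defined:
            return None
        return sum(defined) if or_mode == "sum" else max(defined)
    raise GPRParseError(f"unsupported GPR syntax node {ast.dump(node)}")


def evaluate_gpr(rule: str, values: dict[str, float], or_mode: str = "max") -> float | None:
    """Evaluate one GPR rule against gene values (None = undefined)."""
    return _eval_node(_parse_gpr(rule).body, values, or_mode)


def reaction_expression(
    model: MetabolicModel,
    profile: ExpressionProfile,
    *,
    or_mode: str = "max",
    exclude_genes: set[str] | frozenset[str] = frozenset(),
) -> ReactionExpression:
    """Map a gene-level profile to reaction-level values through GPRs."""
    if or_mode not in ("max", "sum"):
        raise ValueError(f"unknown or_mode {or_mode!r}")
    values = {g: v for g, v in profile.values.items() if g not in exclude_genes}
    out: dict[str, float] = {}
    missing: list[str] = []
    coverage: dict[str, float] = {}
    for r in model.reactions:
        if not r.gpr:
            missing.append(r.id)
            continue
        try:
            genes = gpr_genes(r.gpr)
        except GPRParseError as exc:
            raise GPRParseError(f"reaction {r.id!r}: {exc}") from exc
        genes -= set(exclude_genes)
        coverage[r.id] = (
            sum(g in values for g in genes) / len(genes) if genes else 0.0
        )
        val = evaluate_gpr(r.gpr, values, or_mode) if genes else None
        if val is None:
            missing.append(r.id)
        else:
            out[r.id] = float(val)
    return ReactionExpression(
        condition=profile.condition,
        values=out,
        missing=tuple(missing),
        coverage=coverage,
    )


def expression_ratio(
    numerator: ReactionExpression, denominator: ReactionExpression
) -> dict[str, float]:
    """Per-reaction ``numerator/denominator - 1``.

    Reactions missing from either input are omitted (logged); a zero
    denominator yields NaN (flagged undefined rather than dropped).
    """
    shared = [r for r in numerator.values if r in denominator.values]
    if not shared:
        raise ValueError("no shared reactions between the two expression sets")
    skipped = (set(numerator.values) | set(denominator.values)) - set(shared)
    if skipped:
        logger.info("expression_ratio: %d reactions missing in one input: %s",
                    len(skipped), sorted(skipped))
    out = {}
    for r in shared:
        den = denominator.values[r]
        out[r] = numerator.values[r] / den - 1.0 if den != 0 else float("nan")
    return out


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    D is the supremum distance between the two empirical CDFs; the p-value
    uses the asymptotic two-sided distribution (exact for min(n) < 10).
    """
    a = list(a)
    b = list(b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need at least 2 values")
    method = "exact" if min(len(a), len(b)) < 10 else "asymp"
    res = stats.ks_2samp(a, b, method=method)
    return float(res.statistic), float(res.pvalue)
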