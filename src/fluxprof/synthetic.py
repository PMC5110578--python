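"""Download-free fixtures: a toy fermentation network, box polytopes for
sampler calibration, and two-condition synthetic expression data.

The toy network mimics the anaerobic fermentation branch-point of E. coli:
glucose is glycolytically converted to PEP/pyruvate with NADH formation, and
the NAD+ pool is regenerated by three competing routes --

* lactate:  pyr + nadh -> lac        (1 NAD+ per pyruvate, via LDH)
* ethanol:  pyr -> accoa + formate (PFL), accoa + 2 nadh -> etoh
            (2 NAD+ per pyruvate)
* reductive branch to succinate: pep + co2 -> oaa -> fum (1 NADH) plus
  fumarate reduction by quinol, with NADH16 (nadh + q8 -> nad + q8h2)
  recharging the quinone pool (2 NADH per succinate overall).

The 2:1 NAD+ stoichiometry of ethanol versus lactate production is the
mechanism that makes the pyruvate formate-lyase knockout hit the redox
balance harder than the lactate dehydrogenase knockout, so the flux-sum
contrast between the two knockouts is qualitatively reproducible here.

Knockout behavior is analytically known: deleting LDH removes the only
producer of external lactate, deleting PFL the only producer of formate
(and of acetyl-CoA), so the corresponding exchange fluxes are structural
zeros (FVA min = max = 0), not merely small.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .expression import ExpressionProfile
from .model import MetabolicModel, Metabolite, Reaction

__all__ = [
    "ToySpec",
    "ExpressionSpec",
    "make_toy_fermentation_model",
    "make_box_polytope",
    "make_expression_dataset",
    "TOY_GENES",
]

#: Synthetic gene ids used in the toy model's GPR rules.
TOY_GENES = {
    "LDH": "tg_ldhA",
    "PFL": "tg_pflB",
    "ADHE": "tg_adhE",
    "NADH16": ("tg_nuoA", "tg_nuoB"),
    "FRD": ("tg_frdA", "tg_frdB"),
}


@dataclass(frozen=True)
class ToySpec:
    include_ldh: bool = True
    include_pfl: bool = True
    glucose_uptake_max: float = 10.0
    seed: int = 42

    def __post_init__(self) -> None:
        if not self.glucose_uptake_max > 0:
            raise ValueError("glucose_uptake_max must be > 0")


@dataclass(frozen=True)
class ExpressionSpec:
    genes: tuple[str, ...]
    baseline_mean: float = 8.0  # log2 scale
    lfc: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.1
    seed: int = 42

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        unknown = set(self.lfc) - set(self.genes)
        if unknown:
            raise ValueError(f"lfc keys not in gene list: {sorted(unknown)}")


def make_toy_fermentation_model(spec: ToySpec | None = None) -> MetabolicModel:
    """Branched fermentation network with analytically known knockouts."""
    if spec is None:
        spec = ToySpec()
    mets = [
        Metabolite("glc_e", "glucose", "e"),
        Metabolite("pep_c", "phosphoenolpyruvate", "c"),
        Metabolite("pyr_c", "pyruvate", "c"),
        Metabolite("accoa_c", "acetyl-CoA", "c"),
        Metabolite("oaa_c", "oxaloacetate", "c"),
        Metabolite("fum_c", "fumarate", "c"),
        Metabolite("nad_c", "NAD+", "c"),
        Metabolite("nadh_c", "NADH", "c"),
        Metabolite("q8_c", "ubiquinone-8", "c"),
        Metabolite("q8h2_c", "ubiquinol-8", "c"),
        Metabolite("h_c", "proton", "c"),
        Metabolite("h_e", "proton (ext)", "e"),
        Metabolite("h2o_c", "water", "c"),
        Metabolite("h2o_e", "water (ext)", "e"),
        Metabolite("co2_e", "CO2 (ext)", "e"),
        Metabolite("lac_e", "D-lactate (ext)", "e"),
        Metabolite("for_e", "formate (ext)", "e"),
        Metabolite("etoh_e", "ethanol (ext)", "e"),
        Metabolite("ac_e", "acetate (ext)", "e"),
        Metabolite("succ_e", "succinate (ext)", "e"),
    ]
    UB = 1000.0
    rxns = [
        Reaction("EX_glc_e", {"glc_e": -1.0}, -spec.glucose_uptake_max, 0.0,
                 name="glucose exchange"),
        # lumped glycolysis: 1 glucose -> 2 PEP + 2 NADH
        Reaction("GLYC", {"glc_e": -1.0, "nad_c": -2.0, "pep_c": 2.0,
                          "nadh_c": 2.0, "h_c": 2.0}, 0.0, UB, name="glycolysis (lumped)"),
        Reaction("PYK", {"pep_c": -1.0, "pyr_c": 1.0}, 0.0, UB, name="pyruvate kinase"),
        # pyruvate dehydrogenase keeps the acetyl-CoA pool alive in the
        # formate-lyase knockout, as in the E. coli core network
        Reaction("PDH", {"pyr_c": -1.0, "nad_c": -1.0, "accoa_c": 1.0,
                         "nadh_c": 1.0, "co2_e": 1.0, "h_c": 1.0}, 0.0, UB,
                 name="pyruvate dehydrogenase"),
        Reaction("ADHE", {"accoa_c": -1.0, "nadh_c": -2.0, "h_c": -2.0,
                          "etoh_e": 1.0, "nad_c": 2.0}, 0.0, UB,
                 name="ethanol branch (lumped ACALD+ALCD2x)", gpr=TOY_GENES["ADHE"]),
        Reaction("ACK", {"accoa_c": -1.0, "ac_e": 1.0}, 0.0, UB,
                 name="acetate branch (lumped PTA+ACK)"),
        # reductive branch: PEP carboxylation, then reduction to fumarate
        Reaction("PPC", {"pep_c": -1.0, "co2_e": -1.0, "oaa_c": 1.0}, 0.0, UB,
                 name="PEP carboxylase"),
        Reaction("MDH_FUM", {"oaa_c": -1.0, "nadh_c": -1.0, "h_c": -1.0,
                             "fum_c": 1.0, "nad_c": 1.0, "h2o_c": 1.0}, 0.0, UB,
                 name="malate dehydrogenase + fumarase (lumped)"),
        Reaction("FRD", {"fum_c": -1.0, "q8h2_c": -1.0, "succ_e": 1.0, "q8_c": 1.0},
                 0.0, UB, name="fumarate reductase",
                 gpr=f"{TOY_GENES['FRD'][0]} or {TOY_GENES['FRD'][1]}"),
        Reaction("NADH16", {"nadh_c": -1.0, "q8_c": -1.0, "h_c": -1.0,
                            "nad_c": 1.0, "q8h2_c": 1.0}, 0.0, UB,
                 name="NADH:ubiquinone oxidoreductase",
                 gpr=f"{TOY_GENES['NADH16'][0]} and {TOY_GENES['NADH16'][1]}"),
        # transport/exchange
        Reaction("Ht", {"h_c": -1.0, "h_e": 1.0}, -UB, UB, name="proton diffusion"),
        Reaction("H2Ot", {"h2o_c": -1.0, "h2o_e": 1.0}, -UB, UB, name="water diffusion"),
        Reaction("EX_h_e", {"h_e": -1.0}, -UB, UB),
        Reaction("EX_h2o_e", {"h2o_e": -1.0}, -UB, UB),
        Reaction("EX_co2_e", {"co2_e": -1.0}, -UB, UB),
        Reaction("EX_lac_e", {"lac_e": -1.0}, 0.0, UB),
        Reaction("EX_for_e", {"for_e": -1.0}, 0.0, UB),
        Reaction("EX_etoh_e", {"etoh_e": -1.0}, 0.0, UB),
        Reaction("EX_ac_e", {"ac_e": -1.0}, 0.0, UB),
        Reaction("EX_succ_e", {"succ_e": -1.0}, 0.0, UB),
    ]
    if spec.include_ldh:
        rxns.insert(3, Reaction(
            "LDH", {"pyr_c": -1.0, "nadh_c": -1.0, "h_c": -1.0,
                    "lac_e": 1.0, "nad_c": 1.0}, 0.0, UB,
            name="D-lactate dehydrogenase", gpr=TOY_GENES["LDH"]))
    if spec.include_pfl:
        rxns.insert(3, Reaction(
            "PFL", {"pyr_c": -1.0, "accoa_c": 1.0, "for_e": 1.0}, 0.0, UB,
            name="pyruvate formate-lyase", gpr=TOY_GENES["PFL"]))
    return MetabolicModel(id="toy_fermentation", metabolites=tuple(mets),
                          reactions=tuple(rxns))


def make_box_polytope(n: int, lower, upper) -> MetabolicModel:
    """A model whose flux space is an axis-aligned box (no metabolites).

    The uniform distribution on it has analytically known moments (the
    per-coordinate mean is the midpoint), which calibrates the sampler.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lower = [float(x) for x in (lower if hasattr(lower, "__len__") else [lower] * n)]
    upper = [float(x) for x in (upper if hasattr(upper, "__len__") else [upper] * n)]
    if len(lower) != n or len(upper) != n:
        raise ValueError(
            f"bound lists must have length n={n}; got {len(lower)} and {len(upper)}"
        )
    rxns = tuple(
        Reaction(f"R{k + 1}", {}, lower[k], upper[k]) for k in range(n)
    )
    return MetabolicModel(id=f"box_{n}d", metabolites=(), reactions=rxns)


def make_expression_dataset(
    spec: ExpressionSpec,
) -> tuple[ExpressionProfile, ExpressionProfile]:
    """Two-condition expression data on the log2 scale.

    Control values are Normal(baseline_mean, noise_sd) per gene; the
    perturbed condition draws independent noise and adds the per-gene
    log2-fold-change.  Reproducible from the spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    genes = list(spec.genes)
    control = spec.baseline_mean + spec.noise_sd * rng.standard_normal(len(genes))
    perturbed = spec.baseline_mean + spec.noise_sd * rng.standard_normal(len(genes))
    perturbed = perturbed + np.array([spec.lfc.get(g, 0.0) for g in genes])
    return (
        ExpressionProfile("control", dict(zip(genes, control.tolist()))),
        ExpressionProfile("perturbed", dict(zip(genes, perturbed.tolist()))),
    )
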