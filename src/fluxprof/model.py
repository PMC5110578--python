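"""Constraint-based metabolic models and strain construction.

A :class:`MetabolicModel` is a light, immutable-by-convention container for a
stoichiometric network: ordered metabolites, ordered reactions with flux
bounds (mmol/gDW/h) and gene-protein-reaction (GPR) rules.  The ordering of
metabolites and reactions fixes the row/column layout of the stoichiometric
matrix ``S`` used everywhere downstream (sampling, flux-sums, correlations).

Parsing and serialization of the community formats (SBML Level 3 + FBC,
BiGG-style JSON) are delegated to cobrapy; this module converts between
cobra's object model and the package-native dataclasses.

Strains are derived by reaction deletion: the lactate dehydrogenase knockout
deletes ``LDH_D``, the pyruvate formate-lyase knockout deletes ``PFL``, and
the double knockout (the NZN111-type strain) deletes both.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "Condition",
    "ModelFormatError",
    "ModelValidationError",
    "load_model",
    "save_model",
    "stoichiometric_matrix",
    "delete_reactions",
    "apply_condition",
    "reorient_reactions",
    "anaerobic_condition",
    "resolve_reaction_id",
    "STRAIN_DELETIONS",
]

#: Deletion sets for the four canonical strains.  ``nzn`` is the
#: ldhA/pflB double knockout (NZN111); the single knockouts delete the
#: D-lactate dehydrogenase or pyruvate formate-lyase reaction.
STRAIN_DELETIONS: dict[str, tuple[str, ...]] = {
    "wild_type": (),
    "del_ldh": ("LDH_D",),
    "del_pfl": ("PFL",),
    "nzn": ("LDH_D", "PFL"),
}


class ModelFormatError(ValueError):
    """Raised when a model file cannot be parsed in the declared dialect."""


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("metabolite id must be non-empty")
        if not self.compartment:
            raise ModelValidationError(f"metabolite {self.id!r}: empty compartment")


@dataclass(frozen=True)
class Reaction:
    """A reaction with stoichiometry (negative coefficient = consumed),
    flux bounds in mmol/gDW/h, and an optional boolean GPR rule string."""

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    name: str = ""
    gpr: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("reaction id must be non-empty")
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )

    @property
    def is_exchange(self) -> bool:
        # Boundary reactions touch exactly one metabolite; the BiGG "EX_"
        # prefix is also honored for empty-stoichiometry placeholder rxns.
        return len(self.stoichiometry) == 1 or self.id.startswith("EX_")


@dataclass(frozen=True)
class Condition:
    """Bound overrides keyed by reaction id, e.g. an anaerobic condition."""

    overrides: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rid, (lo, hi) in self.overrides.items():
            if lo > hi:
                raise ModelValidationError(
                    f"condition override for {rid!r}: lower {lo} > upper {hi}"
                )


@dataclass(frozen=True)
class MetabolicModel:
    id: str
    metabolites: tuple[Metabolite, ...]
    reactions: tuple[Reaction, ...]

    def __post_init__(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dupes = sorted({m for m in met_ids if met_ids.count(m) > 1})
            raise ModelValidationError(f"duplicate metabolite ids: {dupes}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dupes = sorted({r for r in rxn_ids if rxn_ids.count(r) > 1})
            raise ModelValidationError(f"duplicate reaction ids: {dupes}")
        known = set(met_ids)
        for r in self.reactions:
            unknown = set(r.stoichiometry) - known
            if unknown:
                raise ModelValidationError(
                    f"reaction {r.id!r} references unknown metabolites: "
                    f"{sorted(unknown)}"
                )

    # -- convenience lookups -------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def reaction_index(self, rid: str) -> int:
        for j, r in enumerate(self.reactions):
            if r.id == rid:
                return j
        raise KeyError(rid)

    @property
    def lower_bounds(self) -> np.ndarray:
        return np.array([r.lower_bound for r in self.reactions], dtype=float)

    @property
    def upper_bounds(self) -> np.ndarray:
        return np.array([r.upper_bound for r in self.reactions], dtype=float)

    @property
    def genes(self) -> list[str]:
        from .expression import gpr_genes

        out: set[str] = set()
        for r in self.reactions:
            if r.gpr:
                out |= gpr_genes(r.gpr)
        return sorted(out)


# ---------------------------------------------------------------------------
# id normalization: the literature writes "LDH-D" / "EX_lac_D (e)" where BiGG
# uses "LDH_D" / "EX_lac__D_e".  Matching collapses case, maps "-" to "_",
# strips spaces/parentheses and collapses runs of underscores.
# ---------------------------------------------------------------------------

def _normalize_id(rid: str) -> str:
    s = rid.replace("-", "_").replace("(", "_").replace(")", "_").replace(" ", "_")
    s = re.sub(r"_+", "_", s).strip("_")
    return s.lower()


def resolve_reaction_id(model: MetabolicModel, name: str) -> str:
    """Resolve ``name`` to a reaction id of ``model``, tolerating the common
    alternative spellings (dash for underscore, ``" (e)"`` compartment tags).

    Raises ``KeyError`` if no reaction matches or the match is ambiguous.
    """
    ids = model.reaction_ids
    if name in ids:
        return name
    target = _normalize_id(name)
    hits = [rid for rid in ids if _normalize_id(rid) == target]
    if len(hits) == 1:
        return hits[0]
    if not hits:
        raise KeyError(f"no reaction matching {name!r} in model {model.id!r}")
    raise KeyError(f"ambiguous reaction name {name!r}: matches {hits}")


# ---------------------------------------------------------------------------
# cobra conversion and I/O
# ---------------------------------------------------------------------------

def _from_cobra(cm) -> MetabolicModel:
    mets = tuple(
        Metabolite(id=m.id, name=m.name or "", compartment=m.compartment or "c")
        for m in cm.metabolites
    )
    rxns = []
    for r in cm.reactions:
        stoich = {m.id: float(c) for m, c in r.metabolites.items()}
        rxns.append(
            Reaction(
                id=r.id,
                name=r.name or "",
                stoichiometry=stoich,
                lower_bound=float(r.lower_bound),
                upper_bound=float(r.upper_bound),
                gpr=r.gene_reaction_rule or "",
            )
        )
    return MetabolicModel(id=cm.id or "model", metabolites=mets, reactions=tuple(rxns))


def to_cobra(model: MetabolicModel):
    """Convert to a cobra.Model (used for serialization and LP cross-checks)."""
    import cobra

    cm = cobra.Model(model.id)
    cmets = {}
    for m in model.metabolites:
        cm_met = cobra.Metabolite(m.id, name=m.name, compartment=m.compartment)
        cmets[m.id] = cm_met
    cm.add_metabolites(list(cmets.values()))
    crxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id, name=r.name)
        cr.lower_bound = r.lower_bound
        cr.upper_bound = r.upper_bound
        crxns.append(cr)
    cm.add_reactions(crxns)
    for r in model.reactions:
        cr = cm.reactions.get_by_id(r.id)
        cr.add_metabolites({cmets[k]: v for k, v in r.stoichiometry.items()})
        if r.gpr:
            cr.gene_reaction_rule = r.gpr
    return cm


def load_model(path, format: str | None = None) -> MetabolicModel:
    """Load a model from SBML (L3+FBC) or BiGG-style JSON.

    ``format`` is ``"sbml"`` or ``"json"``; if omitted it is inferred from
    the file extension.
    """
    import cobra.io

    path = str(path)
    if format is None:
        format = "json" if path.endswith(".json") else "sbml"
    if format not in ("sbml", "json"):
        raise ValueError(f"unknown model format {format!r}")
    try:
        if format == "json":
            cm = cobra.io.load_json_model(path)
        else:
            cm = cobra.io.read_sbml_model(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - normalize parser errors
        raise ModelFormatError(f"cannot parse {path!r} as {format}: {exc}") from exc
    return _from_cobra(cm)


def load_bundled_ecoli_core() -> MetabolicModel:
    """The BiGG *e_coli_core* model, from cobra's bundled copy ("textbook")."""
    from cobra.io import load_model as _cobra_load

    return _from_cobra(_cobra_load("textbook"))


def save_model(model: MetabolicModel, path, format: str | None = None) -> None:
    """Write a model as BiGG-style JSON or SBML L3+FBC."""
    import cobra.io

    path = str(path)
    if format is None:
        format = "json" if path.endswith(".json") else "sbml"
    cm = to_cobra(model)
    if format == "json":
        cobra.io.save_json_model(cm, path)
    elif format == "sbml":
        cobra.io.write_sbml_model(cm, path)
    else:
        raise ValueError(f"unknown model format {format!r}")


# ---------------------------------------------------------------------------
# structural operations
# ---------------------------------------------------------------------------

def stoichiometric_matrix(model: MetabolicModel) -> np.ndarray:
    """Dense S (rows = metabolites, columns = reactions, in model order)."""
    S = np.zeros((len(model.metabolites), len(model.reactions)))
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    for j, r in enumerate(model.reactions):
        for mid, coef in r.stoichiometry.items():
            S[met_index[mid], j] = coef
    return S


def delete_reactions(
    model: MetabolicModel, ids: list[str], new_id: str | None = None
) -> MetabolicModel:
    """Return a new model without the listed reactions.

    Metabolites are retained even if orphaned by the deletion (their
    flux-sum is then zero).  Names tolerate the alternative spellings
    accepted by :func:`resolve_reaction_id`.
    """
    resolved = []
    missing = []
    for rid in ids:
        try:
            resolved.append(resolve_reaction_id(model, rid))
        except KeyError:
            missing.append(rid)
    if missing:
        raise KeyError(f"reactions not in model {model.id!r}: {missing}")
    drop = set(resolved)
    return MetabolicModel(
        id=new_id or model.id,
        metabolites=model.metabolites,
        reactions=tuple(r for r in model.reactions if r.id not in drop),
    )


def apply_condition(model: MetabolicModel, condition: Condition) -> MetabolicModel:
    """Return a copy of ``model`` with bound overrides applied (pure)."""
    resolved = {
        resolve_reaction_id(model, rid): bounds
        for rid, bounds in condition.overrides.items()
    }
    rxns = []
    for r in model.reactions:
        if r.id in resolved:
            lo, hi = resolved[r.id]
            rxns.append(replace(r, lower_bound=float(lo), upper_bound=float(hi)))
        else:
            rxns.append(r)
    return MetabolicModel(id=model.id, metabolites=model.metabolites, reactions=tuple(rxns))


def anaerobic_condition(model: MetabolicModel, oxygen_exchange: str = "EX_o2_e") -> Condition:
    """Anaerobiosis: close oxygen uptake (exchange lower bound 0).

    All other bounds, including the glucose uptake and ATP maintenance
    defaults of the source model, are left untouched; cross-strain
    comparability comes from post-hoc normalization of the mean flux
    distribution to a reference glucose uptake rate.
    """
    try:
        rid = resolve_reaction_id(model, oxygen_exchange)
    except KeyError:
        logger.warning(
            "model %s has no oxygen exchange %r; anaerobic condition is empty",
            model.id,
            oxygen_exchange,
        )
        return Condition({})
    hi = model.reaction(rid).upper_bound
    return Condition({rid: (0.0, hi)})


def reorient_reactions(model: MetabolicModel, ids: list[str]) -> MetabolicModel:
    """Flip the written direction of the listed reactions.

    Negates each stoichiometric coefficient and swaps/negates the bounds, so
    the flux space is unchanged up to the sign of the affected coordinates
    (presentation only; pairwise flux correlations flip sign accordingly).
    """
    flip = {resolve_reaction_id(model, rid) for rid in ids}
    rxns = []
    for r in model.reactions:
        if r.id in flip:
            rxns.append(
                replace(
                    r,
                    stoichiometry={k: -v for k, v in r.stoichiometry.items()},
                    lower_bound=-r.upper_bound,
                    upper_bound=-r.lower_bound,
                )
            )
        else:
            rxns.append(r)
    return MetabolicModel(id=model.id, metabolites=model.metabolites, reactions=tuple(rxns))
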