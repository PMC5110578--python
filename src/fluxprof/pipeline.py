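"""Orchestration: run a full strain profile, a constrained scan, or an
expression comparison, writing TSV outputs plus a JSON provenance record.

These functions are the library-level entry points behind the command-line
interface; each takes a :class:`RunConfig` (or explicit arguments) and
returns the output directory it populated.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import analysis
from .expression import (
    ExpressionProfile,
    expression_ratio,
    ks_two_sample,
    reaction_expression,
    read_expression_tsv,
)
from .model import (
    STRAIN_DELETIONS,
    Condition,
    MetabolicModel,
    anaerobic_condition,
    apply_condition,
    delete_reactions,
    load_model,
    resolve_reaction_id,
    stoichiometric_matrix,
)
from .sampling import SamplerConfig, sample

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_profile", "run_scan", "run_expression", "build_strain_model"]


@dataclass
class RunConfig:
    """Declarative description of one profiling run."""

    model_path: str | None = None  # None = bundled E. coli core model
    model_format: str | None = None
    strain: str = "wild_type"  # key of STRAIN_DELETIONS, or use `deletions`
    deletions: tuple[str, ...] | None = None  # explicit deletion list overrides strain
    condition: str = "anaerobic"  # "anaerobic", "none"
    bound_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    normalize_reference: str | None = "EX_glc__D_e"
    normalize_target: float = 10.0
    histogram_bins: int = 30
    out_dir: str = "fluxprof_out"

    def deletion_set(self) -> tuple[str, ...]:
        if self.deletions is not None:
            return tuple(self.deletions)
        try:
            return STRAIN_DELETIONS[self.strain]
        except KeyError:
            raise ValueError(
                f"unknown strain {self.strain!r}; expected one of "
                f"{sorted(STRAIN_DELETIONS)} or an explicit deletion list"
            ) from None


def _load_base_model(config: RunConfig) -> MetabolicModel:
    if config.model_path is None:
        from .model import load_bundled_ecoli_core

        return load_bundled_ecoli_core()
    return load_model(config.model_path, config.model_format)


def build_strain_model(config: RunConfig) -> MetabolicModel:
    """Load the base model, apply deletions and the condition."""
    model = _load_base_model(config)
    dels = config.deletion_set()
    if dels:
        label = config.strain if config.deletions is None else "custom"
        model = delete_reactions(model, list(dels), new_id=f"{model.id}_{label}")
    if config.condition == "anaerobic":
        model = apply_condition(model, anaerobic_condition(model))
    elif config.condition not in ("none", ""):
        raise ValueError(f"unknown condition {config.condition!r}")
    if config.bound_overrides:
        model = apply_condition(model, Condition(dict(config.bound_overrides)))
    return model


def _model_checksum(model: MetabolicModel) -> str:
    payload = json.dumps(
        [
            [m.id for m in model.metabolites],
            [
                [r.id, sorted(r.stoichiometry.items()), r.lower_bound, r.upper_bound, r.gpr]
                for r in model.reactions
            ],
        ],
        sort_keys=True,
    ).encode()
    return hashlib.sha256(payload).hexdigest()


def _provenance(config: RunConfig, model: MetabolicModel, extra: dict | None = None) -> dict:
    rec = {
        "config": dataclasses.asdict(config),
        "model_id": model.id,
        "model_checksum": _model_checksum(model),
        "seed": config.sampler.seed,
    }
    if extra:
        rec.update(extra)
    return rec


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def run_profile(config: RunConfig) -> Path:
    """Sample one strain's flux polytope and write all summaries.

    Outputs in ``config.out_dir``: samples.tsv (+ sidecar), summary.tsv,
    summary_normalized.tsv, flux_sums.tsv (on the normalized means),
    correlations.tsv, histograms.tsv (long format), provenance.json.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        model = build_strain_model(config)
        S = stoichiometric_matrix(model)
        logger.info("profiling %s (%d reactions), %d samples",
                    model.id, len(model.reactions), config.sampler.n_samples)
        samples = sample(model, config.sampler)
        samples.save(out / "samples.tsv")

        summary = analysis.summarize(samples)
        _write_tsv(summary.to_dataframe(), out / "summary.tsv")
        if config.normalize_reference is not None:
            ref = resolve_reaction_id(model, config.normalize_reference)
            norm = analysis.normalize(summary, ref, config.normalize_target)
            _write_tsv(norm.to_dataframe(), out / "summary_normalized.tsv")
            fs_vector = norm.mean
        else:
            fs_vector = summary.mean
        fs = analysis.flux_sum(S, fs_vector, model.metabolite_ids)
        _write_tsv(fs.to_dataframe(), out / "flux_sums.tsv")

        corr = analysis.correlations(samples)
        _write_tsv(corr.to_dataframe(), out / "correlations.tsv", index=True)

        hists = []
        for rid in model.reaction_ids:
            h = analysis.histogram(samples, rid, config.histogram_bins)
            df = h.to_dataframe()
            df.insert(0, "reaction_id", rid)
            hists.append(df)
        _write_tsv(pd.concat(hists, ignore_index=True), out / "histograms.tsv")

        (out / "provenance.json").write_text(
            json.dumps(_provenance(config, model), indent=2)
        )
    except Exception:
        (out / "FAILED").write_text("run_profile failed; partial outputs retained\n")
        raise
    return out


def run_scan(config: RunConfig, reaction: str, n_bins: int = 4) -> Path:
    """Constrained scan of one reaction over [0, LP-max] in equal bins."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        model = build_strain_model(config)
        rid = resolve_reaction_id(model, reaction)
        ref = (
            resolve_reaction_id(model, config.normalize_reference)
            if config.normalize_reference is not None
            else None
        )
        bins = analysis.constrained_scan(
            model,
            rid,
            n_bins,
            config.sampler,
            normalize_reference=ref,
            normalize_target=config.normalize_target,
        )
        rows = []
        for b, sb in enumerate(bins):
            bdir = out / f"bin_{b}"
            bdir.mkdir(exist_ok=True)
            rec = {
                "bin": b,
                "lower": sb.bounds[0],
                "upper": sb.bounds[1],
                "feasible": sb.feasible,
            }
            if sb.feasible:
                _write_tsv(sb.summary.to_dataframe(), bdir / "summary.tsv")
                _write_tsv(sb.flux_sums.to_dataframe(), bdir / "flux_sums.tsv")
                rec["mean_" + rid] = sb.summary.value(rid)
            rows.append(rec)
        _write_tsv(pd.DataFrame(rows), out / "scan_summary.tsv")
        (out / "provenance.json").write_text(
            json.dumps(
                _provenance(config, model, {"scan_reaction": rid, "n_bins": n_bins}),
                indent=2,
            )
        )
    except Exception:
        (out / "FAILED").write_text("run_scan failed; partial outputs retained\n")
        raise
    return out


def run_expression(
    config: RunConfig,
    control_tsv: str,
    case_tsv: str,
    *,
    exclude_genes: tuple[str, ...] = (),
    log2_input: bool = False,
    or_mode: str = "max",
) -> Path:
    """Map two expression tables onto reactions and compare them.

    Writes per-condition reaction-expression TSVs, the per-reaction
    case/control ratio-minus-one table, and a KS report (gene-level test).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        model = build_strain_model(config)
        control = read_expression_tsv(control_tsv, "control", log2=log2_input)
        case = read_expression_tsv(case_tsv, "case", log2=log2_input)
        excl = frozenset(exclude_genes)
        rx_control = reaction_expression(model, control, or_mode=or_mode, exclude_genes=excl)
        rx_case = reaction_expression(model, case, or_mode=or_mode, exclude_genes=excl)
        _write_tsv(rx_control.to_dataframe(), out / "reaction_expression_control.tsv")
        _write_tsv(rx_case.to_dataframe(), out / "reaction_expression_case.tsv")

        ratio = expression_ratio(rx_case, rx_control)
        df = pd.DataFrame(
            {"reaction_id": list(ratio), "ratio_minus_one": list(ratio.values())}
        )
        _write_tsv(df, out / "ratio_minus_one.tsv")

        a = [v for g, v in control.values.items() if g not in excl]
        b = [v for g, v in case.values.items() if g not in excl]
        D, p = ks_two_sample(a, b)
        report = {
            "ks_statistic": D,
            "p_value": p,
            "significant_at_5pct": bool(p < 0.05),
            "n_control": len(a),
            "n_case": len(b),
            "excluded_genes": sorted(excl),
            "reactions_missing_control": sorted(rx_control.missing),
            "reactions_missing_case": sorted(rx_case.missing),
        }
        (out / "ks_report.json").write_text(json.dumps(report, indent=2))
        (out / "provenance.json").write_text(
            json.dumps(
                _provenance(
                    config, model, {"control": str(control_tsv), "case": str(case_tsv)}
                ),
                indent=2,
            )
        )
    except Exception:
        (out / "FAILED").write_text("run_expression failed; partial outputs retained\n")
        raise
    return out
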