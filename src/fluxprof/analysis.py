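"""Summaries of flux sample sets.

Per-reaction averages (optionally normalized to a reference uptake rate),
metabolite flux-sums, Pearson correlation structure, per-reaction
histograms, and the constrained scan that slices an exchange reaction's
feasible range into bins and profiles each slice.

The flux-sum of metabolite i over a flux vector v is

    Phi_i = 0.5 * sum_j |S_ij v_j|

i.e. the metabolite's turnover rate (production = consumption at steady
state), in the same unit as the fluxes (mmol/gDW/h).  Flux-sums here are
computed on the (normalized) mean flux vector of a sample set.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np
import pandas as pd

from .lp import optimize_reaction
from .model import MetabolicModel, resolve_reaction_id, stoichiometric_matrix
from .sampling import FluxSampleSet, SamplerConfig, sample as _sample

__all__ = [
    "FluxSummary",
    "FluxSumTable",
    "CorrelationMatrix",
    "Histogram",
    "ScanBin",
    "summarize",
    "normalize",
    "flux_sum",
    "flux_sum_per_sample",
    "correlations",
    "histogram",
    "constrained_scan",
]


@dataclass(frozen=True)
class FluxSummary:
    reaction_ids: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray
    normalization: tuple[str, float] | None = None  # (reference reaction, target rate)

    def value(self, rid: str) -> float:
        return float(self.mean[self.reaction_ids.index(rid)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"reaction_id": self.reaction_ids, "mean": self.mean, "sd": self.sd}
        )


@dataclass(frozen=True)
class FluxSumTable:
    metabolite_ids: tuple[str, ...]
    phi: np.ndarray

    def value(self, mid: str) -> float:
        return float(self.phi[self.metabolite_ids.index(mid)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"metabolite_id": self.metabolite_ids, "flux_sum": self.phi})


@dataclass(frozen=True)
class CorrelationMatrix:
    reaction_ids: tuple[str, ...]
    r: np.ndarray  # NaN where undefined (zero-variance reactions)

    def value(self, a: str, b: str) -> float:
        i = self.reaction_ids.index(a)
        j = self.reaction_ids.index(b)
        return float(self.r[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.reaction_ids, columns=self.reaction_ids)


@dataclass(frozen=True)
class Histogram:
    reaction_id: str
    edges: np.ndarray
    counts: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_lo": self.edges[:-1], "bin_hi": self.edges[1:], "count": self.counts}
        )


def summarize(samples: FluxSampleSet) -> FluxSummary:
    """Mean and sample standard deviation (ddof=1) of each reaction's flux."""
    if samples.n_samples < 2:
        raise ValueError("need at least 2 samples to summarize")
    return FluxSummary(
        reaction_ids=tuple(samples.reaction_ids),
        mean=samples.samples.mean(axis=0),
        sd=samples.samples.std(axis=0, ddof=1),
    )


def normalize(summary: FluxSummary, reference: str, target: float = 10.0) -> FluxSummary:
    """Rescale all means and SDs so the reference reaction's mean magnitude
    equals ``target`` (e.g. glucose uptake of 10 mmol/gDW/h).

    Uniform rescaling preserves every ratio between reaction means.
    """
    ref = abs(summary.value(reference))
    if ref == 0.0:
        raise ZeroDivisionError(
            f"cannot normalize: reference reaction {reference!r} has zero mean flux"
        )
    scale = target / ref
    return FluxSummary(
        reaction_ids=summary.reaction_ids,
        mean=summary.mean * scale,
        sd=summary.sd * scale,
        normalization=(reference, float(target)),
    )


def flux_sum(
    S: np.ndarray, v: np.ndarray, metabolite_ids: list[str] | None = None
) -> FluxSumTable:
    """Phi_i = 0.5 * sum_j |S_ij v_j| for every metabolite (matrix row)."""
    S = np.asarray(S, dtype=float)
    v = np.asarray(v, dtype=float)
    if S.ndim != 2 or S.shape[1] != v.shape[0]:
        raise ValueError(f"dimension mismatch: S is {S.shape}, v has {v.shape[0]} entries")
    phi = 0.5 * np.abs(S * v[None, :]).sum(axis=1)
    if metabolite_ids is None:
        metabolite_ids = [f"m{i}" for i in range(S.shape[0])]
    return FluxSumTable(metabolite_ids=tuple(metabolite_ids), phi=phi)


def flux_sum_per_sample(samples: FluxSampleSet, model: MetabolicModel) -> FluxSumTable:
    """Alternative estimator: Phi computed per sample, then averaged.

    Differs from :func:`flux_sum` on the mean vector whenever a flux changes
    sign across samples (|mean| <= mean|.|); provided for comparison.
    """
    S = stoichiometric_matrix(model)
    # |S_ij v_j| = |S_ij| |v_j|, so the per-sample Phi is a matrix product
    phi = 0.5 * (np.abs(samples.samples) @ np.abs(S).T).mean(axis=0)
    return FluxSumTable(metabolite_ids=tuple(model.metabolite_ids), phi=phi)


def correlations(samples: FluxSampleSet) -> CorrelationMatrix:
    """Pearson correlation between every reaction pair over the samples.

    Zero-variance reactions (e.g. those blocked by a knockout) have no
    defined correlation; their rows/columns are NaN rather than 0.
    """
    if samples.n_samples < 3:
        raise ValueError("need at least 3 samples for correlations")
    X = samples.samples
    sd = X.std(axis=0)
    defined = sd > 0
    n = X.shape[1]
    r = np.full((n, n), np.nan)
    if defined.any():
        sub = np.corrcoef(X[:, defined], rowvar=False)
        sub = np.atleast_2d(sub)
        idx = np.flatnonzero(defined)
        r[np.ix_(idx, idx)] = sub
    return CorrelationMatrix(reaction_ids=tuple(samples.reaction_ids), r=r)


def histogram(samples: FluxSampleSet, reaction: str, n_bins: int = 30) -> Histogram:
    """Equal-width histogram of one reaction's sampled fluxes."""
    if reaction not in samples.reaction_ids:
        raise KeyError(f"reaction {reaction!r} not in sample set")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    x = samples.column(reaction)
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:  # constant flux: one occupied unit-width bin
        lo, hi = lo - 0.5, hi + 0.5
    counts, edges = np.histogram(x, bins=n_bins, range=(lo, hi))
    return Histogram(reaction_id=reaction, edges=edges, counts=counts)


@dataclass(frozen=True)
class ScanBin:
    bounds: tuple[float, float]
    feasible: bool
    summary: FluxSummary | None
    flux_sums: FluxSumTable | None
    samples: FluxSampleSet | None = None


def constrained_scan(
    model: MetabolicModel,
    reaction: str,
    n_bins: int,
    config: SamplerConfig,
    *,
    normalize_reference: str | None = None,
    normalize_target: float = 10.0,
    keep_samples: bool = False,
) -> list[ScanBin]:
    """Slice ``[0, LP-max]`` of one reaction into equal bins and profile each.

    For each bin the reaction is constrained to the bin's interval, the
    polytope is re-sampled, the summary is (optionally) normalized per bin,
    and flux-sums are computed on the bin's normalized mean flux vector.
    An infeasible bin is recorded as such and the scan continues.
    """
    from .model import Condition, apply_condition

    rid = resolve_reaction_id(model, reaction)
    v_max = optimize_reaction(model, rid, "max").objective
    if not np.isfinite(v_max) or v_max <= 0:
        raise ValueError(
            f"scan requires a finite positive LP maximum for {rid!r}; got {v_max}"
        )
    edges = np.linspace(0.0, v_max, n_bins + 1)
    S = stoichiometric_matrix(model)
    out: list[ScanBin] = []
    for b in range(n_bins):
        lo, hi = float(edges[b]), float(edges[b + 1])
        constrained = apply_condition(model, Condition({rid: (lo, hi)}))
        try:
            smp = _sample(constrained, config)
        except Exception:
            out.append(ScanBin(bounds=(lo, hi), feasible=False, summary=None, flux_sums=None))
            continue
        summ = summarize(smp)
        if normalize_reference is not None:
            summ = normalize(summ, normalize_reference, normalize_target)
        fs = flux_sum(S, summ.mean, model.metabolite_ids)
        out.append(
            ScanBin(
                bounds=(lo, hi),
                feasible=True,
                summary=summ,
                flux_sums=fs,
                samples=smp if keep_samples else None,
            )
        )
    return out
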