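"""Artificial centering hit-and-run (ACHR) sampling of the flux polytope.

The steady-state flux space of a constraint-based model is the bounded
polytope ``{v : S v = 0, l <= v <= u}``.  ACHR explores it in three steps:

1. find feasible warm-up points that span the polytope (here: the LP
   vertices from flux variability analysis, shrunk toward their mean so no
   point sits exactly at an extremity);
2. store them as columns of a matrix ``W`` and compute an approximate
   center ``s``;
3. iterate: pick a random warm-up column ``y``, move the current point
   ``x`` along the direction ``y - s`` by a step drawn uniformly from the
   feasible interval, and update the center.

Two center/direction update schemes are provided.  The default keeps the
direction set fixed at the warm-up points and lets ``s`` be the running mean
of all accepted points (the COBRA-Toolbox convention, which mixes well on
metabolic networks).  With ``update_warmup=True`` each new point replaces a
random column of ``W`` and the center is recomputed from ``W``, i.e. the
original Kaufman-Smith scheme; it is noticeably slower to mix across wide,
loosely-constrained loops (e.g. the quinone cycle of the E. coli core
network) and is kept for comparison.

Numerical housekeeping: points are periodically reprojected onto the null
space of ``S`` (floating-point drift would otherwise accumulate), a step
whose result violates the bounds beyond tolerance is rejected and the walk
restarts from the center, and coordinates that flux variability proves fixed
(min = max, e.g. reactions structurally blocked by a knockout) are pinned to
their unique value so knockouts yield exact zeros.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import null_space

from .lp import InfeasibleModelError, assert_feasible, flux_variability
from .model import MetabolicModel, stoichiometric_matrix

__all__ = [
    "SamplerConfig",
    "WarmupSet",
    "FluxSampleSet",
    "generate_warmup",
    "sample",
    "step_limits",
    "sampling_error",
]

_BIG_STEP_CAP = 1e9


@dataclass(frozen=True)
class SamplerConfig:
    """Knobs of the ACHR sampler.

    ``n_samples`` full flux vectors are returned, one every
    ``steps_per_sample`` accepted steps (thinning).  ``reproject_every``
    controls how often the chain is re-orthogonalized against the row space
    of S; ``residual_tolerance`` is the steady-state residual each returned
    sample must satisfy (max |S v|).
    """

    n_samples: int = 2000
    n_warmup: int | None = None  # basic hit-and-run warm-up only; FVA mode yields 2 per reaction
    steps_per_sample: int = 100
    seed: int = 42
    residual_tolerance: float = 1e-6
    reproject_every: int = 10
    shrink: float = 0.3
    warmup_mode: str = "fva"  # or "hit_and_run"
    update_warmup: bool = False
    direction_tolerance: float = 1e-7
    bounds_tolerance: float = 1e-9
    max_retries: int = 100

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.residual_tolerance <= 0:
            raise ValueError("residual_tolerance must be > 0")
        if self.n_warmup is not None and self.n_warmup < 2:
            raise ValueError("n_warmup must be >= 2")
        if not 0 <= self.shrink < 1:
            raise ValueError("shrink must be in [0, 1)")
        if self.warmup_mode not in ("fva", "hit_and_run"):
            raise ValueError(f"unknown warmup_mode {self.warmup_mode!r}")


@dataclass
class WarmupSet:
    """Feasible points spanning the polytope, as columns of ``W``."""

    W: np.ndarray  # n_reactions x n_points
    fva_min: np.ndarray
    fva_max: np.ndarray

    @property
    def n_points(self) -> int:
        return self.W.shape[1]


@dataclass
class FluxSampleSet:
    """``n_samples`` flux vectors (rows) over the model's reactions."""

    reaction_ids: list[str]
    samples: np.ndarray  # n_samples x n_reactions
    model_id: str = ""
    config: SamplerConfig = field(default_factory=SamplerConfig)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    def column(self, rid: str) -> np.ndarray:
        return self.samples[:, self.reaction_ids.index(rid)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples, columns=self.reaction_ids)

    def save(self, path) -> None:
        """Write samples as TSV plus a JSON provenance sidecar."""
        path = Path(path)
        self.to_dataframe().to_csv(path, sep="\t", index=False)
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(
            json.dumps(
                {"model_id": self.model_id, "config": asdict(self.config)},
                indent=2,
            )
        )

    @classmethod
    def load(cls, path) -> "FluxSampleSet":
        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        model_id, config = "", SamplerConfig()
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            model_id = meta.get("model_id", "")
            config = SamplerConfig(**meta.get("config", {}))
        return cls(
            reaction_ids=list(df.columns),
            samples=df.to_numpy(dtype=float),
            model_id=model_id,
            config=config,
        )


def step_limits(
    x: np.ndarray,
    d: np.ndarray,
    l: np.ndarray,
    u: np.ndarray,
    epsilon: float | None = None,
) -> tuple[float, float]:
    """Feasible step interval: ``l <= x + a*d <= u`` for all a in [a_min, a_max].

    Coordinates with |d_k| below ``epsilon`` (default ``1e-9 * max(1, |d|_inf)``)
    are ignored.  A direction unbounded on one side (infinite bounds) is
    clamped at a large finite cap with a warning.
    """
    x = np.asarray(x, dtype=float)
    d = np.asarray(d, dtype=float)
    if epsilon is None:
        epsilon = 1e-9 * max(1.0, float(np.abs(d).max()) if d.size else 1.0)
    mask = np.abs(d) > epsilon
    if not mask.any():
        return 0.0, 0.0
    dm = d[mask]
    cand = np.concatenate([(l[mask] - x[mask]) / dm, (u[mask] - x[mask]) / dm])
    pos = cand[cand > 0]
    neg = cand[cand <= 0]
    a_max = float(pos.min()) if pos.size else 0.0
    a_min = float(neg.max()) if neg.size else 0.0
    if not np.isfinite(a_max):
        warnings.warn("unbounded step direction clamped", RuntimeWarning, stacklevel=2)
        a_max = _BIG_STEP_CAP
    if not np.isfinite(a_min):
        warnings.warn("unbounded step direction clamped", RuntimeWarning, stacklevel=2)
        a_min = -_BIG_STEP_CAP
    return a_min, a_max


def _nullspace(S: np.ndarray, n: int) -> np.ndarray:
    if S.shape[0] == 0:
        return np.eye(n)
    N = null_space(S)
    if N.size == 0:
        # polytope is (at most) a single point; keep an empty basis
        return np.zeros((n, 0))
    return N


def generate_warmup(model: MetabolicModel, config: SamplerConfig) -> WarmupSet:
    """Warm-up points spanning the polytope.

    Default (``warmup_mode="fva"``): minimize and maximize each reaction by
    LP (2 points per reaction), then shrink every point toward the running
    mean by ``config.shrink`` so none sits exactly at a vertex.  The
    alternative ``"hit_and_run"`` mode runs a basic hit-and-run walk from a
    feasible interior point and keeps ``n_warmup`` thinned points.
    """
    S = stoichiometric_matrix(model)
    l, u = model.lower_bounds, model.upper_bounds
    if config.warmup_mode == "fva":
        mins, maxs, W = flux_variability(model, return_vertices=True)
    else:
        mins, maxs = flux_variability(model)
        W = _hit_and_run_warmup(model, S, l, u, mins, maxs, config)
    center = W.mean(axis=1, keepdims=True)
    W = center + (1.0 - config.shrink) * (W - center)
    N = _nullspace(S, len(model.reactions))
    if S.shape[0] > 0 and N.shape[1] > 0:
        W = N @ (N.T @ W)
    ws = WarmupSet(W=W, fva_min=mins, fva_max=maxs)
    resid = sampling_error(W.T, S)
    if resid > config.residual_tolerance:
        raise RuntimeError(
            f"warm-up residual {resid:.2e} exceeds tolerance "
            f"{config.residual_tolerance:.2e} for model {model.id!r}"
        )
    return ws


def _hit_and_run_warmup(model, S, l, u, mins, maxs, config) -> np.ndarray:
    """Basic hit-and-run from one interior point, thinned; literal variant
    of the classic warm-up."""
    n = len(model.reactions)
    n_points = config.n_warmup if config.n_warmup is not None else 2 * n
    rng = np.random.default_rng(config.seed)
    N = _nullspace(S, n)
    x = assert_feasible(model)
    if N.shape[1] > 0:
        x = N @ (N.T @ x)
    fixed = (maxs - mins) < config.direction_tolerance
    pts = []
    thin = 5
    while len(pts) < n_points:
        for _ in range(thin):
            if N.shape[1] == 0:
                break
            d = N @ rng.standard_normal(N.shape[1])
            d[fixed] = 0.0
            if np.abs(d).max() < config.direction_tolerance:
                continue
            a_min, a_max = step_limits(x, d, l, u, epsilon=config.direction_tolerance)
            a = a_min + rng.uniform() * max(a_max - a_min, 0.0)
            cand = x + a * d
            if ((l - cand) > 1e-6).any() or ((cand - u) > 1e-6).any():
                continue
            x = cand
        pts.append(x.copy())
    return np.array(pts).T


def sample(
    model: MetabolicModel,
    config: SamplerConfig | None = None,
    warmup: WarmupSet | None = None,
) -> FluxSampleSet:
    """Run the ACHR chain and return ``config.n_samples`` flux vectors.

    Deterministic: identical model + config (seed included) give a
    bit-identical sample set.  Every returned sample satisfies the bounds to
    within ``config.bounds_tolerance`` and the steady-state residual to
    within ``config.residual_tolerance`` (checked; violation raises).
    """
    if config is None:
        config = SamplerConfig()
    S = stoichiometric_matrix(model)
    l, u = model.lower_bounds, model.upper_bounds
    n = len(model.reactions)
    if warmup is None:
        warmup = generate_warmup(model, config)
    W = warmup.W.copy()
    k = W.shape[1]
    if k < 2:
        raise ValueError("need at least 2 warm-up points")

    fixed = (warmup.fva_max - warmup.fva_min) < config.direction_tolerance
    fixed_values = 0.5 * (warmup.fva_min + warmup.fva_max)
    fixed_values[np.abs(fixed_values) < 1e-9] = 0.0  # exact zeros for blocked reactions

    rng = np.random.default_rng(config.seed)
    N = _nullspace(S, n)
    samples = np.empty((config.n_samples, n))

    if fixed.all() or N.shape[1] == 0:
        # polytope is a single point
        point = fixed_values if fixed.all() else W.mean(axis=1)
        samples[:] = point
        _validate(samples, S, l, u, config)
        return FluxSampleSet(
            reaction_ids=model.reaction_ids,
            samples=samples,
            model_id=model.id,
            config=config,
        )

    center = W.mean(axis=1)
    x = center.copy()
    free = ~fixed

    def one_step(x0: np.ndarray, d: np.ndarray) -> np.ndarray | None:
        dm = np.where(free, d, 0.0)
        if np.abs(dm).max() < config.direction_tolerance:
            return None
        a_min, a_max = step_limits(x0, dm, l, u, epsilon=config.direction_tolerance)
        a = a_min + rng.uniform() * max(a_max - a_min, 0.0)
        p = x0 + a * dm
        if ((l - p) > config.bounds_tolerance).any() or (
            (p - u) > config.bounds_tolerance
        ).any():
            return None
        return p

    total = config.n_samples * config.steps_per_sample
    for it in range(1, total + 1):
        yi = rng.integers(k)
        p = one_step(x, W[:, yi] - center)
        tries = 0
        while p is None:
            tries += 1
            if tries > config.max_retries:
                raise RuntimeError(
                    f"sampler cannot escape the current point in model "
                    f"{model.id!r} after {config.max_retries} retries"
                )
            yi = rng.integers(k)
            p = one_step(center, W[:, yi] - center)
        x = p
        if it % config.reproject_every == 0:
            x = N @ (N.T @ x)
        if config.update_warmup:
            # new point replaces a random warm-up column; center follows W
            ri = rng.integers(k)
            center = center + (x - W[:, ri]) / k
            W[:, ri] = x
        else:
            center = ((it - 1) * center + x) / it
        if it % config.steps_per_sample == 0:
            samples[it // config.steps_per_sample - 1] = x

    samples[:, fixed] = fixed_values[fixed]
    _validate(samples, S, l, u, config)
    return FluxSampleSet(
        reaction_ids=model.reaction_ids,
        samples=samples,
        model_id=model.id,
        config=config,
    )


def _validate(samples, S, l, u, config) -> None:
    resid = sampling_error(samples, S)
    if resid > config.residual_tolerance:
        raise RuntimeError(
            f"steady-state residual {resid:.3e} exceeds tolerance "
            f"{config.residual_tolerance:.1e} after reprojection"
        )
    viol = max(
        float((l[None, :] - samples).max(initial=0.0)),
        float((samples - u[None, :]).max(initial=0.0)),
    )
    if viol > config.bounds_tolerance:
        raise RuntimeError(f"bound violation {viol:.3e} in returned samples")


def sampling_error(samples, S: np.ndarray) -> float:
    """Max over samples of the steady-state residual ``|S v|_inf``."""
    if isinstance(samples, FluxSampleSet):
        samples = samples.samples
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if S.shape[0] == 0:
        return 0.0
    return float(np.abs(S @ samples.T).max())
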