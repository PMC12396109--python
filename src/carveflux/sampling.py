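"""Randomized sampling of the steady-state flux polytope.

Two complementary explorations of a carved model's solution space:

* a *global* sampler — artificial-centering hit-and-run over the polytope
  ``{v : S v = 0, lb <= v <= ub}``, with thinning to curb autocorrelation
  and convergence-test-driven sample-size selection;
* a *corner* sampler — repeated LP solves with random normally distributed
  objectives, landing on vertices/faces and thereby weighing the extreme
  phenotypes of the solution space.

All randomness flows from a single seed; identical (model, config, seed)
yields bit-identical sample matrices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import cobra
import numpy as np
import pandas as pd

from . import lp
from .diagnostics import ChainTooShortError, geweke_z, raftery_lewis

__all__ = [
    "SamplerConfig",
    "FluxSampleMatrix",
    "ConvergenceReport",
    "warmup_points",
    "sample_global",
    "sample_corner",
    "sample_until_converged",
    "write_samples",
    "read_samples",
]

_DIR_TOL = 1e-12
_MAX_RETRIES = 1000


@dataclass
class SamplerConfig:
    """Sampling parameters.

    thinning: record every k-th hit-and-run step (default 100; large
    production runs use 10 000).  batch_size: recorded samples per
    convergence check.  max_samples: hard cap on recorded samples.
    n_warmup: LP warmup vertices (default 2 x reaction count).
    z_crit / min_fraction_converged and the Raftery-Lewis (q, r, s)
    parametrize the stopping rule of :func:`sample_until_converged`.
    """

    thinning: int = 100
    batch_size: int = 5000
    max_samples: int = 150_000
    seed: int = 0
    n_warmup: int | None = None
    z_crit: float = 1.96
    min_fraction_converged: float = 0.95
    n_monitored: int = 50
    rl_q: float = 0.025
    rl_r: float = 0.005
    rl_s: float = 0.95

    def __post_init__(self) -> None:
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if self.batch_size < 100:
            raise ValueError("batch_size must be >= 100")
        if self.max_samples < self.batch_size:
            raise ValueError("max_samples must be >= batch_size")


@dataclass
class FluxSampleMatrix:
    """Samples x reactions flux matrix (mol·kgDW⁻¹·h⁻¹) with provenance."""

    values: np.ndarray
    reaction_ids: list[str]
    method: str  # "global" | "corner"
    thinning: int
    seed: int

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.reaction_ids)

    def column(self, reaction_id: str) -> np.ndarray:
        return self.values[:, self.reaction_ids.index(reaction_id)]


@dataclass
class ConvergenceReport:
    geweke_z: dict[str, float]
    fraction_converged: float
    raftery_lewis_nmin: int
    converged: bool
    n_samples_used: int
    variance_estimator: str = "spectral"
    monitored_reactions: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "fraction_converged": self.fraction_converged,
            "raftery_lewis_nmin": self.raftery_lewis_nmin,
            "converged": self.converged,
            "n_samples_used": self.n_samples_used,
            "variance_estimator": self.variance_estimator,
            "monitored_reactions": self.monitored_reactions,
            "geweke_z": self.geweke_z,
        }


def warmup_points(model: cobra.Model, n: int | None = None, seed: int = 0) -> np.ndarray:
    """LP warmup vertices: each reaction's FVA min and max first, then
    optima of random ± single-reaction objectives.  Rows satisfy the
    polytope constraints."""
    pol = lp.polytope_from_model(model)
    return _warmup(pol, n if n is not None else 2 * pol.n_reactions, seed)


def _warmup(pol: lp.FluxPolytope, n: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    nr = pol.n_reactions
    pts = np.empty((n, nr))
    c = np.zeros(nr)
    for k in range(n):
        c[:] = 0.0
        if k < 2 * nr:  # first cycle: FVA corners
            i, sign = divmod(k, 2)
            c[i] = 1.0 if sign == 0 else -1.0
        else:
            c[int(rng.integers(nr))] = 1.0 if rng.random() < 0.5 else -1.0
        pts[k], _ = lp.maximize(pol, c)
    return pts


class _AchrChain:
    """Artificial-centering hit-and-run over a flux polytope (persistent state).

    Directions are drawn as (random warmup vertex - running center); since
    every stored point and the center satisfy ``S v = 0``, every direction
    lies in the null space and steady state is preserved along the chord.
    The running center is the mean over all accepted points.  The warmup
    vertices are re-projected onto the null space once at initialization
    (LP-solver residuals ~1e-7 would otherwise leak out of the null space),
    and walker and center are re-projected every ``_PROJECT_EVERY`` steps:
    the center update feeds the walker's rounding error back into future
    directions, which amplifies it exponentially if left uncorrected.
    """

    _PROJECT_EVERY = 1000

    def __init__(self, pol: lp.FluxPolytope, config: SamplerConfig):
        self.pol = pol
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        n_warm = config.n_warmup if config.n_warmup is not None else 2 * pol.n_reactions
        stored = _warmup(pol, n_warm, config.seed)
        self._pinv = np.linalg.pinv(pol.S)
        self.stored = stored - (self._pinv @ (pol.S @ stored.T)).T
        self.center = self.stored.mean(axis=0)
        self.x = self.center.copy()
        self.n_accepted = self.stored.shape[0]
        self._steps = 0

    def run(self, n_records: int) -> np.ndarray:
        pol, rng = self.pol, self.rng
        lb, ub = pol.lb, pol.ub
        thin = self.config.thinning
        out = np.empty((n_records, pol.n_reactions))
        x, center = self.x, self.center
        n_stored = self.stored.shape[0]
        recorded = 0
        retries = 0
        while recorded < n_records:
            d = self.stored[int(rng.integers(n_stored))] - center
            nrm = float(np.linalg.norm(d))
            if nrm < _DIR_TOL:
                retries += 1
                if retries >= _MAX_RETRIES:
                    raise RuntimeError(
                        f"{_MAX_RETRIES} consecutive degenerate directions; "
                        "polytope may be a single point (run remove_blocked)"
                    )
                continue
            retries = 0
            d /= nrm
            lo = np.where(d > _DIR_TOL, (lb - x) / d, np.where(d < -_DIR_TOL, (ub - x) / d, -np.inf))
            hi = np.where(d > _DIR_TOL, (ub - x) / d, np.where(d < -_DIR_TOL, (lb - x) / d, np.inf))
            tmin = float(lo.max())
            tmax = float(hi.min())
            if tmax <= tmin:  # degenerate chord; stay put this step
                t = 0.0
            else:
                t = tmin + rng.random() * (tmax - tmin)
            x = x + t * d
            self.n_accepted += 1
            center = center + (x - center) / self.n_accepted
            self._steps += 1
            if self._steps % self._PROJECT_EVERY == 0:
                x -= self._pinv @ (pol.S @ x)
                center -= self._pinv @ (pol.S @ center)
            if self._steps % thin == 0:
                out[recorded] = x
                recorded += 1
        self.x, self.center = x, center
        return out


def sample_global(
    model: cobra.Model, config: SamplerConfig | None = None, n_samples: int | None = None
) -> FluxSampleMatrix:
    """Hit-and-run samples of the whole solution space (``n_samples`` rows,
    default one batch).  Apply :func:`carveflux.carve.remove_blocked` first so
    the polytope is full-dimensional."""
    config = config or SamplerConfig()
    n = min(n_samples if n_samples is not None else config.batch_size, config.max_samples)
    pol = lp.polytope_from_model(model)
    chain = _AchrChain(pol, config)
    values = chain.run(n)
    return FluxSampleMatrix(
        values=values,
        reaction_ids=pol.reaction_ids,
        method="global",
        thinning=config.thinning,
        seed=config.seed,
    )


def sample_corner(model: cobra.Model, n: int, seed: int = 0) -> FluxSampleMatrix:
    """Corner-based samples: optima of ``n`` random standard-normal objectives.

    Each sample is an LP optimum, i.e. a vertex or boundary face point of
    the polytope, so this method weighs the extreme metabolic behaviors.
    """
    pol = lp.polytope_from_model(model)
    rng = np.random.default_rng(seed)
    values = np.empty((n, pol.n_reactions))
    for k in range(n):
        c = rng.standard_normal(pol.n_reactions)
        values[k], _ = lp.maximize(pol, c)
    return FluxSampleMatrix(
        values=values, reaction_ids=pol.reaction_ids, method="corner", thinning=1, seed=seed
    )


def sample_until_converged(
    model: cobra.Model, config: SamplerConfig | None = None
) -> tuple[FluxSampleMatrix, ConvergenceReport]:
    """Grow a global sampling chain batch-by-batch until convergence.

    After each batch the Geweke z-score is computed for every reaction and
    the Raftery-Lewis requirement for the ``n_monitored`` highest-variance
    reactions; the chain is declared converged when at least
    ``min_fraction_converged`` of reactions pass |z| < z_crit and the chain
    exceeds the largest Raftery-Lewis requirement.  Non-convergence at
    ``max_samples`` is a reported state, not an error.
    """
    config = config or SamplerConfig()
    pol = lp.polytope_from_model(model)
    chain = _AchrChain(pol, config)
    batches: list[np.ndarray] = []
    n_total = 0
    converged = False
    frac = 0.0
    rl_nmin = 0
    z_by_rxn: dict[str, float] = {}
    monitored: list[str] = []

    while n_total < config.max_samples:
        batch = chain.run(min(config.batch_size, config.max_samples - n_total))
        batches.append(batch)
        n_total += batch.shape[0]
        values = np.concatenate(batches, axis=0)

        zs = np.array([geweke_z(values[:, j]) for j in range(values.shape[1])])
        z_by_rxn = dict(zip(pol.reaction_ids, zs.tolist()))
        frac = float(np.mean(np.abs(zs) < config.z_crit))

        variances = values.var(axis=0)
        order = np.argsort(variances)[::-1][: config.n_monitored]
        monitored = [pol.reaction_ids[j] for j in order]
        rl_nmin = 0
        rl_ok = True
        for j in order:
            if variances[j] == 0:
                continue
            try:
                rl_nmin = max(rl_nmin, raftery_lewis(
                    values[:, j], q=config.rl_q, r=config.rl_r, s=config.rl_s
                ).n_required)
            except ChainTooShortError as exc:
                rl_ok = False
                rl_nmin = max(rl_nmin, int(str(exc).split("at least ")[1].split(" ")[0]))
        if rl_ok and frac >= config.min_fraction_converged and n_total >= rl_nmin:
            converged = True
            break

    samples = FluxSampleMatrix(
        values=np.concatenate(batches, axis=0),
        reaction_ids=pol.reaction_ids,
        method="global",
        thinning=config.thinning,
        seed=config.seed,
    )
    report = ConvergenceReport(
        geweke_z=z_by_rxn,
        fraction_converged=frac,
        raftery_lewis_nmin=rl_nmin,
        converged=converged,
        n_samples_used=n_total,
        monitored_reactions=monitored,
    )
    return samples, report


def write_samples(
    samples: FluxSampleMatrix, path: str | Path, report: ConvergenceReport | None = None
) -> None:
    """Sample matrix as TSV (header = reaction ids) plus a JSON sidecar of
    method/seed/thinning and, when available, the convergence report."""
    path = Path(path)
    samples.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.10g")
    meta = {
        "method": samples.method,
        "seed": samples.seed,
        "thinning": samples.thinning,
        "n_samples": samples.n_samples,
    }
    if report is not None:
        meta["convergence"] = report.to_dict()
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_samples(path: str | Path) -> FluxSampleMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return FluxSampleMatrix(
        values=df.to_numpy(dtype=float),
        reaction_ids=list(df.columns),
        method=meta.get("method", "global"),
        thinning=int(meta.get("thinning", 1)),
        seed=int(meta.get("seed", 0)),
    )
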