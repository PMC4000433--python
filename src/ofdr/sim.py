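"""Generative model and Monte-Carlo runner for the time-course study design.

The emulated experiment observes ``m`` genes at ``n_timepoints`` equally
treated time points, one expression value per gene per time point, with unit
variance and a common equicorrelation ``rho`` across genes within a time
point.  Interest is in differential expression between successive time
points, giving ``q = n_timepoints - 1`` individual hypotheses per gene.

For gene ``i`` the standardized successive difference is
``delta[j, i] = (mu[j+1, i] - mu[j, i]) / sqrt(2)``.  Of the m genes, ``m0``
are global nulls (delta identically zero); the rest — the *false-null
genes* — receive i.i.d. uniform components from one of three intervals:
(-0.75, 0.75) for half of them (weak, sign-mixed effects) and
(-4.25, -2.75) / (2.75, 4.25) for a quarter each (strong one-sided effects).

The test statistic ``T[j, i] = (Z[j+1, i] - Z[j, i]) / sqrt(2)`` is N(delta, 1)
under this model (the factor sqrt(2) standardizes the difference of two
unit-variance variables), with two-sided p-value ``2 * (1 - Phi(|T|))``.

Defaults reproduce the reference study conditions: m = 1000 genes, 6 time
points (q = 5), alpha = 0.05, 1000 replications, rho in {0, 0.2, 0.5, 0.8}.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .core import ALL_METHODS, PValueSetCollection, run_procedure
from .metrics import ErrorPowerEstimates, TruthSpec, evaluate

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "draw_effects",
    "draw_expression",
    "successive_tests",
    "simulate_dataset",
    "run_experiment",
    "run_m0_sweep",
    "DEFAULT_INTERVALS",
    "DEFAULT_MIXTURE",
]

DEFAULT_MIXTURE = (0.5, 0.25, 0.25)
DEFAULT_INTERVALS = ((-0.75, 0.75), (-4.25, -2.75), (2.75, 4.25))
SQRT2 = np.sqrt(2.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the generative model and the Monte-Carlo run.

    ``m0`` counts the true-null genes; ``m - m0`` is the number of false-null
    genes (the x-axis of the error/power sweeps).
    """

    m: int = 1000
    n_timepoints: int = 6
    m0: int | None = None  # true-null genes; defaults to m // 2
    rho: float = 0.0
    alpha: float = 0.05
    mixture: tuple[float, ...] = DEFAULT_MIXTURE
    intervals: tuple[tuple[float, float], ...] = DEFAULT_INTERVALS
    n_reps: int = 1000
    seed: int | None = None

    def __post_init__(self):
        if self.m0 is None:
            object.__setattr__(self, "m0", self.m // 2)
        if not 0 <= self.m0 <= self.m:
            raise ValueError(f"require 0 <= m0 <= m, got m0={self.m0}, m={self.m}")
        if self.n_timepoints < 2:
            raise ValueError("need at least two time points")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"rho must lie in [0, 1), got {self.rho}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if len(self.mixture) != len(self.intervals):
            raise ValueError("mixture and intervals must have equal length")
        if not np.isclose(sum(self.mixture), 1.0):
            raise ValueError(f"mixture proportions must sum to 1, got {sum(self.mixture)}")

    @property
    def q(self) -> int:
        return self.n_timepoints - 1


@dataclass
class SimulatedDataset:
    """One replication: expression values, true effects, and derived truth."""

    Z: np.ndarray       # (n_timepoints, m)
    delta: np.ndarray   # (q, m) standardized successive differences
    truth: TruthSpec    # per-gene, derived from delta (sets = genes)


def _apportion(k: int, proportions: tuple[float, ...], rng: np.random.Generator) -> np.ndarray:
    """Largest-remainder apportionment of k items; remainder ties broken by rng."""
    exact = np.asarray(proportions) * k
    sizes = np.floor(exact).astype(int)
    short = k - sizes.sum()
    if short > 0:
        frac = exact - np.floor(exact)
        # random jitter breaks exact fractional ties without exceeding them
        order = np.argsort(-(frac + rng.uniform(0, 1e-9, frac.size)), kind="stable")
        sizes[order[:short]] += 1
    return sizes


def draw_effects(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, TruthSpec]:
    """Draw the (q, m) effect matrix delta and its ground truth.

    m0 genes, chosen uniformly at random, get a zero column.  The remaining
    genes are partitioned into the mixture groups by largest-remainder
    apportionment and receive q i.i.d. uniform draws from their group's
    interval.
    """
    q, m = config.q, config.m
    delta = np.zeros((q, m))
    n_false = m - config.m0
    if n_false > 0:
        false_genes = rng.permutation(m)[:n_false]
        sizes = _apportion(n_false, config.mixture, rng)
        start = 0
        for size, (lo, hi) in zip(sizes, config.intervals):
            cols = false_genes[start : start + size]
            delta[:, cols] = rng.uniform(lo, hi, size=(q, size))
            start += size
    truth = TruthSpec.from_signs(np.sign(delta).astype(int).T)
    return delta, truth


def draw_expression(
    delta: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Draw Z ~ N(mu, Sigma) with unit variances and equicorrelation rho.

    The means satisfy ``(mu[j+1] - mu[j]) / sqrt(2) = delta[j]`` with
    ``mu[0] = 0`` (only successive differences matter).  Each time point is
    sampled independently via the single-factor construction
    ``Z_j = mu_j + sqrt(rho) * W_j + sqrt(1 - rho) * eps_j`` with scalar
    ``W_j`` — exact in distribution and O(m) per draw.
    """
    if not 0.0 <= config.rho < 1.0:
        raise ValueError(f"rho must lie in [0, 1), got {config.rho}")
    T, m = config.n_timepoints, config.m
    if delta.shape != (T - 1, m):
        raise ValueError(f"delta must have shape {(T - 1, m)}, got {delta.shape}")
    mu = np.vstack([np.zeros(m), np.cumsum(delta * SQRT2, axis=0)])
    W = rng.standard_normal(T)
    eps = rng.standard_normal((T, m))
    return mu + np.sqrt(config.rho) * W[:, None] + np.sqrt(1.0 - config.rho) * eps


def successive_tests(Z: np.ndarray, labels=None) -> PValueSetCollection:
    """z-tests of all successive differences; one hypothesis set per gene.

    ``T[j, i] = (Z[j+1, i] - Z[j, i]) / sqrt(2)`` is standard normal under the
    null, with two-sided p-value ``2 * (1 - Phi(|T|))`` and sign ``sign(T)``.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or Z.shape[0] < 2:
        raise ValueError("Z must be (n_timepoints >= 2, m)")
    T = np.diff(Z, axis=0) / SQRT2
    p = 2.0 * stats.norm.sf(np.abs(T))
    return PValueSetCollection(p.T, np.sign(T).astype(int).T, labels)


def simulate_dataset(config: SimulationConfig, rng: np.random.Generator) -> SimulatedDataset:
    """Draw one full replication (effects, expression, truth)."""
    delta, truth = draw_effects(config, rng)
    Z = draw_expression(delta, config, rng)
    return SimulatedDataset(Z=Z, delta=delta, truth=truth)


def run_experiment(
    config: SimulationConfig,
    methods: tuple[str, ...] = ALL_METHODS,
    keep_reps: bool = False,
) -> dict[str, ErrorPowerEstimates]:
    """Monte-Carlo estimates of OFDR, mdFDR and powers for each method.

    All methods see identical data within a replication (common random
    numbers), so power orderings are compared on the same draws.  Results are
    deterministic given ``config.seed``: per-replication generators are
    spawned from one seed sequence.
    """
    unknown = set(methods) - set(ALL_METHODS)
    if unknown:
        raise ValueError(f"unknown method(s): {sorted(unknown)}")
    streams = np.random.SeedSequence(config.seed).spawn(config.n_reps)
    acc = {name: {"ofdr": [], "mdfdr": [], "power_i": [], "power_ii": []} for name in methods}
    for ss in streams:
        rng = np.random.default_rng(ss)
        data = simulate_dataset(config, rng)
        collection = successive_tests(data.Z)
        for name in methods:
            report = run_procedure(collection, config.alpha, name)
            rep = evaluate(report, data.truth)
            acc[name]["ofdr"].append(rep.ofdr)
            acc[name]["mdfdr"].append(rep.mdfdr)
            acc[name]["power_i"].append(rep.power_i)
            acc[name]["power_ii"].append(rep.power_ii)
    return {
        name: ErrorPowerEstimates.from_replications(
            name,
            np.array(vals["ofdr"]),
            np.array(vals["mdfdr"]),
            np.array(vals["power_i"]),
            np.array(vals["power_ii"]),
            keep_reps=keep_reps,
        )
        for name, vals in acc.items()
    }


def run_m0_sweep(
    config: SimulationConfig,
    n_false_grid: np.ndarray | list[int] | None = None,
    methods: tuple[str, ...] = ALL_METHODS,
) -> pd.DataFrame:
    """Sweep the number of false-null genes and tabulate all estimates.

    Returns a tidy frame with one row per (method, grid point) carrying the
    configuration, the estimates and their standard errors — the input for
    the error/power figures.  The default grid is 11 evenly spaced counts
    from 0 to m.
    """
    if n_false_grid is None:
        n_false_grid = np.linspace(0, config.m, 11).round().astype(int)
    rows = []
    for k, n_false in enumerate(n_false_grid):
        seed = None if config.seed is None else int(config.seed)
        cfg = replace(config, m0=config.m - int(n_false),
                      seed=None if seed is None else seed + k)
        results = run_experiment(cfg, methods)
        for name, est in results.items():
            rows.append(
                {
                    "method": name,
                    "rho": config.rho,
                    "alpha": config.alpha,
                    "m": config.m,
                    "n_false_sets": int(n_false),
                    "n_reps": cfg.n_reps,
                    "ofdr": est.ofdr,
                    "mdfdr": est.mdfdr,
                    "power_i": est.power_i,
                    "power_ii": est.power_ii,
                    "se_ofdr": est.se_ofdr,
                    "se_mdfdr": est.se_mdfdr,
                    "se_power_i": est.se_power_i,
                    "se_power_ii": est.se_power_ii,
                }
            )
    return pd.DataFrame(rows)
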