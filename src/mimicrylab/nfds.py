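"""Negative frequency-dependent selection (NFDS) with positive selection and drift.

A one-locus, two-allele model for a Batesian mimicry supergene: the mimetic
allele *m* is dominant over the non-mimetic allele *n*, and the fitness of
each genotype declines as the frequency of the matching phenotype rises
(predators learn common patterns).  Genotype fitnesses are

    w_mm = a * (1 - z*f_mm - z*f_mn)
    w_mn = b * (1 - z*f_mm - z*f_mn)
    w_nn =      1 - z*f_nn

where ``z`` in [0, 1) is the strength of frequency dependence, ``a`` and
``b`` are extra fitness multipliers for the mimetic homozygote and the
heterozygote, and ``f_mm, f_mn, f_nn`` are Hardy-Weinberg genotype
frequencies.  The deterministic allele-frequency recursion is

    p' = (p^2 w_mm + p q w_mn) / W,   W = p^2 w_mm + 2 p q w_mn + q^2 w_nn

so that p' + q' = 1 exactly.  Genetic drift is Wright-Fisher binomial
resampling of 2*Ne allele copies from p'.

With a = b = 1 (pure NFDS) the deterministic map converges, for any z, to
the phenotype-frequency parity point p* = 1 - sqrt(1/2); for a = b > 1 the
interior equilibrium satisfies q*^2 = (1 - a + a z) / (z (a + 1)) whenever
that quantity lies in (0, 1).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NFDSParams",
    "GenotypeFrequencies",
    "FitnessTriple",
    "Trajectory",
    "FixationSummary",
    "genotype_fitness",
    "deterministic_step",
    "iterate_to_equilibrium",
    "interior_equilibrium",
    "wright_fisher_step",
    "run_replicates",
    "parameter_sweep",
    "paper_grid",
    "fig3b_grid",
]

_FREQ_TOL = 1e-12


@dataclass(frozen=True)
class NFDSParams:
    """Parameters of one simulation setting.

    z : strength of frequency-dependent selection, 0 <= z < 1
    a : fitness multiplier of the mimetic homozygote (>= 0)
    b : fitness multiplier of the heterozygote (>= 0)
    ne : effective population size (diploid individuals, >= 1)
    p0 : initial mimetic allele frequency
    n_generations : horizon of each run
    n_runs : number of independent replicates
    seed : root RNG seed; each run gets its own spawned child stream
    """

    z: float
    a: float = 1.0
    b: float = 1.0
    ne: int = 1000
    p0: float = 0.25
    n_generations: int = 400
    n_runs: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.z < 1.0:
            raise ValueError(f"z must be in [0, 1), got {self.z}")
        if self.a < 0 or self.b < 0:
            raise ValueError("fitness multipliers a, b must be >= 0")
        if self.ne < 1:
            raise ValueError(f"ne must be >= 1, got {self.ne}")
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError(f"p0 must be in [0, 1], got {self.p0}")
        if self.n_generations < 1 or self.n_runs < 1:
            raise ValueError("n_generations and n_runs must be positive")


@dataclass(frozen=True)
class GenotypeFrequencies:
    f_mm: float
    f_mn: float
    f_nn: float

    def __post_init__(self) -> None:
        for f in (self.f_mm, self.f_mn, self.f_nn):
            if not -_FREQ_TOL <= f <= 1 + _FREQ_TOL:
                raise ValueError(f"genotype frequency out of [0, 1]: {f}")
        if abs(self.f_mm + self.f_mn + self.f_nn - 1.0) > 1e-9:
            raise ValueError("genotype frequencies must sum to 1")

    @classmethod
    def from_allele_frequency(cls, p: float) -> "GenotypeFrequencies":
        """Hardy-Weinberg genotype frequencies for mimetic allele frequency p."""
        q = 1.0 - p
        return cls(p * p, 2.0 * p * q, q * q)


@dataclass(frozen=True)
class FitnessTriple:
    w_mm: float
    w_mn: float
    w_nn: float
    w_mean: float


@dataclass(frozen=True)
class Trajectory:
    """Per-generation mimetic allele frequencies of one run (index 0 = p0)."""

    frequencies: np.ndarray
    terminal_state: str  # "segregating" | "fixed_mimetic" | "lost_mimetic"


@dataclass(frozen=True)
class FixationSummary:
    params: NFDSParams
    fixed: int
    lost: int
    segregating: int

    def __post_init__(self) -> None:
        if self.fixed + self.lost + self.segregating != self.params.n_runs:
            raise ValueError("terminal-state counts must sum to n_runs")

    @property
    def fixation_frequency(self) -> float:
        return self.fixed / self.params.n_runs


def genotype_fitness(freqs: GenotypeFrequencies, params: NFDSParams) -> FitnessTriple:
    """Frequency-dependent genotype fitnesses and the HW mean fitness."""
    mimetic = freqs.f_mm + freqs.f_mn
    w_mm = params.a * (1.0 - params.z * mimetic)
    w_mn = params.b * (1.0 - params.z * mimetic)
    w_nn = 1.0 - params.z * freqs.f_nn
    w_mean = freqs.f_mm * w_mm + freqs.f_mn * w_mn + freqs.f_nn * w_nn
    return FitnessTriple(w_mm, w_mn, w_nn, w_mean)


def deterministic_step(p: float, params: NFDSParams) -> float:
    """One generation of selection under random mating; 0 and 1 are fixed points."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"allele frequency out of [0, 1]: {p}")
    if p == 0.0 or p == 1.0:
        return p
    q = 1.0 - p
    freqs = GenotypeFrequencies.from_allele_frequency(p)
    w = genotype_fitness(freqs, params)
    num_p = p * p * w.w_mm + p * q * w.w_mn
    num_q = q * q * w.w_nn + p * q * w.w_mn
    total = num_p + num_q  # equals the HW mean fitness w.w_mean
    return num_p / total


def iterate_to_equilibrium(
    p0: float, params: NFDSParams, tol: float = 1e-12, max_iter: int = 1_000_000
) -> float:
    """Iterate the deterministic map from p0 until |p' - p| < tol."""
    p = p0
    for _ in range(max_iter):
        p_next = deterministic_step(p, params)
        if abs(p_next - p) < tol:
            return p_next
        p = p_next
    raise RuntimeError("deterministic map did not converge")


def interior_equilibrium(params: NFDSParams) -> float | None:
    """Closed-form interior equilibrium for a == b, from equal marginal fitnesses.

    Solves q*^2 = (1 - a + a z) / (z (a + 1)); returns None when a != b,
    z == 0, or the solution falls outside (0, 1).
    """
    if params.a != params.b or params.z == 0.0:
        return None
    q2 = (1.0 - params.a + params.a * params.z) / (params.z * (params.a + 1.0))
    if not 0.0 < q2 < 1.0:
        return None
    return 1.0 - math.sqrt(q2)


def wright_fisher_step(p: float, params: NFDSParams, rng: np.random.Generator) -> float:
    """Selection followed by binomial resampling of 2*Ne allele copies."""
    p_sel = deterministic_step(p, params)
    if p_sel in (0.0, 1.0):
        return p_sel
    n_copies = 2 * params.ne
    return rng.binomial(n_copies, p_sel) / n_copies


def _run_one(
    params: NFDSParams,
    rng: np.random.Generator,
    until_absorption: bool,
    max_generations: int,
    record: bool,
) -> Trajectory:
    p = params.p0
    freqs = [p] if record else None
    horizon = max_generations if until_absorption else params.n_generations
    for _ in range(horizon):
        p = wright_fisher_step(p, params, rng)
        if record:
            freqs.append(p)
        if p in (0.0, 1.0):
            break
    state = (
        "fixed_mimetic" if p == 1.0 else "lost_mimetic" if p == 0.0 else "segregating"
    )
    return Trajectory(np.asarray(freqs if record else [params.p0, p]), state)


def run_replicates(
    params: NFDSParams,
    *,
    until_absorption: bool = False,
    max_generations: int = 1_000_000,
    return_trajectories: bool = False,
) -> FixationSummary | tuple[FixationSummary, list[Trajectory]]:
    """Run ``n_runs`` independent Wright-Fisher trajectories.

    With ``until_absorption`` each run continues past ``n_generations`` until
    the allele fixes or is lost (capped at ``max_generations``); otherwise runs
    stop at the horizon and may end segregating.
    """
    children = np.random.SeedSequence(params.seed).spawn(params.n_runs)
    trajectories = [
        _run_one(
            params,
            np.random.default_rng(child),
            until_absorption,
            max_generations,
            return_trajectories,
        )
        for child in children
    ]
    states = [t.terminal_state for t in trajectories]
    summary = FixationSummary(
        params,
        fixed=states.count("fixed_mimetic"),
        lost=states.count("lost_mimetic"),
        segregating=states.count("segregating"),
    )
    if return_trajectories:
        return summary, trajectories
    return summary


def parameter_sweep(grid: Iterable[NFDSParams]) -> pd.DataFrame:
    """One :func:`run_replicates` summary row per parameter set."""
    grid = list(grid)
    if not grid:
        raise ValueError("parameter grid is empty")
    rows = []
    for params in grid:
        s = run_replicates(params)
        rows.append(
            {
                "z": params.z,
                "a": params.a,
                "b": params.b,
                "ne": params.ne,
                "p0": params.p0,
                "n_generations": params.n_generations,
                "n_runs": params.n_runs,
                "fixed": s.fixed,
                "lost": s.lost,
                "segregating": s.segregating,
                "fixation_frequency": s.fixation_frequency,
            }
        )
    return pd.DataFrame(rows)


#: The 8 selection scenarios of the published sweep: pure NFDS, equal benefit
#: to both mimetic genotypes, and heterozygote advantage.
SCENARIOS_AB: tuple[tuple[float, float], ...] = (
    (1.0, 1.0),
    (1.5, 1.5),
    (3.0, 3.0),
    (5.0, 5.0),
    (1.5, 2.0),
    (2.0, 3.0),
    (4.0, 5.0),
    (1.5, 5.0),
)
Z_GRID: tuple[float, ...] = (0.05, 0.25, 0.5, 0.75, 0.95)
P0_GRID: tuple[float, ...] = (0.05, 0.25, 0.5, 0.75, 0.95)


def paper_grid(
    ne: int = 10_000,
    n_generations: int = 400,
    n_runs: int = 10,
    seed: int | None = None,
) -> list[NFDSParams]:
    """The 8 x 5 x 5 scenario grid (a/b sets x z values x starting frequencies)."""
    grid = []
    for i, ((a, b), z, p0) in enumerate(
        itertools.product(SCENARIOS_AB, Z_GRID, P0_GRID)
    ):
        grid.append(
            NFDSParams(
                z=z, a=a, b=b, ne=ne, p0=p0,
                n_generations=n_generations, n_runs=n_runs,
                seed=None if seed is None else seed + i,
            )
        )
    return grid


def fig3b_grid(
    n_runs: int = 10,
    seed: int | None = None,
    ab_values: Sequence[float] = (1.0, 1.25, 1.5, 1.75, 2.0),
    ne_values: Sequence[int] = (100, 1_000, 10_000, 100_000),
) -> list[NFDSParams]:
    """Selection x drift interaction grid: z=0.25, p0=0.25, 400 generations."""
    grid = []
    for i, (ab, ne) in enumerate(itertools.product(ab_values, ne_values)):
        grid.append(
            NFDSParams(
                z=0.25, a=ab, b=ab, ne=ne, p0=0.25,
                n_generations=400, n_runs=n_runs,
                seed=None if seed is None else seed + i,
            )
        )
    return grid
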