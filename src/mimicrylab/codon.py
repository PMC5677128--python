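"""Forward-in-time codon-sequence evolution with purifying selection.

Re-expresses coalescent-style codon substitution scenarios as explicit
Wright-Fisher populations of haplotypes descending from a known grand most
recent common ancestor (GMRCA).  The substitution model is GY94-flavoured:
point mutations are proposed per nucleotide site at rate ``mu`` times a
per-codon gamma rate multiplier, transitions weighted ``kappa``-fold over
transversions; a proposal that is synonymous in its codon context is always
realized, a nonsynonymous proposal is realized with probability ``omega``,
and proposals creating a stop codon are rejected.  ``omega`` therefore has
the usual dN/dS substitution-model semantics rather than a forward fitness
cost.

Two scenario shapes reproduce the supergene study design:

* a single large population of constant size under strong purifying
  selection (the non-mimetic haplotype class), and
* a two-phase scenario where, after a burn-in identical to the first, one
  haplotype drawn uniformly from the population founds a second population
  that grows rapidly to its target size (the origin of the mimetic
  inversion).  Variants carried by the founder hitchhike to instant fixation
  in the new class regardless of their population frequency — the mechanism
  behind elevated fixed differences and reduced diversity on mimetic
  haplotypes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace


import numpy as np
from scipy import stats

__all__ = [
    "CodonSequence",
    "CodonModel",
    "MutationLog",
    "Phase",
    "ScenarioSpec",
    "SimulatedSample",
    "gamma_category_rates",
    "draw_site_rates",
    "mutate_population",
    "wright_fisher_generation",
    "run_scenario",
    "nonmimetic_constant",
    "mimetic_two_phase",
    "hitchhiking_replicates",
    "neighbor_counts",
    "calibrate_mutation_ratio",
    "mean_pairwise_divergence",
    "seq_to_array",
    "array_to_seq",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
# transition partners: A<->G, C<->T
_TRANSITION = np.array([2, 3, 0, 1], dtype=np.uint8)
_TRANSVERSIONS = {
    0: (1, 3),
    1: (0, 2),
    2: (1, 3),
    3: (0, 2),
}

_STOP_CODONS = {"TAA", "TAG", "TGA"}


def _build_codon_tables() -> tuple[np.ndarray, list[str]]:
    from Bio.Data.CodonTable import unambiguous_dna_by_id

    table = unambiguous_dna_by_id[1]
    aa = np.zeros(64, dtype="<U1")
    codons = []
    for i in range(64):
        codon = BASES[i >> 4] + BASES[(i >> 2) & 3] + BASES[i & 3]
        codons.append(codon)
        aa[i] = "*" if codon in table.stop_codons else table.forward_table[codon]
    return aa, codons


#: amino acid (or "*") for codon index 16*b0 + 4*b1 + b2 with A,C,G,T = 0..3
CODON_AA, CODON_STRINGS = _build_codon_tables()


def seq_to_array(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_INDEX[b] for b in seq], dtype=np.uint8)
    except KeyError as exc:
        raise ValueError(f"non-ACGT base in sequence: {exc}") from exc


def array_to_seq(arr: np.ndarray) -> str:
    return "".join(BASES[b] for b in arr)


@dataclass(frozen=True)
class CodonSequence:
    """A stop-free protein-coding nucleotide sequence."""

    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) == 0 or len(self.sequence) % 3 != 0:
            raise ValueError("sequence length must be a positive multiple of 3")
        if set(self.sequence) - set(BASES):
            raise ValueError("sequence must be over {A,C,G,T}")
        for i in range(0, len(self.sequence), 3):
            if self.sequence[i : i + 3] in _STOP_CODONS:
                raise ValueError(f"internal stop codon at nucleotide {i}")

    @property
    def n_codons(self) -> int:
        return len(self.sequence) // 3

    def to_array(self) -> np.ndarray:
        return seq_to_array(self.sequence)


@dataclass(frozen=True)
class CodonModel:
    """Codon substitution model.

    omega : nonsynonymous/synonymous rate ratio (acceptance probability of a
        nonsynonymous proposal), >= 0
    mu : per-nucleotide per-generation proposal rate
    kappa : transition/transversion rate ratio (default 2)
    gamma_alpha, gamma_K : shape and category count of the discrete-gamma
        among-codon rate variation (K=1 switches it off)
    site_rates : per-codon rate multipliers; drawn via :meth:`with_site_rates`
    """

    omega: float
    mu: float
    kappa: float = 2.0
    gamma_alpha: float = 0.8
    gamma_K: int = 3
    site_rates: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.gamma_K < 1:
            raise ValueError("gamma_K must be >= 1")
        if self.gamma_K > 1 and self.gamma_alpha <= 0:
            raise ValueError("gamma_alpha must be > 0")

    def with_site_rates(self, n_codons: int, rng: np.random.Generator) -> "CodonModel":
        return replace(self, site_rates=draw_site_rates(self, n_codons, rng))

    def nucleotide_rates(self, n_sites: int) -> np.ndarray:
        """Per-nucleotide proposal rates (mu x codon multiplier)."""
        if self.site_rates is None:
            return np.full(n_sites, self.mu)
        if 3 * len(self.site_rates) != n_sites:
            raise ValueError("site_rates length does not match sequence")
        return self.mu * np.repeat(self.site_rates, 3)


def gamma_category_rates(alpha: float, k: int) -> np.ndarray:
    """Mean rates of K equal-probability categories of a mean-1 gamma.

    The category rate is the conditional mean of Gamma(alpha, 1/alpha) within
    each probability bin: K * (F_{alpha+1}(u) - F_{alpha+1}(l)) with bin
    edges at the alpha-gamma quantiles.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return np.ones(1)
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    edges = stats.gamma.ppf(np.linspace(0, 1, k + 1), a=alpha, scale=1 / alpha)
    upper = stats.gamma.cdf(edges, a=alpha + 1, scale=1 / alpha)
    return k * np.diff(upper)


def draw_site_rates(
    model: CodonModel, n_codons: int, rng: np.random.Generator
) -> np.ndarray:
    """Assign each codon one of the K discrete-gamma category rates."""
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    rates = gamma_category_rates(model.gamma_alpha, model.gamma_K)
    return rates[rng.integers(0, model.gamma_K, size=n_codons)]


@dataclass
class MutationLog:
    """Counts of proposed and realized point mutations, by type."""

    proposed_syn: int = 0
    proposed_nonsyn: int = 0
    proposed_stop: int = 0
    realized_syn: int = 0
    realized_nonsyn: int = 0

    def __iadd__(self, other: "MutationLog") -> "MutationLog":
        self.proposed_syn += other.proposed_syn
        self.proposed_nonsyn += other.proposed_nonsyn
        self.proposed_stop += other.proposed_stop
        self.realized_syn += other.realized_syn
        self.realized_nonsyn += other.realized_nonsyn
        return self

    @property
    def realized_total(self) -> int:
        return self.realized_syn + self.realized_nonsyn


def _propose_target(base: int, kappa: float, rng: np.random.Generator) -> int:
    """Draw a target base: transition with weight kappa, transversions weight 1."""
    u = rng.random() * (kappa + 2.0)
    if u < kappa:
        return int(_TRANSITION[base])
    tv = _TRANSVERSIONS[base]
    return tv[0] if u < kappa + 1.0 else tv[1]


def mutate_population(
    pop: np.ndarray,
    model: CodonModel,
    rng: np.random.Generator,
    log: MutationLog | None = None,
) -> np.ndarray:
    """Apply one generation of point mutation to ``pop`` (in place).

    ``pop`` is an (n_haplotypes, n_sites) uint8 array of base codes.  The
    number of proposals is Poisson with mean n_haplotypes * sum(site rates);
    each proposal is accepted per the omega/stop rules and logged.
    """
    n, n_sites = pop.shape
    site_mu = model.nucleotide_rates(n_sites)
    total = n * float(site_mu.sum())
    n_events = rng.poisson(total)
    if n_events == 0:
        return pop
    p_site = site_mu / site_mu.sum()
    sites = rng.choice(n_sites, size=n_events, p=p_site)
    copies = rng.integers(0, n, size=n_events)
    local = MutationLog()
    for copy, site in zip(copies, sites):
        old = int(pop[copy, site])
        new = _propose_target(old, model.kappa, rng)
        if new == old:  # cannot happen, targets differ by construction
            continue
        start = 3 * (site // 3)
        c = pop[copy, start : start + 3]
        pos = site - start
        old_idx = 16 * int(c[0]) + 4 * int(c[1]) + int(c[2])
        new_idx = old_idx + (new - old) * (16, 4, 1)[pos]
        aa_old, aa_new = CODON_AA[old_idx], CODON_AA[new_idx]
        if aa_new == "*":
            local.proposed_stop += 1
            continue
        if aa_new == aa_old:
            local.proposed_syn += 1
            local.realized_syn += 1
            pop[copy, site] = new
        else:
            local.proposed_nonsyn += 1
            if rng.random() < model.omega:
                local.realized_nonsyn += 1
                pop[copy, site] = new
    if log is not None:
        log += local
    return pop


def wright_fisher_generation(
    pop: np.ndarray,
    size_next: int,
    r: float,
    model: CodonModel,
    rng: np.random.Generator,
    log: MutationLog | None = None,
) -> np.ndarray:
    """One Wright-Fisher generation: resample parents, recombine, mutate."""
    if size_next < 1:
        raise ValueError("size_next must be >= 1")
    n, n_sites = pop.shape
    parents = rng.integers(0, n, size=size_next)
    offspring = pop[parents].copy()
    if r > 0 and n_sites > 1:
        # at most one crossover per offspring; probability ~ r per adjacent pair
        p_cross = min(1.0, r * (n_sites - 1))
        cross = np.nonzero(rng.random(size_next) < p_cross)[0]
        if cross.size:
            second = rng.integers(0, n, size=cross.size)
            points = rng.integers(1, n_sites, size=cross.size)
            for k, i in enumerate(cross):
                offspring[i, points[k] :] = pop[second[k], points[k] :]
    return mutate_population(offspring, model, rng, log)


@dataclass(frozen=True)
class Phase:
    """One demographic phase.

    duration : generations
    size : (target) population size in haplotype copies
    founder : if True the phase starts from a single haplotype drawn
        uniformly from the previous phase's population and grows
        logistically to ``size`` over ``growth_generations`` (default a
        tenth of the duration); the previous population keeps evolving
        alongside.
    """

    duration: int
    size: int
    founder: bool = False
    growth_generations: int | None = None

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise ValueError("duration must be >= 0")
        if self.size < 1:
            raise ValueError("size must be >= 1")

    def size_at(self, t: int) -> int:
        """Population size t generations into the phase (1-based)."""
        if not self.founder or self.size == 1:
            return self.size
        g_grow = self.growth_generations
        if g_grow is None:
            g_grow = max(1, round(0.1 * self.duration))
        if t >= g_grow:
            return self.size
        rate = (math.log(self.size - 1) + math.log(99.0)) / g_grow
        s = self.size / (1.0 + (self.size - 1) * math.exp(-rate * t))
        return max(1, min(self.size, round(s)))


@dataclass(frozen=True)
class ScenarioSpec:
    """A simulation scenario: demographic phases plus the codon model."""

    phases: tuple[Phase, ...]
    model: CodonModel
    recombination_rate: float = 6e-6
    sample_size: int = 20
    n_replicates: int = 5

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("at least one phase required")
        if self.phases[0].founder:
            raise ValueError("first phase cannot be a founder phase")
        if self.sample_size < 1:
            raise ValueError("sample_size must be >= 1")


@dataclass
class SimulatedSample:
    """Terminal samples of one scenario replicate.

    ``samples`` maps a population label ("nonmimetic" and, for two-phase
    scenarios, "mimetic") to a (sample_size, n_sites) uint8 array.
    """

    samples: dict[str, np.ndarray]
    gmrca: CodonSequence
    founder: np.ndarray | None
    site_rates: np.ndarray
    mutation_log: MutationLog
    seed: int | None = None

    def sample_sequences(self, label: str) -> list[str]:
        return [array_to_seq(row) for row in self.samples[label]]


def run_scenario(
    spec: ScenarioSpec,
    gmrca: CodonSequence,
    rng: np.random.Generator,
) -> SimulatedSample:
    """Run one replicate of a one- or two-phase scenario from the GMRCA."""
    model = spec.model
    if model.site_rates is None:
        model = model.with_site_rates(gmrca.n_codons, rng)
    anc = gmrca.to_array()
    log = MutationLog()
    r = spec.recombination_rate

    phase0 = spec.phases[0]
    pop = np.tile(anc, (phase0.size, 1))
    for _ in range(phase0.duration):
        pop = wright_fisher_generation(pop, phase0.size, r, model, rng, log)

    founder: np.ndarray | None = None
    derived: np.ndarray | None = None
    for phase in spec.phases[1:]:
        if phase.founder:
            founder = pop[rng.integers(0, pop.shape[0])].copy()
            derived = founder[np.newaxis, :].copy()
            for t in range(1, phase.duration + 1):
                derived = wright_fisher_generation(
                    derived, phase.size_at(t), r, model, rng, log
                )
                # ancestral population keeps evolving alongside
                pop = wright_fisher_generation(pop, pop.shape[0], r, model, rng, log)
        else:
            target = phase.size
            for _ in range(phase.duration):
                pop = wright_fisher_generation(pop, target, r, model, rng, log)

    samples: dict[str, np.ndarray] = {}
    for label, population in (("nonmimetic", pop), ("mimetic", derived)):
        if population is None:
            continue
        if spec.sample_size > population.shape[0]:
            raise ValueError(
                f"sample_size {spec.sample_size} exceeds population "
                f"size {population.shape[0]} for {label!r}"
            )
        idx = rng.choice(population.shape[0], size=spec.sample_size, replace=False)
        samples[label] = population[idx].copy()
    return SimulatedSample(
        samples=samples,
        gmrca=gmrca,
        founder=founder,
        site_rates=model.site_rates,
        mutation_log=log,
    )


def nonmimetic_constant(
    n: int = 800,
    duration: int = 1800,
    mu: float = 8e-5,
    omega: float = 0.05,
    **model_kwargs,
) -> ScenarioSpec:
    """Constant-size purifying-selection scenario (non-mimetic haplotype class)."""
    return ScenarioSpec(
        phases=(Phase(duration, n),),
        model=CodonModel(omega=omega, mu=mu, **model_kwargs),
    )


def mimetic_two_phase(
    n: int = 800,
    phase1: int = 1600,
    phase2: int = 200,
    mu: float = 8e-5,
    omega: float = 0.05,
    growth_generations: int | None = None,
    **model_kwargs,
) -> ScenarioSpec:
    """Founder/hitchhiking scenario: burn-in, then one haplotype founds the
    mimetic class and expands while the ancestral population continues."""
    if growth_generations is None:
        growth_generations = max(1, round(0.1 * phase2))
    return ScenarioSpec(
        phases=(
            Phase(phase1, n),
            Phase(phase2, n, founder=True, growth_generations=growth_generations),
        ),
        model=CodonModel(omega=omega, mu=mu, **model_kwargs),
    )


def hitchhiking_replicates(
    gmrca: CodonSequence,
    n_replicates: int = 20,
    seed: int | None = None,
    spec: ScenarioSpec | None = None,
) -> list[SimulatedSample]:
    """Matched mimetic/non-mimetic samples from the two-phase scenario."""
    if spec is None:
        spec = mimetic_two_phase()
    children = np.random.SeedSequence(seed).spawn(n_replicates)
    return [run_scenario(spec, gmrca, np.random.default_rng(c)) for c in children]


def neighbor_counts(seq: CodonSequence) -> tuple[int, int, int]:
    """Exhaustively classify all 9L single-nucleotide neighbors of ``seq``.

    Returns (n_synonymous, n_nonsynonymous, n_stop_creating) over every
    possible single-base change at every site.  Serves as the independent
    enumeration oracle for the realized mutation-type ratio: with uniform
    proposals (kappa = 1, no rate variation) the expected realized
    nonsyn:syn ratio is omega * n_nonsynonymous / n_synonymous.
    """
    arr = seq.to_array()
    n_syn = n_nonsyn = n_stop = 0
    for start in range(0, arr.size, 3):
        c = arr[start : start + 3]
        old_idx = 16 * int(c[0]) + 4 * int(c[1]) + int(c[2])
        aa_old = CODON_AA[old_idx]
        for pos, weight in enumerate((16, 4, 1)):
            old_base = int(c[pos])
            for new_base in range(4):
                if new_base == old_base:
                    continue
                aa_new = CODON_AA[old_idx + (new_base - old_base) * weight]
                if aa_new == "*":
                    n_stop += 1
                elif aa_new == aa_old:
                    n_syn += 1
                else:
                    n_nonsyn += 1
    return n_syn, n_nonsyn, n_stop


def calibrate_mutation_ratio(
    gmrca: CodonSequence,
    model: CodonModel,
    n_realized: int,
    rng: np.random.Generator,
    n_copies: int = 2000,
) -> MutationLog:
    """Accumulate mutation-type counts on fresh GMRCA copies.

    Each round mutates a fresh population of identical GMRCA copies for one
    generation, so proposals are (almost) always evaluated in the ancestral
    codon context; rounds repeat until at least ``n_realized`` mutations have
    been realized.
    """
    anc = gmrca.to_array()
    log = MutationLog()
    while log.realized_total < n_realized:
        pop = np.tile(anc, (n_copies, 1))
        mutate_population(pop, model, rng, log)
    return log


def mean_pairwise_divergence(sample: np.ndarray) -> float:
    """Mean per-site Hamming distance over all haplotype pairs."""
    n, n_sites = sample.shape
    if n < 2:
        raise ValueError("need at least two haplotypes")
    total = 0.0
    for i in range(n - 1):
        total += np.count_nonzero(sample[i + 1 :] != sample[i], axis=1).sum()
    return total / (n * (n - 1) / 2) / n_sites
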