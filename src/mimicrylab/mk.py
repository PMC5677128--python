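"""McDonald-Kreitman style statistics against a known ancestor.

Variation in a codon alignment is polarized against the ancestral sequence
and binned into fixed vs polymorphic (by derived-allele frequency with a
minor-allele-frequency cutoff, default 0.05) and synonymous vs
non-synonymous (by effect in the ancestral codon context).  The module also
provides the exact tests used on those tables — a 2x2 Fisher exact test by
direct hypergeometric enumeration and a general r x c exact test by full
table enumeration with a Patefield Monte-Carlo fallback — plus
Nei-Gojobori (1986) Ka/Ks with Jukes-Cantor correction and
Benjamini-Hochberg FDR adjustment.

Two-sided exact p-values follow the probability method: the sum of the
probabilities of all tables with the observed margins that are no more
probable than the observed table.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .codon import CODON_AA, BASES, CodonSequence, seq_to_array

__all__ = [
    "MKTable",
    "KaKsResult",
    "OmegaSummary",
    "FisherRxCResult",
    "classify_sites",
    "fisher_exact_2x2",
    "fisher_exact_rxc",
    "benjamini_hochberg",
    "ka_ks",
    "omega_summary",
    "compare_observed_vs_simulated",
    "ScenarioComparison",
]

_MISSING = 255  # code for an N / missing base in alignment arrays
_REL_TOL = 1 + 1e-7  # tie tolerance when comparing table probabilities


@dataclass(frozen=True)
class MKTable:
    """Fixed/polymorphic x synonymous/non-synonymous counts."""

    fixed_syn: int
    fixed_nonsyn: int
    poly_syn: int
    poly_nonsyn: int
    maf_cutoff: float = 0.05
    n_haplotypes: int = 0

    def __post_init__(self) -> None:
        if min(self.fixed_syn, self.fixed_nonsyn, self.poly_syn, self.poly_nonsyn) < 0:
            raise ValueError("MK counts must be non-negative")

    def as_2x2(self) -> np.ndarray:
        """Rows fixed/polymorphic, columns non-synonymous/synonymous."""
        return np.array(
            [[self.fixed_nonsyn, self.fixed_syn], [self.poly_nonsyn, self.poly_syn]]
        )

    def as_vector(self) -> np.ndarray:
        """(fixed_syn, fixed_nonsyn, poly_syn, poly_nonsyn)."""
        return np.array(
            [self.fixed_syn, self.fixed_nonsyn, self.poly_syn, self.poly_nonsyn]
        )

    @property
    def total_fixed(self) -> int:
        return self.fixed_syn + self.fixed_nonsyn

    @property
    def total_poly(self) -> int:
        return self.poly_syn + self.poly_nonsyn


def _alignment_array(sample: Sequence[str] | np.ndarray) -> np.ndarray:
    if isinstance(sample, np.ndarray):
        return sample.astype(np.uint8, copy=False)
    rows = []
    for seq in sample:
        row = np.full(len(seq), _MISSING, dtype=np.uint8)
        for i, base in enumerate(seq.upper()):
            if base in BASES:
                row[i] = BASES.index(base)
            elif base not in "N-?":
                raise ValueError(f"unexpected residue {base!r} in alignment")
        rows.append(row)
    return np.vstack(rows)


def classify_sites(
    sample: Sequence[str] | np.ndarray,
    ancestor: CodonSequence | str,
    maf_cutoff: float = 0.05,
) -> MKTable:
    """Count fixed and polymorphic synonymous/non-synonymous changes.

    Per nucleotide site, every derived allele (a base differing from the
    ancestor) with sample frequency >= 1 - maf_cutoff counts as fixed, with
    frequency in [maf_cutoff, 1 - maf_cutoff) as polymorphic, and below
    maf_cutoff is ignored as rare noise.  Frequencies are computed over
    non-missing calls.  Each counted change is classified by its amino-acid
    effect with the other two codon positions held at the ancestral state.
    """
    if isinstance(ancestor, CodonSequence):
        anc = ancestor.to_array()
    else:
        anc = seq_to_array(ancestor)
    aln = _alignment_array(sample)
    if aln.ndim != 2 or aln.shape[0] < 2:
        raise ValueError("alignment must hold at least two haplotypes")
    if aln.shape[1] != anc.size:
        raise ValueError("alignment length does not match the ancestor")
    if anc.size % 3 != 0:
        raise ValueError("sequence length must be a multiple of 3")

    counts = {"fixed_syn": 0, "fixed_nonsyn": 0, "poly_syn": 0, "poly_nonsyn": 0}
    for site in range(anc.size):
        col = aln[:, site]
        valid = col != _MISSING
        n_valid = int(valid.sum())
        if n_valid == 0:
            continue
        anc_base = int(anc[site])
        start = 3 * (site // 3)
        pos = site - start
        codon = anc[start : start + 3]
        old_idx = 16 * int(codon[0]) + 4 * int(codon[1]) + int(codon[2])
        aa_old = CODON_AA[old_idx]
        for base in range(4):
            if base == anc_base:
                continue
            freq = int((col[valid] == base).sum()) / n_valid
            if freq < maf_cutoff:
                continue
            new_idx = old_idx + (base - anc_base) * (16, 4, 1)[pos]
            kind = "syn" if CODON_AA[new_idx] == aa_old else "nonsyn"
            bin_ = "fixed" if freq >= 1 - maf_cutoff else "poly"
            counts[f"{bin_}_{kind}"] += 1
    return MKTable(maf_cutoff=maf_cutoff, n_haplotypes=aln.shape[0], **counts)


# ---------------------------------------------------------------------------
# exact tests


def fisher_exact_2x2(table: Sequence[Sequence[int]] | np.ndarray) -> float:
    """Two-sided Fisher exact p for a 2x2 table, by hypergeometric enumeration.

    A table with a zero margin is degenerate and returns p = 1.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a non-negative 2x2 table")
    r1, r2 = t.sum(axis=1)
    c1, c2 = t.sum(axis=0)
    n = t.sum()
    if 0 in (r1, r2, c1, c2):
        return 1.0
    dist = stats.hypergeom(n, r1, c1)
    k_obs = t[0, 0]
    p_obs = dist.pmf(k_obs)
    k = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = dist.pmf(k)
    return float(min(1.0, pmf[pmf <= p_obs * _REL_TOL].sum()))


@dataclass(frozen=True)
class FisherRxCResult:
    p: float
    method: str  # "enumeration" | "monte_carlo"
    mc_se: float | None = None
    n_tables: int | None = None


def _log_table_prob(flat: np.ndarray, log_const: float) -> float:
    return log_const - gammaln(flat + 1).sum()


def fisher_exact_rxc(
    table: Sequence[Sequence[int]] | np.ndarray,
    max_tables: int = 10_000_000,
    n_mc: int = 100_000,
    seed: int | None = 0,
) -> FisherRxCResult:
    """Two-sided exact test for an r x c table with fixed margins.

    Enumerates all tables with the observed margins when their number stays
    within ``max_tables`` (p = sum of probabilities <= the observed table's);
    otherwise estimates p by Monte-Carlo with Patefield margin-preserving
    draws, reporting the binomial standard error.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or (t < 0).any():
        raise ValueError("expected a non-negative 2-D table")
    if t.size > 32:
        raise ValueError("table too large; r*c must be <= 32")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    n = int(t.sum())
    if n == 0:
        return FisherRxCResult(1.0, "enumeration", n_tables=1)
    rows_nz = rows[rows > 0]
    cols_nz = cols[cols > 0]
    t_nz = t[np.ix_(rows > 0, cols > 0)]
    log_const = (
        gammaln(rows_nz + 1).sum() + gammaln(cols_nz + 1).sum() - gammaln(n + 1)
    )
    logp_obs = _log_table_prob(t_nz.ravel().astype(float), log_const)
    tol = math.log(_REL_TOL)

    r, c = t_nz.shape
    if r == 1 or c == 1:
        return FisherRxCResult(1.0, "enumeration", n_tables=1)

    # recursive enumeration, aborting to Monte-Carlo if too many tables
    result = {"p": 0.0, "count": 0}

    def fill(i: int, j: int, work: np.ndarray, row_left: int, col_left: np.ndarray):
        if result["count"] > max_tables:
            raise _TooManyTables
        if i == r - 1:
            # last row forced by column margins
            if (col_left < 0).any():
                return
            work[i, :] = col_left
            logp = _log_table_prob(work.ravel().astype(float), log_const)
            result["count"] += 1
            if logp <= logp_obs + tol:
                result["p"] += math.exp(logp)
            return
        if j == c - 1:
            if row_left > col_left[j]:
                return
            work[i, j] = row_left
            new_col = col_left.copy()
            new_col[j] -= row_left
            fill(i + 1, 0, work, int(rows_nz[i + 1]), new_col)
            return
        hi = min(row_left, int(col_left[j]))
        for v in range(hi + 1):
            work[i, j] = v
            new_col = col_left.copy()
            new_col[j] -= v
            fill(i, j + 1, work, row_left - v, new_col)

    try:
        work = np.zeros((r, c), dtype=np.int64)
        fill(0, 0, work, int(rows_nz[0]), cols_nz.astype(np.int64).copy())
        return FisherRxCResult(
            min(1.0, result["p"]), "enumeration", n_tables=result["count"]
        )
    except _TooManyTables:
        pass

    rng = np.random.default_rng(seed)
    rvs = stats.random_table(rows_nz, cols_nz).rvs(n_mc, random_state=rng)
    logps = log_const - gammaln(rvs + 1).sum(axis=(1, 2))
    k = int((logps <= logp_obs + tol).sum())
    p_hat = (1 + k) / (1 + n_mc)
    se = math.sqrt(p_hat * (1 - p_hat) / n_mc)
    return FisherRxCResult(p_hat, "monte_carlo", mc_se=se)


class _TooManyTables(Exception):
    pass


def benjamini_hochberg(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# Nei-Gojobori Ka/Ks


@dataclass(frozen=True)
class KaKsResult:
    """Per-site substitution rates for one sequence pair (NG86 + Jukes-Cantor).

    ``ka``/``ks`` are None when the Jukes-Cantor correction is undefined
    (proportion >= 3/4); ``omega`` is None when Ks is zero or undefined.
    """

    ka: float | None
    ks: float | None
    omega: float | None
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    n_codons_used: int


def _codon_index(c: np.ndarray) -> int:
    return 16 * int(c[0]) + 4 * int(c[1]) + int(c[2])


def _syn_fraction(codon_idx: int) -> float:
    """Number of synonymous sites (0..3) of a codon; stop targets count as
    non-synonymous changes."""
    aa = CODON_AA[codon_idx]
    s = 0.0
    for pos, weight in enumerate((16, 4, 1)):
        base = (codon_idx >> (2 * (2 - pos))) & 3
        n_syn = 0
        for new in range(4):
            if new == base:
                continue
            if CODON_AA[codon_idx + (new - base) * weight] == aa:
                n_syn += 1
        s += n_syn / 3.0
    return s


def _pathway_diffs(c1: int, c2: int) -> tuple[float, float]:
    """Observed (syn, nonsyn) differences between two codons, averaged over
    equal-weighted shortest mutational pathways; pathways through stop
    codons are excluded when any stop-free pathway exists."""
    b1 = [(c1 >> 4) & 3, (c1 >> 2) & 3, c1 & 3]
    b2 = [(c2 >> 4) & 3, (c2 >> 2) & 3, c2 & 3]
    diff_pos = [i for i in range(3) if b1[i] != b2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        cur = list(b1)
        syn = nonsyn = 0.0
        blocked = False
        for pos in order:
            old_idx = 16 * cur[0] + 4 * cur[1] + cur[2]
            aa_old = CODON_AA[old_idx]
            cur[pos] = b2[pos]
            new_idx = 16 * cur[0] + 4 * cur[1] + cur[2]
            aa_new = CODON_AA[new_idx]
            if aa_new == "*" or aa_old == "*":
                blocked = True
            if aa_new == aa_old:
                syn += 1
            else:
                nonsyn += 1
        paths.append((blocked, syn, nonsyn))
    unblocked = [p for p in paths if not p[0]]
    use = unblocked if unblocked else paths
    sd = sum(p[1] for p in use) / len(use)
    nd = sum(p[2] for p in use) / len(use)
    return sd, nd


def _jukes_cantor(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ka_ks(
    seq: CodonSequence | str, ancestor: CodonSequence | str
) -> KaKsResult:
    """Nei-Gojobori counting Ka/Ks between one sequence and the ancestor.

    Synonymous/non-synonymous site counts are averaged between the two
    sequences; observed differences are classified via equal-weighted
    shortest mutational pathways; Jukes-Cantor correction is applied to each
    proportion.  Codons containing missing data in either sequence are
    skipped.  The statistic is symmetric in its two arguments.
    """
    a1 = _alignment_array([seq.sequence if isinstance(seq, CodonSequence) else seq])[0]
    a2 = _alignment_array(
        [ancestor.sequence if isinstance(ancestor, CodonSequence) else ancestor]
    )[0]
    if a1.size != a2.size or a1.size % 3 != 0:
        raise ValueError("sequences must be aligned with equal length divisible by 3")
    S = N = sd = nd = 0.0
    used = 0
    for start in range(0, a1.size, 3):
        c1, c2 = a1[start : start + 3], a2[start : start + 3]
        if (c1 == _MISSING).any() or (c2 == _MISSING).any():
            continue
        i1, i2 = _codon_index(c1), _codon_index(c2)
        if CODON_AA[i1] == "*" or CODON_AA[i2] == "*":
            continue
        used += 1
        s_here = 0.5 * (_syn_fraction(i1) + _syn_fraction(i2))
        S += s_here
        N += 3.0 - s_here
        d_s, d_n = _pathway_diffs(i1, i2)
        sd += d_s
        nd += d_n
    if used == 0:
        raise ValueError("no comparable codons")
    ps = sd / S if S > 0 else 0.0
    pn = nd / N if N > 0 else 0.0
    ks = _jukes_cantor(ps)
    ka = _jukes_cantor(pn)
    omega = None
    if ka is not None and ks is not None and ks > 0:
        omega = ka / ks
    return KaKsResult(ka, ks, omega, S, N, sd, nd, used)


@dataclass(frozen=True)
class OmegaSummary:
    """Mean and standard error of Ka/Ks across haplotypes vs the ancestor."""

    mean: float
    se: float
    per_haplotype: tuple[float, ...]
    n_excluded: int


def omega_summary(
    sample: Sequence[str] | Sequence[CodonSequence],
    ancestor: CodonSequence | str,
) -> OmegaSummary:
    if len(sample) < 2:
        raise ValueError("need at least two haplotypes")
    values = []
    n_excluded = 0
    for seq in sample:
        res = ka_ks(seq, ancestor)
        if res.omega is None:
            n_excluded += 1
        else:
            values.append(res.omega)
    if not values:
        raise ValueError("omega undefined for every haplotype")
    arr = np.asarray(values)
    se = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0
    return OmegaSummary(float(arr.mean()), se, tuple(values), n_excluded)


# ---------------------------------------------------------------------------
# scenario-fit comparison


@dataclass(frozen=True)
class ScenarioComparison:
    p_values: tuple[float, ...]
    fraction_nonsignificant: float
    alpha: float


def compare_observed_vs_simulated(
    observed: MKTable,
    simulated: Iterable[MKTable],
    alpha: float = 0.05,
) -> ScenarioComparison:
    """Fisher 2x4 test of each simulated table against the observed counts.

    Rows are observed vs simulated; columns the four MK categories.  The
    fraction of replicates with p > alpha is the scenario's fit statistic.
    """
    simulated = list(simulated)
    if not simulated:
        raise ValueError("need at least one simulated table")
    ps = []
    obs = observed.as_vector()
    for sim in simulated:
        table = np.vstack([obs, sim.as_vector()])
        ps.append(fisher_exact_rxc(table).p)
    frac = sum(p > alpha for p in ps) / len(ps)
    return ScenarioComparison(tuple(ps), frac, alpha)
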