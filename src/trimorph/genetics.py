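"""Single-locus, three-allele genetics of male alternative mating strategies.

One autosomal locus carries the alleles ``m`` (monogamous), ``p``
(polygynous) and ``s`` (sneaker), giving six diploid genotypes
(``mm, mp, ms, pp, ps, ss``).  Adult males express one of the three
strategies ``M``, ``P`` or ``S``; two genotype-to-phenotype mechanisms are
supported:

* **allelic dominance** -- a fixed dominance order among the alleles (default
  ``p > s > m``) determines which allele a heterozygote expresses;
* **irreversible developmental plasticity** -- a heterozygote chooses, once
  at recruitment into the adult class, whichever of its two encoded
  strategies currently has the higher expected payoff given the adult-male
  strategy frequencies, and keeps that strategy for life.

Allele and strategy integer codes are aligned (``m``/``M`` = 0, ``p``/``P`` =
1, ``s``/``S`` = 2) so a homozygote's strategy code equals its allele code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

ALLELES = ("m", "p", "s")
STRATEGIES = ("M", "P", "S")
GENOTYPES = ("mm", "mp", "ms", "pp", "ps", "ss")

#: Dominance order consistent with the explicit genotype table
#: (pp, pm, ps -> P; mm -> M; ss, ms -> S).
DEFAULT_DOMINANCE_ORDER = ("p", "s", "m")

_ALLELE_CODE = {a: i for i, a in enumerate(ALLELES)}
_STRATEGY_CODE = {s: i for i, s in enumerate(STRATEGIES)}


def allele_code(allele: str) -> int:
    try:
        return _ALLELE_CODE[allele]
    except KeyError:
        raise ValueError(f"unknown allele {allele!r}; expected one of {ALLELES}")


def strategy_code(strategy: str) -> int:
    try:
        return _STRATEGY_CODE[strategy]
    except KeyError:
        raise ValueError(
            f"unknown strategy {strategy!r}; expected one of {STRATEGIES}"
        )


def canonical_genotype(genotype: str) -> str:
    """Return the genotype in canonical (alphabetical) two-character form."""
    if len(genotype) != 2 or any(a not in _ALLELE_CODE for a in genotype):
        raise ValueError(
            f"invalid genotype {genotype!r}; expected two characters from {ALLELES}"
        )
    return "".join(sorted(genotype))


def genotype_codes(genotype: str) -> tuple[int, int]:
    g = canonical_genotype(genotype)
    return _ALLELE_CODE[g[0]], _ALLELE_CODE[g[1]]


def is_heterozygote(genotype: str) -> bool:
    """True iff the genotype's two alleles differ."""
    g = canonical_genotype(genotype)
    return g[0] != g[1]


@dataclass(frozen=True)
class GeneticMechanism:
    """Genotype-to-phenotype mechanism and heterozygote-cost bookkeeping.

    Parameters
    ----------
    mode:
        ``"dominance"`` or ``"plasticity"``.
    dominance_order:
        Permutation of the three alleles, most dominant first.  Only used in
        dominance mode.
    heterozygote_cost:
        Dimensionless cost factor ``c`` in [0, 1): a pure strategist's
        advantage in contests against a heterozygote, and the fractional
        reduction of a heterozygote's initial mean harem size.
    plastic_criterion:
        What a plastic heterozygote compares at recruitment:
        ``"expected"`` (default) -- the frequency-weighted expected payoff
        ``E(i) = sum_k f_k W0(i, k)``; ``"realized"`` -- the mean number of
        females actually won per male of each strategy at the previous
        step's mating, falling back to the expected payoff for strategies
        with no adult males.
    """

    mode: str = "dominance"
    dominance_order: tuple[str, str, str] = DEFAULT_DOMINANCE_ORDER
    heterozygote_cost: float = 0.2
    plastic_criterion: str = "expected"

    def __post_init__(self) -> None:
        if self.mode not in ("dominance", "plasticity"):
            raise ValueError(f"unknown mechanism mode {self.mode!r}")
        if sorted(self.dominance_order) != sorted(ALLELES):
            raise ValueError(
                f"dominance_order must be a permutation of {ALLELES}, "
                f"got {self.dominance_order}"
            )
        if not 0.0 <= self.heterozygote_cost < 1.0:
            raise ValueError("heterozygote_cost must lie in [0, 1)")
        if self.plastic_criterion not in ("realized", "expected"):
            raise ValueError(f"unknown plastic_criterion {self.plastic_criterion!r}")
        object.__setattr__(self, "dominance_order", tuple(self.dominance_order))


def dominance_ranks(order: tuple[str, str, str] = DEFAULT_DOMINANCE_ORDER) -> np.ndarray:
    """Rank of each allele code under `order` (0 = most dominant)."""
    if sorted(order) != sorted(ALLELES):
        raise ValueError(f"dominance order must be a permutation of {ALLELES}")
    ranks = np.empty(3, dtype=np.int8)
    for rank, allele in enumerate(order):
        ranks[_ALLELE_CODE[allele]] = rank
    return ranks


def phenotype_dominance(
    genotype: str, order: tuple[str, str, str] = DEFAULT_DOMINANCE_ORDER
) -> str:
    """Strategy expressed by `genotype` under the allelic-dominance mechanism.

    Returns the strategy of the most dominant allele present.  Total and
    deterministic over the six genotypes and six possible orders.
    """
    a, b = genotype_codes(genotype)
    ranks = dominance_ranks(order)
    return STRATEGIES[a if ranks[a] <= ranks[b] else b]


def _validate_frequencies(freqs, tol: float = 1e-6) -> np.ndarray:
    if isinstance(freqs, dict):
        freqs = [freqs[s] for s in STRATEGIES]
    f = np.asarray(freqs, dtype=float)
    if f.shape != (3,):
        raise ValueError("strategy frequencies must have three entries (M, P, S)")
    if np.any(f < -tol) or not np.isfinite(f).all():
        raise ValueError(f"strategy frequencies must be non-negative, got {f}")
    if abs(f.sum() - 1.0) > tol:
        raise ValueError(f"strategy frequencies must sum to 1, got sum {f.sum()}")
    return np.clip(f, 0.0, None)


def _payoff_array(payoff) -> np.ndarray:
    matrix = getattr(payoff, "matrix", payoff)
    return np.asarray(matrix, dtype=float)


def expected_payoffs(freqs, payoff) -> np.ndarray:
    """Expected per-contest payoff ``E(i) = sum_k f_k W0(i, k)`` per strategy."""
    f = _validate_frequencies(freqs)
    return _payoff_array(payoff) @ f


def phenotype_plastic(genotype: str, freqs, payoff, rng=None) -> str:
    """Strategy chosen at recruitment under irreversible developmental plasticity.

    Homozygotes express their allele's strategy.  A heterozygote compares the
    expected payoffs ``E(i) = sum_k f_k W0(i, k)`` of its two encoded
    strategies at the current adult-male strategy frequencies and expresses
    the better one; exact ties are broken by a fair coin from `rng`.

    Raises ``ValueError`` if `freqs` is malformed (negative entries or not
    summing to one).
    """
    a, b = genotype_codes(genotype)
    if a == b:
        return STRATEGIES[a]
    e = expected_payoffs(freqs, payoff)
    if np.isclose(e[a], e[b]):
        if rng is None:
            rng = np.random.default_rng()
        return STRATEGIES[a if rng.integers(2) == 0 else b]
    return STRATEGIES[a if e[a] > e[b] else b]


def inherit(mother: str, father: str, rng) -> str:
    """Mendelian transmission: one allele drawn uniformly from each parent."""
    ma, mb = genotype_codes(mother)
    fa, fb = genotype_codes(father)
    child = (
        ALLELES[ma if rng.integers(2) == 0 else mb]
        + ALLELES[fa if rng.integers(2) == 0 else fb]
    )
    return canonical_genotype(child)


# ---------------------------------------------------------------------------
# vectorized forms used by the simulation engine (allele pairs as (n, 2)
# integer arrays in canonical order a1 <= a2)


def strategies_dominance(alleles: np.ndarray, order=DEFAULT_DOMINANCE_ORDER) -> np.ndarray:
    ranks = dominance_ranks(order)
    a, b = alleles[:, 0], alleles[:, 1]
    return np.where(ranks[a] <= ranks[b], a, b).astype(np.int8)


def strategies_plastic_values(alleles: np.ndarray, values: np.ndarray, rng) -> np.ndarray:
    """Plastic strategy choice against an arbitrary per-strategy value vector."""
    e = np.asarray(values, dtype=float)
    a, b = alleles[:, 0], alleles[:, 1]
    ea, eb = e[a], e[b]
    coin = rng.integers(0, 2, a.shape[0]).astype(bool)
    out = np.where(np.isclose(ea, eb), np.where(coin, b, a), np.where(ea > eb, a, b))
    return out.astype(np.int8)


def strategies_plastic(alleles: np.ndarray, freqs, payoff, rng) -> np.ndarray:
    """Plastic choice by expected payoff at the given strategy frequencies."""
    return strategies_plastic_values(alleles, expected_payoffs(freqs, payoff), rng)


def inherit_many(
    mother_alleles: np.ndarray, father_alleles: np.ndarray, rng
) -> np.ndarray:
    """Vectorized Mendelian transmission for aligned parent arrays."""
    n = mother_alleles.shape[0]
    rows = np.arange(n)
    from_mother = mother_alleles[rows, rng.integers(0, 2, n)]
    from_father = father_alleles[rows, rng.integers(0, 2, n)]
    out = np.empty((n, 2), dtype=np.int8)
    out[:, 0] = np.minimum(from_mother, from_father)
    out[:, 1] = np.maximum(from_mother, from_father)
    return out
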