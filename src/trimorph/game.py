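"""Rock-paper-scissors contest machinery for male mating competition.

The dyadic payoff matrix ``W0[i, k]`` is the mean number of females a focal
male of strategy ``i`` wins when playing against males of strategy ``k``.
With the default matrix, P beats M, M beats S and S beats P, each by the
same margin, which closes the cycle.  Contest win probabilities are
frequency dependent: a focal male's chance of taking a female from an
opponent is the even-chance baseline plus the difference of the
frequency-weighted payoff terms,

    q = 0.5 + f_i f_k (W0(i, k) - W0(k, i)),

where ``f`` are the current adult-male strategy frequencies.  Two males of
the same strategy always contest at q = 0.5, and a rare strategy earns its
frequency-dependent advantage through whom it meets (encounter rates with
its victim strategy) rather than through inflated per-contest odds.  An
opponent-frequency-weighted ratio form is available as
``win_mode="ratio"``.

A heterozygote cost ``c`` gives a pure strategist (homozygote) an advantage
when playing against a heterozygote; games between two heterozygotes (or
two homozygotes) are uncosted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genetics import STRATEGIES, strategy_code, _validate_frequencies

__all__ = [
    "PayoffMatrix",
    "GameParams",
    "ContestOutcome",
    "validate_frequencies",
    "mean_payoff",
    "win_probability",
    "assign_neighbours",
    "assemble_harems",
    "run_contests",
]

validate_frequencies = _validate_frequencies

_M, _P, _S = 0, 1, 2

#: The three cyclic match-ups in the order stated for the game: S against P
#: neighbours, then M against S, then P against M (attacker listed first).
CYCLIC_ROUNDS = [(_S, _P), (_M, _S), (_P, _M)]
SAME_ROUNDS = [(_M, _M), (_P, _P), (_S, _S)]
ANTI_ROUNDS = [(_P, _S), (_S, _M), (_M, _P)]


@dataclass(frozen=True)
class PayoffMatrix:
    """3x3 dyadic payoff matrix, rows = focal strategy, columns = opponent.

    Internally indexed in (M, P, S) order to match allele/strategy codes.
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.matrix, dtype=float)
        if w.shape != (3, 3):
            raise ValueError("payoff matrix must be 3x3")
        if np.any(w < 0):
            raise ValueError("payoff entries must be non-negative")
        if not np.allclose(np.diag(w), 1.0):
            raise ValueError("same-strategy payoffs (diagonal) must equal 1")
        w.flags.writeable = False
        object.__setattr__(self, "matrix", w)

    @classmethod
    def default(cls) -> "PayoffMatrix":
        """Default matrix: rows P: (1, 2, 0.5), M: (0.5, 1, 2), S: (2, 0.5, 1)
        in (P, M, S) presentation order."""
        return cls.from_pms([[1.0, 2.0, 0.5], [0.5, 1.0, 2.0], [2.0, 0.5, 1.0]])

    @classmethod
    def from_pms(cls, rows) -> "PayoffMatrix":
        """Build from a matrix written in (P, M, S) row/column order."""
        w = np.asarray(rows, dtype=float)
        perm = [1, 0, 2]  # (P, M, S) -> (M, P, S)
        return cls(w[np.ix_(perm, perm)])

    def to_pms(self) -> np.ndarray:
        perm = [1, 0, 2]
        return self.matrix[np.ix_(perm, perm)]

    def value(self, focal: str, opponent: str) -> float:
        return float(self.matrix[strategy_code(focal), strategy_code(opponent)])


@dataclass(frozen=True)
class GameParams:
    """Mating-game parameters.

    ``harem_means`` and ``neighbour_means`` are Poisson means indexed by
    strategy code (M, P, S): default harem sizes h_m=1, h_p=3, h_s=0.5 and
    three neighbours for every strategy.  ``cost_mode`` selects how the pure
    strategist's advantage ``c`` enters the win probability
    (``"multiplicative"``: weight factor 1+c then renormalise;
    ``"additive"``: probability shifted by c and clipped).
    ``cost_under_dominance`` applies the heterozygote cost also when the
    expressed strategy is fixed by dominance.
    """

    harem_means: tuple[float, float, float] = (1.0, 3.0, 0.5)
    neighbour_means: tuple[float, float, float] = (3.0, 3.0, 3.0)
    cost_mode: str = "multiplicative"
    cost_under_dominance: bool = True
    contest_rounds: str = "cyclic_sym"
    steal_scope: str = "assembled"
    win_mode: str = "eq1_additive"

    def __post_init__(self) -> None:
        if any(h < 0 for h in self.harem_means) or any(
            n < 0 for n in self.neighbour_means
        ):
            raise ValueError("Poisson means must be non-negative")
        if self.cost_mode not in ("multiplicative", "additive"):
            raise ValueError(f"unknown cost_mode {self.cost_mode!r}")
        if self.contest_rounds not in ("cyclic", "cyclic_sym", "all"):
            raise ValueError(f"unknown contest_rounds {self.contest_rounds!r}")
        if self.steal_scope not in ("current", "assembled"):
            raise ValueError(f"unknown steal_scope {self.steal_scope!r}")
        if self.win_mode not in ("eq1_additive", "ratio"):
            raise ValueError(f"unknown win_mode {self.win_mode!r}")
        object.__setattr__(self, "harem_means", tuple(self.harem_means))
        object.__setattr__(self, "neighbour_means", tuple(self.neighbour_means))


@dataclass
class ContestOutcome:
    """Record of a single contest (sequential contest path only)."""

    winner: int
    loser: int
    transferred: list[int] = field(default_factory=list)


def mean_payoff(payoff: PayoffMatrix, freqs, i: str, k: str) -> float:
    """Pairwise frequency-weighted payoff term ``f_i f_k W0(i, k)``."""
    f = validate_frequencies(freqs)
    ci, ck = strategy_code(i), strategy_code(k)
    return float(f[ci] * f[ck] * payoff.matrix[ci, ck])


def _base_win(
    payoff: np.ndarray, f: np.ndarray, i: int, k: int, win_mode: str = "eq1_additive"
) -> float:
    if win_mode == "eq1_additive":
        # 0.5 plus the difference of the frequency-weighted payoff terms
        # W1(i,k) - W1(k,i) = f_i f_k (W0(i,k) - W0(k,i))
        delta = f[i] * f[k] * (payoff[i, k] - payoff[k, i])
        return float(np.clip(0.5 + delta, 0.0, 1.0))
    t_f = f[k] * payoff[i, k]
    t_o = f[i] * payoff[k, i]
    if t_f + t_o == 0.0:
        return 0.5  # degenerate: both weights vanish (absent strategies)
    return t_f / (t_f + t_o)


def _apply_cost(q: float, focal_het: bool, opp_het: bool, c: float, mode: str) -> float:
    if c <= 0.0 or focal_het == opp_het:
        return q
    if mode == "multiplicative":
        if opp_het:  # focal is the pure strategist
            return q * (1.0 + c) / (q * (1.0 + c) + (1.0 - q))
        return q / (q + (1.0 - q) * (1.0 + c))
    shifted = q + c if opp_het else q - c
    return float(np.clip(shifted, 0.0, 1.0))


def win_probability(
    payoff: PayoffMatrix,
    freqs,
    focal: str,
    opponent: str,
    focal_het: bool = False,
    opp_het: bool = False,
    c: float = 0.0,
    cost_mode: str = "multiplicative",
    win_mode: str = "eq1_additive",
) -> float:
    """Probability that the focal male wins a female from the opponent.

    Exactly 0.5 for same-strategy uncosted pairs at any frequencies.  The
    default ``win_mode="eq1_additive"`` instead adds the difference of the
    frequency-weighted payoff terms to the even-chance baseline,
    ``0.5 + f_i f_k (W0(i,k) - W0(k,i))``; ``"ratio"`` uses the
    opponent-frequency-weighted ratio
    ``f_k W0(i,k) / (f_k W0(i,k) + f_i W0(k,i))``.  When exactly one
    contestant is a pure strategist, the pure side gets the advantage ``c``.
    """
    if not 0.0 <= c < 1.0:
        raise ValueError("cost must lie in [0, 1)")
    f = validate_frequencies(freqs)
    i, k = strategy_code(focal), strategy_code(opponent)
    q = _base_win(payoff.matrix, f, i, k, win_mode)
    return float(np.clip(_apply_cost(q, focal_het, opp_het, c, cost_mode), 0.0, 1.0))


def assign_neighbours(strategies: np.ndarray, params: GameParams, rng):
    """Directed neighbour pairs for each male.

    Each male draws Poisson(n_strategy) neighbours uniformly among the other
    males (without replacement, capped at the population size minus one).
    Returns ``(focal, neighbour)`` index arrays; resampled every call (the
    neighbourhood has no persistence between time steps).
    """
    n = len(strategies)
    if n < 2:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    means = np.asarray(params.neighbour_means, dtype=float)[strategies]
    counts = np.minimum(rng.poisson(means), n - 1)
    focal = np.repeat(np.arange(n, dtype=np.int64), counts)
    r = rng.integers(0, n - 1, focal.size)
    nbr = r + (r >= focal)  # uniform over the other males
    key = np.unique(focal * n + nbr)  # drop duplicate draws per focal
    return key // n, key % n


def assemble_harems(
    strategies: np.ndarray,
    het: np.ndarray,
    n_females: int,
    params: GameParams,
    c: float,
    rng,
) -> np.ndarray:
    """Initial harem assembly in strategy order P, then M, then S.

    Each male draws a target harem size Poisson(h_strategy), with the mean
    reduced by the factor (1 - c) for heterozygotes.  Females are assigned
    uniformly at random from the unassigned pool until targets or females
    are exhausted; a female belongs to at most one harem.  Returns the
    per-female owner index (-1 = unmated).
    """
    owner = np.full(n_females, -1, dtype=np.int64)
    n_males = len(strategies)
    if n_males == 0 or n_females == 0:
        return owner
    means = np.asarray(params.harem_means, dtype=float)[strategies]
    if c > 0.0:
        means = means * np.where(het, 1.0 - c, 1.0)
    targets = rng.poisson(means)
    order_parts = []
    for strat in (1, 0, 2):  # P, M, S
        idx = np.flatnonzero(strategies == strat)
        rng.shuffle(idx)
        order_parts.append(idx)
    male_order = np.concatenate(order_parts)
    repeated = np.repeat(male_order, targets[male_order])
    fperm = rng.permutation(n_females)
    take = min(n_females, repeated.size)
    owner[fperm[:take]] = repeated[:take]
    return owner


def _pair_probs(
    x: int,
    y: int,
    het_f: np.ndarray,
    het_o: np.ndarray,
    payoff: np.ndarray,
    f: np.ndarray,
    c: float,
    cost_mode: str,
    win_mode: str = "eq1_additive",
) -> np.ndarray:
    q = _base_win(payoff, f, x, y, win_mode)
    p = np.full(het_f.shape[0], q)
    if c > 0.0:
        focal_pure = ~het_f & het_o
        opp_pure = het_f & ~het_o
        if cost_mode == "multiplicative":
            p[focal_pure] = q * (1 + c) / (q * (1 + c) + (1 - q))
            p[opp_pure] = q / (q + (1 - q) * (1 + c))
        else:
            p[focal_pure] = min(q + c, 1.0)
            p[opp_pure] = max(q - c, 0.0)
    return p


def _round_plan(strategies, focal, nbr, contest_rounds):
    """Yield ``(attacker, opponent, x, y)`` arrays per contest round.

    ``"cyclic_sym"`` (default): the three cyclic rounds act on every
    adjacency of the two strategies regardless of the direction it was
    drawn in, with the cycle winner always the attacker, then
    within-strategy contests.  ``"cyclic"``: only adjacencies drawn in the
    winner's own neighbour list.  ``"all"``: every directed adjacency
    attacks as focal (cyclic, reverse, then same-strategy rounds).
    """
    sf, sn = strategies[focal], strategies[nbr]
    if contest_rounds in ("cyclic", "cyclic_sym"):
        for x, y in CYCLIC_ROUNDS:
            sel = np.flatnonzero((sf == x) & (sn == y))
            att, opp = focal[sel], nbr[sel]
            if contest_rounds == "cyclic_sym":
                rev = np.flatnonzero((sf == y) & (sn == x))
                att = np.concatenate([att, nbr[rev]])
                opp = np.concatenate([opp, focal[rev]])
            yield att, opp, x, y
        if contest_rounds == "cyclic_sym":
            for x, y in SAME_ROUNDS:
                sel = np.flatnonzero((sf == x) & (sn == y))
                yield focal[sel], nbr[sel], x, y
    elif contest_rounds == "all":
        for x, y in CYCLIC_ROUNDS + ANTI_ROUNDS + SAME_ROUNDS:
            sel = np.flatnonzero((sf == x) & (sn == y))
            yield focal[sel], nbr[sel], x, y
    else:
        raise ValueError(f"unknown contest_rounds {contest_rounds!r}")


def run_contests(
    strategies: np.ndarray,
    het: np.ndarray,
    owner: np.ndarray,
    focal: np.ndarray,
    nbr: np.ndarray,
    payoff: PayoffMatrix,
    freqs,
    c: float,
    rng,
    cost_mode: str = "multiplicative",
    contest_rounds: str = "cyclic_sym",
    steal_scope: str = "assembled",
    win_mode: str = "eq1_additive",
    method: str = "vectorized",
    record: bool = False,
):
    """Run the contest rounds, transferring females between harems.

    In each round every (attacker, opponent) adjacency from the neighbour
    draw contests once: each eligible female of the opponent transfers to
    the attacker independently with the frequency-dependent win
    probability of the attacking strategy.  Rounds are sequential in the
    stated order (S vs P, M vs S, P vs M, then within-strategy).  With
    ``steal_scope="assembled"`` (default) contests dispute the harems as
    assembled, so a female changes hands at most once per mating phase
    ("prior to copulation"); ``"current"`` lets later contests re-steal
    previously won females.  Strategy frequencies are fixed throughout
    (transfers do not change male strategy counts).

    ``method="sequential"`` is a one-contest-at-a-time reference
    implementation (it can also record per-contest
    :class:`ContestOutcome` entries); ``"vectorized"`` resolves each round
    in batch and is the production path.  Returns the updated owner array
    (and the outcome list when recording).
    """
    f = validate_frequencies(freqs)
    w = payoff.matrix
    owner = owner.copy()
    assembled = owner.copy()
    outcomes: list[ContestOutcome] = []
    if method == "sequential":
        for att, opp, x, y in _round_plan(strategies, focal, nbr, contest_rounds):
            perm = rng.permutation(att.size)
            att, opp = att[perm], opp[perm]
            ref = assembled if steal_scope == "assembled" else owner
            for fm, om in zip(att, opp):
                fm, om = int(fm), int(om)
                p = _pair_probs(x, y, het[[fm]], het[[om]], w, f, c, cost_mode, win_mode)[0]
                # eligible: females the opponent holds (and, under the
                # assembled scope, was originally assigned)
                females = np.flatnonzero((owner == om) & (ref == om))
                if females.size == 0:
                    continue
                moved = females[rng.random(females.size) < p]
                owner[moved] = fm
                if record:
                    outcomes.append(ContestOutcome(fm, om, list(map(int, moved))))
    elif method == "vectorized":
        n_males = len(strategies)
        att_of = np.empty(n_males, dtype=np.int64)
        p_of = np.empty(n_males)
        for att, opp, x, y in _round_plan(strategies, focal, nbr, contest_rounds):
            if att.size == 0:
                continue
            perm = rng.permutation(att.size)
            ff, oo = att[perm], opp[perm]
            order = np.argsort(oo, kind="stable")
            ff, oo = ff[order], oo[order]
            # rank of each contest within its opponent's attacker sequence
            new_grp = np.r_[True, oo[1:] != oo[:-1]]
            starts = np.flatnonzero(new_grp)
            sizes = np.diff(np.r_[starts, oo.size])
            rank = np.arange(oo.size) - np.repeat(starts, sizes)
            p = _pair_probs(x, y, het[ff], het[oo], w, f, c, cost_mode, win_mode)
            round_ref = assembled if steal_scope == "assembled" else owner.copy()
            for r in range(int(sizes.max())):
                m = rank == r
                att_of.fill(-1)
                att_of[oo[m]] = ff[m]
                p_of[oo[m]] = p[m]
                held = round_ref >= 0
                tgt = np.full(owner.shape[0], -1, dtype=np.int64)
                tgt[held] = att_of[round_ref[held]]
                cand = np.flatnonzero((tgt >= 0) & (owner == round_ref))
                if cand.size == 0:
                    continue
                moved = cand[rng.random(cand.size) < p_of[round_ref[cand]]]
                owner[moved] = tgt[moved]
        # within one round each female is resolved against her reference
        # owner's attacker sequence, so she changes hands at most once per
        # round; cross-strategy rounds under the "current" scope are
        # exactly sequential (attackers are never that round's opponents)
    else:
        raise ValueError(f"unknown contest method {method!r}")
    if record:
        return owner, outcomes
    return owner
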