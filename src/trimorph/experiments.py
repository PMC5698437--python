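"""Scenario protocols: two-allele contests, trimorphism maintenance, invasion.

Replicates are embarrassingly parallel and reproducible: replicate ``i`` of
a scenario with base seed ``s`` always uses the generator
``numpy.random.default_rng([s, i])``, so the same (config, seed) pair gives
bit-identical results.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from . import demography, genetics
from .config import ScenarioConfig
from .demography import PopulationState, initial_population, simulate
from .genetics import ALLELES

logger = logging.getLogger(__name__)

MAINTENANCE_WINDOW = 100  # final steps used for mean strategy frequencies


def replicate_rng(base_seed: int, rep: int) -> np.random.Generator:
    """Independent, reproducible RNG stream for one replicate."""
    return np.random.default_rng([int(base_seed), int(rep)])


@dataclass
class ReplicateResult:
    series: pd.DataFrame
    maintained: bool
    alleles_present: np.ndarray
    fixation_time: dict  # allele -> step of loss, or None
    extinct: bool


@dataclass
class MaintenanceSummary:
    """Trimorphism maintenance over replicates of one scenario."""

    n_replicates: int
    n_maintained: int
    maintenance_probability: float
    ci_low: float
    ci_high: float
    mean_strategy_freqs: dict
    loss_time_quantiles: dict
    label: str = ""

    def as_row(self) -> dict:
        row = {
            "label": self.label,
            "n_replicates": self.n_replicates,
            "n_maintained": self.n_maintained,
            "maintenance_probability": self.maintenance_probability,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        }
        row.update({f"mean_f_{s}": v for s, v in self.mean_strategy_freqs.items()})
        return row


@dataclass
class TwoAlleleSummary:
    residents: tuple[str, str]
    expected_winner: str
    n_replicates: int
    n_fixed: int
    n_won_by_expected: int
    loser_extinction_times: list = field(default_factory=list)

    @property
    def fixation_fraction(self) -> float:
        return self.n_fixed / self.n_replicates

    @property
    def expected_winner_fraction(self) -> float:
        return self.n_won_by_expected / self.n_replicates

    @property
    def median_time_to_monomorphism(self) -> float:
        if not self.loser_extinction_times:
            return float("nan")
        return float(np.median(self.loser_extinction_times))


def maintenance_probability(flags, alpha: float = 0.05):
    """Fraction of replicates keeping all three alleles, with exact
    (Clopper-Pearson) binomial confidence interval."""
    flags = np.asarray(flags, dtype=bool)
    n = flags.size
    k = int(flags.sum())
    low, high = proportion_confint(k, n, alpha=alpha, method="beta")
    return k / n, float(low), float(high)


def cycle_winner(allele_a: str, allele_b: str, payoff) -> str:
    """Which of two alleles codes the strategy that beats the other's.

    Strategy X beats Y iff W0(X, Y) > W0(Y, X); allele and strategy codes
    are aligned.
    """
    a, b = genetics.allele_code(allele_a), genetics.allele_code(allele_b)
    if a == b:
        raise ValueError("need two distinct alleles")
    w = payoff.matrix
    if w[a, b] == w[b, a]:
        raise ValueError("payoff matrix gives no winner for this pair")
    return ALLELES[a] if w[a, b] > w[b, a] else ALLELES[b]


def _allele_loss_times(series: pd.DataFrame) -> dict:
    times = {}
    for allele in ALLELES:
        counts = series[f"n_allele_{allele}"].to_numpy()
        gone = np.flatnonzero(counts == 0)
        times[allele] = int(series["step"].iloc[gone[0]]) if gone.size else None
    return times


def run_replicate(
    config: ScenarioConfig,
    rep: int = 0,
    stop_on_allele_loss: bool = False,
    state: PopulationState | None = None,
    rng: np.random.Generator | None = None,
) -> ReplicateResult:
    """Run one replicate of a scenario and summarize allele persistence."""
    if rng is None:
        rng = replicate_rng(config.seed, rep)
    n_present = int(np.count_nonzero(np.asarray(config.initial_allele_freqs) > 0))
    stop = None
    if stop_on_allele_loss:
        stop = lambda s: int(s.alleles_present().sum()) < n_present  # noqa: E731
    series, final = simulate(config, rng, state=state, stop_when=stop)
    present = final.alleles_present()
    return ReplicateResult(
        series=series,
        maintained=bool(present.all()),
        alleles_present=present,
        fixation_time=_allele_loss_times(series),
        extinct=final.size == 0,
    )


def _summarize_maintenance(results, label="") -> MaintenanceSummary:
    flags = [r.maintained for r in results]
    prob, lo, hi = maintenance_probability(flags)
    maintained = [r for r in results if r.maintained]
    mean_freqs = {}
    if maintained:
        tails = pd.concat([r.series.iloc[-MAINTENANCE_WINDOW:] for r in maintained])
        for s in ("M", "P", "S"):
            mean_freqs[s] = float(tails[f"f_{s}"].mean())
    loss_times = []
    for r in results:
        lost = [t for t in r.fixation_time.values() if t is not None]
        if lost:
            loss_times.append(min(lost))
    quantiles = {}
    if loss_times:
        qs = np.quantile(loss_times, [0.25, 0.5, 0.75])
        quantiles = {"q25": float(qs[0]), "median": float(qs[1]), "q75": float(qs[2])}
    return MaintenanceSummary(
        n_replicates=len(results),
        n_maintained=len(maintained),
        maintenance_probability=prob,
        ci_low=lo,
        ci_high=hi,
        mean_strategy_freqs=mean_freqs,
        loss_time_quantiles=quantiles,
        label=label,
    )


def run_maintenance(
    config: ScenarioConfig,
    n_replicates: int | None = None,
    stop_on_allele_loss: bool = True,
    keep_series: bool = False,
):
    """Trimorphism-maintenance protocol: equal initial allele frequencies,
    maintenance probability at the horizon plus mean strategy frequencies
    over the final window of maintaining replicates."""
    f = np.asarray(config.initial_allele_freqs)
    if not np.allclose(f, 1 / 3):
        raise ValueError("maintenance protocol requires equal allele frequencies")
    n = n_replicates if n_replicates is not None else config.replicates
    results = [
        run_replicate(config, rep, stop_on_allele_loss=stop_on_allele_loss)
        for rep in range(n)
    ]
    summary = _summarize_maintenance(results, label=config.label)
    if keep_series:
        return summary, results
    return summary


def run_two_allele(
    config: ScenarioConfig, n_replicates: int | None = None
) -> TwoAlleleSummary:
    """Two-allele competition: which allele fixes, and how fast."""
    f = np.asarray(config.initial_allele_freqs)
    if np.count_nonzero(f == 0) != 1:
        raise ValueError("two-allele protocol requires exactly one absent allele")
    residents = tuple(a for a, fa in zip(ALLELES, f) if fa > 0)
    expected = cycle_winner(residents[0], residents[1], config.payoff)
    n = n_replicates if n_replicates is not None else config.replicates
    n_fixed = n_expected = 0
    times = []
    for rep in range(n):
        rng = replicate_rng(config.seed, rep)
        stop = lambda s: int(s.alleles_present().sum()) <= 1  # noqa: E731
        series, final = simulate(config, rng, stop_when=stop)
        present = final.alleles_present()
        if int(present.sum()) == 1:
            n_fixed += 1
            winner = ALLELES[int(np.flatnonzero(present)[0])]
            if winner == expected:
                n_expected += 1
            loser = residents[0] if residents[1] == winner else residents[1]
            t_loss = _allele_loss_times(series)[loser]
            if t_loss is not None:
                times.append(t_loss)
    return TwoAlleleSummary(
        residents=residents,
        expected_winner=expected,
        n_replicates=n,
        n_fixed=n_fixed,
        n_won_by_expected=n_expected,
        loser_extinction_times=times,
    )


def _swap_heterozygotes(state, residents, invader, n_swap, payoff, mechanism, rng):
    """Replace up to `n_swap` resident heterozygotes by heterozygotes
    carrying the invading allele paired with the losing resident allele."""
    a = genetics.allele_code(residents[0])
    b = genetics.allele_code(residents[1])
    loser = genetics.allele_code(cycle_winner(*residents, payoff))
    loser = b if loser == a else a  # the resident allele that is losing
    inv = genetics.allele_code(invader)
    new_pair = np.sort(np.array([inv, loser], dtype=np.int8))
    lo, hi = min(a, b), max(a, b)

    pools = []
    for cls, alleles in (("juv", state.juv_alleles), ("adult", state.adult_alleles)):
        idx = np.flatnonzero((alleles[:, 0] == lo) & (alleles[:, 1] == hi))
        pools.extend((cls, int(i)) for i in idx)
    if len(pools) < n_swap:
        warnings.warn(
            f"only {len(pools)} resident heterozygotes available; swapping all",
            stacklevel=2,
        )
    chosen = [pools[i] for i in rng.choice(len(pools), min(n_swap, len(pools)), replace=False)] if pools else []
    male_freqs = state.male_strategy_frequencies()
    for cls, i in chosen:
        if cls == "juv":
            state.juv_alleles[i] = new_pair
        else:
            state.adult_alleles[i] = new_pair
            if state.adult_sex[i] == 1:  # adult male: fresh strategy assignment
                state.adult_strategy[i] = demography._assign_strategies(
                    new_pair[None, :], mechanism, payoff, male_freqs, rng
                )[0]
    return len(chosen)


def run_invasion(
    config: ScenarioConfig,
    invader: str,
    burn_in: int = 100,
    n_swap: int = 20,
    n_replicates: int | None = None,
) -> MaintenanceSummary:
    """Rare-allele invasion protocol.

    A two-allele resident population (the two alleles other than `invader`,
    at equal frequencies) is burnt in for `burn_in` steps to its
    quasi-stationary state; then `n_swap` resident heterozygotes are
    exchanged for heterozygotes carrying the invading allele paired with the
    currently losing resident allele, and the run continues to the horizon
    (`config.T` total steps).  Maintenance of all three alleles at the end
    is summarized as in the maintenance protocol.
    """
    inv = genetics.allele_code(invader)
    residents = tuple(a for a in ALLELES if a != invader)
    res_freqs = np.zeros(3)
    for a in residents:
        res_freqs[genetics.allele_code(a)] = 0.5
    if config.T <= burn_in:
        raise ValueError("horizon must exceed the burn-in")
    base = config.with_(initial_allele_freqs=tuple(res_freqs))
    n = n_replicates if n_replicates is not None else config.replicates
    results = []
    for rep in range(n):
        rng = replicate_rng(config.seed, rep)
        state = initial_population(
            base.initial_N if base.initial_N else base.lifecycle.K,
            base.initial_allele_freqs,
            base.mechanism,
            base.payoff,
            rng,
        )
        pre, _ = simulate(base.with_(T=burn_in), rng, state=state)
        n_swapped = _swap_heterozygotes(
            state, residents, invader, n_swap, base.payoff, base.mechanism, rng
        )
        if n_swapped == 0:
            logger.warning("replicate %d: no resident heterozygotes to swap", rep)
        post, final = simulate(
            base.with_(T=config.T - burn_in),
            rng,
            state=state,
            stop_when=lambda s: not s.alleles_present()[inv],
        )
        series = pd.concat([pre, post], ignore_index=True)
        present = final.alleles_present()
        results.append(
            ReplicateResult(
                series=series,
                maintained=bool(present.all()),
                alleles_present=present,
                fixation_time=_allele_loss_times(series),
                extinct=final.size == 0,
            )
        )
    label = config.label or f"invade_{invader}"
    return _summarize_maintenance(results, label=label)


def run_grid(configs, n_replicates: int | None = None) -> pd.DataFrame:
    """Run the maintenance protocol over a list of scenarios; tidy table."""
    rows = []
    for config in configs:
        summary = run_maintenance(config, n_replicates=n_replicates)
        row = summary.as_row()
        row.update(
            mechanism=config.mechanism.mode,
            c=config.mechanism.heterozygote_cost,
            K=config.lifecycle.K,
            s_j=config.lifecycle.s_j,
            s_a=config.lifecycle.s_a,
            F=config.lifecycle.F,
        )
        rows.append(row)
        logger.info(
            "grid cell %s: maintenance %.2f",
            row.get("label", ""),
            row["maintenance_probability"],
        )
    return pd.DataFrame(rows)
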