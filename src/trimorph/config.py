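"""Scenario configuration: one object parameterizing a full simulation.

Configs serialize to a flat key/value YAML document mirroring the model
nomenclature (``sigma, s_j, s_a, k, F, K, W0, h_p, h_m, h_s, n_p, n_m, n_s,
c, mechanism, dominance_order, T, R, seed``); ``W0`` is written in the
(P, M, S) row/column order it is conventionally printed in.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .demography import LifeCycleParams
from .game import GameParams, PayoffMatrix
from .genetics import DEFAULT_DOMINANCE_ORDER, GeneticMechanism


@dataclass(frozen=True)
class ScenarioConfig:
    """Full parameterization of one simulation scenario."""

    mechanism: GeneticMechanism = field(
        default_factory=lambda: GeneticMechanism(heterozygote_cost=0.0)
    )
    lifecycle: LifeCycleParams = field(default_factory=LifeCycleParams)
    game: GameParams = field(default_factory=GameParams)
    payoff: PayoffMatrix = field(default_factory=PayoffMatrix.default)
    initial_allele_freqs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    T: int = 300
    replicates: int = 200
    seed: int = 0
    game_enabled: bool = True
    initial_N: int | None = None
    contest_method: str = "vectorized"
    label: str = ""

    def __post_init__(self) -> None:
        f = np.asarray(self.initial_allele_freqs, dtype=float)
        if f.shape != (3,) or np.any(f < 0) or abs(f.sum() - 1.0) > 1e-8:
            raise ValueError(
                "initial_allele_freqs must be three non-negative values summing to 1"
            )
        object.__setattr__(self, "initial_allele_freqs", tuple(float(x) for x in f))
        if self.T < 1:
            raise ValueError("horizon T must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def with_(self, **kw) -> "ScenarioConfig":
        return replace(self, **kw)

    # -- flat-document serialization --------------------------------------
    def to_dict(self) -> dict:
        lc, gm, mech = self.lifecycle, self.game, self.mechanism
        return {
            "mechanism": mech.mode,
            "dominance_order": "".join(mech.dominance_order),
            "c": mech.heterozygote_cost,
            "cost_mode": gm.cost_mode,
            "cost_under_dominance": gm.cost_under_dominance,
            "contest_rounds": gm.contest_rounds,
            "steal_scope": gm.steal_scope,
            "win_mode": gm.win_mode,
            "plastic_criterion": mech.plastic_criterion,
            "sigma": lc.sigma,
            "s_j": lc.s_j,
            "s_a": lc.s_a,
            "F": lc.F,
            "k": lc.k,
            "K": lc.K,
            "recruitment_form": lc.recruitment_form,
            "W0": self.payoff.to_pms().tolist(),
            "h_m": gm.harem_means[0],
            "h_p": gm.harem_means[1],
            "h_s": gm.harem_means[2],
            "n_m": gm.neighbour_means[0],
            "n_p": gm.neighbour_means[1],
            "n_s": gm.neighbour_means[2],
            "init_freq_m": self.initial_allele_freqs[0],
            "init_freq_p": self.initial_allele_freqs[1],
            "init_freq_s": self.initial_allele_freqs[2],
            "T": self.T,
            "R": self.replicates,
            "seed": self.seed,
            "game_enabled": self.game_enabled,
            "initial_N": self.initial_N,
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "ScenarioConfig":
        doc = dict(doc)
        mech = GeneticMechanism(
            mode=doc.pop("mechanism", "dominance"),
            dominance_order=tuple(doc.pop("dominance_order", DEFAULT_DOMINANCE_ORDER)),
            heterozygote_cost=float(doc.pop("c", 0.0)),
            plastic_criterion=doc.pop("plastic_criterion", "expected"),
        )
        lc = LifeCycleParams(
            sigma=float(doc.pop("sigma", 0.5)),
            s_j=float(doc.pop("s_j", 0.2)),
            s_a=float(doc.pop("s_a", 0.2)),
            F=float(doc.pop("F", 14.0)),
            k=float(doc.pop("k", 0.004)),
            K=int(doc.pop("K", 500)),
            recruitment_form=doc.pop("recruitment_form", "ricker"),
        )
        game = GameParams(
            harem_means=(
                float(doc.pop("h_m", 1.0)),
                float(doc.pop("h_p", 3.0)),
                float(doc.pop("h_s", 0.5)),
            ),
            neighbour_means=(
                float(doc.pop("n_m", 3.0)),
                float(doc.pop("n_p", 3.0)),
                float(doc.pop("n_s", 3.0)),
            ),
            cost_mode=doc.pop("cost_mode", "multiplicative"),
            cost_under_dominance=bool(doc.pop("cost_under_dominance", True)),
            contest_rounds=doc.pop("contest_rounds", "cyclic_sym"),
            steal_scope=doc.pop("steal_scope", "assembled"),
            win_mode=doc.pop("win_mode", "eq1_additive"),
        )
        payoff = (
            PayoffMatrix.from_pms(doc.pop("W0"))
            if "W0" in doc
            else PayoffMatrix.default()
        )
        freqs = (
            float(doc.pop("init_freq_m", 1 / 3)),
            float(doc.pop("init_freq_p", 1 / 3)),
            float(doc.pop("init_freq_s", 1 / 3)),
        )
        initial_n = doc.pop("initial_N", None)
        return cls(
            mechanism=mech,
            lifecycle=lc,
            game=game,
            payoff=payoff,
            initial_allele_freqs=freqs,
            T=int(doc.pop("T", 300)),
            replicates=int(doc.pop("R", 200)),
            seed=int(doc.pop("seed", 0)),
            game_enabled=bool(doc.pop("game_enabled", True)),
            initial_N=None if initial_n in (None, "null") else int(initial_n),
            label=str(doc.pop("label", "")),
        )


def load_config(path) -> ScenarioConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"config file {path} must hold a flat mapping")
    return ScenarioConfig.from_dict(doc)


def save_config(config: ScenarioConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
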