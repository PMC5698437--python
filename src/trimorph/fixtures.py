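"""Deterministic generators for test signals and miniature populations.

Everything here is a pure function of its spec plus seed, so fixtures are
bit-identical across reruns and no data files are needed anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .demography import PopulationState
from .genetics import GeneticMechanism, genotype_codes, strategy_code


@dataclass(frozen=True)
class SignalSpec:
    """Sum-of-sinusoids test signal with optional Gaussian or AR(1) noise.

    ``components`` is a list of (period, amplitude, phase) triples; periods
    must be at least 2 (the Nyquist limit of unit-step sampling).
    """

    components: tuple = ((16.0, 1.0, 0.0),)
    noise_sd: float = 0.0
    ar_phi: float = 0.0
    length: int = 1024
    seed: int = 0

    def __post_init__(self) -> None:
        comps = tuple((float(p), float(a), float(ph)) for p, a, ph in self.components)
        if any(p < 2 for p, _, _ in comps):
            raise ValueError("sinusoid periods must be >= 2 steps")
        if self.length < 1:
            raise ValueError("length must be positive")
        if not -1.0 < self.ar_phi < 1.0:
            raise ValueError("AR(1) coefficient must lie in (-1, 1)")
        object.__setattr__(self, "components", comps)


def make_signal(spec: SignalSpec) -> np.ndarray:
    """Deterministic sum of sinusoids plus (optionally AR(1)-filtered) noise."""
    t = np.arange(spec.length, dtype=float)
    x = np.zeros(spec.length)
    for period, amplitude, phase in spec.components:
        x += amplitude * np.sin(2 * np.pi * t / period + phase)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        eps = rng.normal(0.0, spec.noise_sd, spec.length)
        if spec.ar_phi != 0.0:
            noise = np.empty(spec.length)
            prev = eps[0] / np.sqrt(1 - spec.ar_phi**2)
            for i in range(spec.length):
                prev = spec.ar_phi * prev + eps[i]
                noise[i] = prev
            x += noise
        else:
            x += eps
    return x


def make_ar1(length: int, phi: float, sd: float = 1.0, seed: int = 0) -> np.ndarray:
    """Stationary AR(1) series with coefficient `phi` (no sinusoids)."""
    return make_signal(
        SignalSpec(components=(), noise_sd=sd, ar_phi=phi, length=length, seed=seed)
    )


@dataclass(frozen=True)
class MiniPopulationSpec:
    """Explicit small population for contest-level unit tests.

    ``members`` is a tuple of (count, sex, age_class, genotype, strategy)
    entries, e.g. ``(1, "male", "adult", "pp", "P")``; strategy must be
    given for adult males and omitted (None) otherwise.
    """

    members: tuple = ()
    seed: int = 0


def make_population(spec: MiniPopulationSpec, mechanism: GeneticMechanism | None = None) -> PopulationState:
    """Build the explicit population described by `spec`.

    If an adult male's strategy is left None, it is filled in by
    `mechanism` (dominance only: the plastic choice would need population
    frequencies that a fixture should state explicitly).
    """
    juv_a, juv_sex = [], []
    ad_a, ad_sex, ad_strat = [], [], []
    for count, sex, age, genotype, strategy in spec.members:
        codes = sorted(genotype_codes(genotype))
        is_male = {"male": True, "female": False}[sex]
        for _ in range(int(count)):
            if age == "juvenile":
                if strategy is not None:
                    raise ValueError("juveniles cannot carry a strategy")
                juv_a.append(codes)
                juv_sex.append(1 if is_male else 0)
            elif age == "adult":
                if is_male and strategy is None:
                    if mechanism is None or mechanism.mode != "dominance":
                        raise ValueError(
                            "adult male needs an explicit strategy or a dominance mechanism"
                        )
                    from .genetics import phenotype_dominance

                    strategy = phenotype_dominance(genotype, mechanism.dominance_order)
                if not is_male and strategy is not None:
                    raise ValueError("females cannot carry a strategy")
                ad_a.append(codes)
                ad_sex.append(1 if is_male else 0)
                ad_strat.append(strategy_code(strategy) if is_male else -1)
            else:
                raise ValueError(f"unknown age class {age!r}")
    return PopulationState(
        np.array(juv_a, dtype=np.int8).reshape(-1, 2),
        np.array(juv_sex, dtype=np.int8),
        np.array(ad_a, dtype=np.int8).reshape(-1, 2),
        np.array(ad_sex, dtype=np.int8),
        np.array(ad_strat, dtype=np.int8),
    )
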