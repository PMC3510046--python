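"""Motor stoichiometry and transport economy.

Kinesin-1 heavy chains (Khc/KIF5A) function as homodimers. When wild-type
and mutant monomers are co-expressed and pair at random, the dimer pool is
binomial in the wild-type monomer fraction ``p``: a fraction ``p**2`` of
dimers are wild-type homodimers, ``2*p*(1-p)`` heterodimers and
``(1-p)**2`` mutant homodimers. A cargo hauled by ``n`` independently drawn
dimers then carries at least one mutant-containing motor with probability
``1 - (p**2)**n`` — near certainty for the 5-8 motors per vesicle typical of
kinesin cargo.

Transport economy links the three observables of a transport movie:
``flux = density * velocity`` (organelles per minute passing a cross-section
equals organelles per micron times microns per second, times 60). Holding
flux constant, any fractional drop in velocity must be repaid by a
reciprocal rise in density; `required_density_change` returns that rise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MotorPool",
    "DimerComposition",
    "CargoSpec",
    "TransportEconomy",
    "dimer_composition",
    "prob_cargo_has_mutant",
    "required_density_change",
    "sample_dimers",
]


@dataclass(frozen=True)
class MotorPool:
    """Monomer pool characterised by its wild-type fraction ``p_wt``."""

    p_wt: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_wt <= 1.0) or not np.isfinite(self.p_wt):
            raise ValueError(f"p_wt must lie in [0, 1], got {self.p_wt}")


@dataclass(frozen=True)
class DimerComposition:
    """Fractions of wild-type homodimers, heterodimers and mutant homodimers."""

    f_wt_homo: float
    f_hetero: float
    f_mut_homo: float

    def __post_init__(self) -> None:
        total = self.f_wt_homo + self.f_hetero + self.f_mut_homo
        if min(self.f_wt_homo, self.f_hetero, self.f_mut_homo) < 0:
            raise ValueError("dimer fractions must be non-negative")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"dimer fractions must sum to 1, got {total}")


@dataclass(frozen=True)
class CargoSpec:
    """Number of motor dimers attached to one cargo (5-8 for kinesin vesicles)."""

    n_motors: int

    def __post_init__(self) -> None:
        if int(self.n_motors) != self.n_motors or self.n_motors < 1:
            raise ValueError(f"n_motors must be a positive integer, got {self.n_motors}")


@dataclass(frozen=True)
class TransportEconomy:
    """Cargo density (µm⁻¹), velocity (µm·s⁻¹) and the flux they imply (min⁻¹)."""

    density: float
    velocity: float

    @property
    def flux(self) -> float:
        return self.density * self.velocity * 60.0


def dimer_composition(pool: MotorPool | float) -> DimerComposition:
    """Binomial dimer composition for a monomer pool with wild-type fraction p.

    Random (unbiased) pairing gives wt-homodimer fraction ``p**2``,
    heterodimer ``2 p (1-p)`` and mutant-homodimer ``(1-p)**2``.

    >>> dimer_composition(0.5).f_wt_homo
    0.25
    """
    if not isinstance(pool, MotorPool):
        pool = MotorPool(float(pool))
    p = pool.p_wt
    return DimerComposition(f_wt_homo=p * p, f_hetero=2 * p * (1 - p), f_mut_homo=(1 - p) ** 2)


def sample_dimers(pool: MotorPool | float, n: int, rng: np.random.Generator | int | None = None) -> DimerComposition:
    """Monte-Carlo estimate of the dimer composition from ``n`` random pairings.

    Draws 2*n monomers independently (wild-type with probability p_wt) and
    pairs them; used as the stochastic cross-check of `dimer_composition`.
    """
    if not isinstance(pool, MotorPool):
        pool = MotorPool(float(pool))
    rng = np.random.default_rng(rng)
    wt = rng.random((int(n), 2)) < pool.p_wt
    n_wt_per_dimer = wt.sum(axis=1)
    return DimerComposition(
        f_wt_homo=float(np.mean(n_wt_per_dimer == 2)),
        f_hetero=float(np.mean(n_wt_per_dimer == 1)),
        f_mut_homo=float(np.mean(n_wt_per_dimer == 0)),
    )


def prob_cargo_has_mutant(pool: MotorPool | float, cargo: CargoSpec | int) -> float:
    """Probability that a cargo carries at least one mutant-containing dimer.

    Heterodimers count as mutant-containing (the dominant-negative premise);
    the cargo's dimers are independent draws from the binomial pool, so the
    probability is ``1 - (p_wt**2)**n_motors``.
    """
    if not isinstance(pool, MotorPool):
        pool = MotorPool(float(pool))
    if not isinstance(cargo, CargoSpec):
        cargo = CargoSpec(int(cargo))
    return 1.0 - (pool.p_wt**2) ** cargo.n_motors


def required_density_change(velocity_factor: float) -> float:
    """Fractional density increase keeping flux constant when velocity scales.

    From flux = density * velocity: scaling velocity by ``f`` requires
    scaling density by ``1/f``, i.e. a relative increase of ``1/f - 1``.
    A 50% velocity reduction (f=0.5) therefore demands a 100% density
    increase (returns 1.0).
    """
    if not np.isfinite(velocity_factor) or velocity_factor <= 0:
        raise ValueError(f"velocity_factor must be positive, got {velocity_factor}")
    return 1.0 / velocity_factor - 1.0
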