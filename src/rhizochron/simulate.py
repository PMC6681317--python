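"""Synthetic root systems with known ground-truth rhizochron structure.

The generator draws plants whose lateral-root lengths follow the linear
allometry the rhizochron index estimates: branch points arise as a Poisson
number of uniform positions within the branching zone, and each LR length is
the line value plus Gaussian noise, truncated at zero.  The intercept ``b0``
is anchored at the midpoint of the branching zone, so ``b0`` is the plant's
expected mean LR length and the line stays positive over the whole zone
whenever ``b0 > |m0| * BZ / 2``; the fitted slope is shift-invariant, so the
anchoring does not affect slope recovery, and keeping the line positive
makes truncation at zero rare for realistic noise levels.

Factorial experiments (accession x day x treatment x replicate) derive one
independent random substream per plant deterministically from the design
seed, so a design reproduces bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import RootSystem


@dataclass(frozen=True)
class AccessionParams:
    """Ground-truth parameters of one accession.

    ``m0`` is the true rhizochron slope (dimensionless), ``b0`` the expected
    LR length (mm) at the midpoint of the branching zone (the plant's mean
    LR length), and ``growth_rate`` the primary-root elongation rate in
    mm/day.
    """

    name: str
    m0: float
    b0: float
    growth_rate: float = 5.0

    def __post_init__(self) -> None:
        if self.growth_rate <= 0:
            raise ValueError(f"accession {self.name!r}: growth_rate must be positive")


@dataclass(frozen=True)
class TreatmentEffect:
    """Additive shift in the true slope and a multiplicative LR-length scale."""

    delta_m: float = 0.0
    tlrl_scale: float = 1.0


@dataclass
class SimulationDesign:
    """A factorial root-phenotyping experiment to simulate.

    Defaults emulate an Arabidopsis seedling plate assay: primary roots of a
    few cm scanned at 8-12 days after sowing, about one lateral root every
    2 mm of branching zone (``lam`` = 0.5 /mm), and residual LR-length noise
    ``sigma`` = 0.5 mm around the allometric line.  The pre-BZ takes 20% of
    the PR and the BZ 60%, leaving 20% of unbranched apical PR.
    ``stage_effect`` is the additive change of the true slope per day after
    the first observation day (0 = slope is developmentally stable).
    Treatments are additional arms next to an implicit control arm labelled
    ``""``.
    """

    accessions: list[AccessionParams]
    days: list[int]
    replicates: int
    lam: float = 0.5
    sigma: float = 0.5
    bz_fraction: float = 0.6
    pre_bz_fraction: float = 0.2
    stage_effect: float = 0.0
    treatment_effects: dict[str, TreatmentEffect] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.accessions:
            raise ValueError("design needs at least one accession")
        if not self.days:
            raise ValueError("design needs at least one observation day")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.lam <= 0:
            raise ValueError("branching density lam must be positive")
        if self.sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        if not (0 < self.bz_fraction < 1):
            raise ValueError("bz_fraction must be in (0, 1)")
        if self.pre_bz_fraction < 0 or self.pre_bz_fraction + self.bz_fraction > 1:
            raise ValueError("pre_bz_fraction + bz_fraction must not exceed 1")

    @property
    def treatments(self) -> list[str]:
        return [""] + sorted(self.treatment_effects)


def simulate_root(
    m0: float,
    b0: float,
    prl: float,
    bz_fraction: float,
    lam: float,
    sigma: float,
    rng: np.random.Generator,
    pre_bz_fraction: float = 0.2,
    plant_id: str = "sim",
    accession: str = "",
    day: int = 0,
    treatment: str = "",
) -> RootSystem:
    """Draw one plant with true slope ``m0``.

    The LR count is Poisson(lam x BZ length); positions are uniform over the
    BZ and sorted; with ``c`` the BZ midpoint,
    LR length_i = max(0, m0 * (x_i - c) + b0 + N(0, sigma)).
    Deterministic for a fixed generator state.
    """
    if prl <= 0:
        raise ValueError("prl must be positive")
    pre_bz = pre_bz_fraction * prl
    bz = bz_fraction * prl
    if pre_bz + bz > prl + 1e-12:
        raise ValueError("pre-BZ plus BZ exceeds the primary root length")
    n = int(rng.poisson(lam * bz))
    if n == 0:
        return RootSystem(plant_id, accession, day, treatment, (), prl, ())
    x = np.sort(rng.uniform(pre_bz, pre_bz + bz, n))
    centre = pre_bz + bz / 2.0
    y = np.maximum(0.0, m0 * (x - centre) + b0 + rng.normal(0.0, sigma, n))
    segments = np.diff(x, prepend=0.0)
    return RootSystem(
        plant_id,
        accession,
        day,
        treatment,
        tuple(segments),
        prl - float(x[-1]),
        tuple(y),
    )


def simulate_experiment(design: SimulationDesign) -> tuple[list[RootSystem], pd.DataFrame]:
    """Simulate every accession x day x treatment x replicate cell.

    The primary root grows linearly with day at the accession's rate.  A
    treatment multiplies every LR length by its ``tlrl_scale`` after adding
    ``delta_m`` to the slope, so the cell's true slope is
    ``(m0 + stage_effect * (day - days[0]) + delta_m) * tlrl_scale``.

    Returns the cohort and a ground-truth table with one row per design cell
    (columns accession, day, treatment, m_true, b_true, prl).
    """
    roots: list[RootSystem] = []
    truth_rows = []
    day0 = design.days[0]
    effects = {"": TreatmentEffect(), **design.treatment_effects}
    for ai, acc in enumerate(design.accessions):
        for di, day in enumerate(design.days):
            prl = acc.growth_rate * day
            for ti, treatment in enumerate(design.treatments):
                eff = effects[treatment]
                m_cell = acc.m0 + design.stage_effect * (day - day0) + eff.delta_m
                truth_rows.append(
                    {
                        "accession": acc.name,
                        "day": day,
                        "treatment": treatment,
                        "m_true": m_cell * eff.tlrl_scale,
                        "b_true": acc.b0 * eff.tlrl_scale,
                        "prl": prl,
                    }
                )
                for rep in range(design.replicates):
                    rng = np.random.default_rng([design.seed, ai, di, ti, rep])
                    root = simulate_root(
                        m_cell,
                        acc.b0,
                        prl,
                        design.bz_fraction,
                        design.lam,
                        design.sigma,
                        rng,
                        pre_bz_fraction=design.pre_bz_fraction,
                        plant_id=f"{acc.name}_d{day}_{treatment or 'ctrl'}_r{rep + 1}",
                        accession=acc.name,
                        day=day,
                        treatment=treatment,
                    )
                    if eff.tlrl_scale != 1.0:
                        root = RootSystem(
                            root.plant_id,
                            root.accession,
                            root.day,
                            root.treatment,
                            root.pr_segments,
                            root.pr_tip,
                            tuple(length * eff.tlrl_scale for length in root.lr_lengths),
                        )
                    roots.append(root)
    return roots, pd.DataFrame(truth_rows)


__all__ = [
    "AccessionParams",
    "TreatmentEffect",
    "SimulationDesign",
    "simulate_root",
    "simulate_experiment",
]
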