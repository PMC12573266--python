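"""Seeded generator of synthetic plastic-leachate bioassay datasets.

Emulates two 72-h dark incubations of a heterotrophic protozoan at 20 °C
with dilution series of two leachates — BCP (beach-collected conventional
plastic) and BioP (a starch-based bioplastic) — in triplicate:

* leachate DOC scales linearly with dilution from the control level
  (~1 µg ml⁻¹) up to a per-plastic enrichment factor (5× BCP, 34× BioP);
* the protozoan growth rate follows a log-logistic dose-response rising
  from the control rate (0 d⁻¹) to a leachate-specific plateau
  (0.3 d⁻¹ BCP, 0.4 d⁻¹ BioP) at the undiluted leachate;
* the co-cultured bacteria grow from the inoculum (4.75×10⁵ cells ml⁻¹)
  towards a carrying capacity (≈1.29×10⁷ cells ml⁻¹ in the control) and are
  grazed down at high protozoan densities, giving the negative
  bacteria–protozoan association the downstream ordination expects.

Measurement noise is lognormal (counts are positive): CV 5 % on protozoan
counts (two technical measures averaged, as with Coulter duplicates), 3 % on
DOC and 20 % on bacterial counts.  Everything is driven by one
``numpy.random.Generator``, so a fixed seed reproduces the table
bit-for-bit.  The latent noise-free truths are returned alongside the data
for parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .budget import ENDPOINT_COLUMNS
from .stats import ll2

__all__ = [
    "ExperimentDesign",
    "SimulatedDataset",
    "exp1_design",
    "exp2_design",
    "true_growth_rate",
    "simulate_doc",
    "simulate_growth_endpoint",
    "simulate_bacteria",
    "generate",
]

LEACHATES = ("BCP", "BioP")


@dataclass(frozen=True)
class ExperimentDesign:
    """Design constants of one synthetic bioassay.

    Defaults reproduce the second (Coulter-counted) incubation: initial
    2000 cells ml⁻¹, dilutions 0/3.3/10/33/100 %, triplicates, 72 h at
    20 °C, ESD 13.8 ± 0.06 µm.
    """

    experiment_id: str = "exp2"
    dilutions: tuple[float, ...] = (0.0, 3.3, 10.0, 33.0, 100.0)
    replicates: int = 3
    c_initial: float = 2000.0
    duration: float = 3.0  # days (72 h)
    temperature: float = 20.0
    esd_mean: float = 13.8
    esd_sd: float = 0.06
    count_cv: float = 0.05
    doc_cv: float = 0.03
    bact_cv: float = 0.20
    bact_inoculum: float = 4.75e5
    bact_final_control: float = 1.29e7
    graze_half: float = 1.0e4  # protist density halving bacterial net growth
    doc_control: float = 1.0  # µg ml⁻¹
    doc_fold: dict[str, float] = field(
        default_factory=lambda: {"BCP": 5.0, "BioP": 34.0}
    )
    gr_control: float = 0.0
    gr_max: dict[str, float] = field(
        default_factory=lambda: {"BCP": 0.3, "BioP": 0.4}
    )
    gr_ec50: float = 30.0
    gr_slope: float = -1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if 0.0 not in self.dilutions:
            raise ValueError("dilutions must include the control (0)")
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates")
        for name in ("c_initial", "duration", "doc_control", "bact_inoculum"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")

    def with_overrides(self, **kwargs) -> "ExperimentDesign":
        return replace(self, **kwargs)

    def fold(self, treatment: str) -> float:
        try:
            return self.doc_fold[treatment]
        except KeyError:
            raise ValueError(f"unknown treatment {treatment!r}") from None


def exp1_design(seed: int = 0) -> ExperimentDesign:
    """The first (microscopy-counted) incubation: 400 cells ml⁻¹, 6-step series."""
    return ExperimentDesign(
        experiment_id="exp1",
        dilutions=(0.0, 6.25, 12.5, 25.0, 50.0, 100.0),
        c_initial=400.0,
        seed=seed,
    )


def exp2_design(seed: int = 0) -> ExperimentDesign:
    return ExperimentDesign(seed=seed)


@dataclass(frozen=True)
class SimulatedDataset:
    """Endpoint table plus the latent truths that generated it."""

    endpoints: pd.DataFrame
    latent: pd.DataFrame
    design: ExperimentDesign


# ---------------------------------------------------------------------------
# Latent (noise-free) condition means
# ---------------------------------------------------------------------------


def true_growth_rate(design: ExperimentDesign, treatment: str, dilution_pct: float) -> float:
    """Noise-free growth rate at a condition.

    Log-logistic in dilution with midpoint ``gr_ec50`` and slope
    ``gr_slope``, rescaled so the undiluted (100 %) leachate reaches the
    plateau ``gr_max`` exactly — the plateau is the observable the design is
    anchored to, while the LL.2 shape sets how fast the series approaches it.
    """
    if treatment == "control" or dilution_pct == 0:
        return design.gr_control
    gmax = design.gr_max.get(treatment)
    if gmax is None:
        raise ValueError(f"unknown treatment {treatment!r}")
    f = float(ll2(np.array([dilution_pct]), design.gr_slope, design.gr_ec50)[0])
    f_top = float(ll2(np.array([100.0]), design.gr_slope, design.gr_ec50)[0])
    return design.gr_control + (gmax - design.gr_control) * f / f_top


def _true_doc(design: ExperimentDesign, treatment: str, dilution_pct: float) -> float:
    if treatment == "control" or dilution_pct == 0:
        return design.doc_control
    fold = design.fold(treatment)
    return design.doc_control * (1.0 + (fold - 1.0) * dilution_pct / 100.0)


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Unit-median multiplicative noise with the given coefficient of variation."""
    if cv <= 0:
        return 1.0
    sigma = math.sqrt(math.log(1.0 + cv**2))
    return float(rng.lognormal(mean=0.0, sigma=sigma))


# ---------------------------------------------------------------------------
# Per-condition simulators
# ---------------------------------------------------------------------------


def simulate_doc(
    design: ExperimentDesign,
    treatment: str,
    dilution_pct: float,
    rng: np.random.Generator,
    noise: bool = True,
) -> float:
    """DOC (µg ml⁻¹) of one bottle: linear-in-dilution enrichment + 3 % CV."""
    mean = _true_doc(design, treatment, dilution_pct)
    return mean * (_lognormal_factor(rng, design.doc_cv) if noise else 1.0)


def simulate_growth_endpoint(
    design: ExperimentDesign,
    treatment: str,
    dilution_pct: float,
    rng: np.random.Generator,
    noise: bool = True,
) -> tuple[float, float, float]:
    """One replicate's (c_initial, c_final, esd).

    Exponential growth at the latent rate over the incubation; the final
    count is the mean of two technical measures, each with lognormal CV
    ``count_cv``.  ESD is drawn around the control mean with a small
    treatment shift in [−2 %, +5 %].
    """
    gr = true_growth_rate(design, treatment, dilution_pct)
    c_final_true = design.c_initial * math.exp(gr * design.duration)
    if noise:
        measures = [
            c_final_true * _lognormal_factor(rng, design.count_cv)
            for _ in range(2)
        ]
        c_final = float(np.mean(measures))
        shift = 1.0 + rng.uniform(-0.02, 0.05)
        esd = float(rng.normal(design.esd_mean * shift, design.esd_sd))
    else:
        c_final = c_final_true
        esd = design.esd_mean
    return design.c_initial, c_final, esd


def simulate_bacteria(
    design: ExperimentDesign,
    protist_final: float,
    doc: float,
    rng: np.random.Generator,
    noise: bool = True,
) -> tuple[float, float]:
    """Bacterial (n_initial, n_final) for one bottle.

    Net growth from the inoculum towards the control carrying capacity,
    suppressed by protozoan grazing: the gain is scaled by
    ``(1 + P_control/h)/(1 + P/h)`` with ``h = graze_half``, so the control
    lands on ``bact_final_control`` exactly and dense protozoan populations
    graze the bloom back towards the inoculum.
    """
    if protist_final < 0 or doc < 0:
        raise ValueError("protist_final and doc must be >= 0")
    gain = design.bact_final_control - design.bact_inoculum
    graze = (1.0 + design.c_initial / design.graze_half) / (
        1.0 + protist_final / design.graze_half
    )
    n_final = design.bact_inoculum + gain * graze
    if noise:
        n_final *= _lognormal_factor(rng, design.bact_cv)
    return design.bact_inoculum, float(n_final)


# ---------------------------------------------------------------------------
# Whole-experiment assembly
# ---------------------------------------------------------------------------


def generate(design: ExperimentDesign, noise: bool = True) -> SimulatedDataset:
    """Generate a full endpoint table for a design.

    Conditions are the control (dilution 0) plus every non-zero dilution of
    each leachate, in a fixed order, ``design.replicates`` bottles each;
    the RNG is seeded from ``design.seed`` so output is deterministic.
    """
    rng = np.random.default_rng(design.seed)
    conditions: list[tuple[str, float]] = [("control", 0.0)]
    for treatment in LEACHATES:
        for d in design.dilutions:
            if d > 0:
                conditions.append((treatment, d))

    rows = []
    latent_rows = []
    for treatment, dilution in conditions:
        latent_rows.append(
            {
                "treatment": treatment,
                "dilution_pct": dilution,
                "true_growth_rate": true_growth_rate(design, treatment, dilution),
                "true_doc_ug_ml": _true_doc(design, treatment, dilution),
            }
        )
        for rep in range(1, design.replicates + 1):
            doc = simulate_doc(design, treatment, dilution, rng, noise)
            c_init, c_final, esd = simulate_growth_endpoint(
                design, treatment, dilution, rng, noise
            )
            n_init, n_final = simulate_bacteria(design, c_final, doc, rng, noise)
            rows.append(
                {
                    "experiment_id": design.experiment_id,
                    "treatment": treatment,
                    "dilution_pct": dilution,
                    "replicate": rep,
                    "c_initial_cells_ml": c_init,
                    "c_final_cells_ml": c_final,
                    "esd_um": esd,
                    "duration_h": design.duration * 24.0,
                    "temperature_c": design.temperature,
                    "doc_ug_ml": doc,
                    "bact_initial_cells_ml": n_init,
                    "bact_final_cells_ml": n_final,
                }
            )
    endpoints = pd.DataFrame(rows, columns=ENDPOINT_COLUMNS + [
        "bact_initial_cells_ml", "bact_final_cells_ml"
    ])
    latent = pd.DataFrame(latent_rows)
    return SimulatedDataset(endpoints=endpoints, latent=latent, design=design)
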