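"""Endpoint carbon-flux budget for a heterotrophic protozoan bioassay.

Everything here works on a single dark-incubation endpoint: an initial and a
final cell concentration of the protozoan (*Oxyrrhis marina* in the motivating
experiments), a mean equivalent spherical diameter (ESD), the incubation time
and the initial dissolved organic carbon (DOC) of the medium.  From these the
module derives

* the specific growth rate ``GR = (ln C_f - ln C_i)/t``,
* per-cell carbon from biovolume (``0.123 pg C per µm³``),
* carbon fluxed into new biomass (``C_growth``) and respired
  (``C_respiration = R · C_mean · t`` with ``R = 0.355 d⁻¹`` at 20 °C),
* the carbon-specific assimilation rate
  ``C_assimilation = (C_growth + C_respiration) / (C_mean · t)``,
* the percentage of the DOC pool used (``PCU``),
* the satiating bacterivory ceiling ``I_max`` (71.3 bacteria cell⁻¹ h⁻¹ at
  20 fg C per bacterium, Q10-adjusted to the incubation temperature), and
* the fraction of assimilated carbon that cannot be explained by bacterivory
  and is therefore attributed to osmotrophy.

Units are µg C ml⁻¹ for concentrations (1 mg l⁻¹ ≡ 1 µg ml⁻¹), days for time,
µm for lengths.  All operations validate their domains and raise
:class:`BudgetDomainError` naming the offending field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd

__all__ = [
    "BudgetDomainError",
    "BudgetConstants",
    "ProtistPopulation",
    "BacterialEndpoint",
    "CarbonBudgetResult",
    "growth_rate",
    "esd_to_volume",
    "cell_carbon",
    "mean_biomass",
    "respiration",
    "assimilation",
    "pcu",
    "q10_adjust",
    "max_bacterivory",
    "osmotrophy_fraction",
    "bacterial_carbon_use",
    "full_budget",
    "budget_table",
    "summarize_budgets",
    "ENDPOINT_COLUMNS",
    "FG_TO_UG",
]

#: 1 femtogram expressed in micrograms.
FG_TO_UG = 1e-9

#: Required columns of a long-format endpoint table (one row per replicate).
ENDPOINT_COLUMNS = [
    "experiment_id",
    "treatment",
    "dilution_pct",
    "replicate",
    "c_initial_cells_ml",
    "c_final_cells_ml",
    "esd_um",
    "duration_h",
    "temperature_c",
    "doc_ug_ml",
]

#: Optional bacterial columns; when absent the bacterial outputs are omitted.
BACTERIAL_COLUMNS = ["bact_initial_cells_ml", "bact_final_cells_ml"]


class BudgetDomainError(ValueError):
    """An input is outside the domain of a budget operation."""


def _require(condition: bool, name: str, message: str) -> None:
    if not condition:
        raise BudgetDomainError(f"{name}: {message}")


@dataclass(frozen=True)
class BudgetConstants:
    """Fixed physiological and conversion constants of the budget.

    Parameters
    ----------
    cvol_factor : float
        Carbon-to-biovolume conversion, pg C per µm³.
    resp_rate_r : float
        Daily carbon-specific respiration rate at the incubation
        temperature (20 °C), d⁻¹.
    bact_carbon : float
        Carbon content per bacterial cell, fg C.
    imax_cells : float
        Satiating ingestion rate, bacteria per protist per hour, determined
        at ``imax_ref_temp``.
    q10 : float
        Factor by which metabolic rates change per 10 °C.
    imax_ref_temp : float
        Temperature (°C) at which ``imax_cells`` was measured; the ceiling
        is Q10-scaled from here to the incubation temperature.
    """

    cvol_factor: float = 0.123
    resp_rate_r: float = 0.355
    bact_carbon: float = 20.0
    imax_cells: float = 71.3
    q10: float = 2.0
    imax_ref_temp: float = 25.0

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "imax_ref_temp":
                continue
            value = getattr(self, f.name)
            _require(value > 0, f.name, "must be strictly positive")
        _require(self.q10 >= 1, "q10", "must be >= 1")

    def with_overrides(self, **kwargs: float) -> "BudgetConstants":
        """Return a copy with the given fields replaced (type-checked)."""
        known = {f.name for f in fields(self)}
        unknown = set(kwargs) - known
        if unknown:
            raise BudgetDomainError(
                f"constants: unknown field(s) {sorted(unknown)}"
            )
        return replace(self, **{k: float(v) for k, v in kwargs.items()})


@dataclass(frozen=True)
class ProtistPopulation:
    """One incubation endpoint of the protozoan population.

    ``c_initial``/``c_final`` in cells ml⁻¹, ``esd`` in µm, ``duration`` in
    days, ``temperature`` in °C.
    """

    c_initial: float
    c_final: float
    esd: float
    duration: float
    temperature: float = 20.0

    def __post_init__(self) -> None:
        _require(self.c_initial > 0, "c_initial", "must be > 0")
        _require(self.c_final >= 0, "c_final", "must be >= 0")
        _require(self.esd > 0, "esd", "must be > 0")
        _require(self.duration > 0, "duration", "must be > 0")


@dataclass(frozen=True)
class BacterialEndpoint:
    """Bacterial abundances bracketing the incubation plus the DOC pool."""

    n_initial: float
    n_final: float
    doc: float

    def __post_init__(self) -> None:
        _require(self.n_initial >= 0, "n_initial", "must be >= 0")
        _require(self.n_final >= 0, "n_final", "must be >= 0")
        _require(self.doc > 0, "doc", "must be > 0")


@dataclass(frozen=True)
class CarbonBudgetResult:
    """All derived fluxes for one endpoint.

    ``growth_rate`` d⁻¹; ``cell_carbon`` pg C cell⁻¹; ``b_initial``,
    ``b_final``, ``c_growth``, ``c_mean``, ``c_respiration`` µg C ml⁻¹;
    ``c_assimilation`` and ``i_max`` µg C (µg C)⁻¹ d⁻¹; ``pcu`` percent;
    ``osmotrophy_fraction`` dimensionless in [0, 1].
    """

    growth_rate: float
    cell_carbon: float
    b_initial: float
    b_final: float
    c_growth: float
    c_mean: float
    c_respiration: float
    c_assimilation: float
    pcu: float
    i_max: float
    osmotrophy_fraction: float
    bacterial_pcu: float | None = None


# ---------------------------------------------------------------------------
# Elementary operations, in the order the budget chains them.
# ---------------------------------------------------------------------------


def growth_rate(c_initial: float, c_final: float, duration: float) -> float:
    """Specific growth rate ``(ln c_final − ln c_initial)/duration`` in d⁻¹.

    Negative values (population decline) are returned as-is.
    """
    _require(c_initial > 0, "c_initial", "must be > 0 for a log ratio")
    _require(c_final > 0, "c_final", "must be > 0 for a log ratio")
    _require(duration > 0, "duration", "must be > 0")
    return (math.log(c_final) - math.log(c_initial)) / duration


def esd_to_volume(esd: float) -> float:
    """Biovolume (µm³) of the sphere with diameter ``esd`` (µm)."""
    _require(esd >= 0, "esd", "must be >= 0")
    return (math.pi / 6.0) * esd**3


def cell_carbon(volume: float, cvol_factor: float = 0.123) -> float:
    """Per-cell carbon (pg C) from biovolume via the C:vol factor."""
    _require(volume >= 0, "volume", "must be >= 0")
    _require(cvol_factor > 0, "cvol_factor", "must be > 0")
    return cvol_factor * volume


def mean_biomass(b_initial: float, b_final: float) -> float:
    """Arithmetic-mean carbon biomass over the incubation (µg C ml⁻¹)."""
    _require(b_initial >= 0, "b_initial", "must be >= 0")
    _require(b_final >= 0, "b_final", "must be >= 0")
    return 0.5 * (b_initial + b_final)


def respiration(r: float, c_mean: float, duration: float) -> float:
    """Total respiratory carbon loss ``R · C_mean · t`` (µg C ml⁻¹)."""
    _require(r >= 0, "r", "must be >= 0")
    _require(c_mean >= 0, "c_mean", "must be >= 0")
    _require(duration >= 0, "duration", "must be >= 0")
    return r * c_mean * duration


def assimilation(
    c_growth: float, c_respiration: float, c_mean: float, duration: float
) -> float:
    """Carbon-specific assimilation ``(C_growth + C_resp)/(C_mean · t)``.

    µg C per µg C of protozoan per day.  With zero net growth this reduces
    exactly to the specific respiration rate R.  Negative ``c_growth``
    (decline) is allowed and the result is reported unclamped.
    """
    _require(c_mean > 0, "c_mean", "must be > 0")
    _require(duration > 0, "duration", "must be > 0")
    return (c_growth + c_respiration) / (c_mean * duration)


def pcu(c_growth: float, c_respiration: float, doc: float) -> float:
    """Percentage of the DOC pool used: ``100·(C_growth + C_resp)/[DOC]``."""
    _require(doc > 0, "doc", "must be > 0")
    return 100.0 * (c_growth + c_respiration) / doc


def q10_adjust(rate: float, t_from: float, t_to: float, q10: float = 2.0) -> float:
    """Scale a rate from ``t_from`` to ``t_to`` (°C) with a Q10 law."""
    _require(rate >= 0, "rate", "must be >= 0")
    _require(q10 > 0, "q10", "must be > 0")
    return rate * q10 ** ((t_to - t_from) / 10.0)


def max_bacterivory(
    c_avg: float,
    c_mean: float,
    constants: BudgetConstants | None = None,
    temperature: float = 20.0,
) -> float:
    """Satiating carbon-specific bacterivory ceiling I_max.

    ``imax_cells × bact_carbon(µg) × c_avg × 24 / c_mean`` in
    µg C (µg C)⁻¹ d⁻¹, Q10-adjusted from ``constants.imax_ref_temp`` to the
    incubation ``temperature``.  ``c_avg`` is the mean protozoan cell
    concentration (cells ml⁻¹), ``c_mean`` the mean carbon biomass
    (µg C ml⁻¹).
    """
    constants = constants or BudgetConstants()
    _require(c_avg >= 0, "c_avg", "must be >= 0")
    _require(c_mean > 0, "c_mean", "must be > 0")
    raw = (
        constants.imax_cells
        * constants.bact_carbon
        * FG_TO_UG
        * c_avg
        * 24.0
        / c_mean
    )
    return q10_adjust(raw, constants.imax_ref_temp, temperature, constants.q10)


def osmotrophy_fraction(c_assimilation: float, i_max: float) -> float:
    """Fraction of assimilated carbon not attributable to bacterivory.

    ``1 − I_max/C_assimilation`` clamped to [0, 1]: when the bacterivory
    ceiling exceeds assimilation, bacterial grazing alone could explain the
    budget and the osmotrophic share is 0.
    """
    _require(c_assimilation > 0, "c_assimilation", "must be > 0")
    _require(i_max >= 0, "i_max", "must be >= 0")
    return min(1.0, max(0.0, 1.0 - i_max / c_assimilation))


def bacterial_carbon_use(
    endpoint: BacterialEndpoint, bact_carbon: float = 20.0
) -> float:
    """Percent of the DOC pool converted into net bacterial biomass.

    Net bacterial growth (floored at zero — a decline reports 0 %, not a
    negative use) times the per-cell carbon content, as a percentage of the
    initial DOC.
    """
    _require(bact_carbon > 0, "bact_carbon", "must be > 0")
    net = max(0.0, endpoint.n_final - endpoint.n_initial)
    return 100.0 * net * bact_carbon * FG_TO_UG / endpoint.doc


def full_budget(
    pop: ProtistPopulation,
    doc: float,
    constants: BudgetConstants | None = None,
    bacteria: BacterialEndpoint | None = None,
) -> CarbonBudgetResult:
    """Chain the whole carbon budget for one endpoint.

    Biomasses are per-cell carbon (from the ESD via sphere volume and the
    C:vol factor) times cell concentration; ``C_mean`` and the Eq.-5 cell
    average are arithmetic means of the initial and final states.
    """
    constants = constants or BudgetConstants()
    _require(doc > 0, "doc", "must be > 0")

    gr = growth_rate(pop.c_initial, pop.c_final, pop.duration)
    pg_per_cell = cell_carbon(esd_to_volume(pop.esd), constants.cvol_factor)
    ug_per_cell = pg_per_cell * 1e-6  # pg -> µg
    b_initial = pop.c_initial * ug_per_cell
    b_final = pop.c_final * ug_per_cell
    c_growth = b_final - b_initial
    c_mean = mean_biomass(b_initial, b_final)
    c_resp = respiration(constants.resp_rate_r, c_mean, pop.duration)
    c_assim = assimilation(c_growth, c_resp, c_mean, pop.duration)
    used_pct = pcu(c_growth, c_resp, doc)
    c_avg = 0.5 * (pop.c_initial + pop.c_final)
    i_max = max_bacterivory(c_avg, c_mean, constants, pop.temperature)
    osmo = osmotrophy_fraction(c_assim, i_max) if c_assim > 0 else float("nan")
    bact_pcu = (
        bacterial_carbon_use(bacteria, constants.bact_carbon)
        if bacteria is not None
        else None
    )
    return CarbonBudgetResult(
        growth_rate=gr,
        cell_carbon=pg_per_cell,
        b_initial=b_initial,
        b_final=b_final,
        c_growth=c_growth,
        c_mean=c_mean,
        c_respiration=c_resp,
        c_assimilation=c_assim,
        pcu=used_pct,
        i_max=i_max,
        osmotrophy_fraction=osmo,
        bacterial_pcu=bact_pcu,
    )


# ---------------------------------------------------------------------------
# Table-level interface
# ---------------------------------------------------------------------------

_RESULT_FIELDS = [
    "growth_rate",
    "cell_carbon",
    "b_initial",
    "b_final",
    "c_growth",
    "c_mean",
    "c_respiration",
    "c_assimilation",
    "pcu",
    "i_max",
    "osmotrophy_fraction",
]


def budget_table(
    endpoints: pd.DataFrame, constants: BudgetConstants | None = None
) -> pd.DataFrame:
    """Compute the full budget for every replicate row of an endpoint table.

    ``endpoints`` follows :data:`ENDPOINT_COLUMNS` (``duration_h`` in hours).
    Bacterial outputs are included only when both bacterial columns are
    present and non-null for a row.
    """
    constants = constants or BudgetConstants()
    missing = [c for c in ENDPOINT_COLUMNS if c not in endpoints.columns]
    if missing:
        raise BudgetDomainError(f"endpoints: missing column(s) {missing}")
    has_bacteria = all(c in endpoints.columns for c in BACTERIAL_COLUMNS)

    records = []
    for _, row in endpoints.iterrows():
        pop = ProtistPopulation(
            c_initial=float(row["c_initial_cells_ml"]),
            c_final=float(row["c_final_cells_ml"]),
            esd=float(row["esd_um"]),
            duration=float(row["duration_h"]) / 24.0,
            temperature=float(row["temperature_c"]),
        )
        bacteria = None
        if has_bacteria and not (
            pd.isna(row["bact_initial_cells_ml"])
            or pd.isna(row["bact_final_cells_ml"])
        ):
            bacteria = BacterialEndpoint(
                n_initial=float(row["bact_initial_cells_ml"]),
                n_final=float(row["bact_final_cells_ml"]),
                doc=float(row["doc_ug_ml"]),
            )
        result = full_budget(pop, float(row["doc_ug_ml"]), constants, bacteria)
        rec = {
            "experiment_id": row["experiment_id"],
            "treatment": row["treatment"],
            "dilution_pct": float(row["dilution_pct"]),
            "replicate": row["replicate"],
        }
        rec.update({f: getattr(result, f) for f in _RESULT_FIELDS})
        if result.bacterial_pcu is not None:
            rec["bacterial_pcu"] = result.bacterial_pcu
        records.append(rec)
    return pd.DataFrame.from_records(records)


def summarize_budgets(budgets: pd.DataFrame) -> pd.DataFrame:
    """Per-condition mean ± standard error of every derived flux.

    Aggregation is replicate-first: each flux is computed per replicate by
    :func:`budget_table` and only then averaged, so no Jensen bias enters
    through pooled cell counts.  SE uses the n−1 sample standard deviation
    over replicates.
    """
    value_cols = [c for c in budgets.columns if c in _RESULT_FIELDS + ["bacterial_pcu"]]
    grouped = budgets.groupby(["treatment", "dilution_pct"], sort=True)
    out = []
    for (treatment, dilution), g in grouped:
        rec = {"treatment": treatment, "dilution_pct": dilution, "n": len(g)}
        for col in value_cols:
            vals = g[col].to_numpy(dtype=float)
            rec[f"{col}_mean"] = float(np.mean(vals))
            rec[f"{col}_se"] = (
                float(np.std(vals, ddof=1) / math.sqrt(len(vals)))
                if len(vals) > 1
                else float("nan")
            )
        out.append(rec)
    return pd.DataFrame.from_records(out)
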