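"""Experimental design: stress treatments, schedules, and replication structure.

The experiment evolves barcoded yeast lineages for 50 days under constant or
daily-alternating chemical stress (salt or copper), expressed as fractions of
the ancestral lethal limit (20 g/l NaCl, 8 uM CuSO4).  A design instance is the
single source of truth for the simulator and all downstream bookkeeping:
how many treatments, populations, barcodes per population, assay replication,
and the dilution regime that sets generations per growth cycle.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

#: lethal limit concentration and unit per chemical stressor
LETHAL_LIMITS: dict[str, tuple[float, str]] = {
    "salt": (20.0, "g/l"),  # NaCl
    "copper": (8.0, "uM"),  # CuSO4
}

#: canonical treatment names -> stress-fraction schedule.
#: Single-element schedules are constant; two-element schedules alternate daily,
#: starting on the first-listed (lower) level on day 1.
STANDARD_SCHEDULES: dict[str, tuple[float, ...]] = {
    "EH0": (0.0,),
    "EH40": (0.4,),
    "EH80": (0.8,),
    "EH0_40": (0.0, 0.4),
    "EH20_60": (0.2, 0.6),
    "EH40_80": (0.4, 0.8),
    "EH0_80": (0.0, 0.8),
}


class DesignError(ValueError):
    """Invalid experimental-design configuration."""


@dataclass(frozen=True)
class TreatmentSpec:
    """One evolutionary-history treatment: a chemical and a stress schedule.

    Parameters
    ----------
    name
        Treatment label, e.g. ``"EH0_80"`` (Evolutionary History alternating
        0% and 80% of the lethal limit).
    chemical
        ``"salt"`` or ``"copper"``.
    schedule
        Stress fractions of the lethal limit.  One element = constant;
        two distinct elements = daily alternation starting with the first.
    lethal_limit
        Concentration lethal to the unevolved ancestor, in the chemical's
        native unit (g/l for salt, uM for copper).
    """

    name: str
    chemical: str
    schedule: tuple[float, ...]
    lethal_limit: float

    def __post_init__(self) -> None:
        if self.chemical not in LETHAL_LIMITS:
            raise DesignError(f"unknown chemical {self.chemical!r}")
        if len(self.schedule) not in (1, 2):
            raise DesignError(
                f"{self.name}: schedule must have 1 (constant) or 2 "
                f"(alternating) stress fractions, got {len(self.schedule)}"
            )
        for frac in self.schedule:
            if not 0.0 <= frac <= 1.0:
                raise DesignError(
                    f"{self.name}: stress fraction {frac} outside [0, 1]"
                )
        if len(self.schedule) == 2 and self.schedule[0] == self.schedule[1]:
            raise DesignError(
                f"{self.name}: alternating schedule needs two distinct fractions"
            )
        if self.lethal_limit <= 0:
            raise DesignError(f"{self.name}: lethal limit must be positive")

    @property
    def is_fluctuating(self) -> bool:
        return len(self.schedule) == 2

    @property
    def mean_fraction(self) -> float:
        """Time-averaged stress fraction over the schedule."""
        return float(np.mean(self.schedule))

    def time_fraction(self, stress_fraction: float) -> float:
        """Share of evolution days spent at ``stress_fraction`` (0, 0.5 or 1)."""
        matches = sum(1 for s in self.schedule if s == stress_fraction)
        return matches / len(self.schedule)


def standard_treatment(name: str, chemical: str) -> TreatmentSpec:
    """Build one of the named treatments (EH0 ... EH0_80) for a chemical."""
    if name not in STANDARD_SCHEDULES:
        raise DesignError(
            f"unknown treatment name {name!r}; "
            f"expected one of {sorted(STANDARD_SCHEDULES)}"
        )
    if chemical not in LETHAL_LIMITS:
        raise DesignError(f"unknown chemical {chemical!r}")
    return TreatmentSpec(
        name=name,
        chemical=chemical,
        schedule=STANDARD_SCHEDULES[name],
        lethal_limit=LETHAL_LIMITS[chemical][0],
    )


def stress_series(treatment: TreatmentSpec, days: int) -> np.ndarray:
    """Daily stress concentrations for a treatment, in its native unit.

    Constant schedules repeat one concentration; alternating schedules produce
    a period-2 series starting with the first-listed fraction on day 1.
    """
    if days < 1:
        raise DesignError(f"days must be >= 1, got {days}")
    levels = np.asarray(treatment.schedule, dtype=float) * treatment.lethal_limit
    reps = int(np.ceil(days / len(levels)))
    return np.tile(levels, reps)[:days]


@dataclass(frozen=True)
class ExperimentalDesign:
    """Full replication structure of the evolution and fitness-assay experiment.

    Derived quantities (lineage count, generations per cycle) are computed,
    not stored, so a design cannot drift out of internal consistency.
    """

    treatments: tuple[TreatmentSpec, ...]
    populations_per_treatment: int = 16
    barcodes_per_population: int = 2
    days: int = 50
    dilution_factor: float = 1000.0
    assay_replicates: int = 4
    initial_measure_replicates: int = 5
    reference_spike_fraction: float = 0.70
    plates_per_chemical: int = 2
    assay_fractions: tuple[float, ...] = (0.0, 0.4, 0.8)

    def __post_init__(self) -> None:
        if not self.treatments:
            raise DesignError("design needs at least one treatment")
        names = [(t.chemical, t.name) for t in self.treatments]
        if len(set(names)) != len(names):
            raise DesignError("duplicate (chemical, treatment) pairs")
        for attr in (
            "populations_per_treatment",
            "barcodes_per_population",
            "days",
            "assay_replicates",
            "initial_measure_replicates",
            "plates_per_chemical",
        ):
            if getattr(self, attr) < 1:
                raise DesignError(f"{attr} must be a positive count")
        if self.dilution_factor <= 1:
            raise DesignError("dilution_factor must exceed 1")
        if not 0.0 < self.reference_spike_fraction < 1.0:
            raise DesignError("reference_spike_fraction must lie in (0, 1)")
        if self.populations_per_treatment % self.plates_per_chemical:
            raise DesignError(
                "populations_per_treatment must divide evenly across plates"
            )
        # every chemical must carry the same treatment-name set: the ancestral
        # plate layout is copied onto all plates
        by_chem: dict[str, set[str]] = {}
        for t in self.treatments:
            by_chem.setdefault(t.chemical, set()).add(t.name)
        name_sets = {frozenset(v) for v in by_chem.values()}
        if len(name_sets) != 1:
            raise DesignError("all chemicals must share one treatment-name set")

    # ------------------------------------------------------------------ derived

    @property
    def generations_per_cycle(self) -> float:
        """Doublings per daily growth cycle implied by the dilution factor."""
        return math.log2(self.dilution_factor)

    @property
    def chemicals(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for t in self.treatments:
            seen.setdefault(t.chemical, None)
        return tuple(seen)

    @property
    def treatment_names(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for t in self.treatments:
            seen.setdefault(t.name, None)
        return tuple(seen)

    @property
    def n_lineages(self) -> int:
        return (
            len(self.treatments)
            * self.populations_per_treatment
            * self.barcodes_per_population
        )

    @property
    def n_populations(self) -> int:
        return len(self.treatments) * self.populations_per_treatment

    @property
    def populations_per_plate(self) -> int:
        return self.populations_per_treatment // self.plates_per_chemical

    @property
    def barcodes_per_plate(self) -> int:
        """Distinct non-reference barcodes on one plate (= in the shared layout)."""
        return (
            len(self.treatment_names)
            * self.populations_per_plate
            * self.barcodes_per_population
        )

    def treatment(self, chemical: str, name: str) -> TreatmentSpec:
        for t in self.treatments:
            if t.chemical == chemical and t.name == name:
                return t
        raise DesignError(f"no treatment {name!r} for chemical {chemical!r}")

    # -------------------------------------------------------------- serialization

    def to_dict(self) -> dict:
        return {
            "treatments": [
                {
                    "name": t.name,
                    "chemical": t.chemical,
                    "schedule": list(t.schedule),
                    "lethal_limit": t.lethal_limit,
                }
                for t in self.treatments
            ],
            "populations_per_treatment": self.populations_per_treatment,
            "barcodes_per_population": self.barcodes_per_population,
            "days": self.days,
            "dilution_factor": self.dilution_factor,
            "assay_replicates": self.assay_replicates,
            "initial_measure_replicates": self.initial_measure_replicates,
            "reference_spike_fraction": self.reference_spike_fraction,
            "plates_per_chemical": self.plates_per_chemical,
            "assay_fractions": list(self.assay_fractions),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def build_design(config: Mapping) -> ExperimentalDesign:
    """Validate a design description and return an :class:`ExperimentalDesign`.

    ``config`` accepts either explicit treatment dicts
    (``{"name", "chemical", "schedule", "lethal_limit"}``) under
    ``"treatments"``, or the shorthand ``"treatments": [names...]`` plus
    ``"chemicals": [chemicals...]`` which crosses standard treatments with
    chemicals.  Remaining keys override the replication defaults.
    """
    config = dict(config)
    raw_treatments = config.pop("treatments", None)
    chemicals = config.pop("chemicals", None)
    if not raw_treatments:
        raise DesignError("config must name at least one treatment")

    treatments: list[TreatmentSpec] = []
    for item in raw_treatments:
        if isinstance(item, str):
            for chem in chemicals or ["salt"]:
                treatments.append(standard_treatment(item, chem))
        else:
            item = dict(item)
            if "schedule" in item:
                treatments.append(
                    TreatmentSpec(
                        name=item["name"],
                        chemical=item["chemical"],
                        schedule=tuple(item["schedule"]),
                        lethal_limit=item.get(
                            "lethal_limit", LETHAL_LIMITS[item["chemical"]][0]
                        ),
                    )
                )
            else:
                treatments.append(standard_treatment(item["name"], item["chemical"]))

    kwargs = {}
    for key in (
        "populations_per_treatment",
        "barcodes_per_population",
        "days",
        "dilution_factor",
        "assay_replicates",
        "initial_measure_replicates",
        "reference_spike_fraction",
        "plates_per_chemical",
    ):
        if key in config:
            kwargs[key] = config.pop(key)
    if "assay_fractions" in config:
        kwargs["assay_fractions"] = tuple(config.pop("assay_fractions"))
    return ExperimentalDesign(treatments=tuple(treatments), **kwargs)


def full_design(**overrides) -> ExperimentalDesign:
    """The complete study layout: 7 treatments x 2 chemicals x 16 populations
    x 2 barcodes, 50 days at 1:1000 daily dilution."""
    cfg: dict = {
        "treatments": list(STANDARD_SCHEDULES),
        "chemicals": ["salt", "copper"],
    }
    cfg.update(overrides)
    return build_design(cfg)
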