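"""Complex-presence rules and dataset-wide co-occurrence checks.

Complex presence is defined operationally by the diagnostic scaffold subunits:
RAPTOR implies TORC1 and RICTOR (with or without SIN1) implies TORC2, with TOR
and LST8 shared between the complexes.  Empirically, SIN1 is never found
without RICTOR, and RAPTOR and/or RICTOR are always accompanied by both TOR and
LST8; species violating these co-occurrence constraints are reported (and the
SIN1-without-RICTOR pattern flagged for re-examination) but keep their
rule-derived calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .homology_calling import COMPONENTS

#: tiers that count as a detection (read-rescued P included)
PRESENT_TIERS = frozenset({"H", "M", "L", "P"})

ARCHITECTURES = ("both", "TORC1_only", "TORC2_only", "neither")

RULES = (
    "SIN1_without_RICTOR",
    "RAPTOR_or_RICTOR_without_TOR",
    "RAPTOR_or_RICTOR_without_LST8",
)


@dataclass(frozen=True)
class ComplexCall:
    species: str
    torc1: bool
    torc2: bool
    architecture: str
    tiers: Mapping[str, str]


@dataclass(frozen=True)
class Violation:
    species: str
    rule: str
    components: tuple[str, ...]


@dataclass(frozen=True)
class ConsistencyReport:
    violations: tuple[Violation, ...]
    reexamine: tuple[str, ...] = ()  # species with SIN1 but no RICTOR

    def __bool__(self) -> bool:
        return not self.violations


def call_complexes(tiers: Mapping[str, str], species: str = "") -> ComplexCall:
    """Derive TORC1/TORC2 presence and architecture class from component tiers.

    Pure function of the five tiers: TORC1 iff RAPTOR detected, TORC2 iff
    RICTOR detected; SIN1 never affects the TORC2 call.
    """
    missing = [c for c in COMPONENTS if c not in tiers]
    if missing:
        raise KeyError(f"missing component tiers: {missing}")
    torc1 = tiers["RAPTOR"] in PRESENT_TIERS
    torc2 = tiers["RICTOR"] in PRESENT_TIERS
    if torc1 and torc2:
        arch = "both"
    elif torc1:
        arch = "TORC1_only"
    elif torc2:
        arch = "TORC2_only"
    else:
        arch = "neither"
    return ComplexCall(species, torc1, torc2, arch, dict(tiers))


def check_consistency(matrix: pd.DataFrame) -> ConsistencyReport:
    """Check every species against the three co-occurrence rules.

    ``matrix`` is a species x component tier frame.  The pipeline continues on
    violations; they are reported, and SIN1-without-RICTOR species are
    additionally listed for re-examination.
    """
    violations: list[Violation] = []
    reexamine: list[str] = []
    for species, row in matrix.iterrows():
        present = {c for c in COMPONENTS if row[c] in PRESENT_TIERS}
        scaffold = present.intersection({"RAPTOR", "RICTOR"})
        if "SIN1" in present and "RICTOR" not in present:
            violations.append(Violation(species, RULES[0], ("SIN1", "RICTOR")))
            reexamine.append(species)
        if scaffold and "TOR" not in present:
            violations.append(
                Violation(species, RULES[1], tuple(sorted(scaffold)) + ("TOR",))
            )
        if scaffold and "LST8" not in present:
            violations.append(
                Violation(species, RULES[2], tuple(sorted(scaffold)) + ("LST8",))
            )
    return ConsistencyReport(tuple(violations), tuple(reexamine))


def complex_table(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-species complex calls as a DataFrame (species, torc1, torc2, architecture)."""
    rows = []
    for species, row in matrix.iterrows():
        call = call_complexes(row.to_dict(), species)
        rows.append(
            {
                "species": species,
                "torc1": call.torc1,
                "torc2": call.torc2,
                "architecture": call.architecture,
            }
        )
    return pd.DataFrame(rows, columns=["species", "torc1", "torc2", "architecture"]).set_index(
        "species"
    )


def violations_table(report: ConsistencyReport) -> pd.DataFrame:
    rows = [
        {"species": v.species, "rule": v.rule, "components": ";".join(v.components)}
        for v in report.violations
    ]
    return pd.DataFrame(rows, columns=["species", "rule", "components"])
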