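"""Clade-level and architecture-level composition summaries.

Joins trophic-strategy labels to per-species complex calls and produces
row-normalised proportion tables: architecture-class composition per clade,
and strategy composition per architecture class (plus its transpose).  No
formal association statistic is computed — the summaries are proportions.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .complex_inference import ARCHITECTURES

STRATEGY_CATEGORIES = (
    "autotroph",
    "mixotroph",
    "heterotroph",
    "parasite_intracellular",
    "parasite_extracellular",
    "endosymbiont",
    "unknown",
)


def _proportions(labels: pd.Series, groups: pd.Series, categories) -> pd.DataFrame:
    counts = pd.crosstab(groups, labels).reindex(columns=list(categories), fill_value=0)
    counts = counts.loc[counts.sum(axis=1) > 0]
    out = counts.div(counts.sum(axis=1), axis=0)
    out["n"] = counts.sum(axis=1)
    return out


def architecture_proportions(
    complexes: pd.DataFrame, clade_map: Mapping[str, str]
) -> pd.DataFrame:
    """Per clade, the fraction of species in each architecture class.

    ``complexes`` must have an ``architecture`` column indexed by species.
    Every species needs a clade; clades with zero species are rejected.
    """
    clades = pd.Series({sp: clade_map.get(sp) for sp in complexes.index}, name="clade")
    if clades.isna().any():
        missing = clades[clades.isna()].index.tolist()
        raise ValueError(f"species without a clade: {missing[:5]}")
    if len(set(clade_map.values())) != clades.nunique():
        empty = set(clade_map.values()) - set(clades)
        raise ValueError(f"clades with zero species: {sorted(empty)}")
    table = _proportions(complexes["architecture"], clades, ARCHITECTURES)
    _check(table)
    return table


def strategy_by_architecture(
    complexes: pd.DataFrame, trophic: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Strategy composition per architecture class, and the transpose.

    Species missing from ``trophic`` are reported under ``unknown``.
    """
    strategies = trophic["strategy"].reindex(complexes.index).fillna("unknown")
    arch = complexes["architecture"]
    by_arch = _proportions(strategies, arch, STRATEGY_CATEGORIES)
    by_strategy = _proportions(arch, strategies, ARCHITECTURES)
    _check(by_arch)
    _check(by_strategy)
    return by_arch, by_strategy


def _check(table: pd.DataFrame) -> None:
    # row proportions sum to 1 and counts are conserved, on every output
    props = table.drop(columns="n")
    if not ((props.sum(axis=1) - 1.0).abs() < 1e-9).all():
        raise AssertionError("summary rows do not sum to 1")
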