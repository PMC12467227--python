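"""Bit-score tiers and the contamination screen.

Detections are graded on the effective bit score — the maximum of the overall
and best-domain scores — using fixed bands: scores below 100 bits are not
considered (ABS), [100, 150) is a low-confidence hit (L, typically truncated or
incomplete models), [150, 300) a medium hit (M), and >= 300 a high-confidence
hit (H).  Band boundaries are half-open so every score maps to exactly one
tier.  A fifth tier, P ("probable"), is reserved for presences recovered from
short-read data by the rescue stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import pandas as pd

from .profile_search import ProfileModel, SearchHit, domain_coverage

TIERS = ("H", "M", "L", "P", "ABS")
COMPONENTS = ("TOR", "LST8", "RAPTOR", "RICTOR", "SIN1")


@dataclass(frozen=True)
class RubricConfig:
    """Half-open bit-score bands: [absent_below, low_max) -> L, etc."""

    absent_below: float = 100.0
    low_max: float = 150.0
    medium_max: float = 300.0

    def __post_init__(self) -> None:
        if not (0 < self.absent_below < self.low_max < self.medium_max):
            raise ValueError("rubric bands must be increasing and positive")


@dataclass(frozen=True)
class TierCall:
    species: str
    component: str
    tier: str
    effective_bits: float | None = None
    source: str = "proteome"  # or "read_rescue"
    sequence_id: str = ""
    coverage: float = float("nan")
    flags: frozenset = field(default_factory=frozenset)

    def with_flags(self, *new_flags: str, tier: str | None = None) -> "TierCall":
        return replace(
            self,
            tier=self.tier if tier is None else tier,
            flags=self.flags.union(new_flags),
        )


def effective_score(hit: SearchHit) -> float:
    """Max of overall and best-domain bit scores — the score the rubric grades."""
    scores = [s for s in (hit.overall_bits, hit.best_domain_bits) if s is not None]
    if not scores:
        raise ValueError(f"hit {hit.sequence_id!r} has no computed scores")
    return max(scores)


def assign_tier(bits: float | None, rubric: RubricConfig = RubricConfig()) -> str:
    """Map a bit score to H/M/L/ABS; ``None`` means no hit at all (ABS)."""
    if bits is None:
        return "ABS"
    if math.isnan(bits) or bits < 0:
        raise ValueError(f"invalid bit score: {bits}")
    if bits < rubric.absent_below:
        return "ABS"
    if bits < rubric.low_max:
        return "L"
    if bits < rubric.medium_max:
        return "M"
    return "H"


def best_hit_per_component(
    hits: Iterable[SearchHit],
    species: str,
    rubric: RubricConfig = RubricConfig(),
    profiles: Mapping[str, ProfileModel] | None = None,
    components: Iterable[str] = COMPONENTS,
) -> dict[str, TierCall]:
    """One TierCall per component for one species.

    Among a component's hits the one maximising the effective score is kept;
    ties break on higher domain coverage, then lexicographically smallest
    sequence id.  Components with no hit get an explicit ABS call, so the
    output always has exactly one call per component.
    """
    by_comp: dict[str, list[SearchHit]] = {}
    for h in hits:
        by_comp.setdefault(h.component, []).append(h)

    calls: dict[str, TierCall] = {}
    for comp in components:
        best: SearchHit | None = None
        best_key: tuple | None = None
        cov_known = profiles is not None and comp in profiles
        for h in by_comp.get(comp, ()):
            cov = domain_coverage(h, profiles[comp])[0] if cov_known else 0.0
            key = (effective_score(h), cov, _NegStr(h.sequence_id))
            if best_key is None or key > best_key:
                best, best_key = h, key
        if best is None:
            calls[comp] = TierCall(species, comp, "ABS", None)
        else:
            bits = effective_score(best)
            # coverage is unknown (NaN) when no profile is available, so the
            # contamination screen cannot demote on a score it never computed
            cov = best_key[1] if cov_known else float("nan")
            calls[comp] = TierCall(
                species,
                comp,
                assign_tier(bits, rubric),
                bits,
                sequence_id=best.sequence_id,
                coverage=cov,
            )
    return calls


class _NegStr(str):
    """Orders lexicographically smallest-first inside a max comparison."""

    def __lt__(self, other):  # reversed
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def flag_contaminant(
    call: TierCall,
    alone_in_clade: bool,
    coverage_pass: bool,
    identity_favors_out_clade: bool = False,
) -> TierCall:
    """Screen a positive call that contradicts its clade.

    A hit in a clade where every other member lacks the component is demoted to
    ABS (keeping a ``contaminant`` flag for reporting) when its domain coverage
    fails or its identity profile points outside the clade — the pattern seen
    for misannotated or contaminant (e.g. fungal) proteins.  A clade-discordant
    hit that passes both checks is retained and flagged ``outlier_checked`` so
    genuine outliers are never silently deleted.  Never upgrades a tier.
    """
    if call.tier == "ABS" or not alone_in_clade:
        return call
    if not coverage_pass or identity_favors_out_clade:
        return call.with_flags("contaminant", tier="ABS")
    return call.with_flags("outlier_checked")


def screen_contaminants(
    calls: Mapping[str, Mapping[str, TierCall]],
    clade_map: Mapping[str, str],
    min_coverage: float = 0.25,
) -> dict[str, dict[str, TierCall]]:
    """Apply the contamination screen across a full call matrix.

    ``alone_in_clade`` is computed from the matrix itself: a positive call
    whose clade has at least two other members, all ABS for that component.
    Coverage comes from each call's stored domain coverage.
    """
    out: dict[str, dict[str, TierCall]] = {}
    for species, comp_calls in calls.items():
        clade = clade_map.get(species)
        out[species] = {}
        for comp, call in comp_calls.items():
            others = [
                calls[s][comp].tier
                for s in calls
                if s != species and clade_map.get(s) == clade
            ]
            alone = len(others) >= 2 and all(t == "ABS" for t in others)
            cov_pass = not (call.coverage == call.coverage) or call.coverage >= min_coverage
            out[species][comp] = flag_contaminant(call, alone, cov_pass)
    return out


def calls_to_matrix(calls: Mapping[str, Mapping[str, TierCall]]) -> pd.DataFrame:
    """Species x component tier matrix (values H/M/L/P/ABS)."""
    rows = {
        sp: {comp: c.tier for comp, c in comp_calls.items()}
        for sp, comp_calls in calls.items()
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df = df.reindex(columns=list(COMPONENTS))
    df.index.name = "species"
    return df.sort_index()


def flags_table(calls: Mapping[str, Mapping[str, TierCall]]) -> pd.DataFrame:
    rows = [
        {
            "species": sp,
            "component": comp,
            "tier": c.tier,
            "effective_bits": c.effective_bits,
            "source": c.source,
            "flags": ";".join(sorted(c.flags)),
        }
        for sp, comp_calls in sorted(calls.items())
        for comp, c in comp_calls.items()
        if c.flags
    ]
    return pd.DataFrame(
        rows, columns=["species", "component", "tier", "effective_bits", "source", "flags"]
    )
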