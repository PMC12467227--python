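"""Phylogenetic-outlier detection and short-read rescue.

A component called absent in a species whose close relatives all retain it is a
phylogenetic outlier; when that species' proteome is also of low completeness
(BUSCO-style score), the absence is more plausibly an annotation gap than a
real loss.  For such candidates, translated short-read peptide fragments are
aligned to the component reference and accepted under fixed criteria
(E-value <= 1e-10 and bit score > 50 with the alignment overlapping a known
domain region; for matches shorter than 10 residues — the protein-level
equivalent of a 30-nucleotide match, where E-values are unreliable — a ~70%
identity requirement replaces the score gates).  Enough distinct accepted
matches upgrade the call from ABS to the "probable" tier P; rescue never
touches H/M/L calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Mapping, Sequence

import pandas as pd

from .homology_calling import TierCall
from .loss_inference import TaxonTree
from .profile_search import ProfileModel, score_sequence

PRESENT_TIERS_STRICT = frozenset({"H", "M", "L"})


@dataclass(frozen=True)
class RescueConfig:
    evalue_max: float = 1e-10
    bits_min: float = 50.0
    short_match_len: int = 10  # residues; protein-level twin of 30 nt
    short_match_identity_min: float = 0.70
    min_accepted_matches: int = 2
    busco_low_threshold: float = 0.70
    relative_radius: int = 3  # tree edges defining "close relatives"

    def __post_init__(self) -> None:
        if not (0 < self.short_match_identity_min <= 1):
            raise ValueError("short_match_identity_min must be in (0, 1]")
        if self.bits_min <= 0:
            raise ValueError("bits_min must be positive")


@dataclass(frozen=True)
class ReadMatch:
    fragment_id: str
    component: str
    bits: float
    evalue: float
    align_len: int
    percent_identity: float
    reference_interval: tuple[int, int]  # half-open, on the component reference
    overlaps_domain: bool


def flag_outliers(
    matrix: pd.DataFrame,
    tree: TaxonTree,
    completeness: Mapping[str, float],
    config: RescueConfig = RescueConfig(),
    clade_map: Mapping[str, str] | None = None,
) -> list[tuple[str, str]]:
    """List (species, component) rescue candidates.

    A candidate is an ABS call in a low-completeness species whose neighbours
    (tips within ``relative_radius`` edges) majority-retain the component; an
    ABS call in a clade otherwise uniformly present qualifies regardless of
    radius.  Clade-consistent absences — the internal validation the presence
    clusters provide — are never candidates, nor are absences in
    high-completeness proteomes.
    """
    tips = set(tree.tip_labels)
    missing = set(matrix.index).difference(tips)
    if missing:
        raise ValueError(f"species not in tree: {sorted(missing)[:5]}")

    candidates: list[tuple[str, str]] = []
    for species, row in matrix.iterrows():
        if completeness.get(species, 1.0) >= config.busco_low_threshold:
            continue
        neighbors = [t for t in tree.tips_within(species, config.relative_radius) if t in matrix.index]
        for comp in matrix.columns:
            if row[comp] != "ABS":
                continue
            near = [matrix.at[t, comp] in PRESENT_TIERS_STRICT for t in neighbors]
            if near and sum(near) * 2 >= len(near) and any(near):
                candidates.append((species, comp))
                continue
            if clade_map is not None:
                clade = clade_map.get(species)
                others = [
                    matrix.at[s, comp]
                    for s in matrix.index
                    if s != species and clade_map.get(s) == clade
                ]
                if others and all(t in PRESENT_TIERS_STRICT for t in others):
                    candidates.append((species, comp))
    return candidates


def classify_read_match(
    match: ReadMatch, config: RescueConfig = RescueConfig()
) -> tuple[bool, str]:
    """Accept or reject one read match; returns (accepted, reason).

    Long matches need E-value and bit-score support plus overlap with a known
    domain region; short matches (< ``short_match_len`` residues) swap the
    score gates for a percent-identity floor, since E-values and bit scores are
    unreliable at that length.
    """
    if match.align_len < config.short_match_len:
        if match.percent_identity < config.short_match_identity_min:
            return False, "short_match_identity"
        if not match.overlaps_domain:
            return False, "no_domain_overlap"
        return True, "ok_short"
    if match.evalue > config.evalue_max:
        return False, "evalue"
    if match.bits <= config.bits_min:
        return False, "bits"
    if not match.overlaps_domain:
        return False, "no_domain_overlap"
    return True, "ok"


def match_fragment(
    fragment_id: str,
    fragment: str,
    profile: ProfileModel,
    config: RescueConfig = RescueConfig(),
) -> ReadMatch:
    """Align one peptide fragment to the component reference profile.

    The best local alignment supplies the bit score, aligned length, identity
    and reference interval; the E-value is the Karlin–Altschul expectation
    ``m * n * 2^-bits`` with K = 1 (conservative; the rubric's 50-bit gate
    dominates in practice).

    The short-match identity rule is for short *reads*: when the fragment is at
    least ``short_match_len`` residues long, its reported match length is
    floored at ``short_match_len`` so the E-value/bit-score gates apply.  A
    local aligner will otherwise extract a few-residue perfect-identity snippet
    from any random fragment, which must not qualify under the identity rule.
    """
    hit = score_sequence(profile, fragment, sequence_id=fragment_id, domain_floor=0.0)
    if hit.domains:
        d = hit.domains[0]
        interval = (d.prof_start, d.prof_end)
        align_len = d.prof_end - d.prof_start
        if len(fragment) >= config.short_match_len:
            align_len = max(align_len, config.short_match_len)
        pid = d.percent_identity
        bits = d.bits
    else:
        interval = (0, 0)
        align_len = 0
        pid = 0.0
        bits = hit.best_domain_bits
    overlaps = any(
        s < interval[1] and interval[0] < e for s, e in profile.domain_regions
    )
    evalue = profile.length * max(len(fragment), 1) * 2.0 ** (-bits)
    return ReadMatch(
        fragment_id=fragment_id,
        component=profile.component,
        bits=bits,
        evalue=evalue,
        align_len=align_len,
        percent_identity=pid,
        reference_interval=interval,
        overlaps_domain=overlaps and align_len > 0,
    )


def rescue_component(
    fragments: Sequence[tuple[str, str]],
    profile: ProfileModel,
    species: str,
    config: RescueConfig = RescueConfig(),
) -> TierCall:
    """Attempt rescue of one (species, component) candidate from fragments.

    The call becomes P when at least ``min_accepted_matches`` fragments are
    accepted with non-identical reference intervals (distinct evidence);
    otherwise ABS is retained.  No fragments at all yields ABS with a
    ``no_reads`` flag — absence calls must survive when nothing supports them.
    """
    comp = profile.component
    if not fragments:
        return TierCall(species, comp, "ABS", None, source="read_rescue", flags=frozenset({"no_reads"}))
    accepted: list[ReadMatch] = []
    for frag_id, frag in fragments:
        m = match_fragment(frag_id, frag, profile, config)
        ok, _ = classify_read_match(m, config)
        if ok:
            accepted.append(m)
    intervals = {m.reference_interval for m in accepted}
    distinct_ok = config.min_accepted_matches <= 1 or len(intervals) >= 2
    if len(accepted) >= config.min_accepted_matches and distinct_ok:
        bits = max(m.bits for m in accepted)
        return TierCall(
            species,
            comp,
            "P",
            bits,
            source="read_rescue",
            flags=frozenset({f"accepted_matches:{len(accepted)}"}),
        )
    return TierCall(species, comp, "ABS", None, source="read_rescue")


def run_rescue(
    matrix: pd.DataFrame,
    tree: TaxonTree,
    completeness: Mapping[str, float],
    reads: Mapping[str, Sequence[tuple[str, str]]],
    profiles: Mapping[str, ProfileModel],
    config: RescueConfig = RescueConfig(),
    clade_map: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag outliers, attempt rescue, and return (updated matrix, report).

    Only ABS cells can change, and only to P.
    """
    candidates = flag_outliers(matrix, tree, completeness, config, clade_map)
    updated = matrix.copy()
    rows = []
    for species, comp in candidates:
        frags = reads.get(species, ())
        call = rescue_component(frags, profiles[comp], species, config)
        if call.tier == "P":
            updated.at[species, comp] = "P"
        n_acc = next(
            (int(f.split(":")[1]) for f in call.flags if f.startswith("accepted_matches")),
            0,
        )
        rows.append(
            {
                "species": species,
                "component": comp,
                "n_fragments": len(frags),
                "n_accepted": n_acc,
                "outcome": call.tier,
            }
        )
    report = pd.DataFrame(
        rows, columns=["species", "component", "n_fragments", "n_accepted", "outcome"]
    )
    return updated, report


def parse_diamond_tab(stream: IO[str] | Iterable[str], profile: ProfileModel) -> list[ReadMatch]:
    """Parse DIAMOND tabular output for real runs.

    Expected columns: qseqid sseqid pident length evalue bitscore sstart send
    (identity in percent, subject coordinates 1-based inclusive on the
    component reference).
    """
    matches = []
    for lineno, line in enumerate(stream, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split()
        if len(f) < 8:
            raise ValueError(f"diamond line {lineno}: expected 8 fields, got {len(f)}")
        try:
            sstart, send = int(f[6]), int(f[7])
            lo, hi = min(sstart, send) - 1, max(sstart, send)
            interval = (lo, hi)
            overlaps = any(s < hi and lo < e for s, e in profile.domain_regions)
            matches.append(
                ReadMatch(
                    fragment_id=f[0],
                    component=profile.component,
                    bits=float(f[5]),
                    evalue=float(f[4]),
                    align_len=int(f[3]),
                    percent_identity=float(f[2]) / 100.0,
                    reference_interval=interval,
                    overlaps_domain=overlaps,
                )
            )
        except ValueError as exc:
            raise ValueError(f"diamond line {lineno}: {exc}") from exc
    return matches
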