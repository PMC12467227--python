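"""Synthetic inputs with the statistical structure the analysis assumes.

The generator emulates the whole data regime end-to-end: a clade-structured,
multifurcating taxonomy tree; irreversible component losses planted on its
edges (a Dollo process: a loss suppresses further losses below it); reference
alignments per component family from which profiles are built; proteomes
containing diverged homologs of the truly-present components among background
decoys, degraded by incomplete retention and fragmentation (mimicking
low-completeness assemblies); translated short-read peptide fragments; and
trophic-strategy labels correlated with TORC2 retention.  Everything is
bit-reproducible from ``SimConfig.seed``.

Planted loss configurations are constrained to be *identifiable*: a sampled
edge set is resampled until it equals the minimum-loss Dollo reconstruction of
the tip states it implies.  Non-identifiable configurations (e.g. two sibling
subtrees independently losing everything, indistinguishable from one older
loss) would make exact recovery impossible for any method; see docs/methods.md.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .loss_inference import ABSENT, PRESENT, TaxonTree, dollo_reconstruct
from .profile_search import AMINO_ACIDS, ProfileModel, build_profile

COMPONENTS = ("TOR", "LST8", "RAPTOR", "RICTOR", "SIN1")

#: reference family lengths (match columns); rank-ordered like the real
#: proteins (TOR kinase largest, the WD40 protein LST8 smallest) but scaled
#: down for fast simulation
COMPONENT_LENGTHS = {"TOR": 160, "LST8": 100, "RAPTOR": 130, "RICTOR": 140, "SIN1": 110}

#: components whose losses are planted independently; TOR/LST8 retention is
#: constrained by the co-occurrence rules (see plant_losses)
SCAFFOLDS = ("RAPTOR", "RICTOR", "SIN1")

STRATEGIES = ("autotroph", "mixotroph", "heterotroph", "parasite_intracellular")


@dataclass(frozen=True)
class SimConfig:
    n_tips: int = 30
    n_clades: int = 4
    seed: int = 0
    components: tuple[str, ...] = COMPONENTS
    loss_prob_per_edge: float | Mapping[str, float] = 0.1
    root_state: Mapping[str, str] = field(
        default_factory=lambda: {c: PRESENT for c in COMPONENTS}
    )
    divergence: float = 0.05  # expected substitutions per site
    completeness: float = 1.0  # per-protein retention probability
    fragmentation_prob: float = 0.0
    read_length_aa: int = 30
    read_error_rate: float = 0.02
    n_reads_per_component: int = 20
    n_background_reads: int = 50
    n_decoys: int = 50
    decoy_length_range: tuple[int, int] = (200, 1500)
    trophic_assoc: float = 0.9  # P(autotroph | TORC2 lost)
    msa_depth: int = 8
    msa_divergence: float = 0.03

    def __post_init__(self) -> None:
        if self.n_tips < 3:
            raise ValueError("n_tips must be >= 3 (no informative root split below)")
        if self.divergence < 0 or self.divergence > 1.5:
            raise ValueError("divergence must be in [0, 1.5]")
        if self.read_length_aa < 5:
            raise ValueError("read_length_aa must be >= 5")
        for name, p in [
            ("completeness", self.completeness),
            ("fragmentation_prob", self.fragmentation_prob),
            ("read_error_rate", self.read_error_rate),
            ("trophic_assoc", self.trophic_assoc),
        ]:
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1]")

    def loss_prob(self, component: str) -> float:
        if isinstance(self.loss_prob_per_edge, Mapping):
            return float(self.loss_prob_per_edge.get(component, 0.0))
        # scalar probability applies to the complex-defining scaffolds; TOR and
        # LST8 default to universal retention (their presence is implied by
        # RAPTOR/RICTOR under the co-occurrence rules)
        return float(self.loss_prob_per_edge) if component in SCAFFOLDS else 0.0


@dataclass(frozen=True)
class GroundTruth:
    tree: TaxonTree
    tip_presence: pd.DataFrame  # species x component booleans
    loss_edges: Mapping[str, frozenset]  # per component, edge child labels
    completeness: Mapping[str, float]
    config: SimConfig


def _rng(config: SimConfig, *stream) -> np.random.Generator:
    # zlib.crc32 gives a process-independent stable hash per stream label
    key = [config.seed] + [zlib.crc32(str(s).encode()) % (2**31) for s in stream]
    return np.random.default_rng(key)


# ---------------------------------------------------------------------------
# taxonomy simulation
# ---------------------------------------------------------------------------

def simulate_taxonomy(config: SimConfig) -> TaxonTree:
    """Random rooted taxonomy: tips partitioned into named clades, polytomies.

    Each clade's subtree is built by repeatedly joining 2 or occasionally 3
    random subtrees (taxonomy trees are unresolved at many ranks); clades join
    at the root, as a polytomy when there are more than two.  At least one
    polytomy is guaranteed for n_tips >= 6.
    """
    rng = _rng(config, "taxonomy")
    n, k = config.n_tips, max(1, min(config.n_clades, config.n_tips // 2 or 1))
    tips = [f"S{i + 1:04d}" for i in range(n)]
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1

    children: dict[str, list[str]] = {}
    clade_map: dict[str, str] = {}
    next_internal = [0]

    def new_node(label: str | None = None) -> str:
        if label is None:
            next_internal[0] += 1
            label = f"I{next_internal[0]:03d}"
        return label

    clade_roots = []
    pos = 0
    made_polytomy = False
    for ci in range(k):
        clade_name = f"C{ci + 1:02d}"
        members = tips[pos : pos + int(sizes[ci])]
        pos += int(sizes[ci])
        for t in members:
            clade_map[t] = clade_name
        nodes = list(members)
        while len(nodes) > 1:
            arity = 3 if (len(nodes) >= 3 and rng.random() < 0.2) else 2
            picks = rng.choice(len(nodes), size=arity, replace=False)
            joined = [nodes[i] for i in sorted(picks)]
            nodes = [x for i, x in enumerate(nodes) if i not in set(picks)]
            label = new_node(clade_name if len(nodes) == 0 else None)
            children[label] = joined
            nodes.append(label)
            if arity > 2:
                made_polytomy = True
        root_label = nodes[0]
        if root_label in clade_map or root_label not in children:
            # single-tip clade: wrap so the clade has a named internal node
            label = new_node(clade_name)
            children[label] = [root_label]
            root_label = label
        clade_roots.append(root_label)

    if k == 1:
        root = clade_roots[0]
    else:
        root = "ROOT"
        children[root] = clade_roots
        if k > 2:
            made_polytomy = True

    tree = TaxonTree.build(children, root, clade_map)
    if config.n_tips >= 6 and not made_polytomy:
        # force one polytomy by collapsing the first resolvable internal edge
        clade_names = set(clade_map.values())
        for node in tree.preorder():
            kids = tree.children(node)
            target = next(
                (c for c in kids if not tree.is_tip(c) and c not in clade_names),
                None,
            )
            if target is not None:
                new_kids: list[str] = []
                for c in kids:
                    if c == target:
                        new_kids.extend(tree.children(target))
                    else:
                        new_kids.append(c)
                children[node] = new_kids
                children.pop(target, None)
                tree = TaxonTree.build(children, root, clade_map)
                break
    return tree


# ---------------------------------------------------------------------------
# loss planting
# ---------------------------------------------------------------------------

def _sample_identifiable_losses(
    tree: TaxonTree, prob: float, rng: np.random.Generator, max_tries: int = 500
) -> tuple[frozenset, dict[str, bool]]:
    """Sample a Dollo loss-edge set and the tip presence it implies.

    Edges are visited root-down; each becomes a loss with probability ``prob``
    unless an ancestor edge already is one (irreversibility).  Configurations
    whose edge set is not recoverable from the tip states (not minimal, or no
    surviving tip) are resampled.
    """
    non_root = [n for n in tree.preorder() if n != tree.root]
    if prob >= 1.0:
        # degenerate certain-loss limit: every root-child edge is a loss edge
        # and no tip survives (not recoverable by reconstruction, by design)
        return (
            frozenset(tree.children(tree.root)),
            {t: False for t in tree.tip_labels},
        )
    for _ in range(max_tries):
        lost_below: set[str] = set()
        losses: set[str] = set()
        for node in non_root:
            parent = tree.parent(node)
            if parent in lost_below:
                lost_below.add(node)
                continue
            if rng.random() < prob:
                losses.add(node)
                lost_below.add(node)
        presence = {t: t not in lost_below for t in tree.tip_labels}
        if not any(presence.values()):
            continue
        states = {t: PRESENT if p else ABSENT for t, p in presence.items()}
        rec = dollo_reconstruct(tree, states)
        if rec.loss_edges == frozenset(losses):
            return frozenset(losses), presence
    raise RuntimeError(
        f"no identifiable loss configuration found in {max_tries} draws "
        f"(loss probability {prob} too high for this tree?)"
    )


def plant_losses(tree: TaxonTree, config: SimConfig) -> GroundTruth:
    """Plant irreversible per-component losses satisfying co-occurrence rules.

    RAPTOR and RICTOR losses are sampled independently; SIN1 is absent wherever
    RICTOR is (plus its own extra losses); TOR/LST8 losses (default probability
    zero) are suppressed on edges whose subtree retains RAPTOR or RICTOR, so
    the synthetic truth always satisfies the observed co-occurrence
    constraints.  Loss-edge truth per component is the minimal Dollo edge set
    of its tip pattern, which sampling guarantees equals the planted set for
    the independently-sampled components.
    """
    rng = _rng(config, "losses")
    tips = tree.tip_labels
    presence: dict[str, dict[str, bool]] = {}
    edges: dict[str, frozenset] = {}

    for comp in ("RAPTOR", "RICTOR"):
        if config.root_state.get(comp, PRESENT) != PRESENT:
            presence[comp] = {t: False for t in tips}
            edges[comp] = frozenset()
            continue
        e, p = _sample_identifiable_losses(tree, config.loss_prob(comp), rng)
        presence[comp], edges[comp] = p, e

    # SIN1: subset of RICTOR
    if config.root_state.get("SIN1", PRESENT) != PRESENT:
        presence["SIN1"] = {t: False for t in tips}
        edges["SIN1"] = frozenset()
    else:
        _, extra = _sample_identifiable_losses(tree, config.loss_prob("SIN1"), rng)
        presence["SIN1"] = {t: presence["RICTOR"][t] and extra[t] for t in tips}
        edges["SIN1"] = _minimal_edges(tree, presence["SIN1"])

    # TOR / LST8: present wherever any scaffold is
    scaffold_any = {
        t: presence["RAPTOR"][t] or presence["RICTOR"][t] for t in tips
    }
    for comp in ("TOR", "LST8"):
        if config.root_state.get(comp, PRESENT) != PRESENT:
            if any(scaffold_any.values()):
                raise ValueError(f"{comp} absent at root contradicts scaffold presence")
            presence[comp] = {t: False for t in tips}
            edges[comp] = frozenset()
            continue
        prob = config.loss_prob(comp)
        if prob == 0.0:
            presence[comp] = {t: True for t in tips}
            edges[comp] = frozenset()
        else:
            _, keep = _sample_identifiable_losses(tree, prob, rng)
            presence[comp] = {t: keep[t] or scaffold_any[t] for t in tips}
            edges[comp] = _minimal_edges(tree, presence[comp])

    matrix = pd.DataFrame(
        {comp: [presence[comp][t] for t in tips] for comp in config.components},
        index=pd.Index(tips, name="species"),
    )
    completeness = {t: float(config.completeness) for t in tips}
    return GroundTruth(tree, matrix, edges, completeness, config)


def _minimal_edges(tree: TaxonTree, presence: Mapping[str, bool]) -> frozenset:
    if not any(presence.values()):
        return frozenset()
    states = {t: PRESENT if presence[t] else ABSENT for t in presence}
    return dollo_reconstruct(tree, states).loss_edges


# ---------------------------------------------------------------------------
# sequence emission
# ---------------------------------------------------------------------------

def component_reference_msas(config: SimConfig) -> dict[str, list[str]]:
    """Deterministic reference alignments, one family per component.

    An ancestral sequence per family is sampled from uniform background, then
    ``msa_depth`` orthologs at ``msa_divergence`` substitutions per site.  No
    indels, so sequences are trivially aligned.
    """
    out: dict[str, list[str]] = {}
    for comp in config.components:
        rng = _rng(config, "refs", comp)
        length = COMPONENT_LENGTHS.get(comp, 120)
        ancestor = rng.integers(0, 20, size=length)
        seqs = []
        for _ in range(config.msa_depth):
            seqs.append("".join(AMINO_ACIDS[i] for i in _mutate(ancestor, config.msa_divergence, rng)))
        out[comp] = seqs
    return out


def build_component_profiles(config: SimConfig) -> dict[str, ProfileModel]:
    return {
        comp: build_profile(msa, comp)
        for comp, msa in component_reference_msas(config).items()
    }


def _mutate(idx: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Poisson substitution: each site changes with p = 1 - exp(-rate)."""
    p = 1.0 - np.exp(-rate)
    out = idx.copy()
    hit = rng.random(idx.size) < p
    if hit.any():
        # draw a different residue uniformly
        shift = rng.integers(1, 20, size=int(hit.sum()))
        out[hit] = (out[hit] + shift) % 20
    return out


def _species_protein(
    species: str, comp: str, profile: ProfileModel, config: SimConfig
) -> str:
    """The species' homolog: profile consensus diverged at ``config.divergence``.

    Shared between proteome and read emission so fragments match the protein.
    """
    rng = _rng(config, "protein", species, comp)
    idx = np.array([AMINO_ACIDS.index(c) for c in profile.consensus])
    return "".join(AMINO_ACIDS[i] for i in _mutate(idx, config.divergence, rng))


def emit_proteomes(
    truth: GroundTruth,
    profiles: Mapping[str, ProfileModel],
    config: SimConfig,
) -> dict[str, list[tuple[str, str]]]:
    """Per-species proteomes: (id, sequence) lists, shuffled, degraded.

    Present components contribute one diverged homolog each, embedded among
    ``n_decoys`` background sequences; each protein survives with probability
    ``completeness`` and surviving proteins are truncated to a uniform 20–80%
    prefix or suffix with probability ``fragmentation_prob``.
    """
    if config.divergence < 0:
        raise ValueError("divergence must be non-negative")
    out: dict[str, list[tuple[str, str]]] = {}
    lo, hi = config.decoy_length_range
    for species in truth.tree.tip_labels:
        rng = _rng(config, "proteome", species)
        seqs: list[str] = []
        for comp in config.components:
            if truth.tip_presence.at[species, comp]:
                seqs.append(_species_protein(species, comp, profiles[comp], config))
        for _ in range(config.n_decoys):
            length = int(rng.integers(lo, hi + 1))
            seqs.append("".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length)))
        order = rng.permutation(len(seqs))
        proteome: list[tuple[str, str]] = []
        for rank, si in enumerate(order):
            seq = seqs[int(si)]
            if rng.random() >= config.completeness:
                continue
            if rng.random() < config.fragmentation_prob:
                frac = rng.uniform(0.2, 0.8)
                cut = max(1, int(round(frac * len(seq))))
                seq = seq[:cut] if rng.random() < 0.5 else seq[-cut:]
            proteome.append((f"{species}_p{rank + 1:04d}", seq))
        out[species] = proteome
    return out


def emit_reads(
    truth: GroundTruth,
    profiles: Mapping[str, ProfileModel],
    config: SimConfig,
) -> dict[str, list[tuple[str, str]]]:
    """Per-species peptide fragments emulating translated RNA-seq reads.

    Present components yield ``n_reads_per_component`` fragments of
    ``read_length_aa`` residues sampled uniformly along the protein with
    per-residue substitution errors; ``n_background_reads`` random fragments
    are added regardless, so absent components contribute background only.
    """
    L = config.read_length_aa
    out: dict[str, list[tuple[str, str]]] = {}
    for species in truth.tree.tip_labels:
        rng = _rng(config, "reads", species)
        frags: list[tuple[str, str]] = []
        n = 0
        for comp in config.components:
            if not truth.tip_presence.at[species, comp]:
                continue
            protein = _species_protein(species, comp, profiles[comp], config)
            for _ in range(config.n_reads_per_component):
                start = int(rng.integers(0, max(1, len(protein) - L + 1)))
                frag = protein[start : start + L]
                idx = np.array([AMINO_ACIDS.index(c) for c in frag])
                frag = "".join(AMINO_ACIDS[i] for i in _mutate_errors(idx, config.read_error_rate, rng))
                n += 1
                frags.append((f"{species}_r{n:04d}", frag))
        for _ in range(config.n_background_reads):
            n += 1
            frags.append(
                (
                    f"{species}_r{n:04d}",
                    "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=L)),
                )
            )
        out[species] = frags
    return out


def _mutate_errors(idx: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    out = idx.copy()
    hit = rng.random(idx.size) < p
    if hit.any():
        shift = rng.integers(1, 20, size=int(hit.sum()))
        out[hit] = (out[hit] + shift) % 20
    return out


def background_fragments(
    n: int, config: SimConfig, seed_tag: str = "bgfrags"
) -> list[tuple[str, str]]:
    """Background-only fragments (negative-control input for rescue)."""
    rng = _rng(config, seed_tag)
    return [
        (
            f"bg_r{i + 1:04d}",
            "".join(AMINO_ACIDS[j] for j in rng.integers(0, 20, size=config.read_length_aa)),
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# trophic labels
# ---------------------------------------------------------------------------

def assign_trophic_labels(truth: GroundTruth, config: SimConfig) -> pd.DataFrame:
    """Trophic strategies correlated with TORC2 retention.

    Tips lacking TORC2 (no RICTOR) are autotrophs with probability
    ``trophic_assoc``, else uniform over the other three strategies; tips
    retaining TORC2 are autotrophs with probability ``(1 - trophic_assoc)/3``,
    the unique completion for which ``trophic_assoc = 1/4`` is an exact
    independence null and ``trophic_assoc = 1`` a deterministic association.
    """
    rng = _rng(config, "trophic")
    a = config.trophic_assoc
    rows = []
    others = [s for s in STRATEGIES if s != "autotroph"]
    for species in truth.tree.tip_labels:
        has_torc2 = bool(truth.tip_presence.at[species, "RICTOR"])
        p_auto = (1.0 - a) / 3.0 if has_torc2 else a
        if rng.random() < p_auto:
            strategy = "autotroph"
        else:
            strategy = others[int(rng.integers(0, 3))]
        plastid = {
            "autotroph": "yes",
            "mixotroph": "yes",
            "heterotroph": "no",
            "parasite_intracellular": "derived" if rng.random() < 0.5 else "no",
        }[strategy]
        free_living = "no" if (strategy == "parasite_intracellular" and rng.random() < 0.7) else "yes"
        rows.append(
            {
                "species": species,
                "strategy": strategy,
                "plastid": plastid,
                "free_living_stage": free_living,
            }
        )
    return pd.DataFrame(rows).set_index("species")


# ---------------------------------------------------------------------------
# one-call dataset
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticDataset:
    config: SimConfig
    tree: TaxonTree
    truth: GroundTruth
    profiles: Mapping[str, ProfileModel]
    msas: Mapping[str, list[str]]
    proteomes: Mapping[str, list[tuple[str, str]]]
    reads: Mapping[str, list[tuple[str, str]]]
    trophic: pd.DataFrame


def generate(config: SimConfig) -> SyntheticDataset:
    """Generate a complete synthetic dataset (all pipeline inputs plus truth)."""
    tree = simulate_taxonomy(config)
    truth = plant_losses(tree, config)
    msas = component_reference_msas(config)
    profiles = {c: build_profile(m, c) for c, m in msas.items()}
    return SyntheticDataset(
        config=config,
        tree=tree,
        truth=truth,
        profiles=profiles,
        msas=msas,
        proteomes=emit_proteomes(truth, profiles, config),
        reads=emit_reads(truth, profiles, config),
        trophic=assign_trophic_labels(truth, config),
    )


def write_dataset(dataset: SyntheticDataset, outdir) -> None:
    """Write all inputs as plain-text files (FASTA/Newick/TSV/JSON)."""
    import json
    import os

    os.makedirs(outdir, exist_ok=True)
    os.makedirs(os.path.join(outdir, "proteomes"), exist_ok=True)
    os.makedirs(os.path.join(outdir, "reads"), exist_ok=True)
    os.makedirs(os.path.join(outdir, "msas"), exist_ok=True)

    def write_fasta(path, records):
        with open(path, "w") as fh:
            for name, seq in records:
                fh.write(f">{name}\n{seq}\n")

    for sp, recs in dataset.proteomes.items():
        write_fasta(os.path.join(outdir, "proteomes", f"{sp}.faa"), recs)
    for sp, recs in dataset.reads.items():
        write_fasta(os.path.join(outdir, "reads", f"{sp}.frags.faa"), recs)
    for comp, msa in dataset.msas.items():
        write_fasta(
            os.path.join(outdir, "msas", f"{comp}.afa"),
            [(f"{comp}_{i + 1}", s) for i, s in enumerate(msa)],
        )
    with open(os.path.join(outdir, "tree.nwk"), "w") as fh:
        fh.write(dataset.tree.to_newick() + "\n")

    meta = pd.DataFrame(
        {
            "species": dataset.tree.tip_labels,
            "clade": [dataset.tree.clade_map.get(t, "") for t in dataset.tree.tip_labels],
            "completeness": [
                dataset.truth.completeness[t] for t in dataset.tree.tip_labels
            ],
        }
    ).set_index("species")
    meta = meta.join(dataset.trophic["strategy"].rename("trophic"))
    meta.to_csv(os.path.join(outdir, "metadata.tsv"), sep="\t")

    dataset.truth.tip_presence.to_csv(os.path.join(outdir, "truth_presence.tsv"), sep="\t")
    pd.DataFrame(
        [
            {"component": c, "loss_edges": ";".join(sorted(e))}
            for c, e in dataset.truth.loss_edges.items()
        ]
    ).to_csv(os.path.join(outdir, "truth_losses.tsv"), sep="\t", index=False)

    cfg = {
        k: (list(v) if isinstance(v, tuple) else (dict(v) if isinstance(v, Mapping) else v))
        for k, v in vars(dataset.config).items()
    }
    with open(os.path.join(outdir, "config.json"), "w") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True)
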