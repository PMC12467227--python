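# Methods

`torcscan` maps the presence of the five core TOR-complex components — TOR,
LST8, RAPTOR, RICTOR and SIN1 — across eukaryotic proteomes, derives
TORC1/TORC2 presence per species, reconstructs where in the tree of life each
complex was lost, and summarises how complex architecture co-varies with
trophic strategy.  This note records the models, the defaults that matter, the
numerical choices, and what the synthetic benchmark does and does not show.

## Homology model and scoring

Each component family is a position-specific log2-odds profile built from a
reference alignment.  Columns with ≥ 50% residue occupancy become match
columns; column frequencies are smoothed with +1/20 pseudocounts per residue,
`f_a = (c_a + 1/20) / (n + 1)`, and scored as `log2(f_a / b_a)` against a
background `b` (uniform 1/20 by default).  Because `Σ_a b_a · 2^{s_a} = 1`
column-wise, scores are calibrated bits: a background-distributed column
scores ≈ 0 in expectation and local-alignment theory applies with λ = ln 2.

Sequences are scored by Smith–Waterman local alignment over the profile's
column scores with affine gaps (open 10 bits, extend 1 bit — BLAST-protein-like
magnitudes on the bit scale).  The best alignment is the best domain;
additional non-overlapping domains are found by masking the aligned sequence
region and re-aligning; the overall score is the sum of accepted domains.  The
downstream rubric grades `max(overall, best domain)`, which makes the pipeline
insensitive to how a full-sequence score is defined.

Two numerical choices matter:

* **Domain acceptance floor, 40 bits (config-exposed).**  Null calibration
  (random sequences, lengths 200–1500, against these profiles) puts the best
  local score at ~14 bits on average, q95 ≈ 18, max ≈ 25 over 200 draws.  A
  floor inside the null tail would chain spurious segments into the overall
  sum (~10 segments ≈ 120 bits, enough to cross the 100-bit consideration
  threshold); 40 bits sits far above the null and far below any informative
  homolog fragment (a 20%-length truncation of the smallest family still
  scores ≈ 80 bits).
* **Ungapped seed scan.**  A Kadane-style best-ungapped-segment pass gates the
  gapped DP, as in the acceleration filters of profile-HMM search tools.
  Sequences whose seed score stays below the domain floor are reported with
  that score and no domains.  The seed score equals the gapped optimum for
  indel-free matches and is otherwise within the gap penalties of it — three
  rubric bands below any call boundary for the sequences it short-circuits.

Real HMMER results enter through the `--domtblout` parser instead; tier
assignment is identical in both routes.

## Tier rubric and screens

Effective bits map to confidence tiers on half-open bands: `< 100 → ABS`,
`[100, 150) → L`, `[150, 300) → M`, `≥ 300 → H`, so every score lands in
exactly one tier.  Per species and component the best hit wins (ties: higher
domain coverage, then smallest sequence id), and every (species, component)
pair gets exactly one call.  A positive call in a clade where all other
members lack the component is screened: failing domain coverage (< 25% of the
annotated domain columns, config-exposed) demotes it to ABS with a
`contaminant` flag; passing hits are kept with an `outlier_checked` flag so
genuine outliers survive.  The screen never upgrades.

## Complex rules

TORC1 presence ≡ RAPTOR detected; TORC2 presence ≡ RICTOR detected (SIN1 never
affects the call); read-rescued P tiers count as detections.  Three
co-occurrence rules are checked dataset-wide — SIN1 without RICTOR, and
RAPTOR/RICTOR without TOR or without LST8 — and violations are reported
without overriding the rule-derived calls; SIN1-without-RICTOR species are
listed for re-examination.

## Short-read rescue

An ABS call is a rescue candidate when the species' completeness score is
below 0.70 (config-exposed; "low completeness" has no canonical cutoff) and
either at least half of the tips within 3 tree edges carry the component at
H/M/L, or the species sits in a clade otherwise uniformly present.
Clade-consistent absences are never candidates — presence/absence clusters
within monophyletic groups are the internal validation of the calls.

Peptide fragments are aligned to the component reference with the same local
aligner.  A match is accepted when E ≤ 1e-10, bits > 50 and the alignment
overlaps an annotated domain region; for reads shorter than 10 residues (the
protein-level equivalent of a 30-nucleotide match, where score statistics are
unreliable) a ≥ 70% identity requirement replaces the score gates.  The
short-match rule is keyed to the *read* length: for longer fragments the
reported match length is floored at 10 residues so the score gates always
apply — a local aligner will extract a few-residue perfect-identity snippet
from any random fragment, and letting such snippets qualify under the
identity rule would accept essentially all background reads.  E-values use
the Karlin–Altschul expectation `m·n·2^(−bits)` with K = 1 (conservative; the
50-bit gate dominates).  Two accepted matches with non-identical reference
intervals (distinct evidence) upgrade ABS to P; rescue never touches H/M/L
calls.  Measured operating characteristics at defaults: 0/200 false rescues
on background-only fragments; 100% recovery when reads from a genuinely
present component exist.

## Loss inference

Traits (components, and complexes via their scaffolds) are reconstructed under
an irreversible-loss (Dollo) model: gained once at or above the root, never
regained.  The minimum-loss labelling is closed-form — an internal node is
present iff any non-missing descendant tip is present; every edge from a
present parent into a subtree with absent but no present tips is one
independent loss.  On trees of ≤ 10 tips the count is verified against
exhaustive enumeration of all irreversible labelings.  Root-state inference:
presence under ≥ 2 root children implies presence in the root ancestor (for
the eukaryote tree, LECA); presence confined to one root child is an origin
within the tree.

Polytomies (ubiquitous in NCBI-taxonomy topologies) are evaluated child by
child: k all-absent children under a present parent count k losses — the
maximal, most conservative count consistent with that unresolved topology.
Missing data: with the `missing` policy, an ABS call from a species below the
completeness threshold that was not rescued is treated as unknown;
unknown-only subtrees inherit the parent state and can never create loss
edges, so the policy can only merge or drop losses, never add them.

## Synthetic data: what it emulates

The generator produces every input the pipeline consumes, from a single seed,
bit-reproducibly:

* **Taxonomy**: tips partitioned into named clades; subtrees built by random
  2-way (80%) or 3-way (20%) joins, guaranteeing multifurcation for ≥ 6 tips.
* **Losses**: per-edge Bernoulli (default 0.1) with suppression below an
  existing loss — a proper Dollo process.  RAPTOR and RICTOR are planted
  independently; SIN1 absence is RICTOR absence plus its own extra losses;
  TOR/LST8 default to universal retention, and any sampled TOR/LST8 loss is
  suppressed where a scaffold survives — so the truth always satisfies the
  observed co-occurrence rules.  Sampled configurations are resampled until
  *identifiable*, i.e. the planted edge set equals the minimal Dollo
  reconstruction of the tip states it implies.  Non-identifiable
  configurations (two sibling subtrees independently losing all tips, which
  no tip data can distinguish from one older loss) occur at ~several percent
  per component at these rates and would make exact edge-set recovery
  impossible for any method; restricting the benchmark to identifiable truths
  is what makes "reconstruction equals the planted set" a meaningful test.
  The certain-loss limit (probability 1) is kept as the degenerate exception:
  all root-child edges lost, nothing recoverable.
* **Sequences**: reference families of 100–160 columns (rank-ordered like the
  real proteins, scaled for speed), 8 orthologs at 0.03 substitutions/site,
  no indels.  Homologs are the profile consensus mutated at `divergence`
  substitutions/site (Poisson, `p = 1 − e^(−d)`); proteomes add 50 background
  decoys of 200–1500 residues, then retain each protein with probability
  `completeness` and truncate retained proteins (uniform 20–80% prefix or
  suffix) with probability `fragmentation_prob` (default 0 — degradation is
  opt-in per experiment).
* **Reads**: 20 fragments of 30 residues per present component, sampled
  uniformly along the species' protein with 2% per-residue errors, plus 50
  background fragments per species.
* **Trophic labels**: TORC2-lacking tips are autotrophs with probability
  `trophic_assoc` (default 0.9), else uniform over
  mixotroph/heterotroph/intracellular-parasite; TORC2-retaining tips are
  autotrophs with probability `(1 − trophic_assoc)/3` — the completion under
  which 1/4 is an exact independence null and 1 a deterministic association.

Deliberately not emulated: indels and domain shuffling (so percent identity
and coverage behave cleanly and the aligner's gap path is exercised only by
the score model), multiple gene copies per species, nucleotide-level reads,
assembly artefacts, and real clade-specific rate variation.  Passing the
recovery benchmark therefore shows the calling/reconstruction machinery is
exact under its own model assumptions — not that the rubric thresholds are
optimal for real proteomes, where divergence, paralogy and annotation noise
are all harsher.

## Benchmark problem sizes

The recovery benchmark uses 50 datasets of 30 tips (loss probability
0.1/edge, divergence 0.05, complete proteomes); oracle equivalence uses 200
random trees of ≤ 10 tips; the rescue negative control uses 200 background
trials and the power check 50 trials.  These sizes give stable percentages
while keeping a full run in a few minutes on one core; the real dataset the
method targets (hundreds of genomes) differs only in width, not in any
algorithmic assumption.

## Known limitations

* One detection per component per species: paralogs and gene copies are not
  resolved (e.g. species with two RAPTOR genes count once).
* The contamination screen automates a manual BLAST/MSA review with a
  coverage-plus-clade-context rule; it cannot use out-clade identity unless
  such references are supplied.
* The Dollo count on polytomies is an upper bound conditional on the
  unresolved topology.
* E-values from the in-repo aligner are conservative approximations (K = 1),
  adequate only because the bit-score gates dominate every decision they
  enter.
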