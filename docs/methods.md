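# Methods

This note records the models, defaults and design choices behind
mutscape, in the package's own terms. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Subfamily-specific positions

An SSP is an alignment column whose residue is conserved within each of
two subfamily groups but differs between them. Conservation is assessed
per group with two knobs:

* `min_conservation` (default **1.0**): minimum frequency of the top
  residue among the group's non-gap entries. The strict default encodes
  "conserved within either group" as literal identity; it is configurable
  because real families tolerate noise, and detection is monotone in it
  (raising the threshold never adds SSPs — a tested invariant).
* `max_gap_fraction` (default **0.2** per group per column): columns with
  more gaps than this in a group have no consensus there. Columns where
  the reference sequence is gapped are still reported, just without a
  reference position.

Coordinates are 1-based throughout, matching conventional residue
numbering (Glu107, Ile197). Exactly two groups are supported; more are
rejected rather than silently generalised. Consensus ties (reachable only
at `min_conservation` ≤ 0.5) resolve alphabetically for determinism.

## Positive-selection interface

Branch-site analyses are run externally; this package only parses their
output — either a plain TSV (position, residue, posterior) or the
"Positively selected sites" text block of a codeml main result file. The
default posterior cutoff is **0.95** with a strict `>` comparison, an
arbitrary but documented convention exposed as a flag. Candidate merging
is a tagged set union (origins SSP / PSD / both) and obeys
inclusion–exclusion; it is commutative and idempotent (tested
properties).

## Structural screen

Two explicit geometric criteria replace a manual structural inspection:

* **Proximity**: minimum heavy-atom distance from the candidate residue
  to any catalytic-residue heavy atom or reference-ligand atom ≤
  `distance_cutoff`, default **10 Å**. No literature consensus exists for
  "near the active site"; 10 Å spans first and second shells and is a
  config knob. Loosening it never shrinks the retained set (tested).
* **Network protection** (`protect_network`, default on): a candidate
  whose side-chain N/O sits within **3.5 Å** of an N/O of a catalytic
  residue or ligand is considered part of the catalytic hydrogen-bonding
  network and dropped — mutating such a residue risks destroying the
  geometry catalysis depends on. 3.5 Å is the standard heavy-atom
  hydrogen-bond criterion; a donor–H…acceptor angle test (≥ 120°) applies
  only when the model actually contains hydrogens, which homology models
  normally do not.

PDB input uses the first MODEL only; insertion codes are rejected with a
clear error rather than renumbered. Verdicts are a pure function of the
recorded metrics, so a report can be re-derived from its own TSV. When a
candidate's stated wild-type residue conflicts with the model, the
residue from the provided reference sequence wins (families disagree in
published numberings often enough that this must be explicit).

## Mutation panel

One representative per side-chain class, in preference order:
non-polar (A, G, V), aromatic (F, Y, W), polar (Q, N, S), basic (H, K,
R), acidic (E, D). The first member differing from the wild type is
chosen, which doubles as the within-class alternate rule: an acidic class
at a Glu site yields Asp, a basic class at an Arg site yields His. The
acidic representative is Glu (alternate Asp) so that an Arg site receives
the Glu substitution and a Glu site the Asp one — the combination that
reproduces the classic CHI test panel (E107D, E107Q, R110A, R110E,
R110H, I197P). Proline is appended for loop sites; `is_loop` is an input
flag, not computed secondary structure. Panels are deterministic and
never contain the wild type.

## Docking landscape

**RMSD.** Receptor-frame RMSD over heavy atoms matched by name, with no
superposition: both poses live in one receptor coordinate frame, and
fitting would erase exactly the displacement being measured. No
graph-automorphism symmetry correction is applied (a known limitation for
ligands with topologically equivalent atoms). The implementation is
checked against a per-atom brute-force loop to 1e-10 Å and satisfies the
metric axioms on random pose triples.

**Grouping.** One-dimensional k-means on the RMSD axis, k = 4 by
default, with deterministic initialisation at evenly spaced quantiles of
the sorted RMSD values and a 100-iteration cap. This makes repeated runs
reproducible without a stochastic restart policy; the `seed` argument is
recorded for provenance but the procedure itself is deterministic. All
poses are clustered — no energy pre-filter — though an energy-top-fraction
option would be the natural variant if one reads the landscape as
filtered; the unfiltered reading is the default because the groups are
features of the full plot.

**Labels.** Clusters whose lowest-energy (representative) pose has RMSD
above `flip_threshold` (default **6.0 Å**, the flipped-orientation
regime) are labelled IV; remaining clusters are labelled I, II, III in
strictly descending representative energy. Degenerate cases keep IV
exclusive to flipped clusters: extra near-product clusters continue V,
VI, … and extra flipped clusters become IVb, IVc, …. Representative
selection breaks energy ties by lower RMSD, then lower run id.

**Decision rule.** ΔE(III) = mutant group-III representative energy −
wild-type's. ε (default **0.5 kcal/mol**) absorbs docking-score noise:
empirical docking rescoring rarely reproduces energies more tightly than
about half a kcal/mol, and the three-way verdict (beneficial / neutral /
detrimental) makes the "no real change" outcome explicit instead of
forcing a sign.

## Synthetic data

The generators emulate the *structure* of the real inputs, not their
physics:

* **MSA**: 2 × 7 sequences × 220 columns with 9 planted SSP columns by
  default (the scale of a small two-subfamily isomerase alignment), 120
  fully conserved columns, and background columns substituted per cell at
  5% and gapped at 2% — enough noise to exercise the thresholds without
  drowning the signal. Planted SSP columns have zero within-group noise,
  so zero-noise recovery is exact by construction (and tested across
  seeds).
* **Selection tables**: planted positives draw posteriors from
  U(0.95, 1], the rest from U[0, 0.5), so recovery at the default
  threshold is guaranteed by construction — these tests exercise the
  plumbing and thresholds, not statistical power.
* **Mock ligand**: a rigid planar zig-zag of 12 labelled atoms spanning
  10 Å by default, ±0.5 Å off-axis. Rigid-body perturbations (random
  small rotation about the centroid plus a translation sized to hit the
  target RMSD exactly) plant the mode structure; conformational
  flexibility is not simulated because the downstream computations only
  consume coordinates, labels and energies. The default length is 10 Å
  rather than 12 Å so the flipped geometry (intrinsic RMSD ≈ 6.3 Å) stays
  below the 7.5 Å flip-mode centre, leaving room to place flipped poses
  at the planted centre by translation; a 12 Å ligand flips to ≈ 7.5 Å
  and both exceed the 6 Å group-IV threshold.
* **Ensembles**: 2,000 poses in four modes at 0.5 / 1.8 / 3.5 / 7.5 Å
  with weights 0.30 / 0.25 / 0.25 / 0.20 and Gaussian energies with means
  −5.5 / −6.5 / −7.5 / −7.0 kcal/mol — the qualitative ordering
  E(I) > E(II) > E(III), with the flip mode between II and III. The
  within-mode energy SD is **0.1 kcal/mol**: docking runs that rediscover
  the same basin report near-identical scores, so within-basin spread
  sits an order of magnitude below the ~1 kcal/mol separations between
  basins. This matters because the group representative is a minimum
  statistic — its sampling noise must stay well below the ±0.5 kcal/mol
  verdict margin for planted shifts as small as ±0.6 kcal/mol to be
  resolvable at all. Per-pose RMSD targets are jittered at 5% relative
  SD, keeping modes separated by many SDs so clustering recovery is
  essentially exact.
* **Mutant effects**: planted group-III mean shifts
  {I197P: −1.5, R110A: −1.2, E107D: 0.0, E107Q: +0.8, R110E: +0.6,
  R110H: +1.0} kcal/mol. Only the *sign pattern* mirrors the known
  experimental outcome of those six CHI mutants (two improved, one
  unchanged, three worsened); the magnitudes are the package's own test
  conditions.

What passing these tests shows — and does not. They demonstrate that the
analysis layer is correct: RMSD, grouping, labelling and the decision
rule recover planted structure reliably. They do not validate docking
energies, receptor modelling, or the biological hypothesis that lowering
the group-III energy raises activity; those depend on the external
computations this package deliberately does not perform.

## Pipeline

A single YAML config with per-stage blocks drives
`mutscape run`; stages execute only when their block is present, so a
landscape-only run is valid. Every run writes each stage's artifact, a
resolved config copy, and SHA-256 digests of all inputs; reports are
byte-identical across re-runs with the same config and seed (timestamps
are deliberately excluded). Ranking is by ΔE(III) ascending with
lexicographic tie-break on the mutation string. Exit codes: 0 success,
2 config error, 3 stage failure.

## Problem sizes

Default study sizes — 1,000 RMSD oracle pairs and metric triples, 100
random alignments for the SSP oracle, 20 seeds for planted-SSP recovery,
50 ensembles for clustering recovery, 100 seeds for the sign-pattern
study, 2,000 poses per ensemble — were chosen so the full validation runs
in about a minute on one core while keeping Monte-Carlo uncertainty on
the recovery rates to a few percent.

## Known limitations

* No symmetry-corrected RMSD; symmetric ligands will overstate RMSD for
  equivalent-atom swaps.
* The 1-D k-means grouping assumes the RMSD axis separates the pose
  families; landscapes whose groups overlap in RMSD but differ in energy
  would need 2-D clustering.
* The hydrogen-bond criterion is distance-based when hydrogens are
  absent, so it cannot distinguish donors from acceptors.
* Group labels I–III require at least three near-product clusters; a
  landscape without a group III cannot be compared and raises a clear
  error rather than guessing.
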