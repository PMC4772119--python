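# Methods

## Scope and model

`tmdscan` analyses *bitopic* membrane proteins — exactly one membrane-spanning
helix per chain. Multi-span proteins, signal-peptide discrimination and
topology prediction are out of scope: topology (which terminus is cytosolic)
is a required input annotation, supplied per record in the annotation TSV.
The package's claim is not that it predicts topology or finds every TM helix,
but that, given a single-span protein of known orientation, it assigns a
reproducible, rule-defined helix span whose length can be compared across
groups.

## Hydropathy scales

Two scales ship as plain-text tables (`src/tmdscan/data/*.tsv`, residue–score
pairs, overridable via `load_scale_file`):

* **GES** — water→bilayer transfer free energies in kcal/mol, oriented so
  hydrophobic residues are positive (F 3.7 … R −12.3). Chosen as the default
  because it is thermodynamically grounded rather than statistical.
* **KD** — the Kyte–Doolittle index, used to check that conclusions are not
  scale-dependent.

A residue is classified hydrophobic iff its score is strictly greater than
the scale's `hydrophobic_threshold` (default 0, so profiles cross zero at
the water/membrane boundary). `X` scores 0 on both scales and therefore
classifies as hydrophilic — the conservative choice for edge refinement.
Other ambiguity codes (B, Z, U, *) are rejected at parse time: the
refinement rules need a defined hydrophobicity class per residue, and
silently guessing one would move helix boundaries.

## Detection and refinement

Per protein, deterministic throughout (identical inputs ⇒ identical spans):

1. **Rough scan** (`rough_scan`): the 18-residue window with the maximum
   summed hydropathy, ties broken to the smallest start index. Only the
   single best window is taken — the bitopic assumption.
2. **Flanks** (`attach_flanks`): up to 8 residues per side, truncated at
   sequence ends. The candidate region is therefore 18–34 residues and
   reaches the 26-residue minimum whenever at least one side has 8
   residues available.
3. **Refinement** (`refine_edges`), two phases:
   * *Expand*: from each core edge, annex the next residue while it is
     hydrophobic, or uncharged-hydrophilic and **buried** — ≥ 3 contiguous
     hydrophobic residues immediately on each side, entirely within the
     candidate region.
   * *Contract*: from each edge of the expanded span, chop the terminal
     residue while it is hydrophilic and not buried.

   Charged residues (D, E, K, R and, by default, H) are never
   buried-eligible and so always stop expansion and are always chopped from
   edges; interior hydrophilic residues are untouched. A consequence worth
   noting: every refined span terminates in a hydrophobic residue, because
   any residues contraction removed were themselves hydrophilic, which
   destroys the burial context a hydrophilic terminal would need. If the
   candidate contains no hydrophobic residue at all the record is flagged
   `no_tmd` (not an exception) and excluded from downstream statistics with
   a logged count.

   The burial width (3), flank budget (8), threshold (0), charged set and
   the expand-before-contract order are all config keys (`RunConfig`), so
   each rule's influence can be probed. Expand-first is the default because
   contraction is defined on the edges of an established region; the
   alternative order is available as a flag.
4. **Orientation** (`orient`): position 1 is the cytosolic-most refined
   residue; N-cytosolic records keep sequence order, C-cytosolic records are
   reversed. `TmdRecord.oriented_residues(extent)` continues past the span
   into the exoplasmic side of the full sequence, which aligned profiles
   need (below).

Coordinates are 1-based and inclusive everywhere. TMD length is defined as
the refined span's residue count (hydrophilic residues retained in the
interior are counted); counting only hydrophobic residues is a defensible
alternative the package does not implement.

## Redundancy reduction

BLAST-based clustering is replaced by an internal, dependency-free
equivalent with the same intent (discard sets of sequences > 30% identical):

* **Identity** (`pairwise_identity`): optimal global alignment under
  match = 1, mismatch = 0, gap = 1 per gap position (constants exposed).
  The DP maximizes (score, matches) lexicographically, which pins down the
  number of matches and the alignment length across co-optimal alignments,
  so the identity fraction is a symmetric, well-defined function of the
  pair — no traceback tie-break leaks into the value.
* **Clustering** (`cluster`): single linkage — two records share a cluster
  iff connected by a chain of pairs with identity strictly above the
  threshold (default 0.30), computed on the TMD+flank candidate
  subsequences. The representative is the longest member, ties to the
  lexicographically smallest id.

The original tool's exact metric, denominator and linkage are not
documented; this reconstruction is the package's own definition and is
validated against exhaustive-enumeration oracles in the tests.

## Group statistics

* `group_summary` / `length_distribution`: integer histograms; mean; sample
  (n−1) SD, reported as absent for n = 1; mode with ties to the smallest
  length. Reports round to 2 decimals; internal precision is full.
* `welch_ttest`: two-tailed heteroscedastic t-test (scipy's Welch
  implementation; the Welch–Satterthwaite closed form serves as an
  independent oracle in the tests). Degenerate zero-variance-both samples
  return p = 1 (equal means) or p = 0 (distinct means) with a flag rather
  than NaN.
* `kldm`: Σ p₁·log(p₁/p₂) over the support where **both** histograms are
  nonzero; both vectors are renormalized after trimming (without
  renormalization the quantity is not a divergence between probability
  distributions). Natural log by default; base is a config key. The
  directed values differ; `kldm_symmetric` averages the two directions.
  Non-overlapping supports raise from `kldm` directly and are reported as
  NaN + flag from `compare_groups` — small groups (e.g. the printed viral
  tables) can legitimately share no length.
* `rms_pm_difference`: √(mean over organelle proteins of
  (Lᵢ − mean PM length of species(i))²). The source description is
  ambiguous between a root-*mean*-square and a root-sum-of-squares; RMS is
  the default and the sum variant sits behind `normalize=False`, with no
  claim about which produced any published bar chart.
* No multiple-testing correction is applied; p-values are reported raw, as
  in the analyses this package reproduces.

## Aligned profiles and the mode readout

`mean_hydropathy_profile` averages windowed hydropathy across helices
anchored at position 1, with per-position coverage counts (positions are
averaged over the records that cover them). With `extent` set, each
record's profile continues past its span into the exoplasmic sequence;
`profile_mode_length` then counts the consecutive positions from position 1
with mean score > 0. When one length dominates the group (≳ 60%), the
positions beyond the dominant length are hydrophilic in most records, the
mean dips below zero exactly there, and the readout equals the histogram
mode rather than the mean — the property the tests assert. For broad
length distributions the crossing is smeared and the readout can undershoot
the mode; it is a descriptive statistic, not an estimator with guarantees.
The profile window defaults to 1 (per-residue) for this readout; any window
can be requested.

## Synthetic data generator

`plant_tmd` builds hydrophilic-flank + hydrophobic-run + hydrophilic-flank
sequences with exact ground-truth boundaries; `generate_group` draws run
lengths from a rounded normal clipped to [8, 34] (matching the unimodal
length distributions seen in real organelle sets) and alternates topologies.
Defaults: flanks of 12 hydrophilic residues per side; hydrophobic pool
{L, I, V, F, M, A}; hydrophilic pool {D, E, K, R, N, Q}. Serine is excluded
from the hydrophilic pool because GES scores it +0.6 (hydrophobic), which
would break the guarantee that the planted run is the unique maximal
hydrophobic run; `plant_tmd` validates both pools against the active scale.

Runs longer than the scan window are built with a hydrophobicity **taper**:
a window-sized central core drawn from the stronger half of the hydrophobic
pool ({F, M, I, L} under GES) and periphery from the weaker half ({V, A}).
This mirrors the hydrophobicity gradient of natural TM helices — strongly
hydrophobic residues in the bilayer core, weaker ones toward the
interfaces — and it makes the most-hydrophobic 18-window provably the
centered one, so the ±8 flank budget always covers the full run. Without a
taper (iid residues), the argmax window of a 27–34-residue run can land far
enough off-center that no rule-conforming refinement can reach both true
boundaries; that is a geometric property of the scan-plus-flank design, and
the generator's job is to emulate detectable helices, not that failure
mode.

What the generator does **not** emulate: realistic background amino-acid
composition, helix-breaking prolines inside TMDs, interfacial aromatic
belts, paralogy/redundancy structure, or annotation noise. Passing the
planted-recovery tests therefore demonstrates correctness of the scanning
and refinement rules on unambiguous inputs, not detection performance on
real proteomes.

## Problem sizes and numerical choices

The test-suite and acceptance-script problem sizes (500 planted-recovery
cases, 100 oracle instances per algorithm, groups of 60–200 simulated
records) were chosen to exercise every rule and keep the full run in the
low seconds on one core. The organism-scale datasets behind published
organelle tables (tens of thousands of harvested orthologs) require
accession downloads and are explicitly out of scope; the end-to-end
substitute compares simulated organelle groups instead.

Numerics: window sums/means use numpy sliding windows (pairwise summation;
ties in the rough scan resolve to the first maximum); KLDM clamps |value| <
1e−15 to 0 to absorb round-off when distributions are equal; all histogram
supports are exact integers, no smoothing or binning.

## Known limitations

* Topology must be supplied; records with UNKNOWN topology are an error in
  strict mode, flagged and skipped in lenient mode.
* One helix per protein; a second TM span in the input will be silently
  ignored in favour of the most hydrophobic one.
* The refinement constants (3+3 burial, H counted charged, expand-first)
  reconstruct a procedure whose full flowchart is not publicly documented;
  they are exposed as configuration precisely because they are a
  reconstruction.
* Identity clustering is quadratic in the number of records; it is meant
  for the post-detection TMD+flank subsequences (≤ 34 residues), not whole
  proteomes.
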