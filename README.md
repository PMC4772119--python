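# tmdscan

Hydropathy-based detection, refinement and comparative length statistics of
single-span (bitopic) transmembrane domains (TMDs).

The length of a protein's membrane-embedded helix is a sorting signature: it
tends to track the bilayer thickness of the compartment the protein resides
in, and — for viral membrane proteins — the entry pathway or replication
compartment the virus uses. `tmdscan` implements the sequence-only pipeline
needed to study this: it locates the TMD of each single-span membrane
protein from its hydropathy profile, refines the helix boundaries with
explicit residue-level rules, anchors every helix at its cytosolic end, and
compares groups of helices (organelles, pathways, species) by their length
distributions.

## Method

For each protein sequence with a known topology annotation (which terminus
is cytosolic):

1. **Rough scan.** Slide an 18-residue window along the sequence and keep
   the window with the highest summed hydropathy, regardless of the
   hydrophilic residues inside it. Scores come from the GES
   (Goldman–Engelman–Steitz) transfer free-energy scale (kcal/mol,
   hydrophobic > 0) or the Kyte–Doolittle index.
2. **Flank attachment.** Extend the window by up to 8 residues on each side
   (candidate region of 18–34 residues, truncated at sequence ends).
3. **Edge refinement.** Expand each edge outward through residues that are
   hydrophobic, or uncharged-hydrophilic but *buried* between ≥ 3 contiguous
   hydrophobic residues on both sides; then contract each edge by chopping
   terminal residues that are hydrophilic and not buried. Charged residues
   (D, E, K, R, H) are never buried-eligible; interior hydrophilic residues
   are retained.
4. **Cytosolic anchoring.** List the refined helix from its cytosolic end
   (position 1) to its exoplasmic end, so helices from many proteins can be
   aligned and averaged.

On top of the per-protein spans, the package provides:

* redundancy reduction of TMD+flank subsequences by single-linkage
  clustering at 30% global-alignment identity,
* aligned per-position mean hydropathy and residue-abundance profiles (the
  0-crossing of the mean profile reads off the *modal* TMD length),
* group comparisons: Welch's two-tailed heteroscedastic *t*-test on lengths,
  the Kullback–Leibler divergence measure (KLDM) between length
  distributions — directed both ways on the zero-trimmed common support,
  plus the symmetric average — and the RMS difference of organelle TMD
  lengths from each species' plasma-membrane mean,
* a deterministic synthetic-sequence generator that plants hydrophobic
  helices of known extent, so the whole pipeline is testable against exact
  ground truth without any database access.

## Worked example

```python
from tmdscan import (ProteinRecord, Topology, compare_groups, detect,
                     group_summary, plant_tmd)

# a synthetic protein with a 23-residue helix planted between charged flanks
seq, truth = plant_tmd(23, 12, seed=7, record_id="demo")
rec = ProteinRecord("demo", seq, group="PM", topology=Topology.N_CYTO)
tmd = detect(rec)
print(f"span {tmd.span.start}-{tmd.span.end}, length {tmd.length}")
print("oriented:", tmd.oriented_sequence)

# published per-protein TMD lengths of viruses entering at the plasma
# membrane (PM) vs by clathrin-mediated endocytosis (CME)
s = group_summary([30, 28, 30, 25])
print(f"PM group: {s.mean:.2f} +- {s.sd:.2f} (n={s.n})")
comp = compare_groups([30, 28, 30, 25], [17, 5, 7, 15, 10], "PM", "CME")
print(f"Welch t={comp.t_stat:.2f}, p={comp.p_value:.4f}")
```

prints

```
span 13-35, length 23
oriented: LAFMMMMMMFFFFMMFMIFILVA
PM group: 28.25 +- 2.36 (n=4)
Welch t=6.77, p=0.0006
```

The detected span coincides exactly with the planted helix (positions
13–35), and the viral groups separate cleanly: plasma-membrane-fusing
viruses carry ~28-residue TMDs, endocytosed ones much shorter ones
(10.80 ± 5.12), with a significant Welch test despite the tiny samples.

## Command line

```sh
tmdscan simulate -n 100 --seed 1 --fasta-out sim.fasta \
    --annotations-out sim.tsv --truth-out truth.tsv
tmdscan scan sim.fasta sim.tsv --out tmd.tsv
tmdscan cluster sim.fasta sim.tsv --out clusters.tsv
tmdscan profile sim.fasta sim.tsv --profile-out profile.tsv
tmdscan compare tmd.tsv groupA groupB --out report.json
```

All commands are deterministic for fixed inputs; `-v` logs per-stage record
counts.

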