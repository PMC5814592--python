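# agmap

Genetic linkage maps for an outcrossing (cross-pollinated, CP) F1
population genotyped on a wheat SNP array, homoeologous-group assignment
of the resulting linkage groups against the hexaploid wheat genome, and
detection of alien chromosome addition/substitution lines from
heterozygosity and missingness profiles.

The package is aimed at people mapping wild wheat relatives — such as
*Agropyron* (P genome, chromosomes 1P–7P) — on arrays designed for
wheat, where no reference genome for the mapped species exists and the
interesting downstream products are wheat–alien introgression lines.

## What it computes

**Two-point CP linkage mapping.**  In an F1 of two heterozygous parents
only three segregation patterns are informative: `hkxhk` (AB x AB,
1:2:1), `lmxll` (AB x AA, paternal testcross) and `nnxnp` (AA x AB,
maternal testcross).  For every marker pair the recombination fraction r
and LOD = log10 L(r̂) − log10 L(½) are estimated by maximising the joint
likelihood of the two-locus genotype table over r and the parental
phase(s); for a same-parent testcross pair this is the closed form
r̂ = min(R, N−R)/N.  Markers join linkage groups by single linkage over
pairs with LOD > 11, groups are ordered by weighted 1D scaling of the
Kosambi distance matrix, adjacent gaps are refitted by composite maximum
likelihood over all pairs, and map positions are cumulative Kosambi
distances, d = 25·ln((1+2r)/(1−2r)) cM.  Male, female and integrated
maps are built from the pattern sets each meiosis supports.

**Homoeology and synteny.**  Marker-to-wheat alignment hits (e ≤ 1e-5)
assign each linkage group to the wheat homoeologous group (1–7, A/B/D
pooled) with the largest top-hit share; rank-monotone marker chains give
collinearity blocks, rearranged segments and small-fragment noise.

**Introgression calling.**  An added P chromosome inflates heterozygous
calls on its three wheat homoeologs; a substituted wheat chromosome
inflates missingness of its genome-specific markers.  Robust
median + 5·MAD thresholds across the 21 wheat chromosomes turn both
signals into deterministic addition/substitution calls with
Table-style labels ("6P/6D substitution line").

Since no array dataset of this design is publicly deposited, a fully
seeded synthetic-data module generates CP crosses, hit tables and a
35-line reference panel with known ground truth; the test suite consists
of recovery and calibration checks against that truth.  See
`docs/methods.md` for models, parameters and limitations.

## Worked example

```python
from agmap import LinkageMapper, MarkerQC
from agmap.simulate import SimCrossConfig, default_map_truth, simulate_cp_cross

truth = default_map_truth(seed=1)                    # 7 chromosomes x 100 markers
gm, sim = simulate_cp_cross(truth, SimCrossConfig(seed=2))  # 119 progeny
qc = MarkerQC().fit(gm)                              # categories, patterns, filters
mapper = LinkageMapper().fit(gm, qc_table=qc.table_)
print(mapper.maps_["integrated"].summary().round(2).to_string(index=False))
```

```
 lg  n_markers  n_loci  length_cM  mean_gap_cM  max_gap_cM  gap_le_5
  1         94      94      89.36         0.96        5.13      0.99
  2         94      94      69.66         0.75        8.73      0.98
  3         94      94      85.85         0.92        6.48      0.98
  4         94      94     130.25         1.40        7.91      0.95
  5         93      93     123.61         1.34       12.13      0.93
  6         89      89      82.39         0.94        6.47      0.98
  7         85      85      78.91         0.94        6.00      0.99
```

Seven linkage groups are recovered, one per simulated chromosome (the
group/chromosome pairing is confirmed by the homoeology stage).  Each
row gives the marker and locus counts, the map length in cM, the mean
and maximum adjacent-locus gaps, and `gap_le_5`, the fraction of
adjacent gaps of at most 5 cM (a map-saturation measure).

The same run from the shell, including hit-table anchoring and the
35-line introgression panel:

```bash
agmap all --out-dir run1 --seed 1
```

which ends with artifacts such as `map_integrated.tsv`,
`homoeology_assignments.tsv` (LG4 assigned to group 4 with its
group-2 ambiguity flagged, mirroring a 4P/2P rearrangement) and
`introgression_report.tsv`, whose rows read e.g.

```
line_id  composition  added_P  missing_chromosome  identification
4844-8   40W + 2P     6P       6D                  6P/6D substitution line
II-3-1   40W + 4P     1P+2P    1A                  2P addition and 1P/1A substitution line
```

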