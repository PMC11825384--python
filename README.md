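# shapemut

Shape- and base-readout aware design of DNA point mutations.

Proteins recognize their DNA binding sites through two biophysical modes:
**base readout** — direct contacts (hydrogen bonds, hydrophobic
interactions) with the chemical groups on base edges — and **shape
readout** — recognition of the sequence-dependent 3D structure of the
double helix, such as minor-groove narrowing and its enhanced negative
electrostatic potential. A point mutation can therefore change binding in
two distinct ways, and designing oligos for binding-site optimization,
synthetic enhancers, or shape-preference experiments requires tracking
both axes at once. `shapemut` is a small library + CLI for exactly that:
it enumerates every substitution candidate of a wild-type sequence at up
to seven chosen positions (4^m candidates, up to 4^7 = 16384) and scores
each candidate's distance from the wild type along both axes.

## Model

**Base readout.** Each base pair presents four functional groups on its
major-groove edge and three on its minor-groove edge (hydrogen-bond
acceptor `A`, donor `D`, nonpolar hydrogen `H`, methyl `M`), read 5'→3'
along the reference strand: A:T reads major `[A, D, A, M]`, minor
`[A, H, A]`; G:C reads major `[A, A, D, H]`, minor `[A, D, A]`; a
complementary base reads the reversed lists. Encoding each group as a
length-4 one-hot gives a 16-slot major vector and a 12-slot minor vector
per base pair. The default base distance is the position-wise L1
difference of these 28-slot vectors summed along the sequence; per
substitution it is 6 (A↔C, G↔T) or 8 (all other substitution types),
reflecting how much edge chemistry actually changes. One-hot distance
(2 × Hamming) and Levenshtein edit distance are available alternatives.

**Shape readout.** A pluggable predictor maps a sequence of length *n* to
14 structural feature vectors: 6 base-pair-step parameters (Shift, Slide,
Rise, Tilt, Roll, HelT; length *n* − 1), 6 intra-base-pair parameters
(Shear, Stretch, Stagger, Buckle, ProT, Opening; length *n*), and 2
minor-groove features (MGW, EP; length *n*). The bundled backend is a
k-mer central-value lookup table (the classical pentamer-table family); a
seeded synthetic-table generator provides deterministic,
reverse-complement-consistent backends for testing and demos. The shape
distance between wild type and candidate is either Euclidean
(√Σ(Δvalue)², optionally z-scored per feature over the candidate
ensemble) or Pearson (1 − *r* per feature, averaged; insensitive to
constant offsets — preserves *pattern* rather than absolute values), and
can be restricted to **focal positions**, e.g. the spacer between
cooperative binding sites.

Results are ranked deterministically and a 2-D Pareto front (fewest edits
vs largest/smallest shape change) is available.

## Worked example

```bash
shapemut --seq ACGGTTACAGGTAACCGTAC --positions 6,9 \
         --features MGW,EP --synthetic-seed 13 \
         --out demo.tsv --pareto max
```

prints

```
scored 16 candidates (physchem base metric, euclidean shape metric over MGW,EP) in 0.01 s -> demo.tsv
```

and `demo.tsv` begins (after a `#` provenance header echoing the
configuration):

```
sequence              substitutions  base_distance  shape_distance  shape_d_MGW  shape_d_EP  is_wildtype  rank
ACGGTTACGGGTAACCGTAC  9:A>G          8.000000       7.989038        4.048195     6.887441    0            1
ACGGTGACGGGTAACCGTAC  6:T>G;9:A>G    14.000000      7.347206        4.939074     5.439392    0            2
ACGGTCACGGGTAACCGTAC  6:T>C;9:A>G    16.000000      7.203493        5.388053     4.781129    0            3
```

Reading the top row: the single substitution A→G at position 9 changes
the functional-group encoding by 8 (base readout) and the pooled MGW+EP
profile by 7.99 z-score units (shape readout) — the largest shape
perturbation of all 16 candidates, achieved with one edit, so it heads
the Pareto front written to `demo.pareto.tsv`. The wild type appears in
the table flagged `is_wildtype = 1` with both distances 0.

The same run is available programmatically via
`shapemut.run_design(wt, MutationSpec([6, 9]), DistanceConfig(...),
table)`, and `shapemut-demo --name focal_spacer --seed 1 --out-dir d/`
writes a complete scripted scenario (inputs, table, ranked results,
Pareto front) to a directory.

User-supplied predictor tables are plain TSV — header
`kmer<TAB>feature...`, one row per k-mer — so published pentamer shape
tables can be dropped in directly; `--table file.tsv` replaces
`--synthetic-seed`.

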