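# pdzscan

Comparative sequence analysis of PDZ-domain ligand specificity, built around
the question of how deeply conserved the interaction between the scaffolding
protein Mint and the C-terminus of Ca_V_2 voltage-gated calcium channels is
across animals. The package turns the individual comparative analyses behind
that question into one tested, reusable pipeline:

- **Alignment handling** — FASTA alignments, trimAl-style gap-threshold
  column trimming (a column is kept when its non-gap fraction ≥ gt), and
  Plotcon-style windowed similarity profiles (default window 11, BLOSUM62).
- **Specificity-residue identity matrices** — symmetric percent-identity
  matrices over a reference-anchored residue subset (e.g. the 17 positions in
  the β2/β3 strands and α2 helix of the PDZ ligand-binding groove) and over
  whole domains, with shared-specificity classification at the 70% (subset)
  and 50% (full-domain) identity thresholds.
- **C-terminal SLiM classification** — extraction of C-terminal peptides
  (position 0 = final residue) and assignment to ligand classes:
  `DDWC_like` (W at −1, C at 0), canonical `type_I` (X-[S/T]-X-Φ),
  `W_minus1_other`, and `other`; consensus motifs and motif-presence tables.
- **2-hybrid screen statistics** — colony-weighted hit-table totals, suffix
  and terminal-residue counts, prey ranking; two transcribed example screens
  ship as packaged fixtures.
- **Peptide-library logos** — position frequency matrices, information
  content in bits, and ligand-signature strings such as `GxWV` or `WV` from
  fixed-register hexamer libraries.
- **Metacell co-expression** — binary expression calls, 3-gene Venn
  partitions, conditional co-expression percentages, and positive-control
  calibration.
- **Reporter assays** — β-galactosidase activity, normalization to a
  positive-control interaction, Welch and paired t-tests.
- **Synthetic data** — seeded generators with ground-truth records for every
  stage, so the whole pipeline is exercised without downloads.

## Worked example

The packaged screen tables come from yeast 2-hybrid screens of a placozoan
prey library against (A) a tandem PDZ-1/PDZ-2/P1BM Mint bait and (B) the
PDZ-1 domain alone:

```pycon
>>> from pdzscan import reproduce_table1_stats
>>> reproduce_table1_stats()
{'screen_A': {'total_hits': 12, 'non_terminal_V': 3,
              'top_two_colony_counts': [4, 2]},
 'screen_B': {'total_hits': 32, 'top_colony_count': 17,
              'wv_suffix_hits': 6, 'terminal_I_prey_excluding_top': 2}}
```

Screen A recovered 12 colony-weighted hits, all but 3 ending in valine, the
two strongest prey yielding 4 and 2 colonies; screen B recovered 32 hits
dominated by one prey with 17 colonies, with 6 hits ending in `WV` (a W at
position −1 coupled to a terminal valine) and, excluding that top prey, 2
further prey ending in isoleucine.

Ligand classification follows the position convention 0 = final residue:

```pycon
>>> from pdzscan import Sequence, extract_cterminus, classify_ligand
>>> classify_ligand(extract_cterminus(Sequence("TCav2", "MSKCTAV"), 4)).ligand_class
<LigandClass.TYPE_I: 'type_I'>
>>> classify_ligand(extract_cterminus(Sequence("NCav2c", "FDNDEETWC"), 4)).ligand_class
<LigandClass.DDWC_LIKE: 'DDWC_like'>
```

`ETWC` carries both a W/C ending and a threonine at −2; the documented
precedence groups it with the non-canonical W/C ligands. A planted-motif
library demonstrates the logo stack:

```pycon
>>> from pdzscan import build_pfm, signature
>>> from pdzscan.simulate import gen_peptide_library
>>> table, truth = gen_peptide_library(planted={-3: "G", -1: "W", 0: "V"},
...                                    enrichment_factor=10, seed=1)
>>> str(signature(build_pfm(table)))
'GxWV'
```

A command-line entry point `pdz-evoscan` exposes the same operations
(`trim`, `sweep`, `simplot`, `classify-slim`, `screen-stats`, `logo`,
`coexpr`, `betagal`, `simulate`, `run --config`, `table1`).

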