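# lectevo

Tracing lectin evolution with region-grafted ancestral mutants: a tested
pipeline for chimeric sequence construction, loop hydropathy scoring,
thermostability estimation, glycan-binding specificity analysis, and
MD hydrogen-bond cooperativity networks.

## What it does

- **`lectevo.sequences`** — grafts named regions (N/C-termini, loops) from a
  donor onto a base sequence on a shared reference numbering, diffs
  sequences into `E5Q`-style substitution lists, and scores loop segments
  with summed Kyte–Doolittle hydropathy.
- **`lectevo.thermo`** — converts hemagglutination titers (two-fold dilution
  steps vs an unheated control) into residual-activity curves and reads off
  the half-activity retention temperature T_m by linear interpolation at the
  0.5 crossing (optionally isotonic-smoothed).
- **`lectevo.binding`** — frontal-affinity-chromatography K_d tables with
  explicit no-binding cells; relative binding activities
  K_d(reference)/K_d(lectin), presentation-rounded ratio columns, sugar-pair
  specificity ratios computed from raw K_d cells, structural-motif
  attribution of specificity shifts, binding gain/loss calls, and a
  reconciliation report against a pre-rounded printed table.
- **`lectevo.hbnet`** — geometric H-bond detection on toy trajectories
  (distance ≤ 3.5 Å, donor-H…acceptor angle ≥ 120°, both configurable),
  overall formation rates, a 10–90 % informative-bond filter, 200-ps binned
  formation rates, Pearson correlation of bin-rate vectors, and
  within/between-group averaging into a signed cooperativity network.
- **`lectevo.synthetic`** — seeded generators with ground truth: latent
  factor-driven binary occupancy, logistic inactivation curves, K_d tables
  with planted region effects, and toy multi-model trajectories whose
  donor–acceptor distances follow exact schedules.
- **`lectevo.io` / `lectevo.pipeline` / `lectevo.cli`** — FASTA/CSV/TSV/PDB/
  GraphML readers and writers, packaged fixtures, and a click CLI.

## CLI

```bash
lectevo hydropathy LNSMVNS                       # -> 1.3
lectevo graft --graft NT,CT                      # chimera + substitution list
lectevo simulate --kind curves --out-dir out/    # synthetic fixtures + truth
lectevo tm out/curves.csv                        # half-activity temperatures
lectevo bindcompare --lectin Con-anc-N/C/L5 --pair 44/42
lectevo hbnet --occupancy occ.tsv --out-dir net/ # correlation network
lectevo run --out-dir demo/ --seed 1             # full pipeline over fixtures
```

All stages are deterministic given the config seed; reruns produce
byte-identical outputs.

## Data fixtures

`src/lectevo/data/` ships the K_d fixture table (with printed ratio columns
for reconciliation), glycan structural-motif annotations, the region map,
the Kyte–Doolittle scale, and a gapped alignment fixture. The alignment
sequences are constraint-consistent stand-ins (the primary-source alignment
figure is not machine-readable); every test reads regions from the config
rather than hard-coding boundaries.
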