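# lamshift

Analysis toolkit for nuclear-envelope-directed gene repositioning in muscle
differentiation. During myogenesis (myoblast MB -> myotube MT), specific
nuclear envelope transmembrane proteins (NETs) tether genomic loci to the
nuclear periphery; DamID against lamin B1 maps those contacts genome-wide,
and FISH measures radial position in single nuclei. `lamshift` implements
the full computational chain for this kind of study:

- **DamID core** — in-silico DpnI digestion (GATC fragment maps), read
  counting, per-fragment `log2(LaminB1 Dam / soluble Dam)` tracks, running
  100-kb window statistics, and windowed per-gene MT-MB scores.
- **Lamina domains** — LAD segmentation per condition (2-state Gaussian
  HMM on binned ratios), LAD-sharing coverage statistics, and a caller for
  regions that significantly change lamina association between MB and MT:
  windows with a mean MT-MB difference of at least 2-fold
  (|Δlog2| ≥ 1) are tested against randomized fragment sets with Fisher's
  exact test over 1,000 iterations, and regions with p > 0.01 are
  discarded. Gaining regions are labeled IP (interior -> periphery),
  losing regions PI.
- **Expression statistics** — quantile normalization, empirical-Bayes
  moderated t/F statistics (limma-style variance shrinkage), BH FDR, and
  the |log2FC| > 0.5 at FDR ≤ 5% call rule, plus a 1.4-fold classifier of
  condition means.
- **Integration** — gene-to-region assignment, the IP↔repression /
  PI↔activation concordance 2×2 χ² test, KS comparison of effect
  magnitudes, and knockdown gene-set overlap summaries.
- **Radial imaging** — partition of a nucleus midplane mask into five
  concentric shells of exactly equal area (area-quantiles of the interior
  distance transform; shell 1 peripheral), gene-spot shell assignment,
  per-shell chromosome-territory intensity profiles, population χ²/KS
  comparisons, and distance-to-compartment ECDFs.
- **Synthetic data** — seeded generators for genomes, planted LAD/shift
  architectures, two-condition DamID counts (negative binomial),
  replicated expression matrices with a planted position-expression
  concordance, and nucleus images with spots at controlled radial
  positions. Every planted quantity is recorded so the callers can be
  scored against ground truth.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

Run the whole synthetic-to-report pipeline from one seed:

```bash
cat > cfg.yaml <<EOF
n_chrom: 2
chrom_length: 5000000
shared_fraction: 1.0
n_lads: 5
n_ip: 2
n_pi: 2
n_genes: 300
n_iter: 100
n_cells: 6
depth: 2.0
EOF
lamshift simulate    --seed 7 --config cfg.yaml --outdir work
lamshift call-lads   --counts work/counts.tsv --config cfg.yaml --outdir work
lamshift call-shifts --counts work/counts.tsv --config cfg.yaml --seed 7 --outdir work
lamshift de          --expr work/expression.tsv --out work/de.tsv
lamshift integrate   --shifts work/shifts.tsv --de work/de.tsv --genes work/genes.bed --outdir work
lamshift radial      --cells work/cells --outdir work
lamshift report      --dir work
cat work/report.md
```

which prints:

```
# Pipeline report

- shared LAD coverage: 0.533
- IP regions: 2, PI regions: 2
- position-expression concordance: 0.700 (chi2 p = 0.00485)
- radial MB vs MT chi2 p = 0.00738
```

Reading: the caller found exactly the 2 planted IP and 2 planted PI
regions (`work/shifts.tsv` lists their coordinates, mean Δlog2 close to
the planted ±1.2, and empirical p-values), 70% of the genes inside those
regions changed expression opposite to their repositioning direction (the
planted concordance is 70%), the association is significant, and the
simulated MT nuclei show significantly more peripheral spots than MB
nuclei. Shared LAD coverage is low in this toy run because on a 10 Mb
genome the planted shift regions — which are genuine MB/MT differences in
lamina association — are a large fraction of all lamina-associated
territory. The same artifacts (BED/bedGraph/TSV/JSON) are produced at any
scale, and a rerun with the same seed reproduces every file byte for byte.

The Python API mirrors the CLI: `make_genome`, `plant_architecture`,
`simulate_damid_counts`, `call_shift_regions`, `moderated_stat`,
`concordance_test`, `shell_partition`, and so on, all importable from
`lamshift`.

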