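# porecology

Quantitative analysis toolkit for biofilm development and microbial
community assembly in porous microfluidic habitats.  It bundles the six
analysis stages of a chip-to-community workflow — image-based biofilm
morphometrics, colloid residence-time moment analysis, qPCR compartment
partitioning, rule-based interaction classification, phylogenetic
null-model assembly inference, and exometabolite trend analysis — together
with a synthetic-data module that generates every input with known ground
truth, so the whole pipeline is testable without any external download.

## Modules

| module | what it does |
| --- | --- |
| `porecology.synth` | seeded generators: grain scenes (TIFF), breakthrough curves, qPCR tables, community series (TSV + Newick), co-culture yields, metabolite trajectories — each with analytic ground truth |
| `porecology.imaging` | binarization, grain detection, radial ray-cast thickness profiles, per-grain mean thickness / roughness, genus area fractions |
| `porecology.transport` | mean travel time (first normalized temporal moment of a breakthrough curve), group comparison via Welch/Student t-test |
| `porecology.quantify` | qPCR standard curves and efficiencies, Cq → copies, planktonic/biofilm compartment partitioning, logistic growth fits |
| `porecology.interactions` | co-culture and conditioned-medium interaction classification, compartment frequency metrics with signed-rank tests |
| `porecology.assembly` | phylogenetic binning, betaNRI (taxa-shuffle null), modified Raup–Crick metric, five-process partitioning (HoS/HeS/HD/DL/DR), Bray–Curtis succession trends |
| `porecology.metabolome` | z-scoring, Spearman trend classification (released / consumed / other), cross-table correlation screening, Procrustes concordance |
| `porecology.pipeline` / `porecology.cli` | config-driven orchestration, deterministic seed fan-out, manifests, end-to-end demo |

## CLI

```bash
# full synthetic end-to-end run (deterministic given --seed)
porecology demo --seed 7 --out demo_run

# generate the synthetic input set only
porecology synth --out inputs --seed 7

# individual stages on file inputs
porecology imaging   --input inputs/scenes --layout inputs/layout.csv --out run
porecology transport --curves inputs/curves/pristine_0.csv --out run
porecology quantify  --standards inputs/qpcr_standards.csv --samples inputs/qpcr_samples.csv --vchip 3.0 --out run
porecology interactions --coculture inputs/coculture.csv --out run
porecology assembly  --table inputs/asv_neutral.tsv --tree inputs/tree_neutral.nwk --meta inputs/samples_neutral.csv --nulls 1000 --seed 7 --out run
porecology metabolome --peaks inputs/peaks.csv --out run

# config-driven multi-stage run
porecology run --config config.yaml --out run
```

A run directory contains one subdirectory of CSV outputs per stage plus a
`manifest.json` recording version, parameters, per-stage seeds and
statuses.  Re-running with the same seed reproduces every output
byte-for-byte.

Example `config.yaml`:

```yaml
seed: 7
stages:
  synth: {}
  imaging: {angles: 360}
  transport: {}
  quantify: {vchip: 3.0}
  interactions: {}
  assembly: {nulls: 1000, d_max: 0.2, min_bin_size: 12}
  metabolome: {r_min: 0.5, alpha: 0.05}
```

Stages omit their file inputs to consume the synthetic set written by the
`synth` stage; supply explicit paths to analyze your own data.

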