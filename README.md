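# sugarmap

Reconstruction of bacterial sugar utilization machinery as a tested,
end-to-end pipeline: family-based homology scanning, genome-context analysis
(operon clusters, phyletic co-occurrence), regulon inference by iterative
PWM discovery with a minimum-training-score threshold and a cross-genome
conservation filter, all-components pathway presence calling, and
predicted-vs-observed growth-phenotype concordance.

Because the original 19-genome panel is not redistributable at desk scale,
the package ships two complementary data paths:

- **Packaged fixtures** (`sugarmap/data/*.tsv`) transcribing the published
  family registry (170 isofunctional families across 17 pathways + central
  carbon metabolism), the 19-genome summary table, and the 14 strain x 12
  substrate growth-phenotype matrix.
- **A synthetic panel generator** (`sugarmap.simulate`) that plants homolog
  families at controlled identity, compact operons, regulator binding sites
  drawn from a ground-truth PWM, mosaic pathway presence, and pseudogene
  lesions (frameshift / insertion element) — with machine-readable truth, so
  every inference stage is tested by parameter recovery.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: exact fixture
arithmetic, the Smith-Waterman-vs-enumeration oracle, the threshold-recall
law, planted-motif parameter recovery over 20 seeds, conservation-filter and
BBH properties, the operon-caller oracle, and end-to-end truth recovery on a
10-genome panel at 60% identity with planted pseudogenes.

## CLI

```bash
sugarmap registry-summary              # family registry totals as JSON
sugarmap phenotype                     # growth counts + concordance of the fixture
sugarmap simulate --outdir out --seed 1
sugarmap run-all  --config cfg.yaml --outdir out --seed 1
sugarmap report   --outdir out
```

A pipeline config is a small YAML file:

```yaml
n_genomes: 10
pathways: {SynA: 3, SynB: 3}
scenario: {SynA: [0,1,2,3,4,5,6,7,8,9], SynB: [0,2,4,6,8]}
identity_target: 0.6
pseudogenes: [[0, SynA_r0, frameshift]]
seed: 1
```

Exit codes: 0 ok, 1 validation error, 2 runtime error. Re-running with the
same config and seed reproduces byte-identical outputs.

## Layout

```
src/sugarmap/
  registry.py    packaged fixtures: families, pathways, genomes, phenotypes
  simulate.py    seeded synthetic panels + truth tables
  homology.py    Smith-Waterman scanning, BBH orthology, phyletic profiles
  context.py     operon clustering, coupling scores, gap-filler ranking
  regulon.py     PWM model, motif discovery, scanning, conservation filter
  pathways.py    role assignment, presence/impaired/absent calls, audits
  phenotype.py   growth prediction and concordance scoring
  pipeline.py    stage orchestration; cli.py exposes the `sugarmap` command
```
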