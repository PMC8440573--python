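# soilweb

Soil trophic-network analysis toolkit. Starting from taxa inventories
(plot × taxon presence with read counts) and a knowledge base of pairwise
biotic interactions, it:

1. **builds a metaweb** of potential resource→consumer interactions —
   deduplication with evidence-rank precedence, generalization of genus/
   family-level records to observed member taxa, trimming by soil-layer
   co-occurrence and geographic range (`soilweb.metaweb`);
2. **infers trophic groups** by fitting a directed Bernoulli stochastic
   block model with variational EM and selecting the group count by the
   Integrated Complete-data Likelihood criterion (`soilweb.sbm`);
3. **computes food-web indices** per local (plot-level) web at taxa and
   group level: richness, group richness/entropy (Hill framework), average
   degree, trophic levels and omnivory, link density, path lengths,
   % parasitic links, and bacterial:fungal / detritivore:herbivore energy
   channel ratios (`soilweb.netmetrics`);
4. **quantifies network turnover** between webs with Hill-number node
   β-diversity (orders 0/1/2), PCoA ordination and a permutation pseudo-F
   test (`soilweb.beta`);
5. **relates metrics to land-use intensity**: a PCA-based multicriteria
   intensity index and per-metric mixed models `metric ~ LUI + (1|site)`
   with standardized effect sizes (`soilweb.luistats`).

A synthetic scenario generator (`soilweb.synth`) produces all pipeline
inputs with known ground truth — planted block structure, guild labels,
LUI-dependent taxon loss, lognormal read counts and management criteria
correlated with a latent intensity axis — so the whole pipeline is testable
without external data.

## CLI

```bash
# generate a synthetic scenario, then run everything
soilweb simulate --workdir run1 --seed 7
soilweb run-all  --workdir run1

# or stage by stage
soilweb build-metaweb --workdir run1
soilweb fit-sbm       --workdir run1
soilweb metrics       --workdir run1
soilweb beta          --workdir run1
soilweb lui           --workdir run1
soilweb stats         --workdir run1
soilweb report        --workdir run1
```

Inputs are TSV tables under `<workdir>/inputs/` (taxonomy, annotations,
interactions, observations, design, criteria); artifacts appear under
`<workdir>/outputs/` as CSV/TSV/JSON/GraphML plus a `manifest.json` with
sha256 hashes of every file. Runs are byte-identical under fixed seeds.

## Tests

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the end-to-end acceptance criteria
(metric-oracle equivalence, SBM recovery against planted and exhaustive
oracles, Hill/PCoA closed forms, permutation-test and mixed-model
calibration, filter set-algebra, pipeline determinism and planted
direction-of-effect recovery).

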