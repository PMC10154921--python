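# traitnet

Trait co-occurrence networks for ecological response diversity: build them
from community data, measure their complexity, and test how an
experimental stressor erodes them.

## The problem

A community's capacity to absorb stress depends not just on how many
species it holds but on the *response diversity* hidden in their biological
traits: how many different resistance and recovery strategies back up each
ecosystem-regulating function. `traitnet` implements a network view of
this idea for multi-site field experiments on (for example) benthic
macroinvertebrate communities. Trait modalities — discrete trait levels
such as a feeding mode, each labelled as ecosystem-regulating (`REG`),
recovery-enhancing/-inhibiting (`REC_e`/`REC_i`) or
resistance-enhancing/-inhibiting (`RES_e`/`RES_i`) — are the network's
nodes. Two modalities are connected when the species that bear them
overlap more than trivially, and the number of sharing species is the
connection's strength: the "options" the community has for keeping a
function running when species are lost.

## The model

For one community of `N` species in which `N_i` species bear modality `i`
and `N_j` bear modality `j`, the null placement of modality membership is
hypergeometric; the number `q` of species bearing both has

    P(q) = C(N_i, q) C(N - N_i, N_j - q) / C(N, N_j),
    E[q] = N_i N_j / N.

Pairs with expected co-occurrence `E < 1` carry no response diversity and
are filtered out, as are pairs never observed together (`Q_obs = 0`). Each
retained pair becomes an edge of weight `Q_obs` in that community's trait
network. Five metrics summarize each network: node count, connection
count, `REG~REC_e` and `REG~RES_e` connection counts, and mean node
eigencentrality. Eigencentrality is scored on a single pooled graph
containing every site-treatment network as a disconnected component, so
scores are comparable across communities; the mean over a control
network's nodes is that site's *baseline network complexity*.

The stress analysis works on effect sizes `metric(treatment) /
metric(control)` per site: one- and two-sample t-tests for directional
shifts, and linear quantile regression of effect size on baseline
complexity at taus 0.1–0.9 (exact pinball-loss minimization via linear
programming). A shrinking 90th–10th inter-quantile spread with rising
baseline complexity — converging quantile lines — is the signature of
more predictable stress responses in more complex networks.

A seeded generator (`traitnet.synthetic_data`) emulates the study design
the analysis expects: 24 sites × 3 treatments (control, medium, high
enrichment) × 3 plots, 19–48 taxa per site, a latent cross-site complexity
gradient, and treatment-dependent species loss whose cross-site
variability decays with complexity.

## Worked example

```python
from traitnet import PipelineConfig, run_pipeline

cfg = PipelineConfig(synthetic=True, seed=1, out_dir="demo")
bundle = run_pipeline(cfg)
print(bundle.metrics.head(3).to_string(index=False))
```

```
site treatment  n_nodes  n_connections  n_reg_rece  n_reg_rese  mean_eigencentrality
 S01   control       24            108          14          13              0.276889
 S01      high       15             42           7           8              0.169346
 S01    medium       27            130          15          15              0.300085
```

Site S01's control community supports a 24-node trait network with 108
connections; high enrichment strips it to 15 nodes and 42 connections
(effect sizes 0.62 and 0.39), while medium enrichment slightly *enhances*
it — both realistic outcomes. Across all 24 sites the run's `report.txt`
shows the aggregate picture:

```
baseline network complexity (control mean eigencentrality): 0.277-0.739 across 24 sites
networks built: 72

t-tests on effect sizes (vs control = 1):
  n_connections   medium_vs_control  t=-2.328  p=0.02905
  n_connections   high_vs_control    t=-11.467  p=0.00000
  n_connections   medium_vs_high     t=+6.949  p=0.00000
  ...

quantile-spread convergence (positive difference = converging):
  n_nodes         spread 0.562 -> 0.116  (difference +0.446)
  n_connections   spread 0.794 -> 0.248  (difference +0.545)
```

High enrichment significantly reduces every metric (p ≪ 0.001), medium
responses are weaker and mixed in sign, and the 90th–10th quantile spread
of effect sizes shrinks by roughly half to three quarters from the least
to the most complex baseline networks.

The same run is available from the shell:

```sh
traitnet run --synthetic --seed 1 --out demo
traitnet simulate --seed 1 --out demo-inputs   # just the input files
```

Field data enter through two CSVs (see `traitnet.trait_data`): a trait
table (taxa × modalities, with a `#category` metadata row) and a long-form
community table (`site,treatment,plot,taxon,count`), passed as
`trait_path`/`community_path` in the config.

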