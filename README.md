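# densecon

Dense statistical connectomes from sparse morphological data.

Complete synaptic wiring diagrams of whole brain regions cannot be measured
directly: electron microscopy covers fractions of a cubic millimeter, and
paired recordings reach only a handful of nearby cells.  `densecon`
implements the alternative of *statistical* connectomics: sparse samples of
registered 3D neuron reconstructions are up-scaled into an average dense
model of a region (here modeled after rat vibrissal cortex with its barrel
columns), and connectivity is then *measured inside the model* from
axo-dendritic overlap — a quantitative form of Peters' rule in which every
bouton competes for all postsynaptic targets present in its voxel, not just
the targets of one stained cell.

It is aimed at quantitative neuroanatomists and modelers who have (i) a
region geometry (columns, layers, local vertical axes), (ii) 3D soma
density fields, (iii) labeled SWC reconstructions per cell type, and
(iv) bouton/spine/surface density measurements, and who want pairwise
connection probabilities, synapse-count distributions, population
convergence/divergence, and triplet-motif spectra.

## The model

All quantities live on a voxel grid (default 50 µm, the registration
precision of the reference frame).  For presynaptic neuron *i* and
postsynaptic neuron *j*:

- axon length per voxel × cell-type- and layer-specific bouton density
  gives the bouton field *B_i*(x);
- dendrite/soma length and surface per voxel × the meta-connectivity
  densities λ (spines per µm) and α (PSTs per µm²) give the
  postsynaptic-target field PST_j(x, T(i)) = Σ_L l_{j,L} λ + Σ_L a_{j,L} α;
- within a voxel every PST is equally likely to capture any bouton, so
  p_j(x) = PST_j(x) / PST_all(x), with PST_all summed over **all** neurons;
- the expected synapse count is Ĩ_ij(x) = B_i(x)·p_j(x), its voxel sum
  I_ij is the entry of the innervation matrix, synapse numbers follow
  Poisson(I_ij), and the pair connection probability is
  p_ij = 1 − exp(−I_ij).

Population statistics (convergence C_b = ⟨p_ab⟩, divergence D_a,
P_AB = ⟨p_ab⟩, n_AB = ⟨Poisson(I_ab)⟩) and triplet-motif spectra (64
directed edge configurations on three nodes, reduced to 16 isomorphism
classes) are derived from the matrix.  Unknown surface-PST densities α can
be fitted from the bouton/PST balance collapsed to depth profiles
(nonnegative least squares).

## Worked example

No laboratory dataset ships with the package; the `densecon.fixtures`
module generates a complete synthetic input bundle (reference frame, soma
densities, SWC library, meta-connectivity) at toy scale:

```python
import numpy as np
from densecon.fixtures import FixtureConfig, make_input_bundle, make_meta
from densecon.assembly import build_network
from densecon.innervation import pairwise_innervation
from densecon.population_stats import population_summary

cfg = FixtureConfig(dims=(8, 8, 4), seed=1)
bundle = make_input_bundle(cfg)
meta = make_meta(cfg)
network = build_network(bundle, seed=2)

pre = network.select(cell_type="TC", column_id="C0")    # long-range axons
post = network.select(cell_type="L4SS", column_id="C0")  # polar dendrites
matrix = pairwise_innervation(network, pre, post, meta)
stats = population_summary(matrix)
print(f"P_AB = {stats.p_ab:.3f}")
print(f"convergence = {stats.convergence_mean:.3f} +/- {stats.convergence_sd:.3f}")
```

which prints

```
P_AB = 0.765
convergence = 0.765 +/- 0.144
```

i.e., in this 256-neuron toy model a given thalamocortical axon connects
to a given layer-4 spiny-stellate cell with probability 0.765, and each
L4SS neuron receives input from 76.5 % ± 14.4 % of the thalamocortical
axons (mean ± SD across postsynaptic cells).  Toy-scale probabilities are
high because only a few hundred neurons compete for each bouton; in a
full-scale model the competing target pool is four orders of magnitude
larger and pairwise probabilities drop below 0.5.

Single-pair arithmetic works directly:

```python
from densecon.innervation import connection_probability, synapse_count_distribution
connection_probability(0.66)          # 0.483...
synapse_count_distribution(0.66)[:2]  # P(0 synapses)=0.517, P(1)=0.341
```

The same workflow is scriptable from the shell:

```bash
densecon fixtures --out bundle/
densecon build --bundle bundle/ --seed 2 --out net.h5
densecon innervate --network net.h5 --meta bundle/meta.csv \
    --pre TC,C0 --post L4SS,C0 --out mat.h5
densecon motifs --matrix mat.h5 --triplets 100 --repeats 10 --seed 3 \
    --out motifs.csv
```

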