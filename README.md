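# lirio

Analysis toolkit for a recurring question in plant comparative genomics:
when a newly sequenced genome sits near the base of the Mesangiospermae —
as magnoliid genomes such as *Liriodendron* do — which of the three
possible arrangements of **eudicots**, **monocots** and **magnoliids** does
each gene actually support, and what else does the genome record about its
history?  `lirio` implements the full analytical core of such a study as a
reusable, simulation-validated pipeline:

* **Gene-wise topology conflict (ΔGLS).**  Orthogroups are filtered to
  low-copy, clade-complete sets, then each gene alignment is scored under
  three fixed species-tree hypotheses with a Felsenstein-pruning
  likelihood engine (JC69/HKY/GTR/WAG, discrete-Γ rates, per-branch
  optimization).  The difference in gene-wise log-likelihood scores,
  ΔGLS(i,j) = lnL_i − lnL_j, assigns each gene to the hypothesis it
  supports; Tukey fences remove ΔGLS outliers; a Pearson χ² test asks
  whether support is spread uniformly — the signature of ancient rapid
  divergence.
* **Whole-genome-duplication and LTR dating.**  NG86 Ks/Ka with pathway
  averaging and Jukes–Cantor correction, 4DTv, node-weighted paranome Ks
  distributions, kernel-density peak detection, and age conversion
  T = Ks / (2r).
* **Syntenic depth.**  Collinear-block chaining of homologous anchor
  pairs (longest collinear subsequence with a gap cap, ≥ 5 pairs per
  block) and modal depth ratios (2:1 after one WGD; 3:1 / 3:2 for
  triplicated-versus-unduplicated/duplicated comparisons).
* **Population diversity.**  π, Watterson's θw, Hudson's FST
  (ratio-of-sums) and neighbour-joining grouping from SNP matrices.
* **Synthetic data.**  Every input the pipeline consumes can be generated
  in-package with known ground truth: gene sets evolved under a topology
  mixture, coalescent SNP matrices (msprime), paranomes with planted WGD
  peaks, and post-WGD gene orders with partial duplicate retention.

## Worked example

Score a simulated 60-gene orthogroup set against the three hypotheses,
then date a planted WGD peak:

```python
from lirio.conflict import (build_hypotheses, delta_gls,
                            gene_topology_likelihoods, Orthogroup,
                            support_counts)
from lirio.models import jc69
from lirio.synthetic import simulate_gene_set, simulate_paranome
from lirio.wgd import KsDistribution, ks_density_peaks, ks_to_age
import numpy as np

clades = {"eudicot": ["eud0", "eud1", "eud2", "eud3"],
          "monocot": ["mon0", "mon1", "mon2", "mon3"],
          "magnoliid": ["mag0", "mag1", "mag2"],
          "basal_angiosperm": ["amb0"], "gymnosperm": ["gym0"]}
hyps = build_hypotheses(clades)
model = jc69()
genes = simulate_gene_set(hyps, (1/3, 1/3, 1/3), n_genes=60, length=300,
                          internal_length=0.05, terminal_length=0.2,
                          model=model, seed=1)
results = []
for i, aln in enumerate(genes.alignments):
    og = Orthogroup(f"og{i}", {n: [n] for n in aln.names}, aln)
    results.append(delta_gls(gene_topology_likelihoods(og, hyps, model),
                             orthogroup_id=og.id))
sc = support_counts(results)
print(sc.counts, sc.percentages, round(sc.chi2, 4), round(sc.p, 4))

par = simulate_paranome(1000, 500, wgd_mean=0.7, wgd_sd=0.08, seed=1)
dist = KsDistribution(par.ks_values, np.ones(par.ks_values.size))
peak = ks_density_peaks(dist)[0][0]
print(round(peak, 3), round(ks_to_age(peak, 3.02e-9).ma, 1))
```

This prints

```
(20, 19, 21) (33.33, 31.67, 35.0) 0.1 0.9512
0.683 113.1
```

— 60 genes split nearly evenly across the three topologies (χ² = 0.1,
P = 0.95, no significant winner, exactly the pattern expected when the
three lineages separated in rapid succession), and a paranome Ks peak at
0.683 that converts to a duplication age of ~113 Ma at a synonymous rate
of 3.02 × 10⁻⁹ substitutions · site⁻¹ · yr⁻¹.

The same stages run from the shell against one YAML config:

```bash
lirio all --config run.yaml        # or: conflict | wgd | synteny | popgen
```

Each run writes per-stage TSV/JSON outputs plus a manifest with config
hash and output checksums; identical configs reproduce identical
checksums.

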