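# flowscales

Multiscale flow communities in origin–destination (OD) mobility networks.

Human mobility is organised at several scales at once: neighbourhoods,
commuting basins, metropolitan regions, whole nations. `flowscales` extracts
those scales from OD trip tables in an unsupervised way, quantifies how well
any partition (data-driven or administrative) contains the observed flows,
and fits a simple relaxation model to how that containment responds to a
mobility shock such as a lockdown. It is aimed at computational social
scientists and epidemiological modellers working with tile-level trip counts.

## The model

A directed, weighted graph `G` is built from trip counts averaged over a
baseline window, with intra-tile trips kept apart as self-loops, restricted
to the largest strongly connected component. The random walk
`M = D_out⁺ A` with stationary distribution `π` (`πM = π`) and random-walk
Laplacian `L = I − D_out⁺ A` defines a diffusion whose containment within
candidate communities is measured by Markov stability at scale `r`:

```
MS(r, H) = Tr[ Hᵀ (Π e^{−Lr} − πᵀπ) H ],      Π = diag(π)
```

maximised over partition indicator matrices `H` with a generalised Louvain
algorithm. Short diffusion times reveal fine communities, long times coarse
ones (scales are reported as `s = log₁₀ r`). Robust scales are selected from
the cross-scale and within-scale normalised variation of information (NVI):
basins of the smoothed, pooled Block NVI curve each contribute the scale with
the most reproducible optimisation ensemble.

Containment of a partition is quantified by the community coverage
`C_k = (D̂⁺F)_kk` with `F = Hᵀ(A + diag(intra))H`, the flow-weighted coverage
`C`, and the nodal containment `NC_i`, the share of a tile's inter-tile
outflow staying in its community. Temporal shocks are analysed through the
relative coverage change `ΔC(t) = (C(t) − C(t₀))/C(t₀)` on weekly networks,
fitted by the activation response

```
dx/dt = −βx + αe^{−λt}   →   x(t) = α/(β−λ) (e^{−λt} − e^{−βt}),
```

estimating the stimulus amplitude `α`, stimulus time `1/λ` and recovery time
`1/β` (weeks) with profile-likelihood confidence intervals.

Because real tile-level trip data are typically not redistributable, the
package includes a synthetic generator with a planted flow hierarchy and a
lockdown scenario that redistributes inter-community trips into self-loops
while conserving totals, so the whole pipeline is testable end to end.

## Worked example

```python
import numpy as np
import flowscales as fs

plan = fs.HierarchyPlan(levels=(4, 4), leaf_size=4, decay=0.1, asymmetry=0.1)
table = fs.generate_hierarchical_flows(plan, seed=0)
graph = fs.build_baseline_graph(table)
model = fs.RandomWalkModel.from_graph(graph)
print(f"N = {graph.n_nodes} tiles, irreversibility = "
      f"{fs.detailed_balance_deviation(model):.3f}")

scan = fs.scan(model, np.linspace(-2, 2, 40), n_repeats=50, seed=0)
sel = fs.select_robust_scales(scan)
for i in sel.selected:
    print(f"robust scale s = {scan.scales[i]:+.2f}: "
          f"{scan.partitions[i].n_communities} communities")

fine = fs.planted_partition(plan, 2)
rep = fs.containment(graph, fine)
print(f"fine planted partition: C = {rep.coverage:.3f}, "
      f"NC = {rep.avg_nodal_containment:.3f}")
```

prints

```
N = 64 tiles, irreversibility = 0.089
robust scale s = -2.00: 64 communities
robust scale s = -0.56: 16 communities
robust scale s = +0.67: 4 communities
fine planted partition: C = 0.945, NC = 0.745
```

The walk on the generated network is close to reversible (relative
detailed-balance deviation 0.089), as expected when most trips are
commuting-like round trips. The scale selection recovers, without
supervision, the all-singletons limit and both planted hierarchy levels
(16 blocks, 4 superblocks). The planted fine partition contains 94.5% of
all flow (self-loops included); on average 74.5% of each tile's inter-tile
outflow stays inside its community.

The same workflows are scriptable from the shell:

```
flowscales simulate --plan plan.json --seed 7 -o data/
flowscales baseline -c config.json
flowscales temporal -c config.json
flowscales report   -c config.json
```

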