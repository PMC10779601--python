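# endoprox

Network-proximity screening of drug targets against disease endophenotype
modules on the human protein–protein interactome.

Complex diseases such as Alzheimer's disease decompose into intermediate
pathological mechanisms — amyloidosis, tauopathy, neuroinflammation,
neuronal apoptosis, ER stress, autophagy — each representable as a gene-set
*endophenotype module*. If a drug's protein targets sit unexpectedly close
to one of those modules in the interactome, the drug plausibly modulates
that mechanism. `endoprox` implements that screen end-to-end for anyone
doing network pharmacology: load an interactome edge list, a drug-target
list and a GMT module catalog; compute the proximity statistic per module;
rank and flag significant modules; and report bipartite target–module
membership statistics and pathway overlays as plain TSV/JSON.

## The statistic

For a module *A* and a target set *B* on interactome *G*, the **closest
distance** is

```
d_AB = ( Σ_{a∈A} min_{b∈B} d(a,b) + Σ_{b∈B} min_{a∈A} d(a,b) ) / (|A| + |B|)
```

with `d(a,b)` the unweighted shortest-path (hop) length. Significance comes
from a **degree-preserving permutation null**: each of *n* replicates
(default 10,000) replaces every member of each set with a random node drawn
from the same degree bin, recomputes `d`, and the observed value is
standardised,

```
z = (d_AB − μ_null) / σ_null ,     p = (r + 1) / (n + 1) ,
```

where `r` counts null distances ≤ `d_AB` (one-sided: proximity means small
distance). A module is flagged when `z < −1.8` **and** `p < 0.05` (both
thresholds configurable). Because curated interactomes and module catalogs
are not always at hand, a synthetic-data generator builds
preferential-attachment interactomes and module catalogs with *planted*
proximal modules, so every stage of the pipeline is testable against known
ground truth.

## Worked example

`examples/02_simulate_and_screen.py` generates a 2,000-node scale-free
interactome, a 46-gene target set and 25 modules of which 5 are planted
inside the targets' 1-hop neighbourhood, then screens at 1,000 permutations:

```
graph: 2000 nodes / 5991 edges; 46 targets; 25 modules (5 planted proximal)

most proximal modules (z ascending):
module                     category  n_A_used  n_B_used  d_observed  null_mean  null_sd          z  p_empirical     p_normal  significant
   M01                  amyloidosis        92        46    0.840580   1.901370 0.073749 -14.383747     0.000999 3.272623e-47         True
   M02          neuron inflammation        62        46    0.814815   1.990537 0.082723 -14.212808     0.000999 3.815198e-46         True
   M05                    tauopathy        70        46    0.896552   1.950207 0.081583 -12.915194     0.000999 1.847550e-38         True
   M04 endoplasmic reticulum stress        37        46    1.144578   2.035410 0.097127  -9.171832     0.000999 2.325236e-20         True
   M03             neuron apoptosis        20        46    1.560606   2.219803 0.114963  -5.733968     0.000999 4.905387e-09         True
   M14          neuron inflammation        22        46    3.132353   2.473000 0.110748   5.953638     1.000000 1.000000e+00        False

flagged significant (z < -1.8 and p < 0.05): ['M01', 'M02', 'M03', 'M04', 'M05']
planted ground truth:                        ['M01', 'M02', 'M03', 'M04', 'M05']
-> 5/5 planted modules recovered, 0 decoys wrongly flagged.
```

Each row reads: the module's genes sit on average `d_observed` hops from
the target set, versus `null_mean ± null_sd` for degree-matched random
sets; `z` standardises the gap and `p_empirical` is the add-one permutation
p-value (its floor at 1,000 permutations is 1/1001 ≈ 0.000999). Planted
modules separate from decoys by ten-plus standard deviations; decoys sit
*farther* than random (positive z) because they are drawn ≥ 3 hops from
every target. The other scripts in `examples/` walk through the distance
statistic on a toy 9-protein network, bipartite membership statistics, and
pathway overlays.

## Command line

The same pipeline is scriptable from a shell:

```
endoprox simulate --n-nodes 2000 --targets 46 --modules 25 --planted 5 --seed 7 --out sim/
endoprox screen --edges sim/edges.tsv --targets sim/targets.txt \
    --modules sim/modules.gmt --n-perm 10000 --seed 7 --out results/
endoprox bipartite --modules sim/modules.gmt --out results/
endoprox overlay --targets sim/targets.txt --pathways pathways.gmt --out results/
endoprox run-all ...   # screen + bipartite + overlay + manifest.json
```

Every run writes a `manifest.json` embedding the full configuration and
library versions; re-running from a manifest's config reproduces the
reports byte-for-byte.

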