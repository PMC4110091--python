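# linrob

Robustness analysis of determinative (mosaic) developmental cell lineages.

In organisms such as the nematodes *Caenorhabditis elegans* and *Pellioditis
marina* or the ascidian *Halocynthia roretzi*, cell fates are fixed: a cell
lost during development is not replaced. The developmental cell lineage is a
rooted binary tree whose leaves are terminal cells carrying functional type
labels. `linrob` quantifies how strongly the organism's cellular composition
is affected by two kinds of perturbation, tests whether a lineage is more
robust than constrained random lineages producing the same terminal cells,
measures the tree features responsible, and simulates whether selection
during the evolutionary expansion of a lineage can produce the observed
robustness.

## The model

Robustness of a perturbed lineage is the product of weighted per-type
survival fractions

    f = ∏ᵢ (nᵢ / Nᵢ)^aᵢ,     aᵢ ≥ 1,

over the T terminal cell types excluding apoptotic cells, with Nᵢ the
unperturbed and nᵢ the surviving count of type i.

* **Necrosis robustness f_n** — the exact mean of f over the single removal
  of every non-root cell together with all its descendants (one accidental
  cell death per lineage).
* **Program-failure robustness f_p** — each cell division uses a *program*
  defined recursively by the fates of its two daughters; all internal cells
  sharing a failed program are arrested. The number of failed programs is
  Binomial(N_program, p) with p = 1/N_internal, so the expected number of
  affected internal cells is exactly one in any lineage. f_p is the Monte
  Carlo expectation of f (10 × cell-count replicates by default), with an
  exact subset-enumeration oracle for small program counts.

Null models ("who is more robust than chance?") draw random lineages under
eight constraint sets — free coalescence of the terminal cells, coalescence
with fixed maximum depth, bootstrapped or exactly conserved terminal-depth
multisets, relabeling (free, within-depth, within-depth keeping twin pairs),
and a clonality gradient — and report empirical P and Z for any statistic.

Feature analyses cover the clonality index C (lineal clustering of types),
the rare-early correlation ρ (Spearman, terminal depth vs. type size), the
physical–lineal distance correlation ρ_p-l with a greedy one-swap search for
its ceiling, twin-cell counts and spatial Z-scores, and transcriptome-based
reclassification by hierarchical clustering compared via mutual information.

The macroevolution simulator grows a lineage one terminal per round by
bifurcating an existing terminal (one daughter inherits the parental type),
examining 100 candidate bifurcations per round and drawing the winner
uniformly from the top k by fitness — R = f_n, f_p, S = 1/complexity, or
R^x·S.

## Worked example

```python
import linrob as lr
from linrob.synth import SyntheticSpec, load_census
from linrob import randomize as rz

census = load_census("celegans_embryonic")     # 671 terminals, 9 types
lineage = lr.synth_lineage(SyntheticSpec(
    census=census, rare_early_strength=0.9, twin_enrichment=2.0, seed=11))

spec = lr.RobustnessSpec(excluded=census.excluded, seed=1)
print(round(lr.necrosis_robustness(lineage, spec), 4))        # 0.9554
print(round(lr.program_failure_robustness(lineage, spec), 4)) # 0.9258

nd = lr.null_distribution(
    lineage, lambda l: lr.necrosis_robustness(l, spec),
    rz.RandomizationMode(rz.COALESCENT), n=50, seed=2, name="f_n")
print(nd.p_value, round(nd.z, 2))                             # 0.0 5.52
```

A census-matched synthetic lineage organized with rare types shallow and
enriched twins keeps 95.5 % of its composition after an average necrotic
death and 92.6 % under one expected program failure, and sits 5.5 null
standard deviations above free-coalescent random lineages — none of the 50
random lineages is more robust (empirical P = 0).

The same analyses run from the shell:

```sh
linrob simulate-data --census hroretzi --seed 7 --outdir bundle
linrob robustness --tree bundle/lineage.nwk --types bundle/types.tsv
linrob features   --tree bundle/lineage.nwk --types bundle/types.tsv \
                  --coords bundle/coords.tsv
linrob evolve     --census celegans_embryonic --fitness fn --k 5 --seed 3 \
                  --outdir evo
```

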