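# quantkit

Quantitative phenotyping and gene-network statistics for model-organism
studies of multigenic disease loci (e.g. copy-number-variant regions such as
the 3q29 deletion, whose genes are screened by tissue-specific knockdown in
the fly eye).

The package implements three analyses, each exercisable end to end on
synthetic data with known ground truth:

1. **Ommatidial disorderliness (OD) scoring** — the wild-type compound eye
   tiles ~750 ommatidia in a regular hexagonal lattice. For each detected
   ommatidial center the six vectors to its nearest neighbors are computed;
   the *distance OD* subscore is 100× the mean per-center coefficient of
   variation of the six vector lengths, the *angle OD* subscore is 100× the
   mean deviation of consecutive angular gaps from 60°
   (mean |gap − 60°|/60°), and the composite phenotypic score is their sum.
   A perfect lattice scores exactly 0; rough-eye severity raises the score.
   Necrotic-patch area and stained-cell counting (connected components or
   local maxima) round out the phenotyping.
2. **Weighted-network connectivity** — in a gene-interaction network with
   confidence weights *w* (edges retained when *w* > 2.0, or the top 0.5%
   by weight), the distance between two genes is the shortest path under
   edge length 1/*w*; lower distance = higher connectivity. A query set's
   per-gene mean distances are tested against a random-gene null (500
   random anchors × 100 replicates × 20 random partners) with one-tailed
   Mann-Whitney tests and Benjamini-Hochberg correction.
3. **Overlap enrichment** — the annotated-gene overlap of a candidate set is
   compared with 100,000 random same-size draws from the gene universe; the
   empirical p-value is the upper-tail proportion of simulated overlaps at
   or beyond the observation, reported as the bound p < 1/n_sim when no
   draw reaches it.

A small `stats_core` module provides the self-contained inferential
primitives: Mann-Whitney U (exact enumeration for small samples and for
single-observation tests, tie/continuity-corrected normal approximation
otherwise), BH step-up adjustment, and the ΔΔCt relative-expression formula
2^(−ΔΔCt) for qPCR.

## Worked example

Generate the synthetic study inputs and run the three analyses:

```sh
python analysis/01_simulate_data.py
python analysis/02_score_eyes.py
python analysis/03_network_connectivity.py
python analysis/04_overlap_enrichment.py
```

`02_score_eyes.py` scores 140 synthetic eyes across a severity ladder and
prints the per-condition mean composite OD score:

```
condition  level      mean      std  count
  dropout   0.00  0.133581 0.006795     20
  dropout   0.05  4.699710 2.069249     20
  dropout   0.10  9.550115 4.950261     20
   jitter   0.00  0.134305 0.009625     20
   jitter   1.00 13.066398 0.894091     20
   jitter   2.00 26.100110 1.851828     20
   jitter   4.00 43.018433 4.366228     20
```

The score is near zero for noiseless lattices and rises monotonically with
positional jitter (px) and ommatidial dropout (fraction of sites removed) —
the severity ordering a rough-eye score must reproduce.

`03_network_connectivity.py` profiles a 15-gene module planted at 5× edge
weights in a 500-gene background network, against the 50,000-value
random-gene null:

```
planted_module: 15/15 genes flagged more connected than random (q < 0.05); mean distance 0.178
random_probes: 0/15 genes flagged more connected than random (q < 0.05); mean distance 1.394
```

Every module gene is recovered (mean shortest distance 0.178 versus 1.397
for the null) and no random probe gene is falsely flagged.

`04_overlap_enrichment.py` tests a 756-gene candidate set whose annotation
rate is enriched 1.5× over a 18,000-gene universe (~10.6% annotated):

```
observed 111 annotated candidates vs null min/mean/max = 46/80.22/121; p = 0.00021
```

i.e. 111 annotated candidates were observed while random 756-gene draws
contain 80.2 on average; only 21 of 100,000 simulated draws reached 111.

The same stages are scriptable through the CLI (`quantkit run CONFIG.toml`
plus `simulate-eye`, `score-eye`, `simulate-network`, `connectivity`,
`simulate-universe`, `enrich-overlap` subcommands) or the library API.

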