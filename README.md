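# symptomnet

Network psychometrics for adolescent depression–anxiety comorbidity:
a tested, reusable pipeline for estimating and comparing regularized
partial-correlation networks of PHQ-9 and GAD-7 symptom items.

## The problem

Depression and anxiety screeners are usually summarized by total scores, but
a sum hides *which* symptoms hang together and which ones tie the two
syndromes to each other. Network analysis treats the 16 items — nine
depression symptoms (PHQ-9, `P1`–`P9`) and seven anxiety symptoms (GAD-7,
`G1`–`G7`), each rated 0–3 — as nodes of an undirected graph whose edges are
conditional associations. Three quantities then carry the substantive story:

- **nodal strength** `s_i = Σ_j |w_ij|` — how central a symptom is;
- **bridge strength** `b_i = Σ_{j: cluster(j) ≠ cluster(i)} |w_ij|` — how
  strongly a symptom connects to the *other* syndrome's cluster (candidate
  comorbidity targets);
- **global strength** `Σ_{i<j} |w_ij|` — overall connectivity of the network.

`symptomnet` implements the full analysis chain used in two-group school
vs. vacation survey designs:

1. **survey handling** — validation, exclusion of incomplete/erroneous rows,
   PHQ-9/GAD-7 scoring with severity bands (0–4 / 5–9 / 10–14 / 15+) and the
   clinical cut-off (total ≥ 10), Cronbach's alpha, prevalence summaries;
2. **network estimation** — Spearman rank correlations (the ordinal items are
   skewed), the graphical lasso solved by blockwise coordinate descent over a
   logarithmic penalty grid, and model selection by the extended BIC
   (γ = 0.5 by default); edge weights `w_ij` are the regularized partial
   correlations `−θ_ij/√(θ_ii θ_jj)` of the selected precision matrix Θ;
3. **centrality** — nodal, bridge and global strength with standardized
   profiles;
4. **stability** — nonparametric bootstrap of edge weights (percentile CIs),
   case-dropping subsampling summarized by the CS-coefficient (the largest
   drop proportion at which ≥ 95% of subsample centralities correlate ≥ 0.7
   with the full sample), and bootstrap difference tests between edges and
   between node strengths;
5. **network comparison** — a two-tailed permutation test: group labels are
   shuffled over the pooled respondents, both networks re-estimated per
   iteration, and `P = K/n_perm` counted for the global-strength difference,
   the maximum edge difference, every edge, and every node's strength and
   bridge strength (edge p-values Benjamini–Hochberg adjusted);
6. **reporting** — Fruchterman–Reingold layouts and qgraph-style figures;
7. **synthetic data** — a generator that draws ordinal responses from a
   latent Gaussian graphical model with a known block-structured sparse
   precision matrix (dense within the depression and anxiety blocks, a few
   cross-block bridge edges), per-item thresholds producing realistic skewed
   category frequencies, and a non-positive latent mean shift for the
   vacation group. Because the ground truth is known, every downstream stage
   is testable without any real data.

## Worked example

```python
import symptomnet as sn

scenario = sn.SyntheticScenario(n_per_group=1000, seed=3)
table, truth = sn.simulate_study(scenario)      # two groups, known network
retained, n_excluded = sn.apply_exclusion(table)

school = retained[retained["group"] == "school"]
net = sn.estimate_network(school)
prof = sn.centrality_profile(net)
print(f"{net.edge_count}/{net.n_possible_edges} edges "
      f"({net.density_percent}%), global strength {prof.global_strength:.2f}")

res = sn.compare_networks(school,
                          retained[retained["group"] == "vacation"],
                          config=sn.NctConfig(n_perm=1000, seed=3))
print(f"global strengths {res.global_strengths[0]:.2f} vs "
      f"{res.global_strengths[1]:.2f}, p = {res.p_global:.3f}")
```

prints

```
78/120 edges (65.0%), global strength 6.21
global strengths 6.21 vs 6.48, p = 0.061
```

— the two groups share one true network structure (the generator shifts only
the latent means), so the permutation test correctly finds no significant
global-strength difference, while the exclusion step reports 0 dropped rows
for this fully complete synthetic table.

The same pipeline runs from the shell:

```bash
symptomnet simulate --n-per-group 1000 --seed 3 --out table.csv
symptomnet estimate table.csv --group school --out-stem school_net
symptomnet compare table.csv --n-perm 5000 --out-stem nct
symptomnet run-all --seed 3 --outdir runs     # everything, with a manifest
```

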