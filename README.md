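# alienphylo

Community-phylogenetic analysis of alien-flora checklists.

Alien species introduced to a region form a nested continuum: some remain
**casual** (never self-sustaining), some become **naturalized**
(self-replacing populations), and a subset of those becomes **invasive**
(spreading far from parent plants). Whether the species that advance along
this continuum are a phylogenetically random subset of the introduced flora
— or clustered into particular clades — is a central question for predicting
invasions. `alienphylo` implements the full analysis for a checklist of the
scale of a national alien flora (~1700 species) and a dated phylogeny:

- **Status algebra.** A checklist stores only each species' highest attained
  stage; the five assemblages — alien ⊇ naturalized ⊇ invasive, plus
  casual = alien \ naturalized and NNI = naturalized \ invasive — are
  derived, never stored, so inconsistent stage flags cannot occur.
- **Tabulations.** Counts and proportions by family, lifeform, origin region
  (TDWG level-1; a species counts once toward *each* of its regions) and
  introduction pathway, plus per-family naturalization and invasion rates.
- **MNTD / NTI.** For an assemblage $S$ on a tree with patristic distances
  $d$, the mean nearest-taxon distance is
  $\mathrm{MNTD}(S) = \frac{1}{|S|}\sum_{t \in S}\min_{s \in S,\, s \neq t} d(t,s)$.
  The nearest taxon index standardizes it against a richness-maintaining
  null — uniform same-size draws from the alien reference pool:

  $$\mathrm{NTI} = -\,\frac{\mathrm{MNTD}_{\mathrm{obs}} - \overline{\mathrm{MNTD}}_{\mathrm{null}}}{\mathrm{sd}(\mathrm{MNTD}_{\mathrm{null}})}$$

  Positive NTI = phylogenetic clustering, negative = overdispersion, zero =
  indistinguishable from a random draw. Small null spaces are enumerated
  exhaustively; otherwise 1000 Monte-Carlo draws are used.
- **Between-assemblage distances + PCoA.** The abundance-unweighted mean
  nearest-taxon distance between assemblages (`comdistnt`, with conspecifics
  included by default — important because the stage sets are nested) is
  ordinated by classical Principal Coordinates Analysis with per-axis
  variance fractions.
- **Synthetic data.** A Yule tree simulator and checklist generator whose
  defaults mirror the study-scale composition (1686/1198/232 species;
  annuals rising from ~33.6% of aliens to 62.1% of invasives; 57.8% of
  invasives of American origin; 56.5% of aliens introduced as ornamentals),
  with tunable clade-biased stage membership so the expected NTI sign is
  known by construction.

## Worked example

Simulate a 300-tip flora with clade-biased invasive membership and run the
pipeline:

```python
import alienphylo as ap

config = ap.SyntheticConfig(n_tips=300, n_alien=250, n_naturalized=120,
                            n_invasive=40, seed=11)
tree = ap.simulate_yule(config.n_tips, config.birth_rate, rng=config.seed)
checklist = ap.generate_checklist(config, tree)
tree.write(path="tree.nwk", schema="newick", unquoted_underscores=True)
ap.write_checklist(checklist, "checklist.csv")

summary = ap.run_pipeline(ap.RunConfig(
    checklist_path="checklist.csv", tree_path="tree.nwk",
    output_dir="results", n_draws=1000, seed=42,
))
for entry in summary["nti"]:
    val = "undefined (assemblage = pool)" if entry["undefined"] else f"{entry['nti']:+.2f}"
    print(f"{entry['assemblage_name']:<12} richness {entry['richness']:>4}   NTI {val}")
print("PCoA variance explained:", [round(v, 3) for v in summary["pcoa_variance_explained"]])
```

prints

```
alien        richness  250   NTI undefined (assemblage = pool)
casual       richness  130   NTI -1.65
naturalized  richness  120   NTI +2.69
nni          richness   80   NTI +2.25
invasive     richness   40   NTI +6.94
PCoA variance explained: [0.847, 0.153]
```

The alien assemblage *is* the reference pool, so its richness-preserving
null is degenerate and the result is flagged rather than forced to a number
(a bootstrap null is available as an alternative; it lands near 0). The
invasive assemblage, generated with strong clade bias (rho = 0.8), reads
strongly clustered; mild bias at the naturalized stage (the default rho =
0.3) shows as moderate clustering. `results/` also contains the tabulation
and transition-rate CSVs, the 5×5 between-assemblage distance matrix, PCoA
coordinates and a structured log of seeds and dropped species.

The same analysis is available from the shell:

```sh
alienphylo simulate --out sim --seed 11
alienphylo run --checklist sim/checklist.csv --tree sim/tree.nwk \
    --draws 1000 --seed 42 --out results
```

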