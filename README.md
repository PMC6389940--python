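# hybridpaint

Analysis toolkit for dissecting **recurrent hybrid origins in wild yeast
lineages**. The package re-implements, as tested and reusable code, the
computational pipeline used to establish that a North American
*Saccharomyces paradoxus* lineage (*SpD*) arose recently from a backcross
between one parental lineage (*SpB*) and an older hybrid (*SpC\**):

- **Ancestry painting** — assign donor-lineage ancestry along admixed
  genomes with a gene-level JC69 fixation criterion and a
  parent–parent–hybrid triplet scan; merge blocks within 5 kb; summarize
  donor proportions, heterozygosity windows and translocation-junction
  coverage support.
- **Divergence dating** — polarize region alignments against an outgroup
  and estimate relative divergence times from derived-variant site
  patterns:
  `T1 = (BAAAA + ABAAA) / 2N` and
  `T2 = [ (BAAAA+ABAAA)/2 + BBAAA + (AABAA+AAABA)/2 + AABBA ] / 2N`
  on the five-taxon topology `(((SpB, SpD), (SpC*, SpC)), SpA)`, with a
  four-taxon analogue and a ≥1000-informative-site region filter.
- **Admixture-graph ranking** — f4 statistics
  `f4(P1,P2;P3,P4) = E[(p1−p2)(p3−p4)]` with block-jackknife errors,
  expected f4 from drift-edge path overlaps on admixture graphs, bounded
  least-squares fitting, and ranking of a 15-model candidate family
  (including the nested-hybridization shape M01 and the
  independent-crosses shape M02).
- **Rearrangement parsimony** — signed block permutations (GRIMM dialect)
  to binary inversion/translocation presence characters, exhaustive
  enumeration of all `(2n−3)!!` rooted bifurcating topologies (945 for six
  genomes), Fitch small-parsimony scoring, and conflict (homoplasy)
  detection.
- **Growth phenotypes** — replicate-median log2 colony-growth curves,
  AUC / maximum slope / endpoint size, and the mid-parent statistic
  `d = (x_s − ½[med(X_P1)+med(X_P2)]) / (½|med(X_P1)−med(X_P2)|)`
  (parents sit at ±1, the midpoint at 0, transgressive strains beyond),
  with one-sided Mann–Whitney hybrid-vs-parent tests.
- **3′-tag counting** — per-gene read counting from coverage tracks via a
  400-bp initial 3′ window extended in 100-bp steps until a valley of low
  coverage.

Every stage is exercisable without external data: `hybridpaint.simdata`
generates all inputs (clock-tree JC69 sequences, mosaic hybrid
chromosomes, planted rearrangements, logistic growth curves, 3′ coverage
peaks, graph-drifted allele frequencies) together with the ground truth
needed to score the stage.

## Worked example

Rank the candidate admixture graphs on synthetic f4 data simulated under
the nested-hybridization model M01 (100k SNPs, true SpD mixing proportion
α = 0.5):

```sh
python analysis/03_rank_admixture_models.py
```

```
 rank model         cost  fit_fraction  alpha_SpD
    1   M01 6.856385e-13           1.0   0.502596
    2   M12 2.871833e+03           0.0   0.486641
    3   M11 1.834760e+04           0.0   0.135977
    4   M13 1.834760e+04           0.0   0.135977
    5   M15 1.834760e+04           0.0   0.135977
    6   M02 1.834760e+04           0.0   0.135977

best model: M01 (true alpha_SpD = 0.5, recovered 0.503)
```

The generating model is recovered with essentially zero cost and a
perfect fit fraction (all fitted f4 within 3 SE in every optimization
restart), its mixing proportion is recovered to 0.003, and every
alternative topology misfits by orders of magnitude. The other numbered
drivers under `analysis/` run the painting, dating, rearrangement,
growth and tag-counting stages the same way and write their tables under
`results/`.

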