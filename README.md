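# aaanet

Candidate disease-gene prioritization on protein–protein interaction (PPI)
networks, built around the guilt-by-association premise: genes related to
the same disease tend to interact with each other, so a gene's position in
the interaction network relative to the known disease genes is predictive
of its own involvement. The package was written for abdominal aortic
aneurysm (AAA) gene discovery — a polygenic disease whose curated gene
list serves as the positive class — but nothing in it is specific to one
disease: any curated gene list and any PPI edge list work.

## What it does

1. **Network ingest** — two-column edge lists or BioGRID TAB3 flat files
   (taxid-filtered), with self-loops and duplicate evidence rows dropped.
2. **Topology features** — seven per-gene measures against a disease set
   *P*: degree *D*; disease-neighbor count *N* = |Γ(v) ∩ P|; disease-neighbor
   ratio *R* = N/D; betweenness centrality *B* (unnormalized pair-fraction
   counts); clustering coefficient *C*; mean shortest-path length to the
   disease genes *M* (hops, self and unreachable genes excluded, sentinel
   |V| when nothing is reachable); and PageRank *PR* (damping 0.85).
3. **Resampled classification** — positives vs an equal-sized negative
   sample drawn from the non-positive network genes; stratified 70/30
   split; 10-fold cross-validated grid search (SVM-RBF, naive Bayes,
   random forest, or kNN); the whole procedure repeated (default 200
   times, base seed 123) with re-randomized negatives and splits. Every
   non-positive gene is scored in every repetition and accumulates a
   **vote** whenever it is classified as a disease gene; candidates are
   called from vote fractions (majority rule by default).
4. **Differential-expression screen** — fold change > 1.5 (two-sided) and
   Benjamini–Hochberg adjusted p < 0.05, plus intersection of the DEGs
   with the called candidates. A Welch-t helper is provided for synthetic
   two-group matrices; real studies should supply a precomputed DE table.
5. **Shortest interaction paths** — all shortest paths between a protein
   pair, exported as SIF or JSON subnetworks.
6. **Synthetic ground truth** — planted-partition networks (a disease
   module with internal edge probability p_in over background p_out, part
   of the module hidden from the labels) and linked two-group expression
   matrices, so every stage is testable end to end with known answers.

## Worked example

```sh
aaanet simulate --seed 123 --out sim/
aaanet run --edges sim/edges.tsv --positives sim/positives.txt \
    --classifier rf --reps 20 --seed 123 --rule majority --out run/
```

The second command prints:

```
14 candidate genes called (mean test accuracy 0.986); outputs in run
```

meaning: across 20 repetitions the random forest classified held-out
test genes with 98.6% mean accuracy, and 14 genes outside the labeled
positive set were predicted to be disease genes in a majority of
repetitions. On this simulated study the planted truth is known —
`sim/truth.json` lists the 15 hidden module genes — and 14 of the called
candidates are among them (`run/candidates.csv` has the per-gene votes;
`run/manifest.json` records every resolved parameter and input checksum).
A DE screen and intersection can be added with `aaanet de-screen` and
`aaanet intersect`, and `aaanet shortest-path --from G0012 --to G0255`
extracts interaction routes between two proteins.

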