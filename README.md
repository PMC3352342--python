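# flavicophy

Co-divergence analysis for the "insect-specific" flaviviruses — viruses such
as cell fusing agent virus (CFAV), Kamiti River virus (KRV), *Culex*
flavivirus (CxFV), *Aedes* flavivirus (AeFV), Quang Binh virus (QBV) and
Nakiwogo virus (NAKV) that replicate in mosquito cells but not in mammalian
cells. The central question the package addresses: does the phylogeny of
these viruses mirror the phylogeny of their mosquito hosts (long-term
co-divergence), or does it look like multiple introductions with frequent
host switching?

It is written for virologists and molecular evolutionists who want a
scriptable, testable version of this analysis: event-based cophylogenetic
reconciliation with a randomization test, plus the sequence screens that
usually accompany a study of this group (fusion-peptide motif conservation,
+1 frameshift rescue of stop-codon-interrupted sequences, and a
bootscan-style recombination scan).

## The method

**Reconciliation.** Given a rooted binary virus tree V, a rooted binary host
tree H and a (many-to-one) association of virus strains to host species,
every internal node of V is mapped onto a node of H and assigned one event:

* **codivergence (CE)** — the virus divergence tracks a host divergence:
  the node maps to an internal host node and its children descend into the
  two distinct host child subtrees;
* **duplication (D)** — the virus diverges within a single host lineage;
* **host switch (S)** — exactly one child jumps to a host lineage
  incomparable to the parent's (neither ancestor nor descendant);
* **losses (L)** — host edges traversed by a virus edge without a
  corresponding virus divergence (sorting events).

Non-codivergence events are NCE = D + S + L. There is no single "correct"
cost for these events, so the package enumerates the full **Pareto frontier**
of event vectors (maximize CE; minimize D, S and L separately) by dynamic
programming over (virus node, host node) cells — the set of *potentially
optimal* (POpt) reconciliations — and labels the solutions S1, S2, ... by
decreasing CE, then increasing NCE.

**Significance.** The randomization test draws n random virus topologies
(uniform over labeled rooted binary trees; n = 200 for the full analysis,
100 for subgroups), reconciles each against the fixed host tree with the
same associations, and computes, per observed solution,

* p_ce  = Pr(random tree attains CE ≥ observed CE), and
* p_nce = Pr(random tree attains NCE ≤ observed NCE),

scoring each random tree by its own best value per criterion. Co-divergence
is supported only if **both** P-values fall below α = 0.05 for some
solution; the dual rule corrects for the greater sensitivity of the NCE
criterion.

## Worked example

The packaged inputs are the 14-strain NS5 virus topology, the fixed
mosquito host topology and the strain-to-vector association table. The
reconciliation:

```
$ flavicophy reconcile
label   CE      D       S       L       NCE
S1      4       4       5       2       11
S2      4       5       4       2       11
S3      4       6       3       3       12
S4      4       7       2       4       13
...
```

The best reconciliations explain the virus tree with only 4 codivergence
events out of 13 divergences — most of the virus diversification (CFAV and
KRV strain pairs on a single host species, the CxFV radiation across the two
*Culex* species) must be duplications, host switches and losses. The
randomization test asks whether even that is more congruence than chance:

```
$ flavicophy codivtest --n 200 --seed 1
{
  ...
  "solutions": [
    {"label": "S1", "CE": 4, "NCE": 11, "p_ce": 0.99, "p_nce": 0.98,
     "significant": false},
    ...
  ],
  "codivergence_supported": false
}
```

99 % of random virus trees reach at least 4 codivergences and 98 % need at
most 11 non-codivergence events, so neither criterion — let alone both — is
met: there is **no statistical support for virus–mosquito co-divergence**,
consistent with multiple introductions and frequent host switching. The
same verdict holds for the *Culex*-only and *Stegomyia*-side subgroup
analyses (`--group culex`, `--group stegomyia`).

Other subcommands: `motifscan`, `conserved`, `frameshift`, `orfscan`,
`bootscan`, and `simulate cophylo|recomb|frameshift` for synthetic data
with recorded ground truth. Everything is also importable
(`from flavicophy import reconcile, randomization_test, bootscan, ...`).

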