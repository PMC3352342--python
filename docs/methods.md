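# Methods

## Trees and associations

All analyses operate on rooted, strictly binary, leaf-labeled trees.
Polytomies are rejected at parse time: the event model assigns exactly one
event to each internal virus node, which is only well defined on resolved
trees. Labels are opaque, case-sensitive strings (whitespace-trimmed on
load). The host topology carries no branch lengths and reconciliation is
topology-only: no divergence times are available for the mosquito genera
involved, and the event model never consults time.

The packaged host topology encodes the consensus of the morphological and
molecular literature for the six vector species plus
*Cx. tritaeniorhynchus*: (*Cx. pipiens*, *Cx. quinquefasciatus*) sisters,
*Cx. tritaeniorhynchus* sister to that pair; *Mansonia africana* basal to
an aedine clade in which *Neomelaniconion mcintoshi* is closer to
*Stegomyia* than to *Culex*. *Cx. tritaeniorhynchus* has no associated
strain in the packaged table; an unmapped host leaf cannot change CE, D or
S counts in any reconciliation — it can only add losses — so including it
is conservative (a property test asserts exactly this).

The packaged 14-strain NS5 virus topology fixes the relationships the
sequence analyses of this group support: CFAV sister to AeFV, that pair
sister to KRV, the CFAV+AeFV+KRV clade sister to the CxFV+QBV+NAKV clade
(NAKV basal, QBV sister to CxFV), DENV1 outside both. Within CxFV, where
single-gene analyses are least decisive, the packaged resolution follows
the two recognized CxFV genotypes: (Tokyo, Japan03) with (Iowa07, HOU24518)
versus (Mexico07, Uganda08). The association table keeps QBV on
*Cx. quinquefasciatus* as tested, even though QBV was first isolated from
*Cx. tritaeniorhynchus*.

## Event model

For an internal virus node v mapped to host node h(v) with children images
h(a), h(b):

* **codivergence** iff h(v) is internal and h(a), h(b) lie in its two
  distinct child subtrees;
* **duplication** iff both children's images are at-or-below h(v) without
  satisfying codivergence;
* **host switch** iff exactly one child's image is *incomparable* to h(v)
  (neither ancestor nor descendant — landing on an ancestral edge is never
  allowed). The switched child is taken to land exactly on its image, so
  the switch edge itself contributes no losses;
* **losses** count host edges descended without a virus divergence: for a
  codivergence, the edges from each host child down to the corresponding
  virus child's image; for a duplication or the staying child of a switch,
  the edges from h(v) down to the child's image.

These are the standard event-based semantics that TreeMap popularized,
made fully explicit. Two deliberate simplifications: switches are not
checked for chronological consistency (no timed "jungles" — no times
exist for this host set), and many virus leaves may map to one host leaf,
in which case their divergences are necessarily duplications or switches.

## Pareto-optimal enumeration

Because event costs are not identifiable, optimality is the Pareto
frontier over event vectors (CE maximized; D, S, L each minimized). The
frontier is computed by a dynamic program over (virus node, host node)
cells; each cell holds the Pareto set of achievable vectors for the
subtree, with per-cell dominance pruning (sound because vector addition is
monotone). Solutions are deduplicated by event vector, ordered by
decreasing CE, then increasing NCE, then D, then S (a deterministic
tie-break so the S1/S2/... labels are stable), and one representative node
map is reconstructed per vector. `count_events` independently recomputes
the vector from a solution's node map and raises on any inconsistency.

`brute_force_reconcile` enumerates *every* feasible node map by recursion
over internal nodes (≤ 8 leaves per tree) and Pareto-filters at the end; it
shares nothing with the dynamic program beyond the event definitions and
serves as the oracle in the test suite (100 random instances up to 7
leaves).

## Randomization test

Null model: virus topologies drawn uniformly from the (2k−3)!! labeled
rooted binary topologies by sequential leaf insertion on a uniformly
chosen edge (root edge included); a Yule random-joining alternative is
available as a sensitivity switch. Randomization is topology-only — leaf
labels keep their host associations.

Each random tree is summarized by its best achievable CE and, separately,
its best achievable NCE. These extremes provably lie on the tree's Pareto
frontier, so they are computed by two fast scalar dynamic programs rather
than the full enumeration (200 randomizations of the 14-taxon analysis run
in well under a second). P-values use ≥ / ≤ comparisons with no
continuity correction, matching their definition as plain proportions.
Defaults: n = 200 (full analysis), 100 (subgroups), α = 0.05. The joint
rule (both p_ce < α and p_nce < α, for any solution) is conservative by
construction; on null-simulated datasets the test suite observes a type-I
rate well under 5 %, and near-complete power on congruent 7-host pairs.

Subgroups: the *Culex* analysis keeps the six CxFV strains plus QBV with
the host tree pruned to the *Culex* clade (including the unmapped
*Cx. tritaeniorhynchus*); the *Stegomyia*-side analysis keeps CFAV (2
strains), AeFV and KRV (2 strains) with the aedine host clade
(*Stegomyia* spp. plus *N. mcintoshi*). DENV1 is excluded from subgroups
(it is not insect-specific).

## Relation to TreeMap 2 event counts

TreeMap 2 analyses of this virus–mosquito system have reported optimal
solutions with 10 codivergence events and 16–19 NCEs. Under the explicit
semantics above these counts are not reachable — and not merely because of
a different within-CxFV resolution. With one event per internal virus node,
a codivergence requires a host divergence separating the two child images:
the two CFAV strains and the two KRV strains each share a host species, so
those cherries can never codiverge, and the 7-leaf CxFV+QBV subtree (3
strains on *Cx. pipiens*, 4 on *Cx. quinquefasciatus*) admits at most 3
codivergences, forcing at least 3 non-codivergent nodes of its 6. Any
per-node event assignment on this host topology therefore caps CE well
below 10 (the computed maximum for the packaged topology is 4). The
package reports its own, internally consistent counts; TreeMap 2's
feasibility and counting rules are not documented at the level needed to
replicate its numbers, and no attempt is made to absorb the difference
silently. The randomization verdict is unaffected: it compares observed
and null trees under one and the same semantics, and the no-co-divergence
conclusion is robust across seeds.

## Sequence screens

**Motifs.** Exact/wildcard matching only (no PSSMs): 'X' matches any
residue, a bracket group (e.g. `[GH]`) matches the listed residues at one
position. The four packaged fusion-peptide motifs are all 14 residues.
Protein scans warn (or error, per option) on ACGTUN-only input.

**Conserved columns.** A column counts as conserved for a residue only if
every sequence carries exactly that residue (any gap disqualifies).

**Frameshift rescue.** Translation uses the standard genetic code; stop
codons are exactly {TAA, TAG, TGA}; IUPAC-ambiguous codons translate to
'X' and never count as stops (conservative for rescue detection).
Coordinates are 0-based, half-open, forward strand (the flavivirus genome
is a single positive-sense ORF). `frameshift_rescue` finds the first
frame-0 stop and the longest stop-free codon run obtainable by resuming in
the +1 frame at any codon boundary at or before the stop. `min_codons`
defaults to 52, the size of the smallest documented flavivirus overlapping
ORF (*foo*); the overlapping products of interest in this group run to
~70 codons.

**Bootscan.** Distance is uncorrected p-distance with pairwise gap
deletion — model corrections are unstable in 50-nt windows, the smallest
of the standard 50/100/200/500-nt regime. Step defaults to window/4;
support threshold defaults to 0.7 (a conventional cutoff). Within a
window, each bootstrap replicate resamples columns and votes for the
single nearest non-query sequence; ties cast no vote. A breakpoint
interval spans the midpoints of consecutive above-threshold windows whose
winner changes. No attempt is made to reproduce RDP3's P-values or exact
breakpoint coordinates on the empirical CFAV alignment; validation is on
synthetic recombinants (breakpoint recovered within one window; ≤ 5 %
false-positive calls on clonal data at the default threshold).

## Synthetic data

All generators are pure functions of seed and parameters, and their output
round-trips through the package's own readers.

* `simulate_cophylogeny` draws a uniform host topology and evolves a virus
  lineage down it; at each host divergence each lineage draws at most one
  event (loss p_loss: follow one child only; switch p_switch: one daughter
  follows a host child, the other jumps to a uniform incomparable lineage;
  duplication p_dup: two copies that then both codiverge; else
  codivergence). "At most one event per divergence per lineage" keeps the
  recorded true history unambiguous for recovery tests. With all rates
  zero the virus tree is isomorphic to the host tree. Simulations ending
  with < 3 virus leaves are retried on the same random stream.
* `simulate_recombinant_alignment` mutates two parents a half-divergence
  each from a common ancestor (uniform Jukes–Cantor-style substitutions,
  no indels or rate heterogeneity), builds the query as a parent mosaic at
  the given breakpoints with 5 % relative query-specific noise, and adds
  an outgroup at 1.5× the parent divergence; every divergence scales with
  the parent divergence, so at zero all sequences are identical.
* `simulate_frameshift_sequence` concatenates stop-free frame-0 codons, a
  stop, and a +1-frame tail built codon-by-codon to be stop-free for the
  requested length.

These generators emulate the *structure* the analyses assume — clean
binary histories, uniform substitutions, single breakpoints, exact reading
frames. Real data add alignment error, rate variation, recombination
noise and sampling biases, so green tests here demonstrate correctness of
the methods, not robustness to every property of field data.

## Problem sizes and numerical choices

The test suite exercises the oracle equivalence on 100 random instances of
up to 7 leaves, error control and power of the randomization test on 100
simulated datasets each (99–200 randomizations apiece), bootscan recovery
on 20 recombinant and 50 clonal simulations, and frameshift agreement with
a brute-force scan on sequences up to 3 kb — sizes chosen so the whole
suite completes in a few minutes on one CPU while keeping every binomial
assertion far from its boundary under the fixed seeds. Branch lengths are
serialized to 6 significant digits; all P-values are exact proportions;
all orderings are lexicographically tie-broken, so every result in the
package is bit-reproducible for a given seed.
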