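# Methods

`sdpnet` implements two analysis procedures for curated protein-family
alignments, developed around the glutamic peptidases (eqolisins, MEROPS
G1): (i) hallmark-based scrutiny that removes putatively non-functional
homologs from an MSA, and (ii) identification of specificity-determining
positions (SDPs) by crossing clade-determining positions (CDPs) with a
background-corrected mutual-information (MI) network. A synthetic-MSA
generator with planted ground truth makes every stage testable without any
external data.

## Coordinate system

All residue rules and reports use *reference numbering*: position *k* is
the *k*-th ungapped residue of one designated row of the alignment (for
eqolisins, the mature SCP-B chain, so the catalytic dyad is Q53/E136).
`ReferenceMap` is a bijection between mapped alignment columns and
reference positions; columns where the reference row is gapped are
unmapped. Columns are 1-based everywhere; index 0 is rejected.

## Conservation

For column *c*, conservation is

    cons(c) = max_G |{rows: residue ∈ G}| / n_rows

over disjoint physicochemical groups G (defaults: FYW, ILVM, RKH, DE, NQ,
ST, AG, C, P; residues outside any group are singletons; the scheme is
configurable). Gaps and `X` belong to no group, and the denominator
includes every row, so a gap counts **against** conservation — in a curation
setting a gap at a required site is a violation, not missing data. This
gap-inclusive choice is recorded in the run manifest since screens in the
literature do not always state theirs.

Classes are strict (`cons = 1.0`), high (`0.95 < cons < 1.0`; the 95% cut
is strictly greater-than) and variable. Column information is
Kullback-Leibler: `KL(c) = Σ_a p_a log2(p_a/q_a)` in bits over non-gap
residues, default background q uniform 1/20 (so KL = log2 20 − H for the
default), with 0·log 0 := 0 and all-gap columns flagged undefined rather
than failing whole-alignment profiling. Per-clade logo matrices report
clade-restricted frequencies and the same KL statistic.

## Scrutiny rules

The default ruleset encodes the eqolisin hallmarks (reference numbering):

| positions | allowed | note |
|---|---|---|
| 53, 136 | Q; E | catalytic dyad |
| 8, 41, 44, 55 | G | required glycines (inner sheet / turns) |
| 43 | D, S, G | turn residue; S (phosphomimetic-compatible) and G tolerated |
| 51 | L, I, V | inner-sheet hydrophobic |
| 67 | W, F | F only as the co-evolved W67F/L105W pair; uncompensated F is a warning, not a removal |
| 72 | P | 70's-loop proline |
| 89 | V, I, L, M, F | F is a tolerated hydrophobic swap |
| 105 | V, I, L, M, F, W | W only with F67; E (buried charge) and Y removed |
| 133 | V, I, L, M | plus an explicit no-gap rule |
| — | — | max_insert: any insert > 15 residues removes |

Rule kinds are `required_set`, `forbidden_unless_paired`, `no_gap` and
`max_insert`; rulesets round-trip through YAML. A gap at a required
position triggers the `required_set` rule (gap ∉ allowed), consistent with
the explicit no-gap treatment of 133. An *insert* is a maximal run of
non-gap residues of one sequence confined to columns whose non-gap
occupancy among the other rows is below `occupancy_cut` (default 0.05 —
"lacking homologous counterparts" operationalized as <5% occupancy).
Verdicts are removed (any `remove` rule fired), warned (only `warn` rules)
or retained; warned sequences stay in the retained pool. All fired rules
are reported, not just the first, and scrutiny is idempotent on the
retained subset. The uncompensated-W67F case is a warning by design: a
blanket removal overclaims, and the warning preserves the evidence; it can
be escalated to `remove` in a custom ruleset.

## Clade extraction

Clades may be supplied directly as a two-column table (the faithful route
when clade choices also weigh taxonomy), or extracted from a rooted
support-annotated Newick tree: pre-order traversal accepts the first node
with support strictly above `min_support` (default 0.8) and at least
`min_size` leaves (default 10), and does not descend into accepted clades,
yielding maximal, pairwise-disjoint monophyletic groups labeled I, II, …
In a tree with no support annotation at all, missing supports count as 1.0
(curated tree); in a partially annotated tree, as 0.0 (conservative). The
tree root itself is never a candidate clade.

## CDPs, MI network, SDPs and SDNs

**CDPs.** For each column, `clade_mi` is the plug-in MI (bits) between the
residue symbol (gap kept as a 21st symbol — a clade-specific deletion is
legitimate specificity signal) and the clade label, over clade-assigned
sequences only. Significance comes from a clade-label permutation null:
`p = (1 + #{permutations with MI ≥ observed}) / (1 + n_perm)`,
Benjamini-Hochberg corrected across columns; `is_cdp ⇔ q ≤ α` (default
0.05). The CDP null uses `n_perm = 1000` by default: with ~200 columns the
smallest attainable p is 1/(n_perm+1), and BH needs that headroom for true
positives to clear α. (The original workflow's tools for this step do not
publish their statistics; the permutation-MI formulation computes the same
quantity from first principles.)

**Pairwise MI.** `pairwise_mi` is weighted plug-in MI per column pair
(optional pseudocount on joint counts; default 0 for exactness, a small
value such as 0.5/(21·rows) is reasonable for sparse production data;
optional identity-clustering sequence weights, default off). The average
product correction removes entropic/phylogenetic background:
`MI_APC(i,j) = MI(i,j) − mean_i · mean_j / mean_all`. Significance is a
permutation z-score: each null replicate permutes the rows of every column
independently (column compositions preserved, covariation destroyed), the
same APC is applied, and `z = (MI_APC − null mean)/null sd` with
`n_perm = 50` replicates (enough for a stable mean/sd; the planted-signal
separation is orders of magnitude). Pairs with zero null sd (constant
columns) get z = 0 and a degeneracy flag. The network threshold `z ≥ 6.5`
follows the published network figure; whether that figure's 6.5 was a raw
or standardized score is not stated, and the standardized reading is
adopted and flagged in the manifest.

**Network and SDNs.** Network nodes are columns with at least one edge at
`z ≥ z_cut`; cumulative MI per node is the sum of incident-edge z-scores.
A CDP that is a network node is a pSDP. pSDPs are grouped into
specificity-determining sub-networks (SDNs): two pSDPs share an SDN when a
path of length ≤ `max_link`+1 joins them whose interior nodes are all
non-pSDP (default `max_link = 1`: a direct edge or one linker node, as in
the published SDN that recruits one SDP through a single non-SDP
intermediate). A pSDP in an SDN of size ≥ 2 is reported as a confirmed
SDP; an isolated pSDP keeps its own singleton SDN and pSDP status. This
connectivity criterion stands in for the original workflow's external
confirmation step, whose criterion is unpublished; the manifest records it
as an approximation. Pairs confirmed only by structural compensation
cannot be told apart computationally and are *not* reclassified — the
report keeps them as SDPs for the analyst to judge.

## Synthetic data

The generator emulates a curated eqolisin-like alignment: 6 clades × 40
sequences over 180 core columns (default), 12 invariant hallmark columns
(including the Q/E dyad positions), 8 SDP columns with distinct per-clade
residues, 4 clade-independent two-state compensatory covarying pairs, 10%
background substitution noise, 2% gaps outside planted columns, and 5
contaminants (two broken dyads, a broken glycine, an 18-residue insert —
appended as extra otherwise-all-gap columns — and a gap at required site
133), seed 1. Contaminants copy an existing clean row before the
violation is applied.

Three deliberate idealizations decouple the tests:

* clade founders are identical outside SDP columns, so background columns
  carry no clade signal — CDP calling is tested against a clean null;
* covarying pairs are clade-independent, so network recovery and CDP
  recovery are separate claims;
* hallmark positions are never hit by noise or gaps in clean rows, so a
  correct rule engine must flag exactly the contaminants (noise on rule
  positions is available as a stress option).

Real alignments have none of these guarantees: shared phylogenetic history
makes many columns weakly clade-associated, co-evolution and clade
structure interact, and rule positions do drift. Passing the recovery
tests therefore demonstrates correctness of the machinery under its stated
model, not field performance on NR-mined data. The star-shaped clade tree
(uniform 0.99 supports) exists so tree-based clade extraction recovers the
planted partition exactly; it is not a model of real phylogenies. A
consistency checker (`verify_truth`) re-derives every truth claim from the
emitted alignment (majority-residue checks where noise applies, exact
checks elsewhere).

## Determinism and problem sizes

All randomness flows from a single run seed; each permutation stage derives
a sub-seed from the stage name (CRC32-mixed, kept below 2^31), so stage-wise
and end-to-end runs agree, and reruns are byte-identical (fixed float
formats, sorted JSON keys; the manifest stores SHA-256 digests per output).
The MI kernels one-hot encode the alignment and obtain all pairwise joint
tables from a single matrix product, so a full default-size analysis
(245 × 198, 1000 CDP + 50 z permutations) completes in well under a minute;
the test suite runs its recovery experiments at the default conditions over
seeds 1–10 and its pipeline tests on a scaled 3-clade × 15-sequence
variant, sizes chosen to exercise the same code paths at interactive cost.

## Known limitations

* Automatic clade extraction cannot reproduce published clade choices that
  mixed monophyly with taxonomic judgment; the clade-table input is the
  faithful route.
* The plug-in MI estimator is biased upward at small counts; the
  permutation nulls absorb the bias for testing purposes, but reported raw
  MI values are not bias-corrected.
* APC removes part of a lone strong pair's own signal (its MI inflates its
  column means); rankings are robust, absolute corrected values are
  conservative.
* With 50 z-permutations, z-scores are t-like rather than normal; the 6.5
  threshold is far enough in the tail that this does not matter in
  practice, but z values near the threshold should not be over-read.
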