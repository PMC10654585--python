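# Methods

## The transmission inference

The focal host is an obligate brood parasite, so the vertical
conspecific route is structurally closed (q_vc = 0). Each unique
(host individual × mite taxon) presence — a *record* — is read as at
least one successful colonisation of that individual, and the taxon's
host-specificity category identifies the route: host-specific taxa can
only arrive by horizontal conspecific contact (q_hc), foster-parent
("alien") taxa by the interspecific routes (q_vi dominant, q_hi minor),
and quill-and-skin mites (QSM) by an undetermined route. Under the
assumption that per-record colonisation opportunity is comparable
across categories, the ratio of category record shares estimates the
ratio of effective transmission rates:

    r = share_specific / share_alien

with bounds obtained by assigning the entire QSM share to one side or
the other: lower = specific / (alien + qsm), upper =
(specific + qsm) / alien. Both an exact count-based version and the
display version computed on shares rounded to one decimal are exposed;
the exact bounds provably bracket the point ratio whenever the QSM
share is positive.

**Denominators.** Prevalence uses all examined hosts (mite-free
individuals included); "share of cases" uses mite-bearing hosts only.
Both are reported with their denominator attached because the two
conventions differ (e.g. 130 specific-carrying hosts is 90.3% of 144
examined but 93.5% of 139 mite-bearing hosts).

**Rounding.** Percentages are computed from the integer counts in
decimal arithmetic and rounded half-up (two decimals per taxon, one
decimal for subtotals and shares). This is the rule that reproduces the
published tables cell-for-cell, with three exceptions we treat as
misprints in the source tables because no deterministic rule can
satisfy them simultaneously with the rest (56.25 printed as 56.3
requires half-up; 4.6575 printed as 4.6 and 13.1506 as 13.1 forbid it;
likewise an abundance subtotal of 79.053 printed as 79.0).

## Classification rules

A taxon is classified from explicit evidence in fixed priority:

1. quill- and skin-dwelling mites are QSM regardless of occurrence —
   their contact transmission is restricted and some disperse by
   phoresy, so their records cannot be assigned to either route;
2. a vane taxon is *specific* iff it occurs only on the focal host,
   its sister taxon (when known) is hosted by a congeneric of the
   focal species, and its K2P distance to the nearest foster-parent
   mite (when known) exceeds the gene-flow threshold;
3. everything else is *alien*.

Missing molecular evidence never blocks classification: occurrence
exclusivity alone suffices for *specific* (the survey classified 29
taxa with sequence data for only a few). The gene-flow threshold
defaults to 5%, applied inclusively (d ≤ 0.05 means ongoing gene flow);
the same threshold is reused for the "shallow branch" criterion of the
alien rule, which is a package choice — the source analysis names no
numeric cutoff for that criterion.

## K2P distances and OTU delimitation

The Kimura two-parameter distance separates transition (P) and
transversion (Q) proportions:

    d = -(1/2) ln(1 - 2P - Q) - (1/4) ln(1 - 2Q)

Sites with a gap or N in either sequence are excluded pairwise
(standard for barcoding data, where coverage varies by pair). Distances
are proportions internally and percentages only at display. Observed
proportions outside the log domain raise a saturation error rather than
returning NaN.

OTU delimitation is a barcode-gap sweep: single-linkage clustering
(connected components of the graph with edges d ≤ t) at each threshold
t of a grid, keeping the partition that maximises
min(between-cluster d) − max(within-cluster d). Ties break to the
smallest threshold; partitions in which either term is undefined (one
cluster, or all-singleton clusters) cannot win on gap and are used only
as a fallback. This is deliberately a simplified stand-in for
probability-scored automatic partitioning: it reproduces two-species
configurations such as a 5.5% between / 0.2–0.3% within pair, but it
does not compute any partition score.

## Maximum-parsimony reconciliation

Undated duplication–transfer–loss parsimony on rooted binary trees.
For symbiont node s and host node h, `cost(s, h)` is the minimal cost
with s mapped exactly at h; `in(s, h)` additionally allows descending
host edges at one loss each; `out(s, h)` is the cheapest landing on any
host incomparable with h. Internal nodes choose among:

* codivergence (children into the two distinct host child subtrees),
* duplication (both children at or below h),
* switch (one child retained at/below h, the other landing on an
  incomparable host node; the landing site pays no losses because any
  descendant of an incomparable node is itself incomparable).

The optimum is the minimum of `cost(root, ·)`. Correctness is checked
against exhaustive enumeration of all node mappings on random
tanglegrams of up to six leaves.

**Census conventions.** Every internal symbiont node carries exactly
one of codivergence/duplication/switch; losses are counted per
traversed host edge. A "switch" is the transfer component of a
duplication-plus-transfer (one child stays on the donor lineage). The
backtrace reports one optimal reconciliation under a deterministic
tie-break (codivergence > duplication > switch, then smallest host
label, stopping descent chains as early as possible) together with the
number of co-optimal solutions counted by the DP; co-optima may differ
in switch direction but rarely in census at desk scale.

**Costs.** Costs are a mandatory, logged field with defaults
(cospeciation 0, duplication 1, switch 1, loss 1). The lineage census
reported by the acceptance analysis is additionally checked for
stability over the grid duplication, switch, loss ∈ {1, 2}.

**Time consistency.** Undated switches may imply temporally cyclic
scenarios. `is_time_consistent` runs a necessary-condition check: a
precedence digraph over host nodes (parent before child; each switch
adds parent(recipient) → donor and parent(donor) → recipient) must be
acyclic. It can pass scenarios a full interval-based dating would
reject; it never fails a truly consistent one.

**Known limitation — switch misattribution.** At equal unit costs an
undated MPR explains a codivergence followed by two sorting losses as a
single switch (cost 1 < 2). Histories simulated without switches can
therefore yield positive MPR switch counts; absence recovery is only
guaranteed under a costing where a switch cannot undercut the losses it
saves (e.g. loss = 0.05, switch = 1 at desk-scale tree heights).

## Reference fixtures

The occurrence survey fixture (144 examined hosts — 22 wild captures,
10 roadkills, 112 museum skins — 365 records, 1246 specimens, 29 taxa:
5 specific, 19 alien, 5 QSM) is rebuilt at run time from the printed
per-taxon totals and the printed per-host category-combination margins.
Which taxon sits on which individual host is not published, so records
are placed by a Havel–Hakimi style greedy fill (per-host taxon counts
spread near-evenly within each combination group, taxa assigned
largest-remaining-first) and specimens spread near-evenly across each
taxon's records. Every printed margin — per-taxon record and abundance
counts, per-combination host and record counts — is reproduced exactly;
the within-margin arrangement is one deterministic representative of
the feasible set, which is sufficient because every downstream
statistic depends only on the margins.

The three lineage tanglegrams encode the published topological
relationships: the cowbird-associated *Amerodectes* and
*Proctophyllodes* pairs are sisters on the two *Molothrus* species
(codivergence), with the *Sicalis*-associated *Amerodectes* lineage and
an outgroup-context *Proctophyllodes* attached so that one switch each
is required; the cowbird *Trouessartia* is nested in the
*Sicalis*-associated morphospecies (one switch). Host trees include
intervening taxa (*Agelaius*, *Cardinalis*, *Icterus*, *Zonotrichia*,
*Thraupis*) so the Icteridae and Thraupidae clades are not sisters.
Lineages whose within-genus splits postdate the corresponding host
split (the *Sicalis* mites) are represented as single OTUs: an undated
parsimony analysis cannot see the dating argument and would otherwise
score those splits as extra codivergences that the published census
does not count.

## Synthetic-data generators

**Transmission.** Each focal host is reared by one foster species
(uniform by default; a weight vector is accepted since real foster
usage is unknown), acquiring each of its pool taxa with probability
q_vi; it then makes n conspecific and m interspecific contacts,
acquiring each relevant taxon per contact with probability q_hc / q_hi.
First acquisition creates the record, repeats increment abundance —
mirroring presence/absence counting. The analytic per-taxon record
probability (1 − (1 − q_vc)(1 − q_hc)^n for specific taxa,
1 − (1 − q_vi w_f)(1 − q_hi w_f)^m for foster taxa) is exposed and used
as the recovery oracle. Defaults (144 hosts, 27 foster species × 1
taxon, 5 specific taxa, q_hc = 0.047 over 10 contacts, q_vi = 0.35,
q_hi = 0.03 over 5 contacts) were fixed once so the expected per-host
intensities match the observed survey (~1.91 specific and ~0.50 alien
records per host, expected ratio ≈ 3.8); no empirical contact rates
exist for this system, so these are illustrative calibration points,
not measurements. The simulator has no QSM pool: it generates the two
route-identified categories the estimator actually uses.

**K2P pairs.** Transition/transversion site probabilities are obtained
by solving the K2P expected-distance equations at the target distance
and instantaneous ts/tv ratio, then applied independently per site.
Near-saturating combinations of distance and length trigger a warning.

**Cophylogeny.** Event-level, not continuous-time: the host tree grows
by uniform random leaf splits; at each host split every symbiont
lineage on that host codiverges with probability p_cospeciate or
follows one child (a sorting loss); each surviving lineage then
switch-duplicates to a uniformly chosen other contemporary host with
probability rate_switch and goes extinct with probability rate_loss.
Replicates with fewer than two surviving symbiont lineages are
resampled from derived seeds. The log reports both the full history and
the events observable on the pruned symbiont tree; the full-history
parsimony cost upper-bounds the MPR optimum on every replicate, which
the tests exploit as an oracle.

What the generators do **not** emulate: within-host population
dynamics and competitive exclusion, abundance-dependent transmission,
phoresy, continuous-time branch lengths, rate variation across sites or
lineages, and sequencing error. Passing recovery tests therefore show
the estimators are consistent under the stated models, not that real
surveys satisfy those models.

## Problem sizes and numerical choices

Desk-scale throughout: the survey fixture is 144 × 29; reconciliation
correctness is checked exhaustively at ≤ 6 leaves (200 random
tanglegrams); estimator recovery uses 100 sequence replicates of 1000
sites and 50 occurrence replicates of 2000 hosts per configured ratio.
All simulation code is seeded; equal-cost DP ties resolve by the fixed
preference order; percentage arithmetic is exact decimal, never binary
float division of counts.
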