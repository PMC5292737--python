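# Methods

## The screen

Horizontal transfer (HT) of a transposable element between
reproductively isolated hosts leaves three signatures, and the package
operationalizes all three:

1. **Divergence below the host-age expectation.** Element copies
   inherited vertically in two taxa started diverging at the host
   split; transferred copies started at the transfer. Uncorrected
   p-distance is regressed on host split age by OLS and candidate
   pairs are those significantly below the line (details below).
2. **Element/host tree incongruence.** The element tree is inferred by
   neighbor-joining on the p-distance matrix with site-resampling
   bootstrap. Element-tree edges are translated into host-taxon sets
   through the element→taxon mapping; a host split A|B conflicts with
   an element edge C|D when all four taxon-set intersections are
   non-empty (the natural generalization of split incompatibility to
   multi-labelled trees, needed because one taxon can carry several
   element lineages). A clade-based Robinson–Foulds-style count (the
   symmetric difference between host clades and the element tree's
   "clean" taxon clades — edges whose sides share no taxon) summarizes
   overall incongruence.
3. **Patchy distribution.** Elements are partitioned into lineages:
   same lineage iff nucleotide divergence ≤ 1% *and* identical
   large-indel profile (a shared multi-hundred-bp deletion binds
   copies; an unshared one separates them even at 0.4% divergence).
   A lineage present in ≥ 2 taxa that are not monophyletic on the host
   tree restricted to the surveyed taxa is patchy.

## Point assembly

One point per unordered cross-taxon element pair: host split age (Myr,
from the dated host chronogram), nucleotide p-distance, and amino-acid
p-distance when available. Exclusions, applied before any fitting:

- **Ancient paralogs** — elements whose *median* divergence to all
  others exceeds 0.5. Such a copy (here the clade-B element R2BggB,
  55–56% divergent from everything) predates the genus and carries no
  information about host splits.
- **Degenerate copies** — elements flagged as lacking a meaningful
  reading frame (R2Brdeg). Their nucleotide distances are computable,
  but the analysis drops them from both responses so that the
  nucleotide and amino-acid point sets describe the same pairs; with
  them included the nucleotide refit is dominated by their elevated
  divergences and the published contrast does not reproduce.
- **Intra-taxon pairs** (age 0) — excluded by default; coexisting
  copies within one genome diverge on the paralog clock, not the host
  clock. `include_intra_taxon=True` restores them.

On the bundled table this leaves 19 nucleotide and 19 amino-acid
points over seven elements.

## Flagging rule

The default is one-sided iterative residual pruning: fit OLS on the
active points, standardize residuals, and while the most negative
standardized residual is below −`t_flag` (default 2.0), remove that
point and refit. Removed pairs are the candidates. Two deliberate
choices:

- **Robust scale.** Residuals are standardized by a median/MAD sigma
  rather than the classical OLS sigma. When a third of the points are
  contaminated by transfers (as in the bundled data: 6 of 19), the OLS
  sigma is inflated by the very outliers being tested and classical
  studentized residuals never reach −2; the MAD scale stays anchored
  to the vertical majority. The classical scale remains available
  (`scale="ols"`).
- **Age-class corroboration.** A candidate must also lie below half
  the maximum divergence of its own age class (classes with ≥ 2
  points). The linear trend leaves systematic lack-of-fit residuals —
  the true divergence-age curve saturates — and on clock-like no-HT
  simulations pure residual pruning falsely flags ~10–30% of
  replicates at any usable threshold; requiring a co-eval vertical
  reference removes essentially all of these while leaving genuine
  transfers (which sit far below their class ceiling) untouched.
  Candidates in singleton age classes are dropped as uncorroborable.
  Disable with `corroborate_f=None`.

An alternative `age-class` method (flag anything below *f*× the class
maximum, default 0.5) is provided; it is robust to heavy contamination
but blind in singleton classes and ignores the regression entirely.

The refit API also accepts an explicit exclusion list, so a published
exclusion set can be reproduced independently of any flagging
heuristic.

## Event reconstruction

Flagged pairs are grouped greedily into a minimal set of events: take
the element shared by the most remaining pairs (the hub), and bundle
all its pairs into one event if the partner elements are monophyletic
in the element tree up to intruders that are lineage-mates of a
partner or the hub itself (a back-transferred copy nests inside its
source clade without invalidating the grouping). Direction is a
heuristic, flagged as such on the event: a hub nested inside the
partner clade is called the recipient copy, a hub outside it the
donor; single-pair events leave direction undecided. Each event
carries an age upper bound (the youngest calibrated element-tree MRCA
age over its supporting pairs) and the three criteria flags.

## Tree building and dating

Neighbor-joining follows Saitou–Nei with two determinism rules: ties
in the Q-criterion join the lowest-index pair, and negative branch
lengths are clamped to zero with a warning. Bootstrap support is the
percentage of column-resampled replicates containing each bipartition,
seeded. Dating is a single-rate scaling: the rooted tree is
ultrametricized (node height = mean root-to-tip path below the node),
the rate is the mean of height/age over the calibration nodes, and
ages are height/rate. This exists to order events in reports; it is
not a relaxed-clock analysis, and its absolute ages are expected to
differ from Bayesian estimates.

## Distances

Uncorrected p-distances under pairwise deletion: columns with a gap
(`-`) or missing symbol (`N`/`X`) in either row, or outside either
record's declared coverage interval, are excluded per pair. This keeps
a 5′-only fragment comparable on its covered half. Standard errors are
analytic binomial, `sqrt(d(1−d)/n)`; a site-bootstrap SE is available.
Matrices are stored at full precision; published-table-layout output
rounds half-up to 3 decimals.

## Element characterization

- **Poly-A trimming:** the terminal A-run is removed when ≥ 5 nt
  (observed biological tails run 7–9 nt; shorter runs are likely
  sequence, not tail).
- **ORF finding:** stop-free, ATG-initiated codon runs ≥ 300 bp in the
  three forward frames seed chains; a run in another frame joins when
  it starts within 30 bp of the upstream run's end (overlap allowed —
  a 1-bp deletion makes the frames overlap), and a same-frame run
  joins across a single stop codon (read-through), at most two
  retained stops per ORF. The chain maximizing the joined span wins;
  ties prefer fewer frameshifts. A frameshift caused by a 1-bp indel
  is only localizable, homology-free, to the window between the new
  frame's opening and the old frame's terminal stop (~60–90 bp on
  random sequence); the annotation reports that window and its
  midpoint rather than pretending to base-pair precision.
- **Zinc fingers:** CCHH = `C.{2,4}C.{8,16}H.{3,5}H`, CCHC likewise
  with a terminal C, scanned over the first 250 aa; the patterns are
  a C2H2 consensus and are override-able. One CCHH suggests clade
  R2-D; CCHC+CCHH suggests R2-B.
- **Structural variants:** gap runs ≥ 50 bp in a pairwise alignment
  (the smallest biologically reported feature here is 57 bp);
  insertions are called duplications when the inserted block matches
  its flanking block at ≥ 90% identity. Coordinates are 1-based
  inclusive on the ungapped reference.

## The simulator

The generator emulates the study system: resident element lineages
evolve along the dated host chronogram by an exact per-site jump
process (substitution events per branch are Poisson with mean
rate × duration; JC draws the new base uniformly, K2P weights
transitions by κ). Transfers copy the donor lineage's sequence onto
the recipient branch at the event time, replacing the resident or not;
duplications fork a lineage within a branch; a paralog spec grafts a
lineage that split before the host root. Defaults are the study
conditions: 3 kb elements (the real ones are 3.0–4.8 kb; 3 kb keeps
the suite fast without changing any rate-based conclusion), a rate of
0.005 subs/site/Myr chosen so that 22.8 Myr of separation gives the
observed ~0.20 cross-taxon divergence (tests of detector operating
characteristics use 0.004, the rate at which a 1-Myr transfer between
22.8-Myr-diverged hosts mimics the published contrast), and the
transfer scenario of the nine-element fixture: one replacement
transfer at 8.6 Myr from the *B. rossius* lineage into the
*benazzii*/*maretimi* stem and one non-replacing back-transfer at
0.8 Myr. `direction_constraint` on an event is metadata recording the
presumed reproductive route (hemiclonal paternal→maternal versus
exclusion/androgenesis maternal→paternal); it does not change the
sequences.

What the simulator does *not* emulate: alignment error (deletions are
recorded as gap columns, so downstream pairwise deletion sees perfect
homology), rate variation across sites and lineages, selection,
copy-number dynamics within genomes, insertion-site biology, and
codon structure — root sequences are uniform random, so simulated
elements carry no ORFs; ORF and zinc-finger annotation is exercised on
constructed coding sequences instead.
Passing tests therefore demonstrate that the statistical machinery
recovers transfers under clock-like neutral evolution with known
homology — not that it is robust to alignment artifacts or rate
heterogeneity in real data.

Degradation (`degrade_element`) applies frameshift indels, premature
TAA codons in the frame of position 1, large deletions and tandem
duplications at uniform positions, logging 1-based input coordinates.
In the nine-element fixture the shared 426-bp deletion is applied at
identical coordinates to the donor and back-transferred copies, so
their gap columns coincide in the master alignment as an inherited
deletion should.

## Numerical and degenerate-input conventions

- Zero comparable sites is a *not-computed* marker, never a distance
  of 0; amino-acid pairs involving degenerate records are not-computed.
- R² is reported as the squared Pearson correlation (identical to OLS
  R² for simple regression); regression requires ≥ 3 points.
- The ultrametricity check compares leaf depths to the median depth
  (tolerance 10⁻⁶ relative) and names the offending leaves.
- The host chronogram fixes the basal split at 22.8 Myr, the
  *grandii*/*atticus* radiation at 17 Myr, their split at 15.4 Myr and
  the *benazzii*/*maretimi* split at 2 Myr; all ages are configurable
  by editing the Newick.
- Problem sizes in the test suite (3 kb sequences, 20-replicate
  operating-characteristic batches, 10–100 bootstrap replicates) were
  chosen as the smallest at which the binomial noise floor is well
  below the effects being measured.

## Known limitations

- The dating stand-in assumes a single global clock; its ages support
  event ordering only.
- Direction of transfer is a nesting heuristic; the biological
  argument (which taxon's reproductive system permits which route) is
  outside the package's scope.
- The flagging rule assumes most pairs in an age class are vertical;
  if every pair at some age were transferred, the class ceiling itself
  would be depressed and the guard would veto the candidates.
- Published-table inputs carry no site counts, so standard errors from
  such tables can only be matched approximately.
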