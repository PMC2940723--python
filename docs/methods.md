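# Methods

## The model

The package models the gene regulatory network that patterns the
anterior-posterior axis of the developing cerebral cortex.  Five genes carry
the patterning signal: *Fgf8*, *Pax6* and *Sp8* are expressed in
high-anterior gradients, *Emx2* and *Coup-tfi* in high-posterior gradients.
Expression is Boolean (on/off), reflecting the qualitative nature of the
available expression data: each of the ten nodes (five genes, five
proteins) is 0 or 1, so the system has 2^10 = 1024 states, written as
tuples `[*Fgf8*, Fgf8, *Emx2*, Emx2, *Pax6*, Pax6, *Coup-tfi*, Coup-tfi,
*Sp8*, Sp8]` (gene before its protein; tuple position 0 is the most
significant bit of the state index).

Update semantics (one time step = synthesis or decay):

* a protein is on at `t+1` iff its gene was on at `t`;
* a gene is on at `t+1` iff **all** of its inductive regulator proteins
  were on and **all** of its repressive regulator proteins were off at `t`
  (pure AND conjunction; OR logic is deliberately out of scope).

Space is reduced to two uncoupled compartments (anterior, posterior)
running the same rules and differing only in their initial state: anterior
starts with *Fgf8* gene and protein on (`[1,1,0,...,0]`, *Fgf8* initiated
by mechanisms outside the network), posterior starts all-zero.  The
desired steady states are the Boolean versions of the observed gradients:
anterior `[1,1,0,0,1,1,0,0,1,1]`, posterior `[0,0,1,1,0,0,1,1,0,0]`.
There is no signalling between compartments, so the model cannot (and does
not try to) represent shifted-gradient mutant phenotypes.

## The topology space

Regulation is protein -> gene only; each gene induces its own protein.
The induction of *Fgf8* by Sp8 is the only directly demonstrated
interaction and is fixed in every network, as are the five gene -> protein
edges.  Every other protein -> gene pair is a candidate edge whose sign is
forced by the expression gradients (same gradient direction -> inductive,
opposing -> repressive; auto-edges count as within-group inductions).
This yields exactly 24 variable edges — 12 inductive, 12 repressive — and
a topology is a 24-bit mask: 2^24 = 16,777,216 networks.

The canonical bit ordering (documented in `catalog.py` and exported by
`arealnet catalog`) groups edges by target gene in node order (Fgf8, Emx2,
Pax6, Coup-tfi, Sp8) and orders regulators the same way within each
target.  It is part of the serialization contract and never changes.

Because *Emx2* and *Coup-tfi* enter the model identically (same group,
same start and target values), exchanging them everywhere is a dynamics-
preserving involution on the space; the good set is closed under it.

## Asynchronous dynamics as a Markov chain

Synchronous updating is deterministic but produces artefactual
simultaneous switches; the model therefore uses fully asynchronous
updating: from state `s`, one node is picked uniformly among those whose
synchronous successor differs from the current value, and only that node
flips.  This defines a 1024-state Markov chain per network whose absorbing
states are exactly the synchronous fixed points.

A compartment's score is the probability that the chain started at the
compartment's initial state is absorbed into the desired steady state.
The default computation is an exact first-step-analysis linear solve on
the subgraph reachable from the start state: closed classes are the
strongly connected components without outgoing edges
(`scipy.sparse.csgraph`), and with `Q` the transient block and `B` the
one-step transient-to-class probabilities, absorption probabilities solve
`(I - Q) X = B` (sparse LU).  The iterative alternative — propagate the
start distribution until 99.99% of the mass sits in closed classes, then
normalise — is retained as `method="power_iteration"` and agrees with the
solve to 1e-4 by construction of its stopping rule; a seeded Monte-Carlo
simulator provides a third, independent estimate.  Multi-state closed
classes (cyclic attractors) are handled generally: their mass is never
credited to a desired target (targets are singleton fixed points), and
average expression inside them uses the class's stationary distribution.
Average steady-state expression per node is the class-probability-weighted
mean, interpreted as the mean over an inhomogeneous cell population.

The performance index is `Phi = min(P_anterior, P_posterior)`; a network
is **good** iff `Phi > 0.5` strictly.  Ties at exactly 0.5 are not good;
because the linear solve carries ~1e-15 round-off while the smallest
genuine margin above 1/2 anywhere in the topology space is 1.3e-4, the
comparison uses a 1e-9 guard band (`Phi > 0.5 + 1e-9`) so that provably
tied networks (e.g. the isolated flip-flops) are never counted good.
Good networks necessarily produce average expression gradients spanning
0.5 in the right direction for all ten nodes.

### The empty-conjunction convention

A gene whose only regulators are repressors is governed by the negated
repressors alone (empty AND over inducers = TRUE); this is forced by the
requirement that the posterior genes can switch on from the all-zero
start.  A gene with no regulators at all defaults to constitutively ON,
switchable to OFF (`unregulated_on=False`).  The choice is provably
inconsequential for the screen: it affects only genes with zero incoming
edges, i.e. exactly the networks carrying the `unregulated_node` flag, and
for those one compartment's target is not a fixed point under either
convention, so `Phi = 0` either way.  The good set, and hence the good
fraction, are convention-independent.

## The exhaustive screen

Scoring all 2^24 networks naively costs one sparse solve each.  Two
exact accelerations make the screen cheap:

* **Memoized state tables.**  A gene's next-state column over all 1024
  states depends only on its own incoming-edge bits, so there are just 144
  distinct weighted columns; any network's synchronous table is five
  column lookups plus a fixed protein part.  The cache is asserted
  bit-identical to naive per-node evaluation.
* **Structural pre-classification.**  Five structural flags each preclude
  goodness: an unregulated TF gene (its target value cannot be a fixed
  point in one compartment), Fgf8 not upstream of any TF (the compartments
  are then indistinguishable downstream, so the two disjoint absorption
  events cannot both exceed 1/2), auto-induction (the node is locked into
  its initial state or decays permanently), inductive loops generally (the
  Fgf8/Sp8 case included), and *fully* isolated repressive loops — mutual
  repression where neither partner has any other regulation, so the pair
  forms a flip-flop cut off from the network that resolves its initial
  race at exactly 1/2 per orientation.  One-sided isolation (only one
  partner cut off) is deliberately **not** flagged: such networks can be
  good (1,606 of them are), which is why the flag requires isolation on
  both sides.  The flags are computed vectorised over mask arrays (the
  inductive-loop test via a 4096-entry truth table over the 12 inductive
  bits) and are additionally sample-validated against the full Markov
  analysis in the test suite (1,000 random flagged networks per flag,
  zero good).  Only 0.277% of masks (46,496) carry no flag and receive
  the exact solve, halved again by analysing one representative per
  Emx2/Coup-tfi mirror pair.

`screen_unflagged()` runs this two-stage screen; the streaming
`screen()` API scores every mask individually (optionally with the same
fast path) and supports deterministic, resumable partitions checkpointed
as checksummed TSV chunks.

Full-space results computed by this package: 9,417 good networks
(0.0561% of 2^24, printing as 0.1% at one decimal; 89 further networks
sit at `Phi = 0.5` up to round-off and are excluded by the strict
criterion), best `Phi = 0.7374` (74%) attained by exactly two networks,
masks `514750` and `555250`, which are each other's Emx2/Coup-tfi mirror
images.  The two best networks sit inside the 64-member near-best family
(seven required edges, six optional repressive edges), all of whose
members are good; the good networks average 7.2 interactions away from
the best network, against exactly 12 for the whole space.

A note on sampled checks: a *stratified* 1/256 sub-screen (every 256th
mask) is **not** an unbiased estimate of the good fraction — fixing the
low eight bits to zero removes most of *Emx2*'s candidate regulators, and
the good fraction in that slice is structurally depressed relative to the
space-wide value.  Uniform random sampling is unbiased; assertions about
the good fraction therefore screen the full space via the two-stage path
rather than extrapolating from the stratified slice.

## Downstream analyses

* **Interaction frequencies**: fraction of networks in a set containing
  each variable edge.  Among the good networks the five auto-induction
  edges and Fgf8 -> *Sp8* sit at exactly zero; mirror-image edge pairs
  (Emx2/Coup-tfi) have identical frequencies by symmetry.  Conditional
  frequencies after excluding higher-order bad combinations depend on the
  exact exclusion list used, which is accepted as user input
  (`mine` output or an external list) rather than baked in.
* **Combination mining**: all present/absent patterns over up to four
  variable edges, classified good (all matches good), bad (good fraction
  among matches <= `bad_tolerance`, default 0 = never good), or neutral.
* **Distance analysis**: the distance between two topologies is the
  number of differing interactions (Hamming distance on masks, 0..24).
  Over the whole space distances to any reference are Binomial(24, 1/2)
  with mean exactly 12; the good networks are markedly closer to the best
  network than that.

## Numerical choices and limitations

* Probabilities are double precision throughout; printed-percentage
  comparisons round half away from zero to the printed precision.
* Monte-Carlo runs are capped at 10,000 steps (configurable); the cap is
  far beyond typical absorption times on 1024 states and only guards
  pathological chains, and capped runs are reported, never silently
  dropped.
* The power-iteration stopping rule (99.99% absorbed mass) bounds its
  error by 1e-4; the linear solve is exact up to LU round-off.
* The model is two-level and two-compartment by design: it cannot
  represent graded shifts, inter-compartment signalling, or more than two
  expression levels, and the screen's conclusions are structural
  (which topologies can reproduce the Boolean gradients), not kinetic.
* Problem sizes used by the test suite: exact analyses of the fixture
  networks, property checks on 50-200 random topologies per invariant,
  1,000 random networks per structural flag, Monte-Carlo cross-checks at
  n = 10,000 for 20 random cases, and the two-stage full-space screen for
  the good-fraction and best-network assertions.
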