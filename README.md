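# arealnet

Boolean-network screening of the gene regulatory network that patterns the
anterior-posterior axis of the developing cerebral cortex.

During early corticogenesis, graded expression of five genes — *Fgf8*,
*Pax6* and *Sp8* (high anterior) versus *Emx2* and *Coup-tfi* (high
posterior) — lays down the coordinate system from which cortical areas
later emerge.  Which regulatory interactions between these genes actually
produce the observed counter-gradients is largely unresolved: most
proposed interactions rest on indirect evidence from mutants.  `arealnet`
is for systems/developmental biologists who want to ask, network by
network, *which topologies can do the job at all*.

## The model

Each gene and its protein is a Boolean node (10 nodes, 1024 states).  A
protein is on at `t+1` iff its gene was on at `t`; a gene is on iff all
its inductive regulators were on and all its repressive regulators off
(pure AND logic).  Candidate protein→gene interactions have their sign
forced by the expression gradients (same direction → inductive, opposing →
repressive), giving 24 optional edges beyond 6 fixed ones (gene→protein
synthesis and the experimentally demonstrated Sp8 → *Fgf8*); a topology is
a 24-bit mask, and the full space holds 2^24 = 16,777,216 networks.

Two compartments (anterior/posterior) run the same rules and differ only
in the start state: anterior begins with *Fgf8* gene+protein on, posterior
all-off.  Under fully asynchronous updating (one randomly chosen
changeable node flips per step) each network is an absorbing Markov chain,
and a compartment is scored by the probability of absorption into its
desired steady state:

    P_ant = P( [1,1,0,0,0,0,0,0,0,0] ⇝ [1,1,0,0,1,1,0,0,1,1] )
    P_post = P( [0,0,0,0,0,0,0,0,0,0] ⇝ [0,0,1,1,0,0,1,1,0,0] )
    Φ = min(P_ant, P_post);   good  ⇔  Φ > 1/2

Absorption probabilities are exact (first-step analysis on the reachable
subgraph, `scipy.sparse`); power iteration and a seeded Monte-Carlo
simulator serve as independent cross-checks.  See `docs/methods.md` for
the full model account, numerical choices and limitations.

## Worked example

The long-hypothesised literature network (mask `1854d3`: Fgf8
auto-induction, the Fgf8/Sp8 inductive loop, mutual Fgf8/Emx2 repression,
Coup-tfi → *Emx2*, repression of *Pax6* by Emx2 and Coup-tfi, of *Emx2*
by Pax6, of *Sp8* by Emx2):

```bash
$ arealnet simulate --network 1854d3
{
 "mask_hex": "1854d3",
 "p_anterior": 0.375,
 "p_posterior": 1.0,
 "phi": 0.375,
 "good": false,
 "average_expression": {
  "anterior":  [0.375, 0.375, 0.625, 0.625, 0.375, 0.375, 0.625, 0.625, 0.375, 0.375],
  "posterior": [0.0, 0.0, 1.0, 1.0, 0.0, 0.0, 1.0, 1.0, 0.0, 0.0]
 }
}
```

Read: from the posterior start the network always reaches the desired
posterior state, but from the anterior start it succeeds only 37.5% of
the time (38%), because Fgf8 auto-induction and the Fgf8/Sp8 loop lose a
race against *Fgf8* switching off.  The anterior average expression
(node order `[*Fgf8*, Fgf8, *Emx2*, Emx2, *Pax6*, Pax6, *Coup-tfi*,
Coup-tfi, *Sp8*, Sp8]`) shows anterior genes averaging 0.375 and posterior
genes 0.625 — the gradients point the right way but fail to span 0.5, so
the network is not classified good.

Screening the whole space (`arealnet screen`, or in one call
`arealnet.screen.screen_unflagged(use_symmetry=True)`, ~3 min) shows how
exceptional working topologies are: 9,417 of 16,777,216 networks
(0.06%) are good, none of them containing auto-induction, the Fgf8→*Sp8*
edge, any inductive loop, or a fully isolated mutually-repressive pair.
The best pair of networks (masks `514750`/`555250`, Emx2↔Coup-tfi mirror
images) reach Φ = 0.74, and relaxing them over six optional repressive
edges yields a 64-network family that is good throughout.

Other entry points: `arealnet catalog` (the canonical 24-edge table),
`arealnet fixtures` (built-in networks), `arealnet distance`,
`arealnet export --fmt dot`, `arealnet mine` (combination patterns over
screen checkpoints), and `arealnet summarize`.

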