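"""Boolean update rules and the synchronous state table.

Each network is compiled into one Boolean function per node.  A protein is
active at ``t+1`` iff its gene was active at ``t`` (synthesis in one step,
decay in one step).  A gene is active at ``t+1`` iff *all* of its inductive
regulator proteins were active and *all* of its repressive regulator
proteins were inactive at ``t`` — regulation is a pure AND conjunction; the
model deliberately excludes OR logic.

States are 10-tuples over the nodes
``[*Fgf8*, Fgf8, *Emx2*, Emx2, *Pax6*, Pax6, *Coup-tfi*, Coup-tfi, *Sp8*, Sp8]``
(gene then protein).  A state's integer index treats tuple position 0 as the
most significant bit: ``index = sum(bits[i] << (9 - i))``.

Empty-conjunction convention
----------------------------
A gene whose only regulators are repressors is governed by the negated
repressors alone (the empty AND over inducers is TRUE) — this is required
for the posterior genes to switch on from the all-zero start state.  A gene
with *no* regulators at all (possible only for the four TF genes, since
*Fgf8* always keeps its fixed Sp8 inducer) defaults to constitutively ON
(empty AND = TRUE), switchable to constitutively OFF via
``unregulated_on=False``.  The choice is observable only in networks that
carry the ``unregulated_node`` structural flag, which are never good under
either convention, so the screen's good set does not depend on it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .catalog import GENES, N_VARIABLE_EDGES, NetworkSpec, build_catalog

__all__ = [
    "N_STATES",
    "state_index",
    "state_bits",
    "NodeRule",
    "UpdateRules",
    "compile_rules",
    "sync_next",
    "build_state_table",
    "find_fixed_points",
    "state_table_frame",
]

N_NODES = 10
N_STATES = 1 << N_NODES  # 1024

#: tuple position of gene g / protein g (g = gene index 0..4)
def gene_pos(g: int) -> int:
    return 2 * g


def protein_pos(g: int) -> int:
    return 2 * g + 1


def state_index(bits: Sequence[int]) -> int:
    """Integer index of a 10-tuple state (position 0 is the MSB)."""
    if len(bits) != N_NODES:
        raise ValueError("state must have 10 entries")
    idx = 0
    for b in bits:
        if b not in (0, 1):
            raise ValueError("state bits must be 0 or 1")
        idx = idx << 1 | b
    return idx


def state_bits(index: int) -> tuple[int, ...]:
    """Inverse of :func:`state_index`."""
    if not 0 <= index < N_STATES:
        raise ValueError(f"state index {index} outside [0, 1024)")
    return tuple(index >> (N_NODES - 1 - i) & 1 for i in range(N_NODES))


@dataclass(frozen=True)
class NodeRule:
    """AND-conjunction rule for one node, over tuple positions of regulators."""

    inducers: frozenset[int]
    repressors: frozenset[int]
    #: value when both regulator sets are empty (gene nodes only)
    default: int = 1

    def evaluate(self, bits: Sequence[int]) -> int:
        if not self.inducers and not self.repressors:
            return self.default
        for i in self.inducers:
            if not bits[i]:
                return 0
        for r in self.repressors:
            if bits[r]:
                return 0
        return 1


@dataclass(frozen=True)
class UpdateRules:
    """One :class:`NodeRule` per tuple position, for one network topology."""

    nodes: tuple[NodeRule, ...]
    mask: int
    unregulated_on: bool = True


def compile_rules(spec: NetworkSpec | int, unregulated_on: bool = True) -> UpdateRules:
    """Compile a topology into per-node Boolean rules.

    Protein nodes depend only on their own gene.  Gene nodes collect the
    protein positions of their inductive and repressive regulators from the
    catalog bits set in the mask, plus the fixed Sp8 -> *Fgf8* induction.
    """
    mask = spec.mask if isinstance(spec, NetworkSpec) else int(spec)
    spec = NetworkSpec(mask)
    cat = build_catalog()
    gene_index = {g: i for i, g in enumerate(GENES)}

    inducers: list[set[int]] = [set() for _ in range(N_NODES)]
    repressors: list[set[int]] = [set() for _ in range(N_NODES)]
    for g in range(5):
        inducers[protein_pos(g)].add(gene_pos(g))  # synthesis
    inducers[gene_pos(0)].add(protein_pos(4))  # fixed Sp8 -> *Fgf8*
    for i in range(N_VARIABLE_EDGES):
        if not mask >> i & 1:
            continue
        e = cat.edge(i)
        r = protein_pos(gene_index[e.regulator])
        t = gene_pos(gene_index[e.target])
        (inducers if e.sign == "inductive" else repressors)[t].add(r)

    nodes = tuple(
        NodeRule(
            frozenset(inducers[p]),
            frozenset(repressors[p]),
            default=1 if unregulated_on else 0,
        )
        for p in range(N_NODES)
    )
    return UpdateRules(nodes, mask, unregulated_on)


def sync_next(rules: UpdateRules, state: Sequence[int]) -> tuple[int, ...]:
    """Apply every node's rule simultaneously (deterministic successor)."""
    return tuple(rule.evaluate(state) for rule in rules.nodes)


# ---------------------------------------------------------------------------
# Vectorised state tables.
#
# A gene's next-state column over all 1024 states depends only on which of
# its (at most five) candidate regulators are switched on in the mask, so
# there are just 144 distinct weighted gene columns; any network's table is
# the sum of five column lookups plus the fixed protein part.  The cache
# makes the 2^24-network screen tractable and is asserted bit-identical to
# the naive per-node evaluation in the tests.
# ---------------------------------------------------------------------------

_IDX = np.arange(N_STATES, dtype=np.uint16)
#: bit of tuple position p in every state
_POSBIT = [((_IDX >> (N_NODES - 1 - p)) & 1).astype(np.uint16) for p in range(N_NODES)]

#: protein contribution to the next index: protein g copies gene g
_PROTEIN_PART = sum(
    _POSBIT[gene_pos(g)].astype(np.uint16) << np.uint16(8 - 2 * g) for g in range(5)
).astype(np.uint16)

#: (base bit, regulator gene indices) of each target gene's mask field
_TARGET_FIELDS = [
    (0, (0, 1, 2, 3)),        # *Fgf8*: Sp8 edge is fixed, not in the mask
    (4, (0, 1, 2, 3, 4)),     # *Emx2*
    (9, (0, 1, 2, 3, 4)),     # *Pax6*
    (14, (0, 1, 2, 3, 4)),    # *Coup-tfi*
    (19, (0, 1, 2, 3, 4)),    # *Sp8*
]

_ANTERIOR_IDX = frozenset({0, 2, 4})  # Fgf8, Pax6, Sp8


def _gene_column(t: int, sub: int, unregulated_on: bool) -> np.ndarray:
    """Next-bit column of gene ``t`` given its incoming-edge submask."""
    base, regs = _TARGET_FIELDS[t]
    col = np.ones(N_STATES, dtype=np.uint16)
    n_regs = 0
    for j, r in enumerate(regs):
        if not sub >> j & 1:
            continue
        n_regs += 1
        same = (r in _ANTERIOR_IDX) == (t in _ANTERIOR_IDX)
        pb = _POSBIT[protein_pos(r)]
        col &= pb if same else (1 - pb)
    if t == 0:
        col &= _POSBIT[protein_pos(4)]  # fixed Sp8 inducer
    elif n_regs == 0 and not unregulated_on:
        col[:] = 0
    return col


_COLUMN_CACHE: dict[tuple[int, int, bool], np.ndarray] = {}


def _weighted_column(t: int, sub: int, unregulated_on: bool) -> np.ndarray:
    key = (t, sub, unregulated_on)
    col = _COLUMN_CACHE.get(key)
    if col is None:
        col = (
            _gene_column(t, sub, unregulated_on) << np.uint16(9 - 2 * t)
        ).astype(np.uint16)
        _COLUMN_CACHE[key] = col
    return col


def submasks(mask: int) -> tuple[int, ...]:
    """Split a 24-bit mask into the five per-target-gene submasks."""
    out = []
    for t, (base, regs) in enumerate(_TARGET_FIELDS):
        out.append(mask >> base & ((1 << len(regs)) - 1))
    return tuple(out)


def build_state_table(rules: UpdateRules | NetworkSpec | int) -> np.ndarray:
    """Synchronous next-state index for all 1024 states (uint16 array)."""
    if isinstance(rules, UpdateRules):
        mask, on = rules.mask, rules.unregulated_on
    else:
        mask = rules.mask if isinstance(rules, NetworkSpec) else int(rules)
        on = True
    table = _PROTEIN_PART.copy()
    for t, sub in enumerate(submasks(mask)):
        table += _weighted_column(t, sub, on)
    return table


def find_fixed_points(table: np.ndarray) -> list[int]:
    """States unchanged by the synchronous rules (the chain's absorbing states)."""
    table = np.asarray(table)
    return [int(s) for s in np.flatnonzero(table == _IDX.astype(table.dtype))]


def state_table_frame(table: np.ndarray) -> "pandas.DataFrame":  # noqa: F821
    """State table as a debugging-friendly DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        {
            "state_index": np.arange(N_STATES),
            "state_bits": ["".join(map(str, state_bits(i))) for i in range(N_STATES)],
            "next_index": np.asarray(table, dtype=np.int64),
        }
    )
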