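"""The interaction catalog and the space of candidate network topologies.

Five genes pattern the anterior-posterior axis of the developing cortex:
*Fgf8*, *Pax6* and *Sp8* are expressed in high-anterior gradients, *Emx2*
and *Coup-tfi* in high-posterior gradients.  The model tracks ten Boolean
nodes (each gene plus its protein).  Regulation is protein -> gene only,
and every gene induces its own protein.  The sign of a candidate edge is
forced by the expression gradients: proteins induce genes with the same
gradient direction and repress genes with the opposing direction, so each
ordered (protein, gene) pair yields exactly one candidate interaction.

Six edges are present in every network: the five gene -> protein edges and
the experimentally demonstrated induction of *Fgf8* by the Sp8 protein.
The remaining 24 protein -> gene edges are free, so a topology is a point
in a 2^24 space and is identified by a 24-bit mask over the canonical edge
ordering defined here.

Canonical variable-edge ordering (bit 0 is the least significant bit of the
mask): edges are grouped by target gene in the order Fgf8, Emx2, Pax6,
Coup-tfi, Sp8, and within a target ordered by regulator protein in the same
order; the fixed Sp8 -> *Fgf8* edge is skipped.  This ordering never
changes: it defines the meaning of every serialized mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "GENES",
    "ANTERIOR_GENES",
    "POSTERIOR_GENES",
    "NODE_NAMES",
    "Gene",
    "Interaction",
    "InteractionCatalog",
    "NetworkSpec",
    "N_VARIABLE_EDGES",
    "N_NETWORKS",
    "build_catalog",
    "decode",
    "encode",
    "network_distance",
    "swap_emx2_couptfi",
    "enumerate_networks",
    "catalog_table",
]

#: Gene names in canonical node order.
GENES = ("Fgf8", "Emx2", "Pax6", "Coup-tfi", "Sp8")

#: Genes expressed high-anterior / high-posterior.
ANTERIOR_GENES = frozenset({"Fgf8", "Pax6", "Sp8"})
POSTERIOR_GENES = frozenset({"Emx2", "Coup-tfi"})

#: The ten Boolean nodes in state-tuple order: gene then protein, per gene.
#: Gene nodes are conventionally written in italics (here starred).
NODE_NAMES = tuple(
    name for g in GENES for name in (f"*{g}*", g)
)

N_VARIABLE_EDGES = 24
N_NETWORKS = 1 << N_VARIABLE_EDGES  # 16,777,216

_GENE_INDEX = {g: i for i, g in enumerate(GENES)}


@dataclass(frozen=True)
class Gene:
    """One of the five arealisation genes."""

    name: str

    def __post_init__(self) -> None:
        if self.name not in _GENE_INDEX:
            raise ValueError(f"unknown gene {self.name!r}")

    @property
    def index(self) -> int:
        return _GENE_INDEX[self.name]

    @property
    def gradient_group(self) -> str:
        return "anterior" if self.name in ANTERIOR_GENES else "posterior"


@dataclass(frozen=True)
class Interaction:
    """A directed regulatory edge.

    Protein -> gene edges carry the biology; the regulator is the protein of
    ``regulator`` acting on the gene node of ``target``.  The five
    gene -> protein edges are represented with ``kind='synthesis'``.
    """

    regulator: str
    target: str
    sign: str  # 'inductive' | 'repressive'
    fixed: bool = False
    kind: str = "regulation"  # 'regulation' | 'synthesis'

    def __post_init__(self) -> None:
        for g in (self.regulator, self.target):
            if g not in _GENE_INDEX:
                raise ValueError(f"unknown gene {g!r}")
        if self.sign not in ("inductive", "repressive"):
            raise ValueError(f"bad sign {self.sign!r}")
        if self.kind not in ("regulation", "synthesis"):
            raise ValueError(f"bad kind {self.kind!r}")

    def __str__(self) -> str:
        if self.kind == "synthesis":
            return f"*{self.regulator}* -> {self.target}"
        arrow = "->" if self.sign == "inductive" else "-|"
        return f"{self.regulator} {arrow} *{self.target}*"


def _sign_for(regulator: str, target: str) -> str:
    same = (regulator in ANTERIOR_GENES) == (target in ANTERIOR_GENES)
    return "inductive" if same else "repressive"


def _build_edges() -> tuple[tuple[Interaction, ...], tuple[Interaction, ...]]:
    variable = []
    for target in GENES:
        for regulator in GENES:
            if target == "Fgf8" and regulator == "Sp8":
                continue  # fixed, demonstrated experimentally
            variable.append(
                Interaction(regulator, target, _sign_for(regulator, target))
            )
    fixed = [Interaction("Sp8", "Fgf8", "inductive", fixed=True)]
    fixed += [
        Interaction(g, g, "inductive", fixed=True, kind="synthesis")
        for g in GENES
    ]
    return tuple(variable), tuple(fixed)


@dataclass(frozen=True)
class InteractionCatalog:
    """The 24 candidate edges (in canonical bit order) plus the 6 fixed ones."""

    variable_edges: tuple[Interaction, ...]
    fixed_edges: tuple[Interaction, ...]

    def bit_index(self, regulator: str, target: str) -> int:
        """Mask bit of the variable edge regulator-protein -> target-gene."""
        for i, e in enumerate(self.variable_edges):
            if e.regulator == regulator and e.target == target:
                return i
        raise KeyError(f"{regulator} -> *{target}* is not a variable edge")

    def edge(self, bit: int) -> Interaction:
        return self.variable_edges[bit]


_CATALOG = InteractionCatalog(*_build_edges())


def build_catalog() -> InteractionCatalog:
    """Return the canonical interaction catalog (a module-level singleton)."""
    return _CATALOG


@dataclass(frozen=True)
class NetworkSpec:
    """One network topology, identified by a 24-bit mask.

    Bit ``i`` of ``mask`` switches ``build_catalog().variable_edges[i]``;
    the six fixed edges are implicit in every network.
    """

    mask: int

    def __post_init__(self) -> None:
        if not 0 <= self.mask < N_NETWORKS:
            raise ValueError(f"mask {self.mask} outside [0, 2^24)")

    @property
    def hex(self) -> str:
        return f"{self.mask:06x}"

    @classmethod
    def from_hex(cls, text: str) -> "NetworkSpec":
        return cls(int(text, 16))

    def has_edge(self, regulator: str, target: str) -> bool:
        return bool(self.mask >> _CATALOG.bit_index(regulator, target) & 1)

    def variable_edges(self) -> tuple[Interaction, ...]:
        return tuple(
            e for i, e in enumerate(_CATALOG.variable_edges) if self.mask >> i & 1
        )

    def edges(self) -> tuple[Interaction, ...]:
        """All edges of the network, fixed ones included."""
        return _CATALOG.fixed_edges + self.variable_edges()


def decode(mask: int) -> frozenset[Interaction]:
    """Variable edges selected by ``mask`` (the fixed edges are implicit)."""
    return frozenset(NetworkSpec(mask).variable_edges())


def encode(edges: Sequence[Interaction]) -> int:
    """Inverse of :func:`decode`: a mask from a collection of variable edges."""
    mask = 0
    for e in edges:
        if e.fixed or e.kind != "regulation":
            raise ValueError(f"{e} is not a variable edge")
        mask |= 1 << _CATALOG.bit_index(e.regulator, e.target)
    return mask


def network_distance(a: NetworkSpec | int, b: NetworkSpec | int) -> int:
    """Number of interactions differing between two topologies (0..24)."""
    ma = a.mask if isinstance(a, NetworkSpec) else int(a)
    mb = b.mask if isinstance(b, NetworkSpec) else int(b)
    return int(ma ^ mb).bit_count()


def _swap_permutation() -> np.ndarray:
    """bit -> bit map exchanging the Emx2 and Coup-tfi roles."""
    sigma = {0: 0, 1: 3, 2: 2, 3: 1, 4: 4}  # gene-index swap Emx2 <-> Coup-tfi
    perm = np.empty(N_VARIABLE_EDGES, dtype=np.int64)
    for i, e in enumerate(_CATALOG.variable_edges):
        r = GENES[sigma[_GENE_INDEX[e.regulator]]]
        t = GENES[sigma[_GENE_INDEX[e.target]]]
        perm[i] = _CATALOG.bit_index(r, t)
    return perm


_SWAP_PERM = _swap_permutation()


def swap_emx2_couptfi(spec: NetworkSpec | int) -> NetworkSpec:
    """Mirror a topology by exchanging Emx2 and Coup-tfi everywhere.

    The two posterior genes enter the model symmetrically (same gradient
    group, same start and target values), so this map leaves the dynamics,
    and hence the performance index, unchanged.  It is an involution.
    """
    m = spec.mask if isinstance(spec, NetworkSpec) else int(spec)
    out = 0
    for i in range(N_VARIABLE_EDGES):
        if m >> i & 1:
            out |= 1 << int(_SWAP_PERM[i])
    return NetworkSpec(out)


def swap_masks(masks: np.ndarray) -> np.ndarray:
    """Vectorised :func:`swap_emx2_couptfi` on an array of masks."""
    masks = np.asarray(masks, dtype=np.uint32)
    out = np.zeros_like(masks)
    for i in range(N_VARIABLE_EDGES):
        out |= ((masks >> np.uint32(i)) & np.uint32(1)) << np.uint32(_SWAP_PERM[i])
    return out


def enumerate_networks(start: int = 0, end: int = N_NETWORKS) -> Iterator[NetworkSpec]:
    """Yield NetworkSpec for every mask in ``[start, end)`` in ascending order."""
    if not 0 <= start <= end <= N_NETWORKS:
        raise ValueError(f"invalid range [{start}, {end})")
    for m in range(start, end):
        yield NetworkSpec(m)


def catalog_table() -> "pandas.DataFrame":  # noqa: F821
    """The catalog as a table: regulator, target, sign, fixed, bit_index."""
    import pandas as pd

    rows = [
        {
            "regulator": e.regulator,
            "target": e.target,
            "sign": e.sign,
            "fixed": False,
            "bit_index": i,
        }
        for i, e in enumerate(_CATALOG.variable_edges)
    ]
    rows += [
        {
            "regulator": e.regulator if e.kind == "regulation" else f"*{e.regulator}*",
            "target": e.target,
            "sign": e.sign,
            "fixed": True,
            "bit_index": -1,
        }
        for e in _CATALOG.fixed_edges
    ]
    return pd.DataFrame(rows)
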