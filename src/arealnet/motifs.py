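"""Post-screen structural analyses.

Given the set of good networks (or any set of masks), this module computes
per-interaction presence frequencies, mines present/absent combination
patterns of up to four interactions that are always bad or always good,
and builds distance histograms (Hamming distance on the 24-bit mask,
i.e. the number of interactions differing between two topologies).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .catalog import N_VARIABLE_EDGES, NetworkSpec, build_catalog, network_distance
from .screen import ScreenRecord

__all__ = [
    "CombinationPattern",
    "interaction_frequency",
    "mine_combinations",
    "distance_distribution",
    "frequency_table",
]


def _as_mask_array(network_set: Iterable) -> np.ndarray:
    masks = [
        m.mask if isinstance(m, NetworkSpec) else int(m) for m in network_set
    ]
    if not masks:
        raise ValueError("empty network set")
    return np.asarray(masks, dtype=np.uint32)


def interaction_frequency(network_set: Iterable) -> np.ndarray:
    """Fraction of networks in the set containing each variable edge.

    Returns a length-24 array indexed by catalog bit.  The six fixed edges
    are present in every network by construction and are not listed.
    """
    masks = _as_mask_array(network_set)
    return np.array(
        [np.mean(masks >> np.uint32(b) & 1) for b in range(N_VARIABLE_EDGES)]
    )


def frequency_table(network_set: Iterable, label: str = "frequency") -> pd.DataFrame:
    """Presence frequencies as a table sorted by decreasing frequency."""
    freq = interaction_frequency(network_set)
    cat = build_catalog()
    df = pd.DataFrame(
        {
            "interaction": [str(cat.edge(b)) for b in range(N_VARIABLE_EDGES)],
            "sign": [cat.edge(b).sign for b in range(N_VARIABLE_EDGES)],
            "bit_index": np.arange(N_VARIABLE_EDGES),
            label: freq,
        }
    )
    return df.sort_values(label, ascending=False, ignore_index=True)


@dataclass(frozen=True)
class CombinationPattern:
    """A partial present/absent assignment of up to four variable edges.

    ``present`` and ``absent`` are tuples of catalog bit indices.  A mask
    matches when all ``present`` bits are set and all ``absent`` bits are
    clear.  Classification against a screened record set:

    * ``good`` — every matching network is good;
    * ``bad`` — the good fraction among matches is <= the bad tolerance
      (zero by default: the combination never appears in a good network);
    * ``neutral`` — otherwise.
    """

    present: tuple[int, ...]
    absent: tuple[int, ...]
    n_matching: int
    n_good: int
    classification: str

    @property
    def order(self) -> int:
        return len(self.present) + len(self.absent)

    def describe(self) -> str:
        cat = build_catalog()
        parts = [f"{cat.edge(b)} present" for b in self.present]
        parts += [f"{cat.edge(b)} absent" for b in self.absent]
        return " & ".join(parts)


def mine_combinations(
    records: Sequence[ScreenRecord],
    max_order: int = 4,
    bad_tolerance: float = 0.0,
    suppress_implied: bool = False,
) -> list[CombinationPattern]:
    """Enumerate all present/absent patterns up to ``max_order`` edges.

    For each pattern, counts matching and matching-good networks over the
    record set and classifies the pattern.  With ``suppress_implied`` a
    bad pattern is dropped when a strict sub-pattern of it is already bad
    (every superset of a never-good combination is trivially never good).
    """
    if not 1 <= max_order <= 4:
        raise ValueError("max_order must be in 1..4")
    masks = np.asarray([r.mask for r in records], dtype=np.uint32)
    good = np.asarray([r.good for r in records], dtype=bool)
    good_masks = masks[good]

    out: list[CombinationPattern] = []
    bad_seen: list[tuple[frozenset[int], frozenset[int]]] = []
    for order in range(1, max_order + 1):
        for bits in combinations(range(N_VARIABLE_EDGES), order):
            bit_arr = np.uint32(sum(1 << b for b in bits))
            for signs in product((True, False), repeat=order):
                present = tuple(b for b, s in zip(bits, signs) if s)
                absent = tuple(b for b, s in zip(bits, signs) if not s)
                want = np.uint32(sum(1 << b for b in present))
                match = (masks & bit_arr) == want
                n_match = int(match.sum())
                if n_match == 0:
                    continue
                n_good = int(((good_masks & bit_arr) == want).sum())
                frac = n_good / n_match
                if frac <= bad_tolerance:
                    cls = "bad"
                elif n_good == n_match:
                    cls = "good"
                else:
                    cls = "neutral"
                if cls == "bad" and suppress_implied:
                    p, a = frozenset(present), frozenset(absent)
                    if any(bp <= p and ba <= a for bp, ba in bad_seen):
                        continue
                    bad_seen.append((p, a))
                out.append(
                    CombinationPattern(present, absent, n_match, n_good, cls)
                )
    return out


def distance_distribution(
    network_set: Iterable, reference: NetworkSpec | int
) -> tuple[np.ndarray, float]:
    """Histogram of distances (0..24) from a reference topology, plus mean.

    The distance between two networks is the number of interactions
    differing between them (popcount of the XOR of their masks).
    """
    masks = _as_mask_array(network_set)
    ref = reference.mask if isinstance(reference, NetworkSpec) else int(reference)
    d = np.bitwise_count(masks ^ np.uint32(ref)).astype(np.int64)
    hist = np.bincount(d, minlength=N_VARIABLE_EDGES + 1)
    return hist, float(d.mean())
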