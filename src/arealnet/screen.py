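"""Exhaustive screening of the 2^24 network topologies.

Every topology is scored by its two compartment trajectory probabilities
and the performance index Phi; a network is good iff Phi > 0.5.  Structural
classifiers flag motifs that preclude good performance:

``unregulated_node``
    some TF gene has no incoming variable edge (*Fgf8* is exempt: it always
    keeps its fixed Sp8 inducer);
``fgf8_not_upstream``
    none of the four Fgf8-protein -> TF-gene edges is present, so the two
    compartments (which differ only in initial Fgf8 activity) cannot be
    told apart downstream;
``auto_induction``
    any of the five self-induction edges is present — the node is either
    locked into its initial state or shuts down permanently;
``inductive_loop``
    the inductive edges (including the fixed Sp8 -> *Fgf8*) form a directed
    cycle through gene -> protein synthesis;
``isolated_repressive_loop``
    mutual repression X -| *Y*, Y -| *X* where neither gene has any other
    regulation.  The pair is then dynamically cut off from the rest of the
    network: from the all-off start it resolves by an unbiased race to
    (on, off) or (off, on), so the desired orientation is reached with
    probability exactly 1/2 in each compartment and the network can never
    be strictly good.  One-sided isolation (only *Y* cut off) does *not*
    preclude goodness and is deliberately not flagged.

The screen supports partitioned, resumable runs with checksummed TSV
chunks whose concatenation is bit-identical to a single full run, and an
optional fast path that skips the Markov solve for structurally flagged
networks (sound because flagged networks are never good; a validation mode
re-checks this on samples before trusting it).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .catalog import GENES, N_NETWORKS, NetworkSpec, build_catalog
from .chain import compartment_probabilities, exceeds_half
from .logic import build_state_table

__all__ = [
    "STRUCTURAL_FLAGS",
    "ScreenRecord",
    "ScreenSummary",
    "classify_structural",
    "classify_structural_bulk",
    "screen_unflagged",
    "screen",
    "summarize_screen",
    "records_frame",
    "run_checkpointed_screen",
    "load_checkpointed_records",
]

STRUCTURAL_FLAGS = (
    "unregulated_node",
    "fgf8_not_upstream",
    "auto_induction",
    "inductive_loop",
    "isolated_repressive_loop",
)

_CAT = build_catalog()
_GENE_INDEX = {g: i for i, g in enumerate(GENES)}

# Per-target incoming-edge bit fields (mirrors logic._TARGET_FIELDS).
_TARGET_BITS = {
    1: [4, 5, 6, 7, 8],  # *Emx2*   <- F E P C S
    2: [9, 10, 11, 12, 13],  # *Pax6*
    3: [14, 15, 16, 17, 18],  # *Coup-tfi*
    4: [19, 20, 21, 22, 23],  # *Sp8*
}
_FGF8_UPSTREAM_BITS = (4, 9, 14, 19)  # F -> each TF gene
_AUTO_BITS = (0, 5, 11, 17, 23)

# inductive variable edges as (regulator gene, target gene) with their bit
_INDUCTIVE_EDGES = [
    (_GENE_INDEX[e.regulator], _GENE_INDEX[e.target], i)
    for i, e in enumerate(_CAT.variable_edges)
    if e.sign == "inductive"
]
_REPRESSIVE_BIT = {
    (_GENE_INDEX[e.regulator], _GENE_INDEX[e.target]): i
    for i, e in enumerate(_CAT.variable_edges)
    if e.sign == "repressive"
}


def _has_inductive_cycle(mask: int) -> bool:
    """Cycle detection on the gene-level inductive digraph (fixed S->F incl.)."""
    adj: dict[int, list[int]] = {g: [] for g in range(5)}
    adj[4].append(0)  # fixed Sp8 -> *Fgf8*
    for r, t, bit in _INDUCTIVE_EDGES:
        if mask >> bit & 1:
            adj[r].append(t)
    color = [0] * 5  # 0 unvisited, 1 on stack, 2 done
    def dfs(u: int) -> bool:
        color[u] = 1
        for v in adj[u]:
            if color[v] == 1 or (color[v] == 0 and dfs(v)):
                return True
        color[u] = 2
        return False

    return any(color[g] == 0 and dfs(g) for g in range(5))


def classify_structural(spec: NetworkSpec | int) -> frozenset[str]:
    """Structural flags of a topology (each precludes good performance)."""
    mask = spec.mask if isinstance(spec, NetworkSpec) else int(spec)
    flags = set()
    for t, bits in _TARGET_BITS.items():
        if not any(mask >> b & 1 for b in bits):
            flags.add("unregulated_node")
            break
    if not any(mask >> b & 1 for b in _FGF8_UPSTREAM_BITS):
        flags.add("fgf8_not_upstream")
    if any(mask >> b & 1 for b in _AUTO_BITS):
        flags.add("auto_induction")
    if _has_inductive_cycle(mask):
        flags.add("inductive_loop")
    for (x, y), bit_xy in _REPRESSIVE_BIT.items():
        # both genes TFs (the fixed Sp8 inducer means *Fgf8* is never
        # cut off from the network), both mutual edges present, and
        # neither gene regulated by anything else
        if x == 0 or y == 0 or not mask >> bit_xy & 1:
            continue
        back = _REPRESSIVE_BIT.get((y, x))
        if back is None or not mask >> back & 1:
            continue
        y_only = not any(mask >> b & 1 for b in _TARGET_BITS[y] if b != bit_xy)
        x_only = not any(mask >> b & 1 for b in _TARGET_BITS[x] if b != back)
        if x_only and y_only:
            flags.add("isolated_repressive_loop")
            break
    return frozenset(flags)


def _inductive_loop_lut() -> np.ndarray:
    """Truth table of :func:`_has_inductive_cycle` over the 12 inductive bits."""
    lut = np.zeros(1 << 12, dtype=bool)
    bits = [b for _, _, b in _INDUCTIVE_EDGES]
    for sub in range(1 << 12):
        mask = 0
        for j, b in enumerate(bits):
            if sub >> j & 1:
                mask |= 1 << b
        lut[sub] = _has_inductive_cycle(mask)
    return lut


_LOOP_LUT: np.ndarray | None = None
_INDUCTIVE_BITS = tuple(b for _, _, b in _INDUCTIVE_EDGES)
_FIELD = {t: sum(1 << b for b in bits) for t, bits in _TARGET_BITS.items()}


def classify_structural_bulk(masks: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorised :func:`classify_structural` over an array of masks.

    Returns one boolean array per flag; asserted elementwise-identical to
    the scalar classifier in the tests.  The inductive-loop test uses a
    4096-entry truth table over the 12 inductive bits, computed once by the
    scalar cycle detector.
    """
    global _LOOP_LUT
    m = np.asarray(masks, dtype=np.uint32)
    out: dict[str, np.ndarray] = {}

    unreg = np.zeros(m.shape, dtype=bool)
    for t, f in _FIELD.items():
        unreg |= (m & np.uint32(f)) == 0
    out["unregulated_node"] = unreg

    fgf8_field = np.uint32(sum(1 << b for b in _FGF8_UPSTREAM_BITS))
    out["fgf8_not_upstream"] = (m & fgf8_field) == 0

    auto_field = np.uint32(sum(1 << b for b in _AUTO_BITS))
    out["auto_induction"] = (m & auto_field) != 0

    if _LOOP_LUT is None:
        _LOOP_LUT = _inductive_loop_lut()
    sub = np.zeros(m.shape, dtype=np.uint32)
    for j, b in enumerate(_INDUCTIVE_BITS):
        sub |= ((m >> np.uint32(b)) & np.uint32(1)) << np.uint32(j)
    out["inductive_loop"] = _LOOP_LUT[sub]

    iso = np.zeros(m.shape, dtype=bool)
    for (x, y), bit_xy in _REPRESSIVE_BIT.items():
        if x == 0 or y == 0:
            continue  # *Fgf8* keeps its fixed Sp8 inducer, never isolated
        back = _REPRESSIVE_BIT.get((y, x))
        if back is None:
            continue
        y_others = np.uint32(_FIELD[y] & ~(1 << bit_xy))
        x_others = np.uint32(_FIELD[x] & ~(1 << back))
        iso |= (
            ((m >> np.uint32(bit_xy)) & 1).astype(bool)
            & ((m >> np.uint32(back)) & 1).astype(bool)
            & ((m & y_others) == 0)
            & ((m & x_others) == 0)
        )
    out["isolated_repressive_loop"] = iso
    return out


def screen_unflagged(
    masks: np.ndarray | None = None,
    unregulated_on: bool = True,
    chunk: int = 1 << 22,
    use_symmetry: bool = False,
) -> "pandas.DataFrame":  # noqa: F821
    """Exact analysis of every structurally unflagged topology in ``masks``.

    Defaults to the full 2^24 space.  Structurally flagged topologies are
    never good (each flag provably pins one compartment below 50%; the
    claim is additionally sample-validated in the test suite), so the good
    set, the best performance index and its argmax masks over ``masks``
    are all exactly recoverable from the returned frame.

    With ``use_symmetry`` the Markov solve runs only on canonical
    representatives under the Emx2/Coup-tfi exchange (which leaves both
    compartment probabilities invariant and maps unflagged masks to
    unflagged masks); the mirror's row is copied.  Requires ``masks`` to be
    closed under the exchange (the full space is).
    """
    import pandas as pd

    sel: list[np.ndarray] = []
    if masks is None:
        for lo in range(0, N_NETWORKS, chunk):
            block = np.arange(lo, min(lo + chunk, N_NETWORKS), dtype=np.uint32)
            flags = classify_structural_bulk(block)
            flagged = np.zeros(block.shape, dtype=bool)
            for arr in flags.values():
                flagged |= arr
            sel.append(block[~flagged])
    else:
        masks = np.asarray(masks, dtype=np.uint32)
        flags = classify_structural_bulk(masks)
        flagged = np.zeros(masks.shape, dtype=bool)
        for arr in flags.values():
            flagged |= arr
        sel.append(masks[~flagged])
    todo = np.concatenate(sel)

    p_ant = np.empty(todo.size)
    p_post = np.empty(todo.size)
    if use_symmetry:
        from .catalog import swap_masks

        mirrors = swap_masks(todo)
        canonical = todo <= mirrors
        solved: dict[int, tuple[float, float]] = {}
        for mask in todo[canonical]:
            solved[int(mask)] = _analyse_mask(int(mask), unregulated_on)
        for i, (mask, mirror) in enumerate(zip(todo, mirrors)):
            key = int(mask) if canonical[i] else int(mirror)
            if key not in solved:
                raise ValueError(
                    "mask set is not closed under the Emx2/Coup-tfi exchange"
                )
            p_ant[i], p_post[i] = solved[key]
    else:
        for i, mask in enumerate(todo):
            p_ant[i], p_post[i] = _analyse_mask(int(mask), unregulated_on)
    phi = np.minimum(p_ant, p_post)
    return pd.DataFrame(
        {
            "mask": todo.astype(np.int64),
            "p_anterior": p_ant,
            "p_posterior": p_post,
            "phi": phi,
            "good": np.array([exceeds_half(x) for x in phi]),
        }
    )


@dataclass(frozen=True)
class ScreenRecord:
    """One row of the screen: probabilities, Phi, goodness, structure."""

    mask: int
    p_anterior: float
    p_posterior: float
    phi: float
    good: bool
    flags: frozenset[str]


def _analyse_mask(mask: int, unregulated_on: bool) -> tuple[float, float]:
    table = build_state_table(mask) if unregulated_on else None
    if table is None:
        from .logic import compile_rules

        table = build_state_table(compile_rules(mask, unregulated_on=False))
    return compartment_probabilities(table)


def screen(
    start: int = 0,
    end: int = N_NETWORKS,
    step: int = 1,
    unregulated_on: bool = True,
    fast_structural: bool = False,
    validate_fast: int = 0,
    rng: np.random.Generator | None = None,
) -> Iterator[ScreenRecord]:
    """Score every topology with mask in ``range(start, end, step)``.

    Deterministic and order-independent: the record for a mask never
    depends on the rest of the range, so partitioned runs concatenate to a
    single full run.  ``step`` supports stratified partitions (e.g. every
    256th mask).

    With ``fast_structural`` the Markov solve is skipped for structurally
    flagged topologies, whose probabilities are reported as NaN and
    ``good=False``; enabling it first spot-checks ``validate_fast`` random
    flagged masks per flag (default 64 when 0) against the full analysis.
    """
    if not 0 <= start <= end <= N_NETWORKS:
        raise ValueError(f"invalid range [{start}, {end})")
    if fast_structural:
        _validate_fast_path(validate_fast or 64, unregulated_on, rng)
    for mask in range(start, end, step):
        flags = classify_structural(mask)
        if fast_structural and flags:
            yield ScreenRecord(mask, float("nan"), float("nan"), float("nan"), False, flags)
            continue
        p_ant, p_post = _analyse_mask(mask, unregulated_on)
        phi = min(p_ant, p_post)
        yield ScreenRecord(mask, p_ant, p_post, phi, exceeds_half(phi), flags)


def _validate_fast_path(
    n_per_flag: int, unregulated_on: bool, rng: np.random.Generator | None
) -> None:
    """Spot-check that flagged topologies are never good before skipping them."""
    from .netio import sample_flagged_mask

    rng = rng or np.random.default_rng(0)
    for flag in STRUCTURAL_FLAGS:
        for _ in range(n_per_flag):
            mask = sample_flagged_mask(flag, rng)
            p_ant, p_post = _analyse_mask(mask, unregulated_on)
            if min(p_ant, p_post) > 0.5:
                raise AssertionError(
                    f"structural fast path unsound: mask {mask:06x} with flag "
                    f"{flag} has Phi={min(p_ant, p_post):.3f} > 0.5"
                )


@dataclass
class ScreenSummary:
    """Aggregate view of a completed screen range."""

    total: int
    good_count: int
    good_fraction: float
    best_phi: float
    best_masks: list[int]
    scatter: np.ndarray = field(repr=False)  # (n, 2) of (p_ant, p_post)


def summarize_screen(records: Iterable[ScreenRecord]) -> ScreenSummary:
    """Counts, best Phi and argmax masks, plus scatter data for plotting."""
    total = 0
    good = 0
    best_phi = -1.0
    best_masks: list[int] = []
    scatter = []
    for r in records:
        total += 1
        good += bool(r.good)
        scatter.append((r.p_anterior, r.p_posterior))
        if not np.isnan(r.phi):
            if r.phi > best_phi + 1e-12:
                best_phi, best_masks = r.phi, [r.mask]
            elif abs(r.phi - best_phi) <= 1e-12:
                best_masks.append(r.mask)
    if total == 0:
        raise ValueError("no records to summarise")
    return ScreenSummary(
        total, good, good / total, best_phi, best_masks, np.asarray(scatter)
    )


def records_frame(records: Iterable[ScreenRecord]) -> "pandas.DataFrame":  # noqa: F821
    import pandas as pd

    return pd.DataFrame(
        {
            "mask_hex": f"{r.mask:06x}",
            "p_anterior": r.p_anterior,
            "p_posterior": r.p_posterior,
            "phi": r.phi,
            "good": r.good,
            "flags": ",".join(sorted(r.flags)),
        }
        for r in records
    )


# ---------------------------------------------------------------------------
# Checkpointed runs: fixed-size mask chunks written as deterministic TSV
# with a manifest of SHA-256 checksums, so multi-hour runs can resume and
# reruns of any chunk must reproduce its checksum exactly.
# ---------------------------------------------------------------------------


def _chunk_lines(records: Sequence[ScreenRecord]) -> str:
    lines = ["mask_hex\tp_anterior\tp_posterior\tphi\tgood\tflags"]
    for r in records:
        lines.append(
            f"{r.mask:06x}\t{r.p_anterior:.12g}\t{r.p_posterior:.12g}"
            f"\t{r.phi:.12g}\t{int(r.good)}\t{','.join(sorted(r.flags))}"
        )
    return "\n".join(lines) + "\n"


def run_checkpointed_screen(
    out_dir: str | Path,
    start: int = 0,
    end: int = N_NETWORKS,
    step: int = 1,
    chunk_size: int = 65_536,
    **screen_kwargs,
) -> Path:
    """Run (or resume) a screen, writing checksummed TSV chunks + manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.json"
    manifest = (
        json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    )
    if manifest.get("range") not in (None, [start, end, step]):
        raise ValueError("checkpoint directory belongs to a different range")
    manifest.setdefault("range", [start, end, step])
    chunks = manifest.setdefault("chunks", {})

    masks = range(start, end, step)
    for c0 in range(0, len(masks), chunk_size):
        name = f"chunk_{c0:08d}.tsv"
        if name in chunks:
            path = out_dir / name
            digest = hashlib.sha256(path.read_bytes()).hexdigest()
            if digest != chunks[name]:
                raise ValueError(f"checkpoint corruption detected in {name}")
            continue
        sub = masks[c0 : c0 + chunk_size]
        recs = list(screen(sub.start, sub.stop, sub.step, **screen_kwargs))
        text = _chunk_lines(recs)
        (out_dir / name).write_text(text)
        chunks[name] = hashlib.sha256(text.encode()).hexdigest()
        manifest_path.write_text(json.dumps(manifest, indent=1))
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path


def load_checkpointed_records(out_dir: str | Path) -> Iterator[ScreenRecord]:
    """Stream records back from a checkpoint directory, verifying checksums."""
    out_dir = Path(out_dir)
    manifest = json.loads((out_dir / "manifest.json").read_text())
    for name in sorted(manifest["chunks"]):
        path = out_dir / name
        text = path.read_text()
        if hashlib.sha256(text.encode()).hexdigest() != manifest["chunks"][name]:
            raise ValueError(f"checkpoint corruption detected in {name}")
        for line in text.splitlines()[1:]:
            mask_hex, pa, pp, phi, good, flags = line.split("\t")
            yield ScreenRecord(
                int(mask_hex, 16),
                float(pa),
                float(pp),
                float(phi),
                good == "1",
                frozenset(f for f in flags.split(",") if f),
            )
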