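"""Junction-spanning read classification and IES retention scoring.

Reads are classified by exact matching of *junction probes* rather than by
external alignment, which keeps the pipeline self-contained and exactly
testable. For an IES at MAC offset ``p`` (germline left boundary ``g``,
length ``L``) three probe windows are defined:

* ``minus``       — the excised MAC junction, ``MAC[p-k : p+2+k]``;
* ``plus_left``   — the germline 5' boundary, ``germ[g-k : g+2+k]``;
* ``plus_right``  — the germline 3' boundary, ``germ[g+L-k : g+L+2+k]``.

All three windows are centered on a boundary ``TA`` and have equal width
``2k + 2``. A read (or its reverse complement) supports a boundary when it
contains a contiguous exact match covering at least ``m`` bases on each side
of that TA, i.e. contains the probe *core* of width ``2m + 2``. Counting is
boundary-level: a minus match supports excision at both boundaries of the
IES (2 votes), a plus match supports retention at one boundary (a pair
spanning a whole short IES can collect both). Equal catchments on the plus
and minus side make the expected retention score equal to ``rho * r`` (see
:func:`expected_apparent_irs`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import (
    BoundaryCounts,
    IesAnnotation,
    ReadSet,
    RetentionRecord,
    revcomp,
)

__all__ = [
    "JunctionLibrary",
    "ClassifiedPair",
    "build_junction_library",
    "classify_read_pair",
    "classify_pairs",
    "count_and_score",
    "expected_apparent_irs",
    "estimate_retention",
    "test_retention",
]

PLUS_KINDS = ("plus_left", "plus_right")


@dataclass
class _Probes:
    minus: str
    plus_left: str
    plus_right: str
    minus_core: str
    plus_left_core: str
    plus_right_core: str


@dataclass
class JunctionLibrary:
    """Per-IES probe windows and the exact-match core index."""

    probes: dict[str, _Probes]
    flank_k: int
    min_overlap: int
    collisions: set[str] = field(default_factory=set)
    # core sequence (either strand) -> list of (ies_id, kind)
    index: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    @property
    def core_width(self) -> int:
        return 2 * self.min_overlap + 2


def germline_positions(annotations: Sequence[IesAnnotation]) -> dict[str, int]:
    """Germline offset g of each IES's left boundary (per-replicon cumsum)."""
    out: dict[str, int] = {}
    by_rep: dict[str, list[IesAnnotation]] = {}
    for ann in annotations:
        by_rep.setdefault(ann.replicon, []).append(ann)
    for anns in by_rep.values():
        offset = 0
        for ann in sorted(anns, key=lambda a: a.mac_position):
            out[ann.ies_id] = ann.mac_position + offset
            offset += ann.length
    return out


def build_junction_library(
    mac: dict[str, str],
    germline: dict[str, str],
    annotations: Sequence[IesAnnotation],
    flank_k: int = 100,
    min_overlap: int = 10,
) -> JunctionLibrary:
    """Build the IES+/IES- probe library from the two reference genomes.

    Validates the TA invariants of every annotation against both genomes and
    flags probe-core collisions (identical cores shared by several IESs).
    """
    if flank_k < min_overlap:
        raise ValueError("flank_k must be >= min_overlap")
    gpos = germline_positions(annotations)
    probes: dict[str, _Probes] = {}
    index: dict[str, list[tuple[str, str]]] = {}
    collisions: set[str] = set()
    seen_core: dict[str, tuple[str, str]] = {}

    for ann in annotations:
        p, L = ann.mac_position, ann.length
        mseq, gseq = mac[ann.replicon], germline[ann.replicon]
        if mseq[p : p + 2] != "TA":
            raise ValueError(f"{ann.ies_id}: MAC lacks TA at position {p}")
        g = gpos[ann.ies_id]
        if gseq[g : g + L] != ann.sequence:
            raise ValueError(f"{ann.ies_id}: germline sequence mismatch at {g}")
        k, m = flank_k, min_overlap
        pr = _Probes(
            minus=mseq[max(0, p - k) : p + 2 + k],
            plus_left=gseq[max(0, g - k) : g + 2 + k],
            plus_right=gseq[max(0, g + L - k) : g + L + 2 + k],
            minus_core=mseq[max(0, p - m) : p + 2 + m],
            plus_left_core=gseq[max(0, g - m) : g + 2 + m],
            plus_right_core=gseq[max(0, g + L - m) : g + L + 2 + m],
        )
        probes[ann.ies_id] = pr
        for kind, core in (
            ("minus", pr.minus_core),
            ("plus_left", pr.plus_left_core),
            ("plus_right", pr.plus_right_core),
        ):
            for variant in {core, revcomp(core)}:
                prior = seen_core.get(variant)
                if prior is not None and prior[0] != ann.ies_id:
                    collisions.update({prior[0], ann.ies_id})
                seen_core.setdefault(variant, (ann.ies_id, kind))
                index.setdefault(variant, [])
                if (ann.ies_id, kind) not in index[variant]:
                    index[variant].append((ann.ies_id, kind))
    return JunctionLibrary(
        probes=probes,
        flank_k=flank_k,
        min_overlap=min_overlap,
        collisions=collisions,
        index=index,
    )


@dataclass
class ClassifiedPair:
    """Votes cast by one read pair: ies_id -> (plus_votes, minus_votes)."""

    votes: dict[str, tuple[int, int]] = field(default_factory=dict)
    ambiguous: set[str] = field(default_factory=set)

    @property
    def label(self):
        if self.ambiguous:
            return "ambiguous"
        if not self.votes:
            return "unassigned"
        if len(self.votes) > 1:
            return "multi"
        (ies_id, (plus, minus)), = self.votes.items()
        return ("IES+", ies_id) if plus else ("IES-", ies_id)


def _resolve_votes(matches: set[tuple[str, str]]) -> ClassifiedPair:
    by_ies: dict[str, set[str]] = {}
    for ies_id, kind in matches:
        by_ies.setdefault(ies_id, set()).add(kind)
    out = ClassifiedPair()
    for ies_id, kinds in by_ies.items():
        has_plus = any(k in kinds for k in PLUS_KINDS)
        has_minus = "minus" in kinds
        if has_plus and has_minus:
            out.ambiguous.add(ies_id)
        elif has_minus:
            out.votes[ies_id] = (0, 2)
        else:
            out.votes[ies_id] = (sum(k in kinds for k in PLUS_KINDS), 0)
    return out


def classify_read_pair(
    pair: tuple[str, str] | Sequence[str], library: JunctionLibrary
) -> ClassifiedPair:
    """Classify a single read pair by scanning the probe-core index.

    The bulk path (:func:`classify_pairs`) uses a rolling-hash index with
    identical semantics; this per-pair scan is the simple reference form.
    """
    r1, r2 = pair[0], pair[1]
    if not r1 and not r2:
        return ClassifiedPair()  # unassigned
    matches: set[tuple[str, str]] = set()
    for mate in (r1, r2):
        if not mate:
            continue
        for core, targets in library.index.items():
            if core in mate:
                matches.update(targets)
    return _resolve_votes(matches)


_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _roll_hashes(reads: list[str], width: int) -> tuple[np.ndarray, np.ndarray]:
    """Base-5 positional hashes of every ``width``-window of equal-length reads.

    Base 5 over codes {A,C,G,T,N} is injective for width <= 27, so hash
    equality is sequence equality (no collisions).
    """
    n = len(reads)
    rl = len(reads[0])
    data = np.frombuffer("".join(reads).encode("ascii"), dtype=np.uint8)
    codes = _CODE[data].reshape(n, rl).astype(np.uint64)
    n_win = rl - width + 1
    if n_win <= 0:
        return np.zeros((n, 0), dtype=np.uint64), codes
    pow5 = np.uint64(5) ** np.uint64(width - 1)
    h = np.zeros(n, dtype=np.uint64)
    for j in range(width):
        h = h * np.uint64(5) + codes[:, j]
    out = np.empty((n, n_win), dtype=np.uint64)
    out[:, 0] = h
    for t in range(1, n_win):
        h = (h - codes[:, t - 1] * pow5) * np.uint64(5) + codes[:, t + width - 1]
        out[:, t] = h
    return out, codes


def _hash_str(s: str) -> int:
    h = 0
    for ch in s:
        h = h * 5 + int(_CODE[ord(ch)])
    return h


def classify_pairs(
    pairs: Iterable[tuple[str, str]], library: JunctionLibrary
) -> list[ClassifiedPair]:
    """Vectorized classification of many read pairs (rolling-hash index)."""
    pairs = list(pairs)
    if not pairs:
        return []
    width = library.core_width
    full: dict[int, list[tuple[str, str]]] = {}
    short_cores: list[tuple[str, list[tuple[str, str]]]] = []
    for core, targets in library.index.items():
        if len(core) == width:
            full.setdefault(_hash_str(core), []).extend(targets)
        else:  # probe truncated at a replicon end
            short_cores.append((core, targets))
    hash_keys = np.fromiter(full.keys(), dtype=np.uint64, count=len(full))

    reads: list[str] = []
    for r1, r2 in pairs:
        reads.append(r1)
        reads.append(r2)
    lengths = {len(r) for r in reads}
    if len(lengths) != 1:
        # mixed lengths: fall back to the per-pair scan
        return [classify_read_pair(p, library) for p in pairs]

    match_sets: list[set[tuple[str, str]]] = [set() for _ in pairs]
    if hash_keys.size and lengths != {0}:
        hashes, _ = _roll_hashes(reads, width)
        hit_mask = np.isin(hashes, hash_keys)
        rows, cols = np.nonzero(hit_mask)
        for row, col in zip(rows.tolist(), cols.tolist()):
            match_sets[row // 2].update(full[int(hashes[row, col])])
    for core, targets in short_cores:
        for i, (r1, r2) in enumerate(pairs):
            if core in r1 or core in r2:
                match_sets[i].update(targets)
    return [_resolve_votes(m) for m in match_sets]


def count_and_score(
    reads: ReadSet | Iterable[tuple[str, str]],
    library: JunctionLibrary,
    condition: str = "",
) -> list[RetentionRecord]:
    """Aggregate per-pair votes into per-IES counts and retention scores."""
    if isinstance(reads, ReadSet):
        pairs = [(p.read1, p.read2) for p in reads.pairs]
    else:
        pairs = list(reads)
    counts = {ies_id: BoundaryCounts(ies_id) for ies_id in library.probes}
    for cp in classify_pairs(pairs, library):
        for ies_id, (plus, minus) in cp.votes.items():
            counts[ies_id].ies_plus += plus
            counts[ies_id].ies_minus += minus
            counts[ies_id].pair_plus += plus > 0
            counts[ies_id].pair_minus += minus > 0
        for ies_id in cp.ambiguous:
            counts[ies_id].ambiguous += 1
    return [
        RetentionRecord(ies_id=ies_id, counts=c, condition=condition)
        for ies_id, c in counts.items()
    ]


def expected_apparent_irs(r: float, rho: float) -> float:
    """Expected apparent retention score under old/new MAC dilution.

    A junction-covering fragment supports retention only if it derives from
    the new MAC (probability ``rho``) *and* the locus is unexcised
    (probability ``r``); with equal IES+/IES- probe catchments the expected
    score is ``rho*r / (rho*r + rho*(1-r) + (1-rho)) = rho*r``. This is the
    symmetric-catchment limit; residual geometry effects are checked against
    the fragment-enumeration oracle (:mod:`iespipe.validation`). The inverse
    estimator is :func:`estimate_retention`.
    """
    if not (0.0 <= r <= 1.0 and 0.0 <= rho <= 1.0):
        raise ValueError("r and rho must lie in [0, 1]")
    return rho * r


def estimate_retention(irs: float, rho: float) -> float:
    """Invert the dilution model: ``r_hat = min(1, irs / rho)``."""
    if not 0.0 < rho <= 1.0:
        raise ValueError("rho must lie in (0, 1]")
    if math.isnan(irs):
        return math.nan
    return min(1.0, irs / rho)


def test_retention(
    case: Sequence[RetentionRecord],
    control: Sequence[RetentionRecord],
    alpha: float = 0.05,
    min_reads: int = 10,
) -> list[RetentionRecord]:
    """Call significantly retained IESs in ``case`` against ``control``.

    Per IES, a one-sided exact test (Fisher / hypergeometric) that the IES+
    proportion in the case exceeds the control's, computed on the 2x2 table
    of *fragment-level* counts (``pair_plus``/``pair_minus``; read pairs are
    the independent sampling units — boundary-level votes come in correlated
    twos and would make the test anti-conservative). Falls back to the
    boundary counts when no fragment-level counts were recorded (e.g.
    records rebuilt from minimal tables). Benjamini-Hochberg across all
    tested IESs; IESs with fewer than ``min_reads`` total counts in either
    condition are left untested.
    """
    case_by = {r.ies_id: r for r in case}
    ctrl_by = {r.ies_id: r for r in control}
    if set(case_by) != set(ctrl_by):
        only_case = sorted(set(case_by) - set(ctrl_by))[:5]
        only_ctrl = sorted(set(ctrl_by) - set(case_by))[:5]
        raise ValueError(
            f"case/control IES sets differ (case-only {only_case}, control-only {only_ctrl})"
        )
    ids = sorted(case_by)

    def unit_counts(rec):
        c = rec.counts
        if c.pair_plus or c.pair_minus or not (c.ies_plus or c.ies_minus):
            return c.pair_plus, c.pair_minus
        return c.ies_plus, c.ies_minus

    a = np.array([unit_counts(case_by[i])[0] for i in ids])
    b = np.array([unit_counts(case_by[i])[1] for i in ids])
    c = np.array([unit_counts(ctrl_by[i])[0] for i in ids])
    d = np.array([unit_counts(ctrl_by[i])[1] for i in ids])
    tested = ((a + b) >= min_reads) & ((c + d) >= min_reads)

    # one-sided Fisher exact (greater): survival function of the hypergeometric
    p = np.full(len(ids), np.nan)
    if tested.any():
        at, bt, ct, dt = (x[tested] for x in (a, b, c, d))
        p[tested] = stats.hypergeom.sf(at - 1, at + bt + ct + dt, at + ct, at + bt)
    q = np.full(len(ids), np.nan)
    sig = np.zeros(len(ids), dtype=bool)
    if tested.any():
        rej, q_adj, _, _ = multipletests(p[tested], alpha=alpha, method="fdr_bh")
        q[tested] = q_adj
        sig[tested] = q_adj <= alpha
    out = []
    for i, ies_id in enumerate(ids):
        rec = case_by[ies_id]
        out.append(
            RetentionRecord(
                ies_id=ies_id,
                counts=rec.counts,
                condition=rec.condition,
                p_value=float(p[i]),
                q_value=float(q[i]),
                significant=bool(sig[i]),
                tested=bool(tested[i]),
            )
        )
    return out
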