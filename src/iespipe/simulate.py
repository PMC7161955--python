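"""Synthetic germline/somatic genome pairs and whole-cell paired-end reads.

This module emulates the data underlying a genome-wide IES excision
experiment in *Paramecium*-like ciliates, scaled down to desk size:

* a somatic (MAC) genome of one or more AT-rich replicons;
* TA-bounded, single-copy IESs whose lengths follow a periodic mixture of
  size peaks with a dominant first peak at 26-30 bp, and whose positions can
  be clustered into designated IES-dense regions;
* per-IES retention probabilities under an experimental condition
  (uniform, all/none, or a logistic model on IES length and local density);
* error-free paired-end reads drawn from a whole-cell DNA mixture of
  new-MAC material (IES retained with its per-locus probability) and old-MAC
  fragments (always IES-free).

Everything is deterministic given the configured seed.
"""

from __future__ import annotations

import math
import warnings
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .types import IesAnnotation, ReadPair, ReadSet, SimulationTruth, MIN_IES_LENGTH

__all__ = [
    "SimulationConfig",
    "GenerationError",
    "sample_ies_lengths",
    "generate_genome_pair",
    "assign_retention",
    "simulate_read_pairs",
    "excise_all",
]

#: default mixture over size-peak bins (bin 1 = 26-30 bp, +10 bp per bin)
DEFAULT_PEAK_WEIGHTS = (0.35, 0.25, 0.15, 0.10, 0.08, 0.04, 0.02, 0.01)


class GenerationError(RuntimeError):
    """Raised when a configuration cannot be realized (e.g. infeasible packing)."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic genome.

    ``length_peak_weights`` is a probability vector over consecutive size-peak
    bins; bin ``k`` spans ``[26 + k*peak_period, 30 + k*peak_period]`` bp and
    lengths are uniform within a bin. ``cluster_fraction`` is the probability
    that an IES is placed inside one of ``dense_region_count`` windows of
    ``dense_region_span`` bp; ``dense_peak_weights``, when given, replaces the
    length mixture for those clustered IESs (letting short IESs concentrate
    in dense regions, as they do around real IES-rich loci).
    """

    n_replicons: int = 1
    replicon_length: int = 50_000
    n_ies: int = 100
    min_ies_length: int = MIN_IES_LENGTH
    length_peak_weights: tuple[float, ...] = DEFAULT_PEAK_WEIGHTS
    peak_period: int = 10
    cluster_fraction: float = 0.0
    dense_region_count: int = 0
    dense_region_span: int = 1_500
    dense_peak_weights: tuple[float, ...] | None = None
    gc_content: float = 0.28
    sparse_min_gap: int = 200
    dense_min_gap: int = 50
    # keep boundary windows clear of replicon ends (> default mean_insert)
    edge_margin: int = 400
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_replicons, self.replicon_length, self.n_ies) < 0:
            raise ValueError("counts and lengths must be >= 0")
        if self.min_ies_length < MIN_IES_LENGTH:
            raise ValueError(f"min_ies_length must be >= {MIN_IES_LENGTH}")
        _check_weights(self.length_peak_weights)
        if self.dense_peak_weights is not None:
            _check_weights(self.dense_peak_weights)
        if not 0.0 <= self.cluster_fraction <= 1.0:
            raise ValueError("cluster_fraction outside [0, 1]")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content outside (0, 1)")
        if self.cluster_fraction > 0 and self.dense_region_count == 0:
            raise ValueError("cluster_fraction > 0 requires dense regions")


def _check_weights(weights: Sequence[float]) -> None:
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or w.size == 0 or np.any(w < 0):
        raise ValueError("peak weights must be a non-negative vector")
    if abs(float(w.sum()) - 1.0) > 1e-9:
        raise ValueError(f"peak weights sum to {w.sum()}, expected 1")


def sample_ies_lengths(
    n: int,
    peak_weights: Sequence[float] = DEFAULT_PEAK_WEIGHTS,
    rng_seed: int | np.random.Generator = 0,
    peak_period: int = 10,
    first_peak: tuple[int, int] = (26, 30),
) -> list[int]:
    """Draw ``n`` IES lengths from the periodic size-peak mixture.

    Bin ``k`` (0-based) is the closed interval
    ``[first_peak[0] + k*peak_period, first_peak[1] + k*peak_period]``,
    uniform within the bin.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    _check_weights(peak_weights)
    rng = _as_rng(rng_seed)
    if n == 0:
        return []
    bins = rng.choice(len(peak_weights), size=n, p=np.asarray(peak_weights, float))
    lo = first_peak[0] + bins * peak_period
    hi = first_peak[1] + bins * peak_period
    return list((lo + rng.integers(0, hi - lo + 1)).astype(int))


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(4, size=length, p=probs)
    return "".join("ACGT"[c] for c in codes)


def _pack_min_gap(
    rng: np.random.Generator, lo: int, hi: int, k: int, gap: int
) -> list[int]:
    """k sorted positions in [lo, hi) with pairwise distance >= gap.

    Uses the sorted-uniform transform (draw in the shrunken interval, then
    re-inflate), which is exact and never rejects.
    """
    if k == 0:
        return []
    slack = (hi - lo) - (k - 1) * gap
    if slack < 1:
        raise GenerationError(
            f"cannot place {k} positions with gap {gap} in [{lo}, {hi})"
        )
    base = np.sort(rng.integers(0, slack, size=k))
    return list(base + lo + np.arange(k) * gap)


def _place_positions(
    cfg: SimulationConfig, rng: np.random.Generator, replicon_names: list[str]
) -> tuple[dict[str, list[int]], dict[str, list[tuple[int, int]]], list[bool]]:
    """Choose MAC insertion points per replicon.

    Returns (positions per replicon, dense windows per replicon, and a flag
    per IES — in final sorted order — telling whether it sits in a dense
    region).
    """
    n_rep = len(replicon_names)
    per_rep = [cfg.n_ies // n_rep + (1 if i < cfg.n_ies % n_rep else 0) for i in range(n_rep)]
    dense_per_rep = [
        cfg.dense_region_count // n_rep + (1 if i < cfg.dense_region_count % n_rep else 0)
        for i in range(n_rep)
    ]

    positions: dict[str, list[int]] = {}
    windows: dict[str, list[tuple[int, int]]] = {}
    dense_flags: list[bool] = []
    margin = cfg.edge_margin
    for name, n_here, n_win in zip(replicon_names, per_rep, dense_per_rep):
        usable_lo, usable_hi = margin, cfg.replicon_length - margin
        if usable_hi <= usable_lo:
            raise GenerationError("replicon too short for edge margins")
        win_starts = _pack_min_gap(
            rng, usable_lo, usable_hi - cfg.dense_region_span, n_win,
            cfg.dense_region_span + 2 * cfg.sparse_min_gap,
        ) if n_win else []
        wins = [(s, s + cfg.dense_region_span) for s in win_starts]
        windows[name] = wins

        in_dense = rng.random(n_here) < cfg.cluster_fraction if wins else np.zeros(n_here, bool)
        n_dense = int(in_dense.sum())
        n_sparse = n_here - n_dense

        dense_pos: list[int] = []
        if n_dense:
            assignment = rng.integers(0, len(wins), size=n_dense)
            for w_idx, (w_lo, w_hi) in enumerate(wins):
                k = int((assignment == w_idx).sum())
                dense_pos.extend(_pack_min_gap(rng, w_lo, w_hi, k, cfg.dense_min_gap))

        # sparse IESs go in the complement of the dense windows
        segments: list[tuple[int, int]] = []
        cur = usable_lo
        for w_lo, w_hi in wins:
            segments.append((cur, w_lo - cfg.sparse_min_gap))
            cur = w_hi + cfg.sparse_min_gap
        segments.append((cur, usable_hi))
        segments = [(a, b) for a, b in segments if b - a > cfg.sparse_min_gap]
        caps = [max(0, (b - a) // cfg.sparse_min_gap - 1) for a, b in segments]
        if sum(caps) < n_sparse:
            raise GenerationError(
                f"replicon {name}: cannot host {n_sparse} sparse IESs with "
                f"min gap {cfg.sparse_min_gap} (capacity {sum(caps)}); "
                "increase replicon_length or reduce n_ies"
            )
        sparse_pos: list[int] = []
        remaining = n_sparse
        for (a, b), cap in zip(segments, caps):
            share = min(cap, remaining) if (a, b) == segments[-1] else min(
                cap, round(n_sparse * cap / sum(caps))
            )
            share = min(share, remaining)
            sparse_pos.extend(_pack_min_gap(rng, a, b, share, cfg.sparse_min_gap))
            remaining -= share
        # distribute any rounding remainder into segments with spare capacity
        seg_i = 0
        while remaining > 0 and seg_i < len(segments):
            a, b = segments[seg_i]
            have = [p for p in sparse_pos if a <= p < b]
            if caps[seg_i] - len(have) > 0:
                extra = _pack_min_gap(rng, a, b, len(have) + 1, cfg.sparse_min_gap)
                sparse_pos = [p for p in sparse_pos if not (a <= p < b)] + extra
                remaining -= 1
            else:
                seg_i += 1
        if remaining > 0:
            raise GenerationError(f"replicon {name}: packing overflow ({remaining} left)")

        dense_set = set(dense_pos)
        allpos = sorted(dense_pos + sparse_pos)
        if len(set(allpos)) != len(allpos):
            raise GenerationError("duplicate insertion points generated")
        positions[name] = allpos
        dense_flags.extend(p in dense_set for p in allpos)
    return positions, windows, dense_flags


def generate_genome_pair(
    config: SimulationConfig,
) -> tuple[dict[str, str], dict[str, str], list[IesAnnotation]]:
    """Generate a (MAC, germline) genome pair plus IES annotations.

    The MAC is random sequence at the configured GC content with ``TA``
    forced at every insertion point; the germline is the MAC with every IES
    sequence spliced in. Excising all annotated IESs from the germline
    reproduces the MAC byte-exactly (see :func:`excise_all`).
    """
    cfg = config
    rng = np.random.default_rng(cfg.rng_seed)
    names = [f"scaffold_{i + 1}" for i in range(cfg.n_replicons)]

    positions, _windows, dense_flags = _place_positions(cfg, rng, names)

    mac: dict[str, str] = {}
    germ: dict[str, str] = {}
    annotations: list[IesAnnotation] = []
    flag_iter = iter(dense_flags)
    counter = 0
    for name in names:
        seq = list(_random_sequence(rng, cfg.replicon_length, cfg.gc_content))
        pos = positions[name]
        flags = [next(flag_iter) for _ in pos]
        for p in pos:
            seq[p], seq[p + 1] = "T", "A"
        mac_seq = "".join(seq)

        n_dense_here = sum(flags)
        dense_w = cfg.dense_peak_weights or cfg.length_peak_weights
        dense_lengths = iter(
            sample_ies_lengths(n_dense_here, dense_w, rng, cfg.peak_period)
        )
        sparse_lengths = iter(
            sample_ies_lengths(len(pos) - n_dense_here, cfg.length_peak_weights, rng, cfg.peak_period)
        )

        parts: list[str] = []
        cur = 0
        for p, is_dense in zip(pos, flags):
            length = next(dense_lengths) if is_dense else next(sparse_lengths)
            counter += 1
            ies_seq = "TA" + _random_sequence(rng, length - 2, cfg.gc_content)
            annotations.append(
                IesAnnotation(
                    ies_id=f"IES.{name}.{counter:05d}",
                    replicon=name,
                    mac_position=p,
                    sequence=ies_seq,
                )
            )
            parts.append(mac_seq[cur:p])
            parts.append(ies_seq)
            cur = p
        parts.append(mac_seq[cur:])
        mac[name] = mac_seq
        germ[name] = "".join(parts)
    return mac, germ, annotations


def excise_all(
    germline: dict[str, str], annotations: Iterable[IesAnnotation]
) -> dict[str, str]:
    """Remove every annotated IES from the germline (the round-trip check)."""
    by_rep: dict[str, list[IesAnnotation]] = {}
    for ann in annotations:
        by_rep.setdefault(ann.replicon, []).append(ann)
    out: dict[str, str] = {}
    for name, seq in germline.items():
        anns = sorted(by_rep.get(name, []), key=lambda a: a.mac_position)
        parts = []
        cur = 0
        offset = 0  # germline minus MAC coordinate shift so far
        for ann in anns:
            g = ann.mac_position + offset
            if seq[g : g + ann.length] != ann.sequence:
                raise ValueError(f"{ann.ies_id}: germline does not carry the IES at {g}")
            parts.append(seq[cur:g])
            cur = g + ann.length
            offset += ann.length
        parts.append(seq[cur:])
        out[name] = "".join(parts)
    return out


def assign_retention(
    annotations: Sequence[IesAnnotation],
    densities: dict[str, int],
    model: str = "uniform",
    rng_seed: int = 0,
    *,
    r: float | None = None,
    b0: float = 0.0,
    b_len: float = 0.0,
    b_dens: float = 0.0,
    rho: float = 0.5,
    short_cutoff: int = 30,
) -> SimulationTruth:
    """Assign a true retention probability to every IES.

    Models
    ------
    ``uniform``         every IES gets probability ``r``.
    ``all_retained``    r = 1 everywhere (e.g. an excision-factor knockdown).
    ``none_retained``   r = 0 everywhere (e.g. a control RNAi).
    ``feature_logistic`` r_i = logistic(b0 + b_len*[length_i <= short_cutoff]
                        + b_dens*density_i): retention favoring short IESs in
                        IES-dense neighborhoods.
    """
    missing = [a.ies_id for a in annotations if a.ies_id not in densities]
    if missing:
        raise ValueError(f"densities missing for {missing[:5]}{'...' if len(missing) > 5 else ''}")
    if model == "uniform":
        if r is None or not 0.0 <= r <= 1.0:
            raise ValueError("uniform model needs r in [0, 1]")
        retention = {a.ies_id: float(r) for a in annotations}
    elif model == "all_retained":
        retention = {a.ies_id: 1.0 for a in annotations}
    elif model == "none_retained":
        retention = {a.ies_id: 0.0 for a in annotations}
    elif model == "feature_logistic":
        retention = {}
        for a in annotations:
            x = b0 + b_len * (a.length <= short_cutoff) + b_dens * densities[a.ies_id]
            retention[a.ies_id] = 1.0 / (1.0 + math.exp(-x))
    else:
        raise ValueError(f"unknown retention model {model!r}")
    return SimulationTruth(retention=retention, rho=rho)


def _mosaic_fragment(
    mac_seq: str,
    points: list[int],
    seq_at: dict[int, str],
    retained_at: dict[int, bool],
    start: int,
    flen: int,
) -> tuple[str, bool]:
    """Build a new-MAC fragment starting at MAC offset ``start``.

    Walks rightwards along the MAC, splicing in the IES sequence at every
    insertion point whose per-fragment retention coin came up true. Returns
    the fragment sequence and whether any IES base was included.
    """
    out: list[str] = []
    got = 0
    cur = start
    any_ies = False
    i = bisect_right(points, start)
    while got < flen and i < len(points):
        p = points[i]
        span = p - cur
        if got + span >= flen:
            break
        out.append(mac_seq[cur:p])
        got += span
        cur = p
        if retained_at[p]:
            ies = seq_at[p]
            any_ies = True
            take = min(len(ies), flen - got)
            out.append(ies[:take])
            got += take
        i += 1
    if got < flen:
        out.append(mac_seq[cur : cur + flen - got])
    frag = "".join(out)
    return frag[:flen], any_ies


def simulate_read_pairs(
    mac: dict[str, str],
    germline: dict[str, str],
    annotations: Sequence[IesAnnotation],
    truth: SimulationTruth,
    coverage: float = 50.0,
    read_length: int = 100,
    mean_insert: int = 300,
    rng_seed: int = 0,
) -> ReadSet:
    """Simulate error-free whole-cell paired-end reads.

    Each fragment derives from an old-MAC molecule (relative rate ``1 - rho``
    per position, template = MAC) or from a new-MAC molecule (relative rate
    ``rho``). New-MAC fragment starts are uniform over *germline*
    coordinates: a start inside an IES body exists only on molecules that
    retained that IES, so it is kept with probability ``r_i`` (thinning);
    every further IES locus the fragment walks over is independently retained
    with its own probability. The fragment length equals ``mean_insert``
    (shorter only when downstream excision runs into a replicon end); read 2
    is the reverse complement of the fragment's 3' end. The number of
    fragments is set so the mean read depth over the MAC approximates
    ``coverage``.
    """
    if read_length > mean_insert:
        raise ValueError("read_length must be <= mean_insert")
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    from .scoring import germline_positions
    from .types import revcomp

    rng = np.random.default_rng(rng_seed)
    names = sorted(mac)
    mac_slots = np.array([max(0, len(mac[n]) - mean_insert + 1) for n in names], dtype=float)
    germ_slots = np.array(
        [max(0, len(germline[n]) - mean_insert + 1) for n in names], dtype=float
    )
    if mac_slots.sum() == 0:
        raise ValueError("replicons shorter than mean_insert")
    genome_len = sum(len(mac[n]) for n in names)
    n_frag = int(round(coverage * genome_len / (2 * read_length)))
    if n_frag == 0:
        warnings.warn("coverage too low: zero fragments simulated")
        return ReadSet([], read_length, mean_insert, coverage)

    by_rep_points: dict[str, list[int]] = {n: [] for n in names}
    seq_at: dict[str, dict[int, str]] = {n: {} for n in names}
    r_at: dict[str, dict[int, float]] = {n: {} for n in names}
    gpos = germline_positions(annotations)
    g_start: dict[str, list[int]] = {n: [] for n in names}  # germline left bounds
    for ann in sorted(annotations, key=lambda a: (a.replicon, a.mac_position)):
        by_rep_points[ann.replicon].append(ann.mac_position)
        seq_at[ann.replicon][ann.mac_position] = ann.sequence
        r_at[ann.replicon][ann.mac_position] = truth.retention[ann.ies_id]
        g_start[ann.replicon].append(gpos[ann.ies_id])

    # per-position fragment rate lambda = n_frag / mac_slots, applied to MAC
    # slots for old-MAC draws and germline slots for new-MAC draws, so the
    # old/new rate ratio at any junction-flanking position is (1-rho) : rho
    lam = n_frag / mac_slots.sum()
    rho = truth.rho
    n_old_exp = n_frag * (1.0 - rho)
    n_new_exp = lam * germ_slots.sum() * rho
    n_draws = int(round(n_old_exp + n_new_exp))
    p_new = n_new_exp / (n_old_exp + n_new_exp) if n_draws else 0.0

    is_new = rng.random(n_draws) < p_new
    u_rep = rng.random(n_draws)
    u_start = rng.random(n_draws)
    mac_cum = np.cumsum(mac_slots / mac_slots.sum())
    germ_cum = np.cumsum(germ_slots / germ_slots.sum())

    pairs: list[ReadPair] = []
    for k in range(n_draws):
        if not is_new[k]:
            ri = int(np.searchsorted(mac_cum, u_rep[k], side="right"))
            name = names[ri]
            mseq = mac[name]
            s = int(u_start[k] * mac_slots[ri])
            frag = mseq[s : s + mean_insert]
            prov, mac_anchor = "old_mac", s
        else:
            ri = int(np.searchsorted(germ_cum, u_rep[k], side="right"))
            name = names[ri]
            mseq = mac[name]
            u = int(u_start[k] * germ_slots[ri])
            points = by_rep_points[name]
            gstarts = g_start[name]
            idx = bisect_right(gstarts, u) - 1
            prefix = ""
            if idx >= 0:
                p_anchor = points[idx]
                ies_seq = seq_at[name][p_anchor]
                if u < gstarts[idx] + len(ies_seq):
                    # start inside an IES body: the molecule must retain it
                    if rng.random() >= r_at[name][p_anchor]:
                        continue
                    prefix = ies_seq[u - gstarts[idx] :][:mean_insert]
                    s = p_anchor
                else:
                    s = u - (gstarts[idx] + len(ies_seq) - points[idx])
            else:
                s = u
            need = mean_insert - len(prefix)
            coins: dict[int, bool] = {}
            j = bisect_right(points, s)
            while j < len(points) and points[j] < s + need + 1:
                p = points[j]
                coins[p] = bool(rng.random() < r_at[name][p])
                j += 1
            if need and coins:
                body, any_ies = _mosaic_fragment(mseq, points, seq_at[name], coins, s, need)
            else:
                body, any_ies = mseq[s : s + need], False
            frag = prefix + body
            prov = "new_retained" if (prefix or any_ies) else "new_excised"
            mac_anchor = s
        if len(frag) < read_length:
            continue  # replicon-end remnant too short to sequence
        pairs.append(
            ReadPair(
                read1=frag[:read_length],
                read2=revcomp(frag[-read_length:]),
                provenance=prov,
                replicon=name,
                start=mac_anchor,
            )
        )
    return ReadSet(pairs, read_length, mean_insert, coverage)
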