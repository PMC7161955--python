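"""Feature analysis of retained-IES sets: length peaks, neighbor density,
log2 enrichment indexes, matched random-sampling nulls, overlaps and
replicate correlation.

Density is computed between MAC insertion points (IESs are points on the
somatic genome after excision): the density of IES *i* is the number of
other IESs on the same replicon whose insertion point lies strictly within
``window`` bp on either side.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import IesAnnotation, MatchedSample

__all__ = [
    "neighbor_density",
    "density_class",
    "enrichment_index",
    "length_stats",
    "matched_random_sample",
    "set_overlap",
    "replicate_correlation",
]


def neighbor_density(
    annotations: Sequence[IesAnnotation], window: int = 1000
) -> dict[str, int]:
    """Number of other IESs within ``window`` bp (strict) of each insertion point."""
    out: dict[str, int] = {}
    by_rep: dict[str, list[IesAnnotation]] = {}
    for ann in annotations:
        by_rep.setdefault(ann.replicon, []).append(ann)
    for rep, anns in by_rep.items():
        anns = sorted(anns, key=lambda a: a.mac_position)
        pos = np.array([a.mac_position for a in anns])
        if len(np.unique(pos)) != len(pos):
            raise ValueError(f"duplicate insertion points on {rep} (IESs are single-copy)")
        lo = np.searchsorted(pos, pos - window, side="right")
        hi = np.searchsorted(pos, pos + window, side="left")
        for ann, n in zip(anns, (hi - lo - 1).tolist()):
            out[ann.ies_id] = int(n)
    return out


def density_class(density: int, max_class: int = 8) -> str:
    """Top-coded density class label: '0', '1', ..., '{max_class}+'."""
    return f"{max_class}+" if density >= max_class else str(density)


def enrichment_index(
    retained_ids: Iterable[str],
    universe: Sequence[IesAnnotation],
    profile: Mapping[str, int],
    max_class: int = 8,
) -> pd.DataFrame:
    """Per density-class fractions of the retained set vs the universe.

    The enrichment index EI(c) = log2(f_retained(c) / f_universe(c)) is the
    (log2) factor by which a density class is over-represented among retained
    IESs; it is NaN (undefined) when either fraction is zero.
    """
    retained = set(retained_ids)
    uni_ids = {a.ies_id for a in universe}
    stray = retained - uni_ids
    if stray:
        raise ValueError(f"retained ids absent from universe: {sorted(stray)[:5]}")
    classes = [str(c) for c in range(max_class)] + [f"{max_class}+"]
    n_uni = {c: 0 for c in classes}
    n_ret = {c: 0 for c in classes}
    for ann in universe:
        c = density_class(profile[ann.ies_id], max_class)
        n_uni[c] += 1
        if ann.ies_id in retained:
            n_ret[c] += 1
    tot_uni = sum(n_uni.values())
    tot_ret = sum(n_ret.values())
    rows = []
    for c in classes:
        f_uni = n_uni[c] / tot_uni if tot_uni else math.nan
        f_ret = n_ret[c] / tot_ret if tot_ret else math.nan
        ei = (
            math.log2(f_ret / f_uni)
            if f_uni and f_ret and not (math.isnan(f_uni) or math.isnan(f_ret))
            else math.nan
        )
        rows.append(
            {
                "density_class": c,
                "n_retained": n_ret[c],
                "n_universe": n_uni[c],
                "f_retained": f_ret,
                "f_universe": f_uni,
                "ei": ei,
            }
        )
    return pd.DataFrame(rows)


def length_stats(
    lengths: Sequence[int],
    first_peak: tuple[int, int] = (26, 30),
    max_length: int | None = None,
):
    """First-peak fraction and empirical cumulative length curve.

    Returns ``(peak_fraction, ecdf)`` where ``ecdf`` is a callable evaluable
    at any length. ``max_length`` restricts the set (strictly shorter than)
    before computing, as done when plotting only IESs < 150 bp. The peak
    fraction is NaN for an empty set.
    """
    arr = np.asarray(sorted(lengths), dtype=float)
    if max_length is not None:
        arr = arr[arr < max_length]
    if arr.size == 0:
        return math.nan, lambda x: math.nan
    frac = float(np.mean((arr >= first_peak[0]) & (arr <= first_peak[1])))

    def ecdf(x: float) -> float:
        return float(np.searchsorted(arr, x, side="right") / arr.size)

    return frac, ecdf


def matched_random_sample(
    universe: Sequence[IesAnnotation],
    reference_ids: Iterable[str],
    match_on: str,
    profile: Mapping[str, int] | None = None,
    rng_seed: int = 0,
    max_class: int = 8,
    exclude_reference: bool = False,
) -> MatchedSample:
    """Random sample from the universe matched stratum-by-stratum to a reference.

    Strata are exact length in bp (``match_on="length"``) or top-coded
    density class (``match_on="density"``). Per stratum the sample draws,
    without replacement, as many universe members as the reference holds;
    when a stratum is short the whole stratum is taken, so the sample may be
    smaller than the reference.
    """
    reference = list(reference_ids)
    if not reference:
        raise ValueError("empty reference set")
    if match_on not in ("length", "density"):
        raise ValueError(f"match_on must be 'length' or 'density', got {match_on!r}")
    if match_on == "density" and profile is None:
        raise ValueError("density matching requires a density profile")

    def stratum(ann: IesAnnotation):
        if match_on == "length":
            return ann.length
        return density_class(profile[ann.ies_id], max_class)

    by_id = {a.ies_id: a for a in universe}
    ref_strata: dict = {}
    for rid in reference:
        if rid not in by_id:
            raise ValueError(f"reference id {rid} has no annotation in universe")
        s = stratum(by_id[rid])
        ref_strata[s] = ref_strata.get(s, 0) + 1

    pool: dict = {}
    ref_set = set(reference)
    for ann in universe:
        if exclude_reference and ann.ies_id in ref_set:
            continue
        pool.setdefault(stratum(ann), []).append(ann.ies_id)

    rng = np.random.default_rng(rng_seed)
    ids: list[str] = []
    obtained: dict = {}
    for s in sorted(ref_strata, key=str):
        want = ref_strata[s]
        avail = sorted(pool.get(s, []))
        take = min(want, len(avail))
        if take:
            ids.extend(rng.choice(avail, size=take, replace=False).tolist())
        obtained[s] = take
    return MatchedSample(
        ids=sorted(ids),
        match_on=match_on,
        requested=ref_strata,
        obtained=obtained,
        rng_seed=rng_seed,
    )


def set_overlap(set_a: Iterable[str], set_b: Iterable[str]):
    """Exact set arithmetic: sizes, intersection and overlap fractions."""
    a, b = set(set_a), set(set_b)
    inter = len(a & b)
    return {
        "n_a": len(a),
        "n_b": len(b),
        "n_intersection": inter,
        "frac_of_a": inter / len(a) if a else math.nan,
        "frac_of_b": inter / len(b) if b else math.nan,
    }


def replicate_correlation(
    scores_a: Mapping[str, float], scores_b: Mapping[str, float]
):
    """Spearman rank correlation of two score maps on shared, defined scores.

    Returns ``(rho, n_used)``; ``rho`` is NaN (flagged by ``n_used``) when
    fewer than 3 shared defined scores exist. Ties get average ranks.
    """
    shared = [
        k
        for k in scores_a
        if k in scores_b
        and not math.isnan(scores_a[k])
        and not math.isnan(scores_b[k])
    ]
    if len(shared) < 3:
        return math.nan, len(shared)
    a = [scores_a[k] for k in shared]
    b = [scores_b[k] for k in shared]
    rho = stats.spearmanr(a, b).statistic
    return float(rho), len(shared)
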