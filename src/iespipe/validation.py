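"""Independent reference implementations used to validate the fast paths.

Nothing here shares code with :mod:`iespipe.scoring`'s rolling-hash
classifier or with the read simulator's mosaic walk: probe cores are
re-derived directly from genome slices, matching is a plain substring scan,
and expectations are computed by enumerating every fragment start position.
These are deliberately slow, transparent implementations intended for
cross-checks on small instances and for oracle-expectation comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .types import IesAnnotation, SimulationTruth, revcomp


def _cores_from_genomes(
    mac: dict[str, str],
    annotations: Sequence[IesAnnotation],
    min_overlap: int,
) -> dict[str, dict[str, str]]:
    """Re-derive the three probe cores per IES from MAC slices + IES sequence.

    Independent of the junction library: the germline context around the left
    boundary is ``MAC[p-m:p] + seq[:m+2]`` and around the right boundary
    ``seq[-m:] + MAC[p:p+m+2]``, with no germline string ever built.
    """
    m = min_overlap
    out: dict[str, dict[str, str]] = {}
    for ann in annotations:
        p, seq = ann.mac_position, ann.sequence
        mseq = mac[ann.replicon]
        out[ann.ies_id] = {
            "minus": mseq[max(0, p - m) : p + 2 + m],
            "plus_left": mseq[max(0, p - m) : p] + seq[: m + 2],
            "plus_right": seq[-m:] + mseq[p : p + m + 2],
        }
    return out


def bruteforce_counts(
    pairs: Sequence[tuple[str, str]],
    mac: dict[str, str],
    annotations: Sequence[IesAnnotation],
    min_overlap: int = 10,
) -> dict[str, tuple[int, int, int]]:
    """Count boundary-level IES+/IES- votes by naive substring scanning.

    Returns ``ies_id -> (plus, minus, ambiguous, pair_plus, pair_minus)``
    under the same vote semantics as the production classifier: per pair,
    matches on either mate or strand are pooled; a minus (junction) match
    contributes 2 boundary votes, each plus boundary 1; a within-IES sign
    conflict makes the pair ambiguous for that IES; the pair-level tallies
    count at most one vote per pair per IES.
    """
    cores = _cores_from_genomes(mac, annotations, min_overlap)
    totals = {a.ies_id: [0, 0, 0, 0, 0] for a in annotations}
    for r1, r2 in pairs:
        for ann in annotations:
            kinds = set()
            for kind, core in cores[ann.ies_id].items():
                for mate in (r1, r2):
                    if mate and (core in mate or revcomp(core) in mate):
                        kinds.add(kind)
            if not kinds:
                continue
            has_plus = bool(kinds & {"plus_left", "plus_right"})
            has_minus = "minus" in kinds
            t = totals[ann.ies_id]
            if has_plus and has_minus:
                t[2] += 1
            elif has_minus:
                t[1] += 2
                t[4] += 1
            else:
                t[0] += len(kinds & {"plus_left", "plus_right"})
                t[3] += 1
    return {k: tuple(v) for k, v in totals.items()}


@dataclass
class ExpectedCounts:
    ies_id: str
    e_plus: float
    e_minus: float

    @property
    def expected_irs(self) -> float:
        denom = self.e_plus + self.e_minus
        return self.e_plus / denom if denom else float("nan")


def enumerate_expected_counts(
    mac: dict[str, str],
    annotations: Sequence[IesAnnotation],
    truth: SimulationTruth,
    n_fragments: int,
    read_length: int = 100,
    mean_insert: int = 300,
    min_overlap: int = 10,
) -> dict[str, ExpectedCounts]:
    """Exhaustive fragment-position enumeration of expected vote counts.

    For every IES, every fragment start position that could produce a vote is
    enumerated; for each start the excised-form and retained-form fragments
    are built by direct string construction and scanned for the probe cores.
    Expected counts weight the retained form by ``rho * r`` and the excised
    form by ``1 - rho * r`` (old-MAC plus new-but-excised material).

    Fragment starts are enumerated over MAC positions for the excised form
    and over germline positions for the retained form (flank starts plus
    starts inside the IES body, the latter existing only on molecules that
    retained the IES — mirroring the simulator's thinning). Assumes IES loci
    are farther apart than ``mean_insert`` so a fragment never overlaps two
    loci (the estimation scenarios guarantee this); counts are then exact
    expectations of the simulator's generative model.
    """
    cores = _cores_from_genomes(mac, annotations, min_overlap)
    s_total = sum(max(0, len(seq) - mean_insert + 1) for seq in mac.values())
    lam = n_fragments / s_total  # expected fragments per start position
    out: dict[str, ExpectedCounts] = {}
    for ann in annotations:
        p, seq = ann.mac_position, ann.sequence
        mseq = mac[ann.replicon]
        s_max_rep = len(mseq) - mean_insert
        core = cores[ann.ies_id]
        sum_plus = 0.0
        sum_minus = 0.0
        lo = max(0, p - mean_insert)
        hi = min(s_max_rep, p - 1)  # flank starts are strictly left of the junction
        for s in range(lo, hi + 1):
            frag_exc = mseq[s : s + mean_insert]
            mates_exc = (frag_exc[:read_length], frag_exc[-read_length:])
            if any(core["minus"] in mate for mate in mates_exc):
                sum_minus += 2.0
            frag_ret = (mseq[s:p] + seq + mseq[p:])[:mean_insert]
            mates_ret = (frag_ret[:read_length], frag_ret[-read_length:])
            for kind in ("plus_left", "plus_right"):
                if any(core[kind] in mate for mate in mates_ret):
                    sum_plus += 1.0
        for o in range(len(seq)):  # starts inside the retained IES body
            frag_ret = (seq[o:] + mseq[p:])[:mean_insert]
            mates_ret = (frag_ret[:read_length], frag_ret[-read_length:])
            for kind in ("plus_left", "plus_right"):
                if any(core[kind] in mate for mate in mates_ret):
                    sum_plus += 1.0
        rr = truth.rho * truth.retention[ann.ies_id]
        out[ann.ies_id] = ExpectedCounts(
            ies_id=ann.ies_id,
            e_plus=lam * rr * sum_plus,
            e_minus=lam * (1.0 - rr) * sum_minus,
        )
    return out
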