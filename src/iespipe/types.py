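"""Domain types shared across the pipeline.

Coordinate convention: all internal coordinates are 0-based, half-open.
An IES annotated at MAC position ``p`` means the somatic (MAC) replicon
carries the conserved ``TA`` at ``[p, p+2)`` and the germline replicon is
obtained by inserting the full IES sequence (which itself starts with
``TA``) immediately *before* that position::

    germline = MAC[:p] + ies.sequence + MAC[p:]

so the germline locus reads  ...flank | TA+core... | TA | flank...  with one
TA left behind on the MAC after precise excision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

__all__ = [
    "IesAnnotation",
    "SimulationTruth",
    "ReadPair",
    "ReadSet",
    "BoundaryCounts",
    "RetentionRecord",
    "MatchedSample",
]

MIN_IES_LENGTH = 26

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class IesAnnotation:
    """One Internal Eliminated Sequence.

    Attributes
    ----------
    ies_id : str
        Unique identifier.
    replicon : str
        Name of the replicon (scaffold/chromosome) the IES maps to.
    mac_position : int
        0-based offset ``p`` of the excision junction on the MAC replicon;
        the MAC carries ``TA`` at ``[p, p+2)``.
    sequence : str
        Germline IES sequence, starting with ``TA``.
    """

    ies_id: str
    replicon: str
    mac_position: int
    sequence: str

    def __post_init__(self) -> None:
        if self.mac_position < 0:
            raise ValueError(f"{self.ies_id}: negative MAC position")
        # the 26-bp genomic minimum is enforced at generation time
        # (SimulationConfig); the type itself only requires the TA boundary
        if len(self.sequence) < 4:
            raise ValueError(f"{self.ies_id}: IES sequence too short")
        if not self.sequence.upper().startswith("TA"):
            raise ValueError(f"{self.ies_id}: IES sequence does not start with TA")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class SimulationTruth:
    """Planted per-IES retention probabilities plus the old/new MAC mixture.

    ``retention[ies_id]`` is the probability that a *new-MAC* copy of the
    locus still carries the IES (is unexcised). ``rho`` is the fraction of
    junction-covering DNA that originates from the new developing MAC; the
    remaining ``1 - rho`` comes from old-MAC fragments, which never carry an
    IES. Whole-cell DNA preparations therefore dilute retention evidence and
    make observed scores *apparent* retention scores.
    """

    retention: dict[str, float]
    rho: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"rho={self.rho} outside [0, 1]")
        for ies_id, r in self.retention.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"retention[{ies_id}]={r} outside [0, 1]")


class ReadPair(NamedTuple):
    """One simulated paired-end read with its provenance."""

    read1: str
    read2: str
    provenance: str  # new_retained | new_excised | old_mac
    replicon: str
    start: int  # fragment start, MAC coordinates


@dataclass
class ReadSet:
    pairs: list[ReadPair]
    read_length: int
    mean_insert: int
    coverage_target: float

    def __post_init__(self) -> None:
        for p in self.pairs:
            if len(p.read1) != self.read_length or len(p.read2) != self.read_length:
                raise ValueError("read length inconsistent with read_length")
            if p.provenance not in ("new_retained", "new_excised", "old_mac"):
                raise ValueError(f"unknown provenance {p.provenance!r}")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class BoundaryCounts:
    """Per-IES boundary-level support counts.

    Counts are per boundary, not per pair: each IES has two boundaries, and a
    read pair matching the excised MAC junction supports excision at *both*
    of them (contributing 2 to ``ies_minus``), while a pair matching a
    germline boundary probe supports retention at that boundary (1 vote, or 2
    if a single pair spans both boundaries of a short IES). This keeps the
    IES+ and IES- catchments equal, so the retention score is an unbiased
    estimate of the apparent retention frequency.
    """

    ies_id: str
    ies_plus: int = 0
    ies_minus: int = 0
    ambiguous: int = 0
    #: fragment-level support (at most one vote per read pair per IES);
    #: these are the independent sampling units the exact test runs on,
    #: while the boundary-level counts above define the retention score
    pair_plus: int = 0
    pair_minus: int = 0

    def __post_init__(self) -> None:
        if min(self.ies_plus, self.ies_minus, self.ambiguous,
               self.pair_plus, self.pair_minus) < 0:
            raise ValueError("negative counts")


@dataclass
class RetentionRecord:
    """Counts plus (apparent) retention score and significance call."""

    ies_id: str
    counts: BoundaryCounts
    condition: str = ""
    p_value: float = math.nan
    q_value: float = math.nan
    significant: bool = False
    tested: bool = False

    @property
    def irs(self) -> float:
        """Apparent IES retention score, ``plus / (plus + minus)``.

        NaN (undefined) when the IES has no junction-covering evidence.
        """
        denom = self.counts.ies_plus + self.counts.ies_minus
        if denom == 0:
            return math.nan
        return self.counts.ies_plus / denom


@dataclass
class MatchedSample:
    """A random sample from the universe matched to a reference set."""

    ids: list[str]
    match_on: str  # "length" | "density"
    requested: dict = field(default_factory=dict)  # stratum -> count wanted
    obtained: dict = field(default_factory=dict)  # stratum -> count drawn
    rng_seed: int = 0

    def __len__(self) -> int:
        return len(self.ids)
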