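"""Readers/writers for FASTA, GFF3, FASTQ and the pipeline's TSV tables.

Internal coordinates are 0-based half-open; GFF3 is written/read as 1-based
inclusive. Tabular outputs carry ``#`` header comments with the tool
version, config hash and seeds so every file is traceable to its run.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import math
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .types import IesAnnotation, ReadPair, ReadSet, RetentionRecord

GFF_FEATURE_TYPE = "internal_eliminated_sequence"


def config_hash(obj) -> str:
    """Stable short hash of a configuration-like object."""
    try:
        payload = json.dumps(obj, sort_keys=True, default=lambda o: vars(o))
    except TypeError:
        payload = repr(obj)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def metadata_lines(seed=None, cfg_hash: str | None = None) -> list[str]:
    lines = [f"# iespipe {__version__}"]
    if cfg_hash is not None:
        lines.append(f"# config_hash={cfg_hash}")
    if seed is not None:
        lines.append(f"# seed={seed}")
    return lines


# -- FASTA -------------------------------------------------------------------

def write_fasta(path, genome: dict[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sorted(genome.items())
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# -- GFF3 --------------------------------------------------------------------

def write_gff3(
    path,
    annotations: Sequence[IesAnnotation],
    seed=None,
    cfg_hash: str | None = None,
) -> None:
    """IES annotations on the MAC genome.

    Each feature marks the excision-junction TA (1-based inclusive
    ``[p+1, p+2]``) and carries the germline sequence so the germline genome
    can be rebuilt from MAC + GFF3 alone.
    """
    lines = ["##gff-version 3"] + metadata_lines(seed, cfg_hash)
    for ann in sorted(annotations, key=lambda a: (a.replicon, a.mac_position)):
        attrs = f"ID={ann.ies_id};length={ann.length};sequence={ann.sequence}"
        lines.append(
            "\t".join(
                [
                    ann.replicon,
                    "iespipe",
                    GFF_FEATURE_TYPE,
                    str(ann.mac_position + 1),
                    str(ann.mac_position + 2),
                    ".",
                    "+",
                    ".",
                    attrs,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path, replicon_lengths: dict[str, int] | None = None) -> list[IesAnnotation]:
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True, merge_strategy="error"
    )
    out: list[IesAnnotation] = []
    for feat in db.features_of_type(GFF_FEATURE_TYPE):
        if feat.start > feat.end:
            raise ValueError(f"{path}: start > end for feature {feat.id}")
        if feat.start < 1:
            raise ValueError(f"{path}: coordinate < 1 for feature {feat.id}")
        if replicon_lengths is not None:
            limit = replicon_lengths.get(feat.seqid)
            if limit is None:
                raise ValueError(f"{path}: unknown replicon {feat.seqid}")
            if feat.end > limit:
                raise ValueError(
                    f"{path}: feature {feat.id} ends at {feat.end} beyond replicon "
                    f"length {limit}"
                )
        out.append(
            IesAnnotation(
                ies_id=feat.id,
                replicon=feat.seqid,
                mac_position=feat.start - 1,  # 1-based inclusive -> 0-based offset
                sequence=feat.attributes["sequence"][0],
            )
        )
    return out


# -- FASTQ -------------------------------------------------------------------

def _open_text(path, mode: str):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_fastq_pair(reads: ReadSet, path1, path2, quality_char: str = "I") -> None:
    """Write mates to two (optionally gzipped) FASTQ files, kept in sync.

    Qualities are constant: the simulator is error-free and the analysis is
    count-based.
    """
    with _open_text(path1, "w") as f1, _open_text(path2, "w") as f2:
        for i, pair in enumerate(reads.pairs):
            qual = quality_char * reads.read_length
            name = f"frag_{i:07d}:{pair.replicon}:{pair.start}:{pair.provenance}"
            f1.write(f"@{name}/1\n{pair.read1}\n+\n{qual}\n")
            f2.write(f"@{name}/2\n{pair.read2}\n+\n{qual}\n")


def read_fastq_pair(path1, path2) -> list[tuple[str, str]]:
    with _open_text(path1, "r") as f1, _open_text(path2, "r") as f2:
        it1 = SeqIO.parse(f1, "fastq")
        it2 = SeqIO.parse(f2, "fastq")
        pairs = []
        for r1, r2 in zip(it1, it2, strict=True):
            if r1.id.rsplit("/", 1)[0] != r2.id.rsplit("/", 1)[0]:
                raise ValueError(f"FASTQ pair out of sync at {r1.id} / {r2.id}")
            pairs.append((str(r1.seq), str(r2.seq)))
    return pairs


# -- score / truth tables ----------------------------------------------------

SCORE_COLUMNS = [
    "ies_id",
    "replicon",
    "position",
    "ies_plus",
    "ies_minus",
    "ambiguous",
    "pair_plus",
    "pair_minus",
    "irs",
    "p_value",
    "q_value",
    "significant",
]


def records_frame(
    records: Sequence[RetentionRecord],
    annotations: Sequence[IesAnnotation] | None = None,
) -> pd.DataFrame:
    ann_by = {a.ies_id: a for a in annotations} if annotations else {}
    rows = []
    for rec in sorted(records, key=lambda r: r.ies_id):
        ann = ann_by.get(rec.ies_id)
        rows.append(
            {
                "ies_id": rec.ies_id,
                "replicon": ann.replicon if ann else "",
                "position": ann.mac_position if ann else -1,
                "ies_plus": rec.counts.ies_plus,
                "ies_minus": rec.counts.ies_minus,
                "ambiguous": rec.counts.ambiguous,
                "pair_plus": rec.counts.pair_plus,
                "pair_minus": rec.counts.pair_minus,
                "irs": rec.irs,
                "p_value": rec.p_value,
                "q_value": rec.q_value,
                "significant": rec.significant,
            }
        )
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)


def write_tsv(path, frame: pd.DataFrame, seed=None, cfg_hash: str | None = None) -> None:
    """TSV with ``#`` metadata header; NaN rendered as ``NA``."""
    header = "\n".join(metadata_lines(seed, cfg_hash))
    body = frame.to_csv(sep="\t", index=False, na_rep="NA", float_format="%.6g")
    Path(path).write_text(header + "\n" + body)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])


def write_truth_tsv(path, truth, annotations, densities, seed=None, cfg_hash=None) -> None:
    rows = [
        {
            "ies_id": a.ies_id,
            "r": truth.retention[a.ies_id],
            "density": densities[a.ies_id],
            "length": a.length,
        }
        for a in sorted(annotations, key=lambda a: a.ies_id)
    ]
    frame = pd.DataFrame(rows, columns=["ies_id", "r", "density", "length"])
    write_tsv(path, frame, seed=seed, cfg_hash=cfg_hash)


def scores_from_frame(frame: pd.DataFrame) -> dict[str, float]:
    """ies_id -> irs map (NaN kept) from a score table."""
    return {
        str(row.ies_id): (float(row.irs) if not pd.isna(row.irs) else math.nan)
        for row in frame.itertuples()
    }
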