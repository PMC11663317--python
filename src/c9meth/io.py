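"""Readers and writers for the supported formats.

The plain tabular fixture is a directory of TSVs (``reads.tsv``, ``cpg.tsv``,
optional ``truth.tsv`` and ``meta.tsv``) plus a FASTA of read sequences; it
round-trips losslessly. SAM/BAM input/output uses the standard
base-modification convention (``MM:Z:C+m?`` with skipped-C deltas and
``ML:B,C`` scores) together with the PacBio ``np`` (pass count) and ``rq``
(predicted accuracy) tags.
"""

from __future__ import annotations

import array
import os
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import (
    CPG_COLUMNS,
    META_COLUMNS,
    READ_COLUMNS,
    TRUTH_COLUMNS,
    require_columns,
)
from .simulate import SimulatedCohort

_STRING_FILL = ["father_id", "pedigree_id", "true_interruption_units"]


def write_fixture(cohort: SimulatedCohort, path: str | os.PathLike) -> Path:
    """Write the reads/cpg/truth/meta tables and a FASTA under ``path``.

    Refuses duplicated read ids or sample ids (id collisions would corrupt
    every downstream join).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    reads, cpg, truth, meta = cohort.reads, cohort.cpg, cohort.truth, cohort.meta
    if reads["read_id"].duplicated().any():
        raise ValueError("duplicate read_id values in reads table")
    if meta is not None and len(meta) and meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id values in meta table")

    reads.to_csv(path / "reads.tsv", sep="\t", index=False)
    cpg.to_csv(path / "cpg.tsv", sep="\t", index=False)
    if truth is not None:
        truth.to_csv(path / "truth.tsv", sep="\t", index=False)
    if meta is not None:
        meta.to_csv(path / "meta.tsv", sep="\t", index=False)

    records = [
        SeqRecord(Seq(seq), id=rid, description="")
        for rid, seq in zip(reads["read_id"], reads["sequence"])
    ]
    SeqIO.write(records, path / "reads.fasta", "fasta")
    return path


def read_fixture(path: str | os.PathLike) -> SimulatedCohort:
    """Read a fixture directory back into the four tables."""
    path = Path(path)
    reads = pd.read_csv(path / "reads.tsv", sep="\t")
    require_columns(reads, READ_COLUMNS, "reads")
    if (path / "cpg.tsv").stat().st_size > 0:
        cpg = pd.read_csv(path / "cpg.tsv", sep="\t")
    else:  # pragma: no cover - degenerate empty file
        cpg = pd.DataFrame(columns=CPG_COLUMNS)
    if cpg.empty:
        cpg = pd.DataFrame(columns=CPG_COLUMNS)
    truth = meta = None
    if (path / "truth.tsv").exists():
        truth = pd.read_csv(path / "truth.tsv", sep="\t")
        for col in _STRING_FILL:
            if col in truth:
                truth[col] = truth[col].fillna("").astype(str)
    if (path / "meta.tsv").exists():
        meta = pd.read_csv(path / "meta.tsv", sep="\t")
        for col in _STRING_FILL:
            if col in meta:
                meta[col] = meta[col].fillna("").astype(str)
    _check_cpg_consistency(reads, cpg)
    return SimulatedCohort(reads=reads, cpg=cpg, truth=truth, meta=meta)


def _check_cpg_consistency(reads: pd.DataFrame, cpg: pd.DataFrame) -> None:
    """Every CpG call must sit on the C of a CG in its read's sequence."""
    if cpg.empty:
        return
    seq_of = dict(zip(reads["read_id"], reads["sequence"]))
    for read_id, grp in cpg.groupby("read_id"):
        seq = seq_of.get(read_id)
        if seq is None:
            raise ValueError(f"CpG calls reference unknown read {read_id!r}")
        pos = grp["read_pos_0based"].to_numpy()
        bad = [p for p in pos if seq[p:p + 2] != "CG"]
        if bad:
            raise ValueError(
                f"read {read_id!r}: CpG call at position {bad[0]} does not sit on a CG"
            )


# ---------------------------------------------------------------------------
# SAM/BAM with MM/ML base-modification tags
# ---------------------------------------------------------------------------

def write_bam(reads: pd.DataFrame, cpg: pd.DataFrame, path: str | os.PathLike) -> Path:
    """Write reads as unaligned SAM/BAM records with 5mC MM/ML tags.

    ``MM:Z:C+m?`` deltas count skipped (uncalled) C bases between successive
    called CpG cytosines on the forward strand; ``ML`` holds the 0-255
    scores. Pass count and predicted accuracy go to the PacBio ``np``/``rq``
    tags. The output format follows the file extension (.sam or .bam).
    """
    path = Path(path)
    header = {"HD": {"VN": "1.6", "SO": "unknown"}}
    mode = "wb" if path.suffix == ".bam" else "w"
    calls = {rid: grp.sort_values("read_pos_0based")
             for rid, grp in cpg.groupby("read_id")}
    with pysam.AlignmentFile(str(path), mode, header=header) as out:
        for row in reads.itertuples(index=False):
            a = pysam.AlignedSegment(out.header)
            a.query_name = row.read_id
            a.query_sequence = row.sequence
            a.is_unmapped = True
            a.query_qualities = pysam.qualitystring_to_array("I" * len(row.sequence))
            grp = calls.get(row.read_id)
            a.set_tag("np", int(row.n_passes), value_type="i")
            a.set_tag("rq", float(row.predicted_accuracy), value_type="f")
            if grp is not None and len(grp):
                c_positions = [i for i, b in enumerate(row.sequence) if b == "C"]
                c_index = {p: i for i, p in enumerate(c_positions)}
                deltas, prev = [], -1
                for p in grp["read_pos_0based"]:
                    ci = c_index[int(p)]
                    deltas.append(ci - prev - 1)
                    prev = ci
                a.set_tag("MM", "C+m?," + ",".join(map(str, deltas)) + ";", value_type="Z")
                a.set_tag("ML", array.array("B", map(int, grp["score"])))
            out.write(a)
    return path


def read_bam(path: str | os.PathLike) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read SAM/BAM records with MM/ML 5mC annotations.

    Returns (reads, cpg) tables. Sample and individual ids are parsed from
    query names of the form ``<individual>_T<t>_<tissue>/<serial>`` when
    present, else left as the full read name. Malformed MM/ML pairs raise a
    per-record error naming the read.
    """
    path = Path(path)
    mode = "rb" if path.suffix == ".bam" else "r"
    read_rows, cpg_rows = [], []
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        # until_eof also covers headerless/unaligned SAM, which plain
        # iteration refuses
        for rec in fh.fetch(until_eof=True):
            seq = rec.query_sequence or ""
            name = rec.query_name
            sample_id = name.rsplit("/", 1)[0]
            individual_id = sample_id.split("_T")[0]
            read_rows.append(
                (name, individual_id, sample_id, seq,
                 int(rec.get_tag("np")) if rec.has_tag("np") else 1,
                 float(rec.get_tag("rq")) if rec.has_tag("rq") else np.nan,
                 True, True)
            )
            if rec.has_tag("MM"):
                mm = rec.get_tag("MM")
                ml = list(rec.get_tag("ML")) if rec.has_tag("ML") else []
                positions = _decode_mm(name, seq, mm)
                if len(positions) != len(ml):
                    raise ValueError(
                        f"read {name!r}: MM encodes {len(positions)} sites but "
                        f"ML has {len(ml)} scores"
                    )
                for p, s in zip(positions, ml):
                    if seq[p:p + 2] != "CG":
                        raise ValueError(
                            f"read {name!r}: modification call at {p} is not on a CpG"
                        )
                    cpg_rows.append((name, p, int(s)))
    reads = pd.DataFrame(read_rows, columns=READ_COLUMNS)
    cpg = pd.DataFrame(cpg_rows, columns=CPG_COLUMNS)
    return reads, cpg


def _decode_mm(name: str, seq: str, mm: str) -> list[int]:
    """Positions (0-based, on the C) encoded by a forward-strand C+m MM tag."""
    entry = next((e for e in mm.split(";") if e.startswith("C+m")), None)
    if entry is None:
        return []
    parts = entry.split(",")
    try:
        deltas = [int(x) for x in parts[1:] if x != ""]
    except ValueError as exc:
        raise ValueError(f"read {name!r}: malformed MM tag {mm!r}") from exc
    c_positions = [i for i, b in enumerate(seq) if b == "C"]
    out, ci = [], -1
    for d in deltas:
        ci += d + 1
        if ci >= len(c_positions):
            raise ValueError(f"read {name!r}: MM tag skips past the last C")
        out.append(c_positions[ci])
    return out
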