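"""Read pre-processing: barcode extraction and PCR-duplicate collapsing.

Library reads begin with a 7 nt random barcode followed by two fixed bases;
the barcode is moved into the read name (and a sidecar table) and the first 9
bases are trimmed before mapping. After alignment, reads sharing the same
reference, leftmost mapped position, strand and barcode are PCR duplicates of
one molecule: all but one are discarded. The retained read is the one with
the lexicographically smallest name, which makes collapsing deterministic and
independent of input order.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import pysam
from Bio import SeqIO

__all__ = [
    "BARCODE_LENGTH",
    "TRIM_LENGTH",
    "ExtractStats",
    "DedupStats",
    "extract_barcodes",
    "collapse_duplicates",
    "dedupe_records",
    "read_barcode_table",
]

BARCODE_LENGTH = 7
TRIM_LENGTH = 9  # barcode plus two fixed bases


@dataclass
class ExtractStats:
    total: int = 0
    written: int = 0
    discarded_n_barcode: int = 0
    discarded_short: int = 0


@dataclass
class DedupStats:
    total: int = 0
    retained: int = 0
    duplicates_removed: int = 0
    unmapped_dropped: int = 0
    no_barcode: int = 0


def _open_text(path: Union[str, Path], mode: str):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def extract_barcodes(
    fastq_in: Union[str, Path],
    fastq_out: Union[str, Path],
    table_out: Optional[Union[str, Path]] = None,
    barcode_length: int = BARCODE_LENGTH,
    trim_length: int = TRIM_LENGTH,
) -> ExtractStats:
    """Move the leading barcode of each read into its name and trim.

    The first ``barcode_length`` bases become the barcode (appended to the
    read name after ``_`` and written to the sidecar TSV); ``trim_length``
    bases are removed from the read. Reads with any N in the barcode, or
    shorter than the trim length, are discarded. Gzip-transparent on both
    ends. Returns the bookkeeping counts.
    """
    stats = ExtractStats()
    table = open(table_out, "w") if table_out is not None else None
    try:
        with _open_text(fastq_in, "r") as ih, _open_text(fastq_out, "w") as oh:
            for rec in SeqIO.parse(ih, "fastq"):
                stats.total += 1
                if len(rec) < trim_length:
                    stats.discarded_short += 1
                    continue
                barcode = str(rec.seq[:barcode_length]).upper()
                if "N" in barcode:
                    stats.discarded_n_barcode += 1
                    continue
                trimmed = rec[trim_length:]
                trimmed.id = f"{rec.id}_{barcode}"
                trimmed.description = ""
                SeqIO.write(trimmed, oh, "fastq")
                if table is not None:
                    table.write(f"{rec.id}\t{barcode}\n")
                stats.written += 1
    finally:
        if table is not None:
            table.close()
    return stats


def read_barcode_table(path: Union[str, Path]) -> dict[str, str]:
    out = {}
    with _open_text(path, "r") as fh:
        for line in fh:
            name, barcode = line.rstrip("\n").split("\t")
            out[name] = barcode
    return out


def _barcode_of(read: pysam.AlignedSegment, table: Optional[Mapping[str, str]]) -> Optional[str]:
    name = read.query_name
    if table is not None and name in table:
        return table[name]
    if "_" in name:
        tail = name.rsplit("_", 1)[1]
        if tail and all(c in "ACGT" for c in tail):
            return tail
    return None


def dedupe_records(
    reads: Iterable[pysam.AlignedSegment],
    barcode_table: Optional[Mapping[str, str]] = None,
    stats: Optional[DedupStats] = None,
) -> list[pysam.AlignedSegment]:
    """Collapse duplicates among alignment records, order-independently.

    One record is retained per (reference, leftmost position, strand,
    barcode) group — the one with the smallest query name. Unmapped records
    are dropped; barcode-less records are kept ungrouped and counted. Output
    is coordinate-sorted with the grouping key and name as tie-breaks, so the
    result is a deterministic function of the input multiset.
    """
    if stats is None:
        stats = DedupStats()
    groups: dict[tuple, pysam.AlignedSegment] = {}
    loose: list[pysam.AlignedSegment] = []
    for read in reads:
        stats.total += 1
        if read.is_unmapped:
            stats.unmapped_dropped += 1
            continue
        barcode = _barcode_of(read, barcode_table)
        if barcode is None:
            stats.no_barcode += 1
            loose.append(read)
            continue
        key = (read.reference_id, read.reference_start, read.is_reverse, barcode)
        held = groups.get(key)
        if held is None or read.query_name < held.query_name:
            groups[key] = read
    kept = list(groups.values()) + loose
    stats.retained = len(kept)
    stats.duplicates_removed = stats.total - stats.unmapped_dropped - stats.retained
    kept.sort(
        key=lambda r: (r.reference_id, r.reference_start, r.is_reverse, r.query_name)
    )
    return kept


def collapse_duplicates(
    sam_in: Union[str, Path],
    sam_out: Union[str, Path],
    barcode_table: Optional[Union[str, Path, Mapping[str, str]]] = None,
) -> DedupStats:
    """File-level duplicate collapsing (SAM/BAM in, SAM/BAM out)."""
    if isinstance(barcode_table, (str, Path)):
        barcode_table = read_barcode_table(barcode_table)
    stats = DedupStats()
    with pysam.AlignmentFile(str(sam_in)) as ih:
        kept = dedupe_records(ih, barcode_table, stats)
        mode = "wb" if str(sam_out).endswith(".bam") else "w"
        with pysam.AlignmentFile(str(sam_out), mode, template=ih) as oh:
            for read in kept:
                oh.write(read)
    return stats
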