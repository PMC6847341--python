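"""Shared fixtures: simulated pileup fixture suite and a samtools oracle.

The samtools oracle builds a tiny five-read alignment with known per-position
outcomes (matches, a substitution, a deletion, an insertion, a reverse-strand
read), pipes it through ``samtools mpileup``, and returns both the pileup text
and the per-position truth counts derived independently from the read
definitions — so parser agreement is checked against samtools itself, not
against this package's own emitter.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass
from pathlib import Path

import pysam
import pytest

from m7gmap.simulate import make_fixture_suite

REFERENCE = "AGCTTAGCTAGGCTGATCGATCGGCTAGCTAGGATCGATCCGATTAGCCGTAGGCTAACG"


@dataclass
class OracleRead:
    name: str
    start: int  # 0-based leftmost
    cigar: str
    seq: str
    reverse: bool


def _oracle_reads() -> list[OracleRead]:
    ref = REFERENCE
    reads = [
        OracleRead("r1_match", 0, "20M", ref[0:20], False),
        # substitution at reference position 10 (1-based): ref base -> complementary choice
        OracleRead(
            "r2_mismatch",
            4,
            "16M",
            ref[4:9] + ("A" if ref[9] != "A" else "C") + ref[10:20],
            False,
        ),
        # deletion of reference position 15 (1-based), read spans 10..20
        OracleRead("r3_del", 9, "5M1D5M", ref[9:14] + ref[15:20], False),
        # insertion of 2 bases after reference position 12 (1-based)
        OracleRead("r4_ins", 6, "6M2I8M", ref[6:12] + "CA" + ref[12:20], False),
        OracleRead("r5_rev", 4, "20M", ref[4:24], True),
    ]
    return reads


def oracle_truth() -> dict[int, dict[str, int]]:
    """Per 1-based position: expected match/sub/ins/del observation counts."""
    truth: dict[int, dict[str, int]] = {}

    def bump(pos: int, kind: str):
        truth.setdefault(pos, {"match": 0, "sub": 0, "ins": 0, "del": 0})[kind] += 1

    for read in _oracle_reads():
        rpos = read.start  # 0-based reference cursor
        qpos = 0
        num = ""
        events: list[tuple[int, str]] = []  # (1-based ref pos, kind)
        for c in read.cigar:
            if c.isdigit():
                num += c
                continue
            n = int(num)
            num = ""
            if c == "M":
                for k in range(n):
                    base = read.seq[qpos + k]
                    events.append(
                        (rpos + k + 1, "match" if base == REFERENCE[rpos + k] else "sub")
                    )
                rpos += n
                qpos += n
            elif c == "I":
                # insertion attaches to the preceding aligned base
                pos, kind = events[-1]
                events[-1] = (pos, "ins")
                qpos += n
            elif c == "D":
                for k in range(n):
                    events.append((rpos + k + 1, "del"))
                rpos += n
        for pos, kind in events:
            bump(pos, kind)
    return truth


@pytest.fixture(scope="session")
def samtools_available() -> bool:
    return shutil.which("samtools") is not None


@pytest.fixture(scope="session")
def samtools_pileup(tmp_path_factory, samtools_available) -> tuple[str, dict]:
    """(mpileup text, per-position truth counts) for the five-read fixture."""
    if not samtools_available:
        pytest.fail("samtools not found on PATH; required as parser oracle")
    d = tmp_path_factory.mktemp("samtools_oracle")
    fa = d / "ref.fa"
    fa.write_text(f">oracle\n{REFERENCE}\n")
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": "oracle", "LN": len(REFERENCE)}],
    }
    bam = d / "reads.bam"
    with pysam.AlignmentFile(str(bam), "wb", header=header) as out:
        for read in sorted(_oracle_reads(), key=lambda r: r.start):
            a = pysam.AlignedSegment(out.header)
            a.query_name = read.name
            a.query_sequence = read.seq
            a.reference_id = 0
            a.reference_start = read.start
            a.cigarstring = read.cigar
            a.mapping_quality = 60
            a.flag = 16 if read.reverse else 0
            a.query_qualities = pysam.qualitystring_to_array("I" * len(read.seq))
            out.write(a)
    pysam.index(str(bam))
    result = subprocess.run(
        ["samtools", "mpileup", "-B", "-Q", "0", "-f", str(fa), str(bam)],
        capture_output=True,
        text=True,
        check=True,
    )
    return result.stdout, oracle_truth()


@pytest.fixture(scope="session")
def fixture_suite(tmp_path_factory):
    """Canonical simulated fixture files (null, two-site, indel-rich, zero-depth)."""
    d = tmp_path_factory.mktemp("fixtures")
    configs = make_fixture_suite(seed=7, outdir=d)
    return d, configs
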