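"""Parsing of samtools-mpileup text into per-position, per-sample observations.

The mpileup base-string grammar is resolved into one observation per aligned
read base (or deletion placeholder ``*``): ``.``/``,`` are reference matches on
the forward/reverse strand, letters are mismatches, ``^X`` marks a read start
(the mapping-quality character ``X`` is consumed and discarded), ``$`` a read
end, ``+n<seq>``/``-n<seq>`` an insertion/deletion attached to the preceding
observation, and ``>``/``<`` reference skips (CIGAR N), which consume a quality
character but yield no observation. An insertion token upgrades its anchor
observation to kind insertion (the token is the insertion's only
representation); a deletion token is consumed without upgrading the anchor,
because the deleted positions carry their own ``*`` placeholder observations
and upgrading would count one deleted read twice. Coordinates are 1-based
throughout, as in mpileup itself.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterator, TextIO

import numpy as np

__all__ = [
    "Observation",
    "SampleColumn",
    "PileupSite",
    "PileupParseError",
    "tokenize_bases",
    "parse_mpileup",
    "MATCH",
    "SUBSTITUTION",
    "INSERTION",
    "DELETION",
]

# observation kind codes (shared with error_model)
MATCH = 0
SUBSTITUTION = 1
INSERTION = 2
DELETION = 3

KIND_NAMES = {
    MATCH: "reference_match",
    SUBSTITUTION: "substitution",
    INSERTION: "insertion",
    DELETION: "deletion",
}

# internal tokenizer codes for non-observation characters
_DROP_N = 250  # 'N'/'n' observations are uninformative under the two-class model
_SKIP = 251  # '>'/'<' reference skips: consume a quality char, no observation
_INVALID = 255


class PileupParseError(ValueError):
    """Raised when a pileup line or base string violates the mpileup grammar."""


@dataclass(frozen=True)
class Observation:
    """A single aligned read base (or deletion placeholder) at one position."""

    kind: int
    observed_base: str
    error_prob: float
    reverse_strand: bool

    @property
    def is_mutated(self) -> bool:
        return self.kind != MATCH


@dataclass
class SampleColumn:
    """The raw depth/bases/qualities triplet of one sample at one position."""

    reported_depth: int
    base_string: str
    quality_string: str


@dataclass
class PileupSite:
    reference_name: str
    position: int  # 1-based, mpileup convention
    reference_base: str
    samples: list[SampleColumn] = field(default_factory=list)

    def sample_observations(self, index: int) -> list[Observation]:
        """Tokenize one sample column into observations."""
        col = self.samples[index]
        if col.reported_depth == 0:
            return []
        return tokenize_bases(col.base_string, col.quality_string, self.reference_base)

    def sample_arrays(self, index: int):
        """Tokenize one sample column into (kind, quality-code, strand, base) arrays."""
        col = self.samples[index]
        if col.reported_depth == 0:
            e = np.empty(0, dtype=np.uint8)
            return e, e, np.empty(0, dtype=bool), e
        return tokenize_to_arrays(col.base_string, col.quality_string, self.reference_base)


# ---------------------------------------------------------------------------
# tokenizer
# ---------------------------------------------------------------------------

# Class lookup for simple (one char = one quality char) pileup characters.
_CLASS_LUT = np.full(256, _INVALID, dtype=np.uint8)
_STRAND_LUT = np.zeros(256, dtype=bool)
for _c, _k, _rev in [
    (".", MATCH, False),
    (",", MATCH, True),
    ("*", DELETION, False),
    ("#", DELETION, True),
    (">", _SKIP, False),
    ("<", _SKIP, True),
    ("N", _DROP_N, False),
    ("n", _DROP_N, True),
]:
    _CLASS_LUT[ord(_c)] = _k
    _STRAND_LUT[ord(_c)] = _rev
for _c in "ACGT":
    _CLASS_LUT[ord(_c)] = SUBSTITUTION
    _CLASS_LUT[ord(_c.lower())] = SUBSTITUTION
    _STRAND_LUT[ord(_c.lower())] = True

_HAS_COMPLEX = re.compile(r"[\^$+\-]")
_INDEL_LEN = re.compile(r"(\d+)")


def tokenize_to_arrays(
    base_string: str, quality_string: str, reference_base: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Resolve a pileup base string into parallel per-observation arrays.

    Returns ``(kinds, quality_codes, reverse_strand, base_codes)``; quality
    and base codes are raw ASCII (Phred+33 and the literal pileup character).
    ``N``/``n`` reads and ``>``/``<`` skips are dropped (they consume a
    quality character but carry no usable observation).
    """
    if _HAS_COMPLEX.search(base_string) is None:
        return _tokenize_fast(base_string, quality_string, reference_base)
    return _tokenize_scan(base_string, quality_string, reference_base)


def _tokenize_fast(bases: str, quals: str, ref: str):
    b = np.frombuffer(bases.encode("ascii"), dtype=np.uint8)
    cls = _CLASS_LUT[b].copy()
    if (cls == _INVALID).any():
        bad = chr(b[cls == _INVALID][0])
        raise PileupParseError(f"unexpected pileup character {bad!r}")
    if len(quals) != len(b):
        raise PileupParseError(
            f"quality string length {len(quals)} != observation count {len(b)}"
        )
    # a letter equal to the reference base counts as a match (case-insensitive)
    ru, rl = ord(ref.upper()), ord(ref.lower())
    cls[(b == ru) | (b == rl)] = MATCH
    q = np.frombuffer(quals.encode("ascii"), dtype=np.uint8)
    keep = cls <= DELETION
    return cls[keep], q[keep], _STRAND_LUT[b[keep]], b[keep]


def _tokenize_scan(bases: str, quals: str, ref: str):
    kinds: list[int] = []
    qcodes: list[int] = []
    strands: list[bool] = []
    chars: list[int] = []
    ru, rl = ref.upper(), ref.lower()
    i, qi, n, nq = 0, 0, len(bases), len(quals)
    last = -1  # index into kinds of the most recent kept observation
    last_dropped = False
    while i < n:
        c = bases[i]
        if c == "^":
            if i + 1 >= n:
                raise PileupParseError("dangling '^' read-start marker")
            i += 2  # mapping-quality char consumed, no observation
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            m = _INDEL_LEN.match(bases, i + 1)
            if m is None:
                raise PileupParseError(f"malformed indel token at offset {i}")
            ln = int(m.group(1))
            i = m.end() + ln
            if i > n:
                raise PileupParseError("indel sequence runs past end of base string")
            if c == "-":
                # deletion tokens are consumed but do not upgrade the anchor:
                # the deleted bases appear as '*' placeholders on their own
                # rows, and counting the anchor too would double-count
                continue
            if last_dropped:
                continue  # indel anchored on a dropped N read
            if last < 0:
                raise PileupParseError("indel token with no anchoring observation")
            kinds[last] = INSERTION
            continue
        # plain observation character: consumes one quality character
        if qi >= nq:
            raise PileupParseError("quality string shorter than observation count")
        code = _CLASS_LUT[ord(c)]
        if code == _INVALID:
            raise PileupParseError(f"unexpected pileup character {c!r}")
        q = ord(quals[qi])
        qi += 1
        i += 1
        if code == _SKIP:
            last_dropped = True
            continue
        if code == _DROP_N:
            last_dropped = True
            continue
        if code == SUBSTITUTION and (c == ru or c == rl):
            code = MATCH
        kinds.append(int(code))
        qcodes.append(q)
        strands.append(bool(_STRAND_LUT[ord(c)]))
        chars.append(ord(c))
        last = len(kinds) - 1
        last_dropped = False
    if qi != nq:
        raise PileupParseError(
            f"quality string length {nq} != observation count {qi}"
        )
    return (
        np.asarray(kinds, dtype=np.uint8),
        np.asarray(qcodes, dtype=np.uint8),
        np.asarray(strands, dtype=bool),
        np.asarray(chars, dtype=np.uint8),
    )


def tokenize_bases(
    base_string: str, quality_string: str, reference_base: str
) -> list[Observation]:
    """Resolve a pileup base string into a list of :class:`Observation`.

    Error probabilities are Phred-derived, ``10**(-Q/10)`` capped at 0.75.
    """
    from .error_model import phred_code_to_error

    kinds, qcodes, strands, chars = tokenize_to_arrays(
        base_string, quality_string, reference_base
    )
    obs = []
    for k, q, rev, ch in zip(kinds, qcodes, strands, chars):
        c = chr(ch)
        if k == DELETION:
            base = "*"
        elif c in ".,":
            base = reference_base.upper()
        else:
            base = c.upper()
        obs.append(
            Observation(
                kind=int(k),
                observed_base=base,
                error_prob=phred_code_to_error(int(q)),
                reverse_strand=bool(rev),
            )
        )
    return obs


# ---------------------------------------------------------------------------
# file-level parser
# ---------------------------------------------------------------------------

def parse_mpileup(stream: TextIO, n_samples: int | None = None) -> Iterator[PileupSite]:
    """Parse multi-sample mpileup text into :class:`PileupSite` records.

    Each line carries ``3 + 3*n_samples`` tab-separated fields: reference name,
    1-based position, reference base, then a (depth, bases, qualities) triplet
    per sample. Zero-depth samples appear as ``0 * *`` and yield no
    observations. ``n_samples`` is inferred from the first line when omitted.
    Base and quality strings are retained verbatim; non-monotone positions
    within a reference raise a warning, not an error.
    """
    last_ref: str | None = None
    last_pos = -1
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if n_samples is None:
            if len(fields) < 6 or (len(fields) - 3) % 3 != 0:
                raise PileupParseError(
                    f"line {lineno}: cannot infer sample count from {len(fields)} fields"
                )
            n_samples = (len(fields) - 3) // 3
        if len(fields) != 3 + 3 * n_samples:
            raise PileupParseError(
                f"line {lineno}: expected {3 + 3 * n_samples} fields, got {len(fields)}"
            )
        ref, pos_s, base = fields[0], fields[1], fields[2]
        try:
            pos = int(pos_s)
        except ValueError:
            raise PileupParseError(f"line {lineno}: non-integer position {pos_s!r}")
        if pos < 1:
            raise PileupParseError(f"line {lineno}: position {pos} < 1")
        if ref == last_ref and pos <= last_pos:
            warnings.warn(
                f"line {lineno}: non-monotone position {pos} after {last_pos} on {ref}",
                stacklevel=2,
            )
        last_ref, last_pos = ref, pos
        samples = []
        for s in range(n_samples):
            d_s, bs, qs = fields[3 + 3 * s : 6 + 3 * s]
            try:
                depth = int(d_s)
            except ValueError:
                raise PileupParseError(
                    f"line {lineno}: non-integer depth {d_s!r} in sample {s + 1}"
                )
            if depth < 0:
                raise PileupParseError(f"line {lineno}: negative depth in sample {s + 1}")
            samples.append(SampleColumn(depth, bs, qs))
        yield PileupSite(ref, pos, base, samples)
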