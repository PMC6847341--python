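"""Synthetic multi-sample mpileup generation with planted m7G ground truth.

The generative model mirrors what the caller assumes about NaBH4-driven
mutational profiling. A modified position is parameterized by the
modification stoichiometry ``theta`` (fraction of molecules carrying m7G,
what a mixing experiment varies) and the detection level ``r`` (per
fully-modified-molecule mutation yield of reverse transcription across the
abasic site, which depends on sequence context). In treated samples each read
covering a modified position is mutated with probability ``theta * r`` — a
uniform non-reference base, or an insertion/deletion for a configurable
fraction of mutation events. Every base-bearing read then passes a symmetric
sequencing-error channel at the Phred-determined rate; control samples
receive error only. Depths are Poisson per sample and position. Everything is
reproducible from the config seed, and the emitted text is valid mpileup.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, TextIO, Union

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "SimTruth",
    "make_reference",
    "sample_g_positions",
    "simulate_pileup",
    "write_reference_fasta",
    "make_fixture_suite",
]

_UPPER = np.frombuffer(b"ACGT", dtype=np.uint8)
_LOWER = np.frombuffer(b"acgt", dtype=np.uint8)
_IDX = {b: i for i, b in enumerate("ACGT")}


class SimConfigError(ValueError):
    """Raised when a simulation config is internally inconsistent."""


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for one simulated experiment.

    ``modified_positions`` maps 1-based positions (which must be G in the
    generated reference) to ``(theta, r)``. ``error_phred`` is the integer
    Phred score of the symmetric error channel (``None`` = error-free reads).
    ``quality_phred`` sets the quality characters written to the pileup; by
    default they match the channel, but real libraries carry background
    mutations (RT misincorporation, residual misalignment) beyond what their
    post-BAQ qualities claim, and setting ``quality_phred`` above
    ``error_phred`` emulates exactly that miscalibration.
    """

    reference_length: int = 10_000
    gc_fraction: float = 0.5
    n_treated: int = 3
    n_control: int = 3
    mean_depth: int = 2000
    modified_positions: dict[int, tuple[float, float]] = field(default_factory=dict)
    error_phred: Optional[int] = 30
    quality_phred: Optional[int] = None  # emitted quality; None = same as error_phred
    indel_fraction_of_mutations: float = 0.25
    read_marks: bool = False  # decorate lines with ^/$ read boundary markers
    zero_depth: frozenset[tuple[int, int]] = frozenset()  # (position, sample index)
    reference_name: str = "ref"
    seed: int = 0

    @property
    def error_rate(self) -> float:
        return 0.0 if self.error_phred is None else 10.0 ** (-self.error_phred / 10.0)

    @property
    def quality_char(self) -> str:
        phred = self.quality_phred if self.quality_phred is not None else self.error_phred
        q = 93 if phred is None else min(int(phred), 93)
        return chr(33 + q)

    @property
    def n_samples(self) -> int:
        return self.n_treated + self.n_control

    def validate(self) -> None:
        if self.reference_length < 1 or self.mean_depth < 0:
            raise SimConfigError("reference_length and mean_depth must be positive")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise SimConfigError("gc_fraction outside [0, 1]")
        if self.n_treated < 1 or self.n_control < 1:
            raise SimConfigError("need at least one treated and one control sample")
        for pos, (theta, r) in self.modified_positions.items():
            if not 1 <= pos <= self.reference_length:
                raise SimConfigError(f"modified position {pos} outside reference")
            if not (0.0 <= theta <= 1.0 and 0.0 <= r <= 1.0):
                raise SimConfigError(f"theta/r outside [0, 1] at position {pos}")
        if not 0.0 <= self.indel_fraction_of_mutations <= 1.0:
            raise SimConfigError("indel_fraction_of_mutations outside [0, 1]")


@dataclass
class SimTruth:
    """Ground-truth ledger paired with a simulated pileup.

    ``sites``: one row per modified position (position, ref_base, theta, r).
    ``per_sample``: one row per (position, sample) with the planted
    mutated-read count and the realized non-reference observation count
    (identical when the error channel is off).
    """

    reference: str
    sites: pd.DataFrame
    per_sample: pd.DataFrame
    config: SimConfig


def make_reference(config: SimConfig) -> str:
    """The deterministic reference sequence implied by a config's seed."""
    rng = np.random.default_rng([int(config.seed) % (2**31), 17])
    gc = config.gc_fraction
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    idx = rng.choice(4, size=config.reference_length, p=p)
    return np.frombuffer(b"ACGT", dtype="S1")[idx].tobytes().decode()


def sample_g_positions(
    reference: str, n: int, seed: int, rng: Optional[np.random.Generator] = None
) -> list[int]:
    """Choose ``n`` distinct G positions (1-based) uniformly at random."""
    if rng is None:
        rng = np.random.default_rng([int(seed) % (2**31), 23])
    gs = np.flatnonzero(np.frombuffer(reference.encode(), dtype=np.uint8) == ord("G")) + 1
    if len(gs) < n:
        raise SimConfigError(f"reference has only {len(gs)} G positions, need {n}")
    return sorted(int(p) for p in rng.choice(gs, size=n, replace=False))


def _cell(
    rng: np.random.Generator,
    ref_idx: int,
    p_mut: float,
    mean_depth: int,
    eps: float,
    indel_frac: float,
    qchar: str,
    read_marks: bool,
) -> tuple[int, str, str, int, int]:
    """Generate one (position, sample) pileup triplet plus truth counts."""
    depth = int(rng.poisson(mean_depth))
    if depth == 0:
        return 0, "*", "*", 0, 0
    n_mut = int(rng.binomial(depth, p_mut)) if p_mut > 0 else 0
    n_indel = int(rng.binomial(n_mut, indel_frac)) if n_mut else 0
    n_ins = int(rng.binomial(n_indel, 0.5)) if n_indel else 0
    n_del = n_indel - n_ins
    n_sub = n_mut - n_indel
    m = depth - n_ins - n_del  # reads showing a plain base at this column
    base_idx = np.full(m, ref_idx, dtype=np.int64)
    if n_sub:
        base_idx[:n_sub] = (ref_idx + rng.integers(1, 4, size=n_sub)) % 4
    if eps > 0.0 and m:
        err = rng.random(m) < eps
        k = int(err.sum())
        if k:
            base_idx[err] = (base_idx[err] + rng.integers(1, 4, size=k)) % 4
    rev = rng.random(m) < 0.5
    is_ref = base_idx == ref_idx
    chars = np.where(
        is_ref,
        np.where(rev, ord(","), ord(".")),
        np.where(rev, _LOWER[base_idx], _UPPER[base_idx]),
    ).astype(np.uint8)
    parts = [chars.tobytes().decode("ascii")]
    for _ in range(n_ins):
        r = rng.random() < 0.5
        ins_base = "ACGT"[int(rng.integers(0, 4))]
        parts.append(("," if r else ".") + "+1" + (ins_base.lower() if r else ins_base))
    parts.append("*" * n_del)
    bases = "".join(parts)
    if read_marks:
        bases = "^~" + bases + "$"
    quals = qchar * depth
    n_nonref = int((~is_ref).sum()) + n_ins + n_del
    return depth, bases, quals, n_mut, n_nonref


def simulate_pileup(
    config: SimConfig, out: Union[str, Path, TextIO, None] = None
) -> tuple[Union[str, Path], SimTruth]:
    """Generate the mpileup text and ground truth for a config.

    When ``out`` is a path or stream the pileup is streamed there and the
    first return value is the path (or stream); otherwise the full text is
    returned. Sample columns are ordered treated first, then control.
    """
    config.validate()
    reference = make_reference(config)
    for pos in config.modified_positions:
        if reference[pos - 1] != "G":
            raise SimConfigError(
                f"modified position {pos} is {reference[pos - 1]}, not G, "
                "in the generated reference"
            )
    rng = np.random.default_rng([int(config.seed) % (2**31), 29])
    eps = config.error_rate
    qchar = config.quality_char
    conditions = ["treated"] * config.n_treated + ["control"] * config.n_control

    close_handle = False
    if out is None:
        handle: TextIO = io.StringIO()
    elif isinstance(out, (str, Path)):
        handle = open(out, "w")
        close_handle = True
    else:
        handle = out

    records = []
    try:
        for pos in range(1, config.reference_length + 1):
            ref_base = reference[pos - 1]
            ref_idx = _IDX[ref_base]
            theta, r = config.modified_positions.get(pos, (0.0, 0.0))
            fields = [config.reference_name, str(pos), ref_base]
            for s, cond in enumerate(conditions):
                p_mut = theta * r if cond == "treated" else 0.0
                if (pos, s) in config.zero_depth:
                    depth, bases, quals, n_mut, n_nonref = 0, "*", "*", 0, 0
                else:
                    depth, bases, quals, n_mut, n_nonref = _cell(
                        rng,
                        ref_idx,
                        p_mut,
                        config.mean_depth,
                        eps,
                        config.indel_fraction_of_mutations,
                        qchar,
                        config.read_marks,
                    )
                fields += [str(depth), bases, quals]
                records.append((pos, s, cond, depth, n_mut, n_nonref))
            handle.write("\t".join(fields) + "\n")
        if out is None:
            text_or_path: Union[str, Path] = handle.getvalue()
        else:
            text_or_path = out
    finally:
        if close_handle:
            handle.close()

    sites = pd.DataFrame(
        [
            (pos, reference[pos - 1], theta, r)
            for pos, (theta, r) in sorted(config.modified_positions.items())
        ],
        columns=["position", "ref_base", "theta", "detection_level"],
    )
    per_sample = pd.DataFrame(
        records,
        columns=["position", "sample", "condition", "depth", "n_planted_mutated", "n_emitted_nonref"],
    )
    return text_or_path, SimTruth(reference, sites, per_sample, config)


def write_reference_fasta(reference: str, name: str, path: Union[str, Path]) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    SeqIO.write([SeqRecord(Seq(reference), id=name, description="")], str(path), "fasta")


def make_fixture_suite(seed: int, outdir: Union[str, Path]) -> dict[str, SimConfig]:
    """Write the canonical small fixture set used by the test suite.

    Produces a null experiment, a two-site experiment echoing the 10% / 5%
    rRNA rate differences, an indel-rich file exercising the full pileup
    grammar, and a file with a zero-depth sample column. Deterministic in
    ``seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(seed) % (2**31 - 10)

    configs: dict[str, SimConfig] = {}
    null_cfg = SimConfig(
        reference_length=200, n_treated=2, n_control=2, mean_depth=300,
        error_phred=30, seed=seed,
    )
    configs["null"] = null_cfg

    two_cfg = SimConfig(
        reference_length=300, n_treated=3, n_control=3, mean_depth=2000,
        error_phred=30, seed=seed + 1,
    )
    g1, g2 = sample_g_positions(make_reference(two_cfg), 2, two_cfg.seed)
    configs["twosite"] = replace(
        two_cfg, modified_positions={g1: (1.0, 0.10), g2: (1.0, 0.05)}
    )

    indel_cfg = SimConfig(
        reference_length=100, n_treated=1, n_control=1, mean_depth=200,
        error_phred=None, indel_fraction_of_mutations=0.8, read_marks=True,
        seed=seed + 2,
    )
    (g,) = sample_g_positions(make_reference(indel_cfg), 1, indel_cfg.seed)
    configs["indelrich"] = replace(indel_cfg, modified_positions={g: (1.0, 0.5)})

    configs["zerodepth"] = SimConfig(
        reference_length=50, n_treated=2, n_control=1, mean_depth=100,
        error_phred=30, zero_depth=frozenset({(10, 1), (11, 1)}), seed=seed + 3,
    )

    for name, cfg in configs.items():
        _, truth = simulate_pileup(cfg, outdir / f"{name}.pileup")
        truth.sites.to_csv(outdir / f"{name}.sites.tsv", sep="\t", index=False)
        truth.per_sample.to_csv(outdir / f"{name}.truth.tsv", sep="\t", index=False)
        write_reference_fasta(truth.reference, cfg.reference_name, outdir / f"{name}.fa")
    return configs
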