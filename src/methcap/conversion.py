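"""The conversion algebra behind conversion-aware bait design.

Enzymatic/bisulfite conversion reads unmethylated cytosines as thymines.
A capture bait therefore has to match the *post-conversion* sequence of its
locus, which depends on the (unknown) methylation state and on which strand
the library fragment derives from. This module provides:

* whole-genome conversion variants (all C->T, or all G->A) used for
  specificity screening in converted sequence space;
* per-bait methylation-state application: keep the C of each "methylated"
  CpG, convert every other C, optionally in the reverse-complement frame.

Non-CpG cytosines are always converted in methylation-state outputs
(CHG/CHH methylation is negligible in the intended assay). N bases pass
through every transform unchanged.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .errors import ContractViolationError
from .io_formats import SequenceRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_C_TO_T = str.maketrans("Cc", "Tt")
_G_TO_A = str.maketrans("Gg", "Aa")


def revcomp(seq: str) -> str:
    """Reverse complement, preserving case; N maps to N."""
    return seq.translate(_COMPLEMENT)[::-1]


class ConversionMode(str, Enum):
    UNMODIFIED = "unmodified"
    SENSE_UNMETHYLATED = "sense_unmethylated"  # all C -> T
    ANTISENSE_UNMETHYLATED = "antisense_unmethylated"  # all G -> A

    @property
    def suffix(self) -> str:
        return {"unmodified": ".unmod", "sense_unmethylated": ".CT",
                "antisense_unmethylated": ".GA"}[self.value]


PATTERNS = ("all_methylated", "split_A", "split_B", "unmethylated")
STRANDS = ("sense", "antisense")


@dataclass(frozen=True)
class MethylationState:
    """One of the 4 x 2 methylation-pattern/strand combinations."""

    pattern: str
    strand: str

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ContractViolationError(f"unknown pattern {self.pattern!r}")
        if self.strand not in STRANDS:
            raise ContractViolationError(f"unknown strand {self.strand!r}")

    @property
    def label(self) -> str:
        return f"{self.pattern}|{self.strand}"


ALL_STATES: tuple[MethylationState, ...] = tuple(
    MethylationState(p, s) for p in PATTERNS for s in STRANDS
)


@dataclass(frozen=True)
class GenomeVariant:
    """A whole genome transformed to one conversion state."""

    genome_id: str
    mode: ConversionMode
    sequences: tuple[SequenceRecord, ...]


def enumerate_cpg_sites(seq: str) -> list[int]:
    """Ascending 0-based positions of the C of every CG dinucleotide.

    Case-insensitive; N never matches.
    """
    s = seq.upper()
    return [i for i in range(len(s) - 1) if s[i] == "C" and s[i + 1] == "G"]


def convert_genome(seq: str, mode: ConversionMode) -> str:
    """Apply a whole-sequence conversion; length and case preserved."""
    mode = ConversionMode(mode)
    if mode is ConversionMode.UNMODIFIED:
        return seq
    if mode is ConversionMode.SENSE_UNMETHYLATED:
        return seq.translate(_C_TO_T)
    return seq.translate(_G_TO_A)


def derive_seed(*parts: object) -> int:
    """Stable 64-bit seed from a tuple of identifying parts (hierarchical seeding)."""
    digest = hashlib.sha256("|".join(map(str, parts)).encode()).digest()
    return int.from_bytes(digest[:8], "little")


def make_split_sets(cpg_positions: Sequence[int], seed: int) -> tuple[set[int], set[int]]:
    """Deterministically partition CpG positions into two halves (A, B).

    |A| = ceil(n/2). The same seed always yields the same partition.
    """
    positions = sorted(set(cpg_positions))
    if len(positions) != len(cpg_positions):
        raise ContractViolationError("cpg_positions must be distinct")
    if not positions:
        return set(), set()
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(positions))
    k = math.ceil(len(positions) / 2)
    a = {positions[i] for i in order[:k]}
    b = {positions[i] for i in order[k:]}
    return a, b


def _methylate_in_frame(seq: str, kept: set[int]) -> str:
    out = []
    for i, ch in enumerate(seq):
        if ch == "C" and i not in kept:
            out.append("T")
        elif ch == "c" and i not in kept:
            out.append("t")
        else:
            out.append(ch)
    return "".join(out)


def apply_methylation_state(
    seq: str,
    state: MethylationState,
    methylated_positions: Iterable[int] | None = None,
) -> str:
    """Render the post-conversion sequence of ``seq`` under a methylation state.

    ``methylated_positions`` are 0-based sense-frame positions of CpG
    cytosines to protect; it is only consulted for the split patterns
    (all_methylated/unmethylated override it with all/none). For
    ``strand='antisense'`` the output is the reverse-complement-frame
    sequence with the antisense C of each protected CpG retained — i.e. the
    literal sequence a synthesizer would receive.
    """
    cpg = set(enumerate_cpg_sites(seq))
    if state.pattern == "all_methylated":
        kept = cpg
    elif state.pattern == "unmethylated":
        kept = set()
    else:
        kept = set(methylated_positions or ())
        extra = kept - cpg
        if extra:
            raise ContractViolationError(
                f"methylated positions {sorted(extra)} are not CpG cytosines"
            )
    if state.strand == "sense":
        return _methylate_in_frame(seq, kept)
    length = len(seq)
    # A sense CpG C at i pairs with the antisense CpG C at revcomp index L-2-i.
    mapped = {length - 2 - i for i in kept}
    return _methylate_in_frame(revcomp(seq), mapped)
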