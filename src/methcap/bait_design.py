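"""Bait tiling, per-candidate conversion-permutation variants, and
composition filtering (repeat-mask fraction, GC range, cross-hit counts).

The default geometry is 80 nt baits at 2x tiling density (step = 40), with
nine sequences per candidate: the unmodified original plus the eight
methylation-state permutations (all methylated, two complementary random
half-methylated splits, unmethylated; each on sense and antisense strands).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .conversion import (
    ALL_STATES,
    apply_methylation_state,
    derive_seed,
    enumerate_cpg_sites,
    make_split_sets,
    revcomp,
)
from .errors import ConfigurationError, CoordinateError
from .io_formats import SequenceRecord, TargetRegion, genome_as_dict

logger = logging.getLogger(__name__)

ORIGINAL_STATE = "original"


@dataclass(frozen=True)
class BaitCandidate:
    """An 80 nt (by default) tiled window over a target region.

    ``start`` is the 0-based genomic start of the window; ``sequence`` is in
    target orientation (reverse-complemented for '-' strand targets).
    ``gc_fraction`` and ``mask_fraction`` refer to the unmodified sequence.
    """

    id: str
    target_name: str
    chrom: str
    start: int
    length: int
    sequence: str
    mask_fraction: float
    gc_fraction: float
    n_cpg: int


@dataclass(frozen=True)
class BaitVariant:
    candidate_id: str
    state: str  # "original" or "<pattern>|<strand>"
    sequence: str
    multiplicity: int = 1


@dataclass(frozen=True)
class FilterReport:
    candidate_id: str
    pass_mask: bool
    pass_gc: bool
    pass_hits: bool | None  # None = undetermined (no hit table)
    retained: bool


def extract_target_sequence(
    genome: Sequence[SequenceRecord] | Mapping[str, SequenceRecord],
    region: TargetRegion,
) -> str:
    """Substring ``[start, end)`` of the region's chromosome, case preserved.

    '-' strand regions are reverse-complemented into target orientation.
    """
    by_id = genome if isinstance(genome, Mapping) else genome_as_dict(genome)
    rec = by_id.get(region.chrom)
    if rec is None:
        raise CoordinateError(
            f"region {region.name!r}: chromosome {region.chrom!r} not in genome"
        )
    if region.end > rec.length:
        raise CoordinateError(
            f"region {region.name!r}: [{region.start}, {region.end}) exceeds "
            f"{region.chrom} length {rec.length}"
        )
    seq = rec.sequence[region.start : region.end]
    return revcomp(seq) if region.strand == "-" else seq


def compute_gc(seq: str) -> float:
    """GC fraction over non-N bases; 0.0 when the sequence is all N/empty."""
    upper = seq.upper()
    denom = len(upper) - upper.count("N")
    if denom == 0:
        return 0.0
    return (upper.count("G") + upper.count("C")) / denom


def compute_mask_fraction(
    seq: str, mask_intervals: Iterable[tuple[int, int]] | None = None
) -> float:
    """Fraction of positions lowercase or N, unioned with explicit intervals.

    ``mask_intervals`` are 0-based half-open intervals relative to the bait.
    """
    if not seq:
        return 0.0
    masked = [c.islower() or c.upper() == "N" for c in seq]
    if mask_intervals is not None:
        for s, e in mask_intervals:
            for i in range(max(0, s), min(len(seq), e)):
                masked[i] = True
    return sum(masked) / len(seq)


def tile_candidates(
    target_seq: str,
    region: TargetRegion,
    bait_length: int = 80,
    tiling_density: int = 2,
    anchor_end: bool = False,
    max_n: int = 0,
) -> list[BaitCandidate]:
    """Tile fixed-length candidates over a target at the given density.

    step = bait_length / tiling_density; offsets 0, step, 2*step, ... while
    the window fits. With ``anchor_end`` an extra window flush with the 3'
    end is added when the last regular window falls short. Candidates with
    more than ``max_n`` ambiguous bases are dropped.
    """
    if bait_length < 1 or tiling_density < 1:
        raise ConfigurationError("bait_length and tiling_density must be >= 1")
    if bait_length % tiling_density != 0:
        raise ConfigurationError(
            f"bait_length {bait_length} not divisible by tiling density {tiling_density}"
        )
    step = bait_length // tiling_density
    length = len(target_seq)
    if length < bait_length:
        logger.warning(
            "target %s (%d bp) shorter than bait length %d; no candidates",
            region.name, length, bait_length,
        )
        return []
    offsets = list(range(0, length - bait_length + 1, step))
    if anchor_end and offsets[-1] + bait_length != length:
        offsets.append(length - bait_length)
    candidates: list[BaitCandidate] = []
    for idx, offset in enumerate(offsets):
        seq = target_seq[offset : offset + bait_length]
        if seq.upper().count("N") > max_n:
            logger.warning("dropping candidate %s_c%03d: too many Ns", region.name, idx)
            continue
        if region.strand == "-":
            genomic_start = region.end - offset - bait_length
        else:
            genomic_start = region.start + offset
        candidates.append(
            BaitCandidate(
                id=f"{region.name}_c{idx:03d}",
                target_name=region.name,
                chrom=region.chrom,
                start=genomic_start,
                length=bait_length,
                sequence=seq,
                mask_fraction=compute_mask_fraction(seq),
                gc_fraction=compute_gc(seq),
                n_cpg=len(enumerate_cpg_sites(seq)),
            )
        )
    return candidates


def enumerate_variants(
    candidate: BaitCandidate, seed: int, dedup: bool = False
) -> list[BaitVariant]:
    """The nine per-candidate sequences: original + eight methylation states.

    The random half-methylated split is drawn once per candidate from a seed
    derived from (seed, candidate.id), so overlapping candidates get
    independent splits and whole designs are reproducible. ``dedup``
    collapses identical sequences, recording multiplicity.
    """
    cpg = enumerate_cpg_sites(candidate.sequence)
    split_a, split_b = make_split_sets(cpg, derive_seed(seed, candidate.id))
    variants = [BaitVariant(candidate.id, ORIGINAL_STATE, candidate.sequence)]
    for state in ALL_STATES:
        mset = split_a if state.pattern == "split_A" else split_b
        seq = apply_methylation_state(candidate.sequence, state, mset)
        variants.append(BaitVariant(candidate.id, state.label, seq))
    if not dedup:
        return variants
    by_seq: dict[str, BaitVariant] = {}
    for v in variants:
        if v.sequence in by_seq:
            prev = by_seq[v.sequence]
            by_seq[v.sequence] = replace(prev, multiplicity=prev.multiplicity + 1)
        else:
            by_seq[v.sequence] = v
    return list(by_seq.values())


def filter_candidates(
    candidates: Sequence[BaitCandidate],
    hit_table: Mapping[str, int] | None = None,
    max_mask: float = 0.25,
    gc_min: float = 0.10,
    gc_max: float = 0.80,
    max_hits: int = 10,
) -> tuple[list[BaitCandidate], list[FilterReport]]:
    """Apply the composition/specificity filters.

    Retention requires mask_fraction strictly below ``max_mask``, GC within
    the inclusive ``[gc_min, gc_max]`` range, and — when a hit table is
    supplied — at most ``max_hits`` cross-hits. Bounds follow the design
    contract: mask strict '<', GC and hits inclusive.
    """
    if not (0 <= max_mask <= 1 and 0 <= gc_min <= gc_max <= 1):
        raise ConfigurationError("filter thresholds out of range")
    retained: list[BaitCandidate] = []
    reports: list[FilterReport] = []
    for cand in candidates:
        pass_mask = cand.mask_fraction < max_mask
        pass_gc = gc_min <= cand.gc_fraction <= gc_max
        if hit_table is None or cand.id not in hit_table:
            pass_hits: bool | None = None
        else:
            pass_hits = hit_table[cand.id] <= max_hits
        keep = pass_mask and pass_gc and (pass_hits is not False)
        reports.append(FilterReport(cand.id, pass_mask, pass_gc, pass_hits, keep))
        if keep:
            retained.append(cand)
    return retained, reports
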