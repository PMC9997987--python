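"""Deterministic cross-hybridization screening in converted sequence space.

Every bait variant is searched against every conversion variant of every
screening genome (3 variants per genome: unmodified, all-C->T, all-G->A).
The hit criterion is a seed-and-extend local-alignment count:

* exact k-mer seeds (default k=12) locate candidate genome regions;
* each region is scored by Smith-Waterman with linear gap costs
  (match +1 / mismatch -1 / gap -2 by default) in both query orientations;
* genome end-positions whose best local score reaches ``min_score`` are
  clustered — positions closer than the bait length merge into a single
  counted occurrence — and the per-genome-variant count is capped at
  ``max_tabulated``.

This replaces an external BLAST screen with a parameter-complete,
oracle-checkable criterion. Alignments with no exact k-mer seed are missed
by construction; at the default thresholds such alignments require
improbably regular mismatch spacing and do not occur in random sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

if TYPE_CHECKING:
    from .bait_design import BaitCandidate, BaitVariant

import numpy as np

from .conversion import ConversionMode, GenomeVariant, convert_genome, revcomp
from .errors import ConfigurationError
from .io_formats import SequenceRecord

_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Case-insensitive 0..4 encoding (4 = N/other, never matches)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class HitCriterion:
    """Scoring and tabulation parameters for the specificity screen."""

    match_score: int = 1
    mismatch_score: int = -1
    gap_score: int = -2
    min_score: int = 40
    max_tabulated: int = 500
    seed_k: int = 12
    merge_distance: int | None = None  # None -> bait length
    # seeded diagonals whose best ungapped segment scores below
    # min_score - prefilter_margin skip the gapped DP stage entirely
    prefilter_margin: int = 10

    def __post_init__(self) -> None:
        if self.max_tabulated < 1:
            raise ConfigurationError("max_tabulated must be >= 1")
        if self.match_score <= 0 or self.mismatch_score >= 0 or self.gap_score >= 0:
            raise ConfigurationError("scores must be match>0, mismatch<0, gap<0")


@dataclass
class SpecificityReport:
    candidate_id: str
    hits: dict[tuple[str, str, str], int] = field(default_factory=dict)
    max_hits: int = 0


# ---------------------------------------------------------------------------
# Alignment kernel: per-column best local alignment scores


def _endpoint_scores_numpy(q: np.ndarray, t: np.ndarray,
                           match: int, mismatch: int, gap: int) -> np.ndarray:
    """best[j] = max over query rows of the local DP cell ending at text col j.

    Row-wise vectorization: within a row, the left-gap chain
    H[i][j] = max_{k<=j} (A[k] - gp*(j-k)) is a running max of A[k] + gp*k.
    """
    gp = -gap
    n = t.size
    prev = np.zeros(n + 1, dtype=np.int64)
    best = np.zeros(n, dtype=np.int64)
    ramp = gp * np.arange(1, n + 1, dtype=np.int64)
    for i in range(q.size):
        qi = q[i]
        sub = np.where((t == qi) & (qi < 4), match, mismatch)
        a = np.maximum(prev[:-1] + sub, prev[1:] - gp)
        np.maximum(a, 0, out=a)
        c = a + ramp
        np.maximum.accumulate(c, out=c)
        cur = np.empty(n + 1, dtype=np.int64)
        cur[0] = 0
        np.subtract(c, ramp, out=cur[1:])
        np.maximum(best, cur[1:], out=best)
        prev = cur
    return best


try:  # optional numba acceleration; numpy fallback is exact-equivalent
    from numba import njit

    @njit(cache=False)
    def _endpoint_scores_numba(q, t, match, mismatch, gap):  # pragma: no cover
        n = t.size
        m = q.size
        prev = np.zeros(n + 1, dtype=np.int64)
        cur = np.zeros(n + 1, dtype=np.int64)
        best = np.zeros(n, dtype=np.int64)
        for i in range(m):
            qi = q[i]
            cur[0] = 0
            for j in range(1, n + 1):
                s = match if (t[j - 1] == qi and qi < 4) else mismatch
                v = prev[j - 1] + s
                w = prev[j] + gap
                if w > v:
                    v = w
                w = cur[j - 1] + gap
                if w > v:
                    v = w
                if v < 0:
                    v = 0
                cur[j] = v
                if v > best[j - 1]:
                    best[j - 1] = v
            prev, cur = cur, prev
        return best

    @njit(cache=False)
    def _best_ungapped_numba(q, t, d, match, mismatch):  # pragma: no cover
        j0 = d if d > 0 else 0
        j1 = min(t.size, d + q.size)
        best = 0
        run = 0
        for j in range(j0, j1):
            s = match if (t[j] == q[j - d] and q[j - d] < 4) else mismatch
            run += s
            if run < 0:
                run = 0
            elif run > best:
                best = run
        return best

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def endpoint_scores(q: np.ndarray, t: np.ndarray, criterion: HitCriterion) -> np.ndarray:
    if _HAVE_NUMBA:
        return _endpoint_scores_numba(
            q, t, criterion.match_score, criterion.mismatch_score, criterion.gap_score
        )
    return _endpoint_scores_numpy(
        q, t, criterion.match_score, criterion.mismatch_score, criterion.gap_score
    )


def _best_ungapped(q: np.ndarray, t: np.ndarray, d: int, match: int, mismatch: int) -> int:
    if _HAVE_NUMBA:
        return int(_best_ungapped_numba(q, t, d, match, mismatch))
    return _best_ungapped_numpy(q, t, d, match, mismatch)


# ---------------------------------------------------------------------------
# Seed index


class _SequenceIndex:
    """Exact k-mer positions of one genome sequence (uppercase)."""

    def __init__(self, sequence: str, k: int) -> None:
        self.k = k
        self.codes = encode(sequence)
        self.length = len(sequence)
        upper = sequence.upper()
        table: dict[str, list[int]] = {}
        for i in range(self.length - k + 1):
            kmer = upper[i : i + k]
            if "N" in kmer:
                continue
            table.setdefault(kmer, []).append(i)
        self.table = table

    def seed_diagonals(self, query_upper: str) -> list[int]:
        """Distinct diagonals d = genome_pos - query_pos with a seed match."""
        diagonals: set[int] = set()
        table = self.table
        k = self.k
        for i in range(len(query_upper) - k + 1):
            positions = table.get(query_upper[i : i + k])
            if positions:
                for g in positions:
                    diagonals.add(g - i)
        return sorted(diagonals)


def _best_ungapped_numpy(q: np.ndarray, t: np.ndarray, d: int,
                         match: int, mismatch: int) -> int:
    """Best ungapped segment score (Kadane) along diagonal d."""
    j0 = max(0, d)
    j1 = min(t.size, d + q.size)
    if j1 <= j0:
        return 0
    ts = t[j0:j1]
    qs = q[j0 - d : j1 - d]
    s = np.where((ts == qs) & (qs < 4), match, mismatch)
    c = np.cumsum(s)
    prefix_min = np.minimum.accumulate(np.concatenate(([0], c[:-1])))
    return int(np.max(c - prefix_min))


def _merged_regions(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals.sort()
    regions = [intervals[0]]
    for lo, hi in intervals[1:]:
        if lo <= regions[-1][1]:
            regions[-1] = (regions[-1][0], max(regions[-1][1], hi))
        else:
            regions.append((lo, hi))
    return regions


def _hit_endpoints_seq(query: str, index: _SequenceIndex, criterion: HitCriterion) -> set[int]:
    """1-based genome end-positions with best local score >= min_score."""
    endpoints: set[int] = set()
    m = len(query)
    n = index.length
    # a gapped alignment overlapping a seeded diagonal stripe stays within
    # ~m/2 + slack of it (gap budget bounded by the score threshold)
    pad = m // 2 + 16
    threshold = criterion.min_score - criterion.prefilter_margin
    for oriented in (query, revcomp(query)):
        diagonals = index.seed_diagonals(oriented.upper())
        if not diagonals:
            continue
        qcodes = encode(oriented)
        intervals: list[tuple[int, int]] = []
        for d in diagonals:
            if threshold > 0:
                score = _best_ungapped(
                    qcodes, index.codes, d,
                    criterion.match_score, criterion.mismatch_score,
                )
                if score < threshold:
                    continue
            intervals.append((max(0, max(0, d) - pad), min(n, min(n, d + m) + pad)))
        for lo, hi in _merged_regions(intervals):
            best = endpoint_scores(qcodes, index.codes[lo:hi], criterion)
            for j in np.flatnonzero(best >= criterion.min_score):
                endpoints.add(lo + int(j) + 1)
    return endpoints


def cluster_count(endpoints: set[int], merge_distance: int, cap: int) -> int:
    """Count clusters of endpoint positions; gaps <= merge_distance merge."""
    if not endpoints:
        return 0
    ordered = sorted(endpoints)
    count = 1
    prev = ordered[0]
    for p in ordered[1:]:
        if p - prev > merge_distance:
            count += 1
            if count >= cap:
                return cap
        prev = p
    return count


def count_hits(
    variant_seq: str,
    genome_variant: GenomeVariant,
    criterion: HitCriterion = HitCriterion(),
    _indexes: Sequence[_SequenceIndex] | None = None,
) -> int:
    """Merged-cluster count of local-alignment hits of a bait variant.

    Both query orientations are searched against the genome variant's forward
    strand; overlapping genome hits collapse to one occurrence; the total is
    capped at ``criterion.max_tabulated``.
    """
    if not variant_seq:
        raise ConfigurationError("empty bait variant sequence")
    merge = criterion.merge_distance or len(variant_seq)
    if _indexes is None:
        _indexes = [_SequenceIndex(rec.sequence, criterion.seed_k)
                    for rec in genome_variant.sequences]
    total = 0
    for index in _indexes:
        endpoints = _hit_endpoints_seq(variant_seq, index, criterion)
        total += cluster_count(endpoints, merge, criterion.max_tabulated)
        if total >= criterion.max_tabulated:
            return criterion.max_tabulated
    return total


# ---------------------------------------------------------------------------
# Genome variant construction and the full screen


def build_genome_variant_set(
    genomes: Sequence[tuple[str, Sequence[SequenceRecord]]],
) -> list[GenomeVariant]:
    """Three conversion variants (unmodified, C->T, G->A) per input genome."""
    if not genomes:
        raise ConfigurationError("at least one genome is required")
    ids = [gid for gid, _ in genomes]
    if len(set(ids)) != len(ids):
        raise ConfigurationError("duplicate genome ids")
    out: list[GenomeVariant] = []
    for gid, records in genomes:
        for mode in ConversionMode:
            converted = tuple(
                SequenceRecord(rec.id, convert_genome(rec.sequence, mode))
                for rec in records
            )
            out.append(GenomeVariant(gid, mode, converted))
    return out


def screen_candidates(
    candidates: Sequence["BaitCandidate"],
    variants_per_candidate: Sequence["BaitVariant"],
    genome_variants: Sequence[GenomeVariant],
    criterion: HitCriterion = HitCriterion(),
) -> list[SpecificityReport]:
    """Hit counts for every bait variant x genome variant; per-candidate max.

    Deterministic for fixed inputs. Raises :class:`ConfigurationError` when
    the genome-variant set is empty or a genome is missing a conversion mode.
    """
    if not genome_variants:
        raise ConfigurationError("empty genome variant list")
    modes_by_genome: dict[str, set[ConversionMode]] = {}
    for gv in genome_variants:
        modes_by_genome.setdefault(gv.genome_id, set()).add(gv.mode)
    for gid, modes in modes_by_genome.items():
        missing = set(ConversionMode) - modes
        if missing:
            raise ConfigurationError(
                f"genome {gid!r} missing conversion modes: "
                f"{sorted(m.value for m in missing)}"
            )
    known = {c.id for c in candidates}
    by_candidate: dict[str, list["BaitVariant"]] = {}
    for v in variants_per_candidate:
        if v.candidate_id not in known:
            raise ConfigurationError(f"variant references unknown candidate {v.candidate_id!r}")
        by_candidate.setdefault(v.candidate_id, []).append(v)

    indexes = {
        id(gv): [_SequenceIndex(rec.sequence, criterion.seed_k) for rec in gv.sequences]
        for gv in genome_variants
    }
    reports: list[SpecificityReport] = []
    for cand in candidates:
        report = SpecificityReport(candidate_id=cand.id)
        for variant in by_candidate.get(cand.id, []):
            for gv in genome_variants:
                n = count_hits(variant.sequence, gv, criterion, _indexes=indexes[id(gv)])
                report.hits[(gv.genome_id, gv.mode.value, variant.state)] = n
        report.max_hits = max(report.hits.values(), default=0)
        reports.append(report)
    return reports
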