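"""Independent brute-force oracles used to check the package's fast paths.

Everything here is deliberately naive: plain loops, no shared code with the
implementation beyond dataclass inputs.
"""

from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq.upper()))


def sw_column_maxima(query: str, text: str, match: int = 1,
                     mismatch: int = -1, gap: int = -2) -> list[int]:
    """Full Smith-Waterman DP; best[j] = best local score ending at text col j+1."""
    q = query.upper()
    t = text.upper()
    n = len(t)
    prev = [0] * (n + 1)
    best = [0] * n
    for qi in q:
        cur = [0] * (n + 1)
        for j in range(1, n + 1):
            s = match if (t[j - 1] == qi and qi != "N") else mismatch
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
        prev = cur
    return best


def oracle_count_hits(query: str, text: str, min_score: int = 40,
                      merge_distance: int | None = None, cap: int = 500,
                      match: int = 1, mismatch: int = -1, gap: int = -2) -> int:
    """Exhaustive-scan hit count with the same scoring and merge rule."""
    merge = merge_distance if merge_distance is not None else len(query)
    endpoints: set[int] = set()
    for oriented in (query, naive_revcomp(query)):
        best = sw_column_maxima(oriented, text, match, mismatch, gap)
        for j, score in enumerate(best):
            if score >= min_score:
                endpoints.add(j + 1)
    if not endpoints:
        return 0
    ordered = sorted(endpoints)
    count = 1
    prev = ordered[0]
    for p in ordered[1:]:
        if p - prev > merge:
            count += 1
        prev = p
    return min(count, cap)


def brute_tile_offsets(length: int, bait_length: int, step: int,
                       anchor_end: bool) -> list[int]:
    """Enumerate every valid tiling offset directly."""
    offsets = [o for o in range(0, length + 1) if o % step == 0 and o + bait_length <= length]
    if anchor_end and offsets and offsets[-1] + bait_length != length:
        offsets.append(length - bait_length)
    return offsets


def brute_region_mean(records, region) -> float | None:
    """Unweighted mean percent of records inside a region, by direct scan."""
    vals = []
    for r in records:
        if r.chrom == region.chrom and region.start < r.pos <= region.end:
            vals.append(r.percent)
    if not vals:
        return None
    return sum(vals) / len(vals)


def brute_contains(region, chrom: str, pos: int) -> bool:
    """0-based containment check done by materializing the base list."""
    bases = [(region.chrom, b + 1) for b in range(region.start, region.end)]
    return (chrom, pos) in bases
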