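"""Capture-evaluation analytics.

Per-target coverage summaries, CpG callset filtering / region intersection /
cross-callset site matching, site-level Pearson correlation, per-region mean
methylation, paired t-tests, spike-in conversion-control reports, and random
"promoter" region construction for out-of-panel comparisons.

Interval logic bridges BED (0-based half-open) and Bismark (1-based) at the
boundary: a 1-based position p lies in region [s, e) iff s < p <= e.
Site matching keys on (chrom, pos) without strand — coverage records are
treated as strand-agnostic positions.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ConfigurationError, DataError, UndefinedStatisticError
from .io_formats import (
    CpGRecord,
    CytosineContextRecord,
    TargetRegion,
    percent_methylation,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CoverageSummary:
    region: TargetRegion
    mean_depth: float
    breadth: float  # fraction of bases with depth >= 1
    min_depth: int
    max_depth: int


@dataclass(frozen=True)
class MatchedSites:
    keys: tuple[tuple[str, int], ...]
    percents_a: tuple[float, ...]
    percents_b: tuple[float, ...]

    @property
    def n(self) -> int:
        return len(self.keys)


@dataclass(frozen=True)
class ComparisonResult:
    r: float
    n_sites: int
    region_means_a: dict[str, float]
    region_means_b: dict[str, float]
    t_stat: float
    dof: int
    p_value: float


@dataclass(frozen=True)
class ConversionReport:
    """Spike-in control metrics, all on the 0-100 scale.

    ``lambda_error`` is residual methylation on the unmethylated control
    (conversion error); ``puc19_retention`` is retained methylation on the
    CpG-methylated control (100 - overconversion). Missing categories are
    None.
    """

    lambda_error: float | None
    puc19_retention: float | None
    chg_level: float | None
    chh_level: float | None


def summarize_region_coverage(
    depth_track: Mapping[tuple[str, int], int],
    regions: Sequence[TargetRegion],
) -> list[CoverageSummary]:
    """Mean/breadth/min/max depth per region; absent positions count as 0."""
    summaries: list[CoverageSummary] = []
    get = depth_track.get
    for region in regions:
        depths = [get((region.chrom, pos), 0) for pos in range(region.start + 1, region.end + 1)]
        arr = np.asarray(depths, dtype=np.int64)
        summaries.append(
            CoverageSummary(
                region=region,
                mean_depth=float(arr.mean()),
                breadth=float((arr >= 1).mean()),
                min_depth=int(arr.min()),
                max_depth=int(arr.max()),
            )
        )
    return summaries


def filter_cov_records(
    records: Sequence[CpGRecord], min_depth: int = 5, unique: bool = True
) -> list[CpGRecord]:
    """Keep records with depth >= min_depth; optionally collapse duplicates.

    "Above 5x" is implemented inclusively (depth >= 5); pass min_depth=6 for
    a strict reading. Duplicate (chrom, pos) keys must carry identical
    counts, otherwise a :class:`DataError` names the site.
    """
    if min_depth < 0:
        raise ConfigurationError("min_depth must be >= 0")
    kept = [r for r in records if r.depth >= min_depth]
    if not unique:
        return kept
    by_key: dict[tuple[str, int], CpGRecord] = {}
    out: list[CpGRecord] = []
    for rec in kept:
        key = (rec.chrom, rec.pos)
        prev = by_key.get(key)
        if prev is None:
            by_key[key] = rec
            out.append(rec)
        elif (prev.count_m, prev.count_u) != (rec.count_m, rec.count_u):
            raise DataError(
                f"conflicting duplicate records at {rec.chrom}:{rec.pos} "
                f"({prev.count_m}m/{prev.count_u}u vs {rec.count_m}m/{rec.count_u}u)"
            )
    return out


def intersect_with_regions(
    records: Sequence[CpGRecord], regions: Sequence[TargetRegion]
) -> list[CpGRecord]:
    """Records whose position falls in >= 1 region; emitted once each."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for region in regions:
        by_chrom.setdefault(region.chrom, []).append((region.start, region.end))
    for ivs in by_chrom.values():
        ivs.sort()
    out: list[CpGRecord] = []
    for rec in records:
        ivs = by_chrom.get(rec.chrom)
        if ivs is None:
            continue
        # 1-based pos p is in [s, e) iff s < p <= e
        if any(s < rec.pos <= e for s, e in ivs):
            out.append(rec)
    return out


def match_sites(a: Sequence[CpGRecord], b: Sequence[CpGRecord]) -> MatchedSites:
    """Align two callsets on their common (chrom, pos) keys."""
    map_a = {(r.chrom, r.pos): r for r in a}
    if len(map_a) != len(a):
        raise DataError("callset A has duplicate (chrom, pos) keys")
    map_b = {(r.chrom, r.pos): r for r in b}
    if len(map_b) != len(b):
        raise DataError("callset B has duplicate (chrom, pos) keys")
    common = sorted(map_a.keys() & map_b.keys())
    return MatchedSites(
        keys=tuple(common),
        percents_a=tuple(map_a[k].percent for k in common),
        percents_b=tuple(map_b[k].percent for k in common),
    )


def pearson_r(m: MatchedSites) -> float:
    """Product-moment correlation of the matched percent series."""
    if m.n < 2:
        raise UndefinedStatisticError(f"correlation undefined for n={m.n} matched sites")
    x = np.asarray(m.percents_a, dtype=float)
    y = np.asarray(m.percents_b, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("correlation undefined: a series has zero variance")
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc @ yc) / math.sqrt((xc @ xc) * (yc @ yc)))


def region_mean_methylation(
    records: Sequence[CpGRecord], regions: Sequence[TargetRegion]
) -> dict[str, float]:
    """Unweighted mean of site percents per region, keyed by region name.

    Regions with zero sites are absent from the result (missing, not 0).
    """
    sums: dict[str, list[float]] = {}
    for region in regions:
        vals = [r.percent for r in records if region.contains_pos(r.chrom, r.pos)]
        if vals:
            sums[region.name] = vals
    return {name: float(np.mean(vals)) for name, vals in sums.items()}


def paired_t_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, int, float]:
    """Two-sided paired t-test; returns (t, dof, p).

    Degenerate zero-variance differences: mean 0 -> (0, n-1, 1); nonzero
    mean -> (+-inf, n-1, 0).
    """
    if len(x) != len(y):
        raise DataError("paired series must have equal length")
    n = len(x)
    if n < 2:
        raise DataError("paired t-test needs n >= 2 pairs")
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    sd = float(d.std(ddof=1))
    dof = n - 1
    mean = float(d.mean())
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, dof, 1.0
        logger.warning("paired_t_test: zero-variance nonzero-mean differences (degenerate)")
        return math.copysign(math.inf, mean), dof, 0.0
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), dof))
    return t, dof, p


def _pooled_percent(records: Sequence[CytosineContextRecord]) -> float | None:
    m = sum(r.count_m for r in records)
    total = m + sum(r.count_u for r in records)
    if total == 0:
        return None
    return percent_methylation(m, total - m)


def conversion_report(
    report_records: Sequence[CytosineContextRecord],
    lambda_chrom: str,
    puc19_chrom: str,
) -> ConversionReport:
    """Spike-in conversion metrics pooled over call counts.

    lambda_error pools every lambda-control cytosine (any context);
    puc19_retention pools the methylated control's CpG cytosines; CHG/CHH
    levels pool the sample's records excluding both control chromosomes.
    """
    lam = [r for r in report_records if r.chrom == lambda_chrom]
    puc = [r for r in report_records if r.chrom == puc19_chrom and r.context == "CpG"]
    sample = [r for r in report_records if r.chrom not in (lambda_chrom, puc19_chrom)]
    chg = [r for r in sample if r.context == "CHG"]
    chh = [r for r in sample if r.context == "CHH"]

    values: dict[str, float | None] = {}
    for field_name, recs in (
        ("lambda_error", lam),
        ("puc19_retention", puc),
        ("chg_level", chg),
        ("chh_level", chh),
    ):
        value = _pooled_percent(recs)
        if value is None:
            warnings.warn(f"conversion_report: no calls for {field_name}", stacklevel=2)
        values[field_name] = value
    return ConversionReport(**values)


def random_promoter_regions(
    chrom_lengths: Mapping[str, int],
    promoters: Sequence[TargetRegion],
    n_tracks: int = 200,
    track_len: int = 10000,
    seed: int = 0,
) -> list[TargetRegion]:
    """Intersect uniform random fixed-length tracks with promoter regions.

    Tracks are placed uniformly over chromosomes at least ``track_len`` long
    (weighted by the number of valid start positions); each nonempty
    track-promoter intersection yields one output region, deduplicated by
    coordinates. Tracks may overlap each other.
    """
    eligible = [(c, ln) for c, ln in chrom_lengths.items() if ln >= track_len]
    if not eligible:
        raise ConfigurationError(f"no chromosome is >= track_len ({track_len})")
    rng = np.random.default_rng(seed)
    weights = np.asarray([ln - track_len + 1 for _, ln in eligible], dtype=float)
    weights /= weights.sum()
    by_chrom: dict[str, list[TargetRegion]] = {}
    for p in promoters:
        by_chrom.setdefault(p.chrom, []).append(p)
    seen: set[tuple[str, int, int]] = set()
    out: list[TargetRegion] = []
    for i in range(n_tracks):
        idx = int(rng.choice(len(eligible), p=weights))
        chrom, ln = eligible[idx]
        start = int(rng.integers(0, ln - track_len + 1))
        end = start + track_len
        for prom in by_chrom.get(chrom, []):
            s = max(start, prom.start)
            e = min(end, prom.end)
            if e <= s:
                continue
            key = (chrom, s, e)
            if key in seen:
                continue
            seen.add(key)
            out.append(TargetRegion(chrom, s, e, f"rand{i:03d}_{prom.name}", prom.strand))
    return out
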