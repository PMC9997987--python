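"""Seeded synthetic data: genomes, promoter-like targets, methylation
profiles, and simulated converted coverage with realistic error structure.

The generative model is deliberately simple and fully config-exposed:

* per-base depth ~ Poisson(mean_target_depth inside targets, else
  mean_background_depth), inflated by 1/(1 - duplication_rate);
* per-site methylated calls ~ Binomial(depth, q) with
  q = p * (1 - overconversion) + (1 - p) * conversion_error,
  where p is the site's true methylation probability;
* CpG true_p is Beta-distributed by regime (low in promoter targets, high in
  background); non-CpG cytosines have p = 0; control chromosomes are forced
  to 0 (unmethylated control) or 1 at CpGs (methylated control).

Everything is bit-reproducible for a fixed seed. No read-level simulation:
coverage is generated directly at the call level so suites run in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .conversion import derive_seed
from .errors import ConfigurationError, PackingError
from .io_formats import (
    CpGRecord,
    CytosineContextRecord,
    SequenceRecord,
    TargetRegion,
    percent_methylation,
)

REGIME_PROMOTER = "promoter_low"
REGIME_BACKGROUND = "background_high"
REGIME_CONTROL_UNMETH = "control_unmethylated"
REGIME_CONTROL_METH = "control_methylated"
REGIME_NON_CPG = "non_cpg"


@dataclass
class MethylationProfile:
    """True methylation probabilities for every plus-strand cytosine."""

    sites: list[tuple[str, int]]  # (chrom, 1-based pos)
    true_p: np.ndarray
    regimes: list[str]
    contexts: list[str]  # CpG / CHG / CHH per site
    trinucleotides: list[str]
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.sites)
        if not (len(self.true_p) == len(self.regimes) == len(self.contexts)
                == len(self.trinucleotides) == n):
            raise ConfigurationError("profile field lengths disagree")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    mean_target_depth: float = 150.0
    mean_background_depth: float = 2.0
    conversion_error: float = 0.012
    overconversion: float = 0.023
    duplication_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.mean_target_depth <= 0 or self.mean_background_depth <= 0:
            raise ConfigurationError("mean depths must be > 0")
        for name in ("conversion_error", "overconversion", "duplication_rate"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ConfigurationError(f"{name} must be in [0, 1)")


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def make_genome(
    seed: int,
    chrom_lengths: Mapping[str, int],
    mask_fraction: float = 0.0,
    mask_run_length: int = 200,
) -> list[SequenceRecord]:
    """Uniform-random ACGT chromosomes, with optional soft-masked runs.

    Masked runs of ~``mask_run_length`` bases are lowered until at least
    ``mask_fraction`` of each chromosome is lowercase.
    """
    records: list[SequenceRecord] = []
    for chrom, length in chrom_lengths.items():
        if length < 1:
            raise ConfigurationError(f"chromosome {chrom!r} length must be >= 1")
        rng = np.random.default_rng(derive_seed(seed, "genome", chrom))
        codes = _BASES[rng.integers(0, 4, size=length)]
        seq = codes.tobytes().decode("ascii")
        if mask_fraction > 0:
            masked = np.zeros(length, dtype=bool)
            target = int(mask_fraction * length)
            guard = 0
            while masked.sum() < target and guard < 10 * length:
                start = int(rng.integers(0, length))
                run = min(mask_run_length, length - start)
                masked[start : start + run] = True
                guard += 1
            chars = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
            chars[masked] += 32  # ASCII lowercase
            seq = chars.tobytes().decode("ascii")
        records.append(SequenceRecord(chrom, seq))
    return records


def make_promoter_targets(
    genome: Sequence[SequenceRecord],
    n: int,
    length: int = 4000,
    seed: int = 0,
) -> list[TargetRegion]:
    """n non-overlapping random regions of fixed length, seeded."""
    capacity = sum(rec.length // length for rec in genome)
    if capacity < n:
        raise PackingError(
            f"cannot place {n} non-overlapping {length} bp regions "
            f"(capacity {capacity})"
        )
    rng = np.random.default_rng(derive_seed(seed, "targets"))
    eligible = [rec for rec in genome if rec.length >= length]
    weights = np.asarray([rec.length - length + 1 for rec in eligible], dtype=float)
    weights /= weights.sum()
    placed: dict[str, list[tuple[int, int]]] = {}
    regions: list[TargetRegion] = []
    attempts = 0
    max_attempts = 1000 * n + 1000
    while len(regions) < n:
        attempts += 1
        if attempts > max_attempts:
            raise PackingError(
                f"failed to place {n} non-overlapping regions after {attempts} attempts"
            )
        rec = eligible[int(rng.choice(len(eligible), p=weights))]
        start = int(rng.integers(0, rec.length - length + 1))
        end = start + length
        if any(s < end and start < e for s, e in placed.get(rec.id, [])):
            continue
        placed.setdefault(rec.id, []).append((start, end))
        regions.append(TargetRegion(rec.id, start, end, f"prom_{len(regions):03d}", "+"))
    return regions


def _target_mask(length: int, chrom: str, targets: Sequence[TargetRegion]) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for t in targets:
        if t.chrom == chrom:
            mask[t.start : min(t.end, length)] = True
    return mask


def make_methylation_profile(
    genome: Sequence[SequenceRecord],
    targets: Sequence[TargetRegion],
    seed: int = 0,
    promoter_beta: tuple[float, float] = (1.0, 9.0),
    background_beta: tuple[float, float] = (7.0, 3.0),
    control_chroms: Mapping[str, str] | None = None,
) -> MethylationProfile:
    """Assign a true methylation probability to every plus-strand cytosine.

    CpG sites draw from Beta(promoter_beta) inside targets and
    Beta(background_beta) elsewhere. ``control_chroms`` maps chromosome id to
    'unmethylated' (all p = 0) or 'methylated' (CpG p = 1).
    """
    control_chroms = dict(control_chroms or {})
    for chrom, kind in control_chroms.items():
        if kind not in ("unmethylated", "methylated"):
            raise ConfigurationError(f"control chrom {chrom!r}: unknown kind {kind!r}")
    sites: list[tuple[str, int]] = []
    true_p: list[float] = []
    regimes: list[str] = []
    contexts: list[str] = []
    trinucs: list[str] = []
    chrom_lengths: dict[str, int] = {}
    for rec in genome:
        chrom_lengths[rec.id] = rec.length
        rng = np.random.default_rng(derive_seed(seed, "profile", rec.id))
        seq = rec.sequence.upper()
        length = rec.length
        in_target = _target_mask(length, rec.id, targets)
        control = control_chroms.get(rec.id)
        for i, base in enumerate(seq):
            if base != "C":
                continue
            nxt = seq[i + 1] if i + 1 < length else "N"
            nxt2 = seq[i + 2] if i + 2 < length else "N"
            if nxt == "G":
                context = "CpG"
            elif nxt2 == "G":
                context = "CHG"
            else:
                context = "CHH"
            tri = (seq[i : i + 3] + "NN")[:3]
            if context == "CpG":
                if control == "unmethylated":
                    p, regime = 0.0, REGIME_CONTROL_UNMETH
                elif control == "methylated":
                    p, regime = 1.0, REGIME_CONTROL_METH
                elif in_target[i]:
                    p, regime = float(rng.beta(*promoter_beta)), REGIME_PROMOTER
                else:
                    p, regime = float(rng.beta(*background_beta)), REGIME_BACKGROUND
            else:
                p = 0.0
                regime = REGIME_CONTROL_UNMETH if control == "unmethylated" else REGIME_NON_CPG
            sites.append((rec.id, i + 1))
            true_p.append(p)
            regimes.append(regime)
            contexts.append(context)
            trinucs.append(tri)
    return MethylationProfile(
        sites=sites,
        true_p=np.asarray(true_p, dtype=float),
        regimes=regimes,
        contexts=contexts,
        trinucleotides=trinucs,
        chrom_lengths=chrom_lengths,
    )


def simulate_coverage(
    profile: MethylationProfile,
    config: SimulationConfig,
    targets: Sequence[TargetRegion],
) -> tuple[list[CpGRecord], list[CytosineContextRecord], dict[tuple[str, int], int]]:
    """Draw one library's coverage and methylation calls from a profile.

    Returns (CpG coverage records, per-cytosine context records, per-base
    depth track). Records are emitted only where depth > 0.
    """
    rng = np.random.default_rng(derive_seed(config.seed, "coverage"))
    inflate = 1.0 / (1.0 - config.duplication_rate)
    depth_arrays: dict[str, np.ndarray] = {}
    depth_track: dict[tuple[str, int], int] = {}
    for chrom, length in profile.chrom_lengths.items():
        lam = np.where(
            _target_mask(length, chrom, targets),
            config.mean_target_depth * inflate,
            config.mean_background_depth * inflate,
        )
        depths = rng.poisson(lam)
        depth_arrays[chrom] = depths
        nz = np.flatnonzero(depths)
        for i in nz:
            depth_track[(chrom, int(i) + 1)] = int(depths[i])

    n = len(profile.sites)
    site_depth = np.empty(n, dtype=np.int64)
    for idx, (chrom, pos) in enumerate(profile.sites):
        site_depth[idx] = depth_arrays[chrom][pos - 1]
    q = (
        profile.true_p * (1.0 - config.overconversion)
        + (1.0 - profile.true_p) * config.conversion_error
    )
    count_m = rng.binomial(site_depth, q)
    count_u = site_depth - count_m

    cov_records: list[CpGRecord] = []
    context_records: list[CytosineContextRecord] = []
    for idx in range(n):
        depth = int(site_depth[idx])
        if depth == 0:
            continue
        chrom, pos = profile.sites[idx]
        m = int(count_m[idx])
        u = int(count_u[idx])
        context = profile.contexts[idx]
        if context == "CpG":
            cov_records.append(
                CpGRecord(chrom, pos, percent_methylation(m, u), m, u)
            )
        context_records.append(
            CytosineContextRecord(
                chrom, pos, "+", m, u, context, profile.trinucleotides[idx]
            )
        )
    return cov_records, context_records, depth_track


def simulate_duplicate_library(
    profile: MethylationProfile,
    config: SimulationConfig,
    targets: Sequence[TargetRegion],
    seed2: int,
) -> tuple[list[CpGRecord], list[CytosineContextRecord], dict[tuple[str, int], int]]:
    """Independent redraw from the same profile — a technical replicate."""
    return simulate_coverage(profile, replace(config, seed=seed2), targets)
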