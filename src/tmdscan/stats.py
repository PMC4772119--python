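"""Comparative statistics of TMD length distributions and aligned profiles.

Groups of single-span TMDs (e.g. proteins of one organelle, or viruses
sharing an entry pathway) are summarized as integer length histograms and
compared with:

* Welch's two-tailed heteroscedastic t-test on the lengths,
* the Kullback-Leibler divergence measure (KLDM) between the two length
  distributions, computed on the support where both histograms are
  nonzero (renormalized after trimming), in both directions, plus the
  symmetric average of the two,
* the RMS difference between each protein's TMD length and the mean
  plasma-membrane TMD length of its species.

Aligned per-position mean hydropathy and residue-abundance profiles are
computed with every helix anchored at its cytosolic end (position 1).
"""

from __future__ import annotations

import dataclasses
import math
from collections import Counter
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .detection import TmdRecord
from .hydropathy import HydropathyScale, windowed_profile
from .seqio import AMINO_ACIDS


# ---------------------------------------------------------------------------
# Length distributions and summaries

@dataclasses.dataclass
class GroupSummary:
    n: int
    mean: float
    sd: float | None  # sample (n-1) standard deviation; None when n == 1
    mode: int

    def rounded(self, ndigits: int = 2) -> tuple[float, float | None]:
        return (
            round(self.mean, ndigits),
            None if self.sd is None else round(self.sd, ndigits),
        )


@dataclasses.dataclass
class LengthDistribution:
    """Integer histogram of TMD lengths."""

    counts: dict[int, int]
    n: int
    mean: float
    sd: float | None
    mode: int

    def probabilities(self) -> dict[int, float]:
        return {k: v / self.n for k, v in sorted(self.counts.items())}


def _check_lengths(lengths: Sequence) -> list[int]:
    lengths = list(lengths)
    if not lengths:
        raise ValueError("empty length sample")
    out = []
    for v in lengths:
        if float(v) != int(v):
            raise ValueError(f"TMD lengths must be integers, got {v!r}")
        if int(v) < 1:
            raise ValueError(f"TMD lengths must be >= 1, got {v!r}")
        out.append(int(v))
    return out


def group_summary(lengths: Iterable[int]) -> GroupSummary:
    """Mean, sample SD, n and mode of a group's TMD lengths."""
    vals = _check_lengths(lengths)
    n = len(vals)
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if n > 1 else None
    counts = Counter(vals)
    top = max(counts.values())
    mode = min(k for k, v in counts.items() if v == top)
    return GroupSummary(n=n, mean=mean, sd=sd, mode=mode)


def length_distribution(lengths: Iterable[int]) -> LengthDistribution:
    vals = _check_lengths(lengths)
    summary = group_summary(vals)
    return LengthDistribution(
        counts=dict(sorted(Counter(vals).items())),
        n=summary.n,
        mean=summary.mean,
        sd=summary.sd,
        mode=summary.mode,
    )


# ---------------------------------------------------------------------------
# Welch's t-test

@dataclasses.dataclass
class WelchResult:
    t_stat: float
    p_value: float
    df: float
    flag: str = ""


def welch_ttest(x: Sequence[float], y: Sequence[float]) -> WelchResult:
    """Two-tailed heteroscedastic (Welch) t-test on two length samples."""
    x, y = list(x), list(y)
    if len(x) < 2 or len(y) < 2:
        raise ValueError(
            f"welch_ttest needs >= 2 observations per sample, got {len(x)} and {len(y)}"
        )
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    if vx == 0.0 and vy == 0.0:
        if np.mean(x) == np.mean(y):
            return WelchResult(0.0, 1.0, float("nan"), flag="zero_variance_equal_means")
        return WelchResult(
            math.copysign(float("inf"), float(np.mean(x) - np.mean(y))),
            0.0,
            float("nan"),
            flag="zero_variance_distinct_means",
        )
    res = sps.ttest_ind(x, y, equal_var=False)
    return WelchResult(float(res.statistic), float(res.pvalue), float(res.df))


# ---------------------------------------------------------------------------
# Kullback-Leibler divergence measure (KLDM)

def _as_counts(dist) -> dict[int, float]:
    if isinstance(dist, LengthDistribution):
        return dict(dist.counts)
    if isinstance(dist, Mapping):
        return dict(dist)
    return dict(Counter(_check_lengths(dist)))


def trim_zero_support(p1, p2) -> tuple[dict[int, float], dict[int, float], list[int]]:
    """Restrict two histograms to their common support and renormalize.

    KLDM involves log(p1/p2), so any length absent from either sample must
    be dropped before the divergence is computed. After trimming, each
    vector is renormalized to sum to 1.
    """
    c1, c2 = _as_counts(p1), _as_counts(p2)
    support = sorted(k for k in c1 if c1.get(k, 0) > 0 and c2.get(k, 0) > 0)
    if not support:
        raise ValueError(
            "non-overlapping distributions: no length has nonzero probability in both"
        )
    t1 = np.array([c1[k] for k in support], dtype=float)
    t2 = np.array([c2[k] for k in support], dtype=float)
    t1 /= t1.sum()
    t2 /= t2.sum()
    return (
        dict(zip(support, t1)),
        dict(zip(support, t2)),
        support,
    )


def kldm(p1, p2, log_base: float = math.e) -> float:
    """Directed KL divergence of p1 from p2 on the trimmed common support.

    KLDM(P1 || P2) = sum over the trimmed support of p1 * log(p1 / p2);
    natural log by default. Asymmetric in its arguments.
    """
    t1, t2, support = trim_zero_support(p1, p2)
    a1 = np.array([t1[k] for k in support])
    a2 = np.array([t2[k] for k in support])
    value = float(np.sum(a1 * np.log(a1 / a2)))
    if log_base != math.e:
        value /= math.log(log_base)
    # clamp the tiny negative round-off that can arise when P1 == P2
    return 0.0 if abs(value) < 1e-15 else value


def kldm_symmetric(p1, p2, log_base: float = math.e) -> float:
    """Average of the two directed KLDM values."""
    return 0.5 * (kldm(p1, p2, log_base) + kldm(p2, p1, log_base))


@dataclasses.dataclass
class GroupComparison:
    group_x: str
    group_y: str
    n_x: int
    n_y: int
    mean_x: float
    mean_y: float
    sd_x: float | None
    sd_y: float | None
    mode_x: int
    mode_y: int
    t_stat: float
    p_value: float
    kldm_xy: float
    kldm_yx: float
    kldm_sym: float
    trimmed_support: list[int]
    flag: str = ""

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def compare_groups(
    lengths_x: Sequence[int],
    lengths_y: Sequence[int],
    name_x: str = "X",
    name_y: str = "Y",
    log_base: float = math.e,
) -> GroupComparison:
    """Full two-group comparison: summaries, Welch t-test and KLDM.

    When the two length histograms share no support, KLDM is undefined;
    the comparison is then reported with NaN divergences and the
    ``non_overlapping_distributions`` flag instead of raising.
    """
    sx, sy = group_summary(lengths_x), group_summary(lengths_y)
    welch = welch_ttest(lengths_x, lengths_y)
    flag = welch.flag
    try:
        d_xy = kldm(lengths_x, lengths_y, log_base)
        d_yx = kldm(lengths_y, lengths_x, log_base)
        _, _, support = trim_zero_support(lengths_x, lengths_y)
    except ValueError:
        d_xy = d_yx = float("nan")
        support = []
        flag = (flag + ";" if flag else "") + "non_overlapping_distributions"
    return GroupComparison(
        group_x=name_x,
        group_y=name_y,
        n_x=sx.n,
        n_y=sy.n,
        mean_x=sx.mean,
        mean_y=sy.mean,
        sd_x=sx.sd,
        sd_y=sy.sd,
        mode_x=sx.mode,
        mode_y=sy.mode,
        t_stat=welch.t_stat,
        p_value=welch.p_value,
        kldm_xy=d_xy,
        kldm_yx=d_yx,
        kldm_sym=0.5 * (d_xy + d_yx),
        trimmed_support=support,
        flag=flag,
    )


# ---------------------------------------------------------------------------
# Aligned profiles (position 1 = cytosolic end of the refined span)

@dataclasses.dataclass
class MeanProfile:
    positions: np.ndarray
    scores: np.ndarray
    coverage: np.ndarray
    window: int


def _covered_records(records: Sequence[TmdRecord]) -> list[TmdRecord]:
    usable = [r for r in records if r.has_tmd and r.oriented_sequence]
    if not usable:
        raise ValueError("no oriented TMD records to profile")
    return usable


def mean_hydropathy_profile(
    records: Sequence[TmdRecord],
    scale: HydropathyScale,
    window: int = 1,
    extent: int | None = None,
) -> MeanProfile:
    """Per-position mean windowed hydropathy across aligned helices.

    Every record contributes its windowed profile starting at position 1
    (its cytosolic span end); the mean at a position is taken over the
    records whose profile covers it, with per-position coverage counts
    reported. With ``extent`` set, each record's profile continues past
    the refined span into the exoplasmic side of its full sequence, which
    is what makes the 0-crossing of the mean profile reflect the modal
    TMD length.
    """
    usable = _covered_records(records)
    sums: dict[int, float] = {}
    cover: dict[int, int] = {}
    for rec in usable:
        seq = rec.oriented_residues(extent) if extent else rec.oriented_sequence
        if len(seq) < window:
            continue
        prof = windowed_profile(seq, scale, window)
        for pos, val in zip(prof.positions, prof.scores):
            sums[pos] = sums.get(pos, 0.0) + float(val)
            cover[pos] = cover.get(pos, 0) + 1
    if not sums:
        raise ValueError(f"no record is at least as long as the window ({window})")
    positions = np.array(sorted(sums), dtype=int)
    scores = np.array([sums[p] / cover[p] for p in positions])
    coverage = np.array([cover[p] for p in positions], dtype=int)
    return MeanProfile(positions=positions, scores=scores, coverage=coverage, window=window)


def profile_mode_length(profile: MeanProfile, threshold: float = 0.0) -> int:
    """TMD length read off the mean profile: the number of consecutive
    positions, starting at position 1, with mean score above threshold.

    On sets dominated by one length this equals the distribution mode
    rather than the mean."""
    count = 0
    expected = 1
    for pos, val in zip(profile.positions, profile.scores):
        if pos != expected:
            break
        if val > threshold:
            count += 1
            expected += 1
        else:
            break
    return count


def abundance_profile(
    records: Sequence[TmdRecord],
    scale: HydropathyScale | None = None,
    extent: int | None = None,
):
    """Per-position residue frequencies across aligned helices.

    Returns a DataFrame indexed by aligned position with one column per
    residue (frequencies over the records covering that position, summing
    to 1), a ``hydrophobic`` class column (sum of the hydrophobic-residue
    frequencies, if a scale is given) and a ``coverage`` count.
    """
    import pandas as pd

    usable = _covered_records(records)
    residues = list(AMINO_ACIDS + "X")
    counts: dict[int, Counter] = {}
    for rec in usable:
        seq = rec.oriented_residues(extent) if extent else rec.oriented_sequence
        for i, res in enumerate(seq, start=1):
            counts.setdefault(i, Counter())[res] += 1
    positions = sorted(counts)
    rows = []
    for pos in positions:
        total = sum(counts[pos].values())
        freqs = {r: counts[pos].get(r, 0) / total for r in residues}
        row = dict(freqs)
        if scale is not None:
            row["hydrophobic"] = sum(
                f for r, f in freqs.items() if scale.is_hydrophobic(r)
            )
        row["coverage"] = total
        rows.append(row)
    df = pd.DataFrame(rows, index=pd.Index(positions, name="position"))
    return df


# ---------------------------------------------------------------------------
# RMS difference from plasma-membrane lengths

def rms_pm_difference(
    organelle: Sequence[tuple[str, int]],
    pm: Sequence[tuple[str, int]],
    normalize: bool = True,
) -> float:
    """Deviation of organelle TMD lengths from species PM means.

    ``organelle`` and ``pm`` are (species, length) pairs. For each
    organelle protein the difference from the mean plasma-membrane TMD
    length of its species is squared; with ``normalize`` (default) the
    root of the *mean* squared difference is returned (RMS), otherwise
    the root of the plain sum.
    """
    if not organelle:
        raise ValueError("empty organelle record set")
    pm_by_species: dict[str, list[int]] = {}
    for species, length in pm:
        pm_by_species.setdefault(species, []).append(length)
    missing = sorted({s for s, _ in organelle} - set(pm_by_species))
    if missing:
        raise ValueError(f"species without PM records: {missing}")
    pm_mean = {s: float(np.mean(v)) for s, v in pm_by_species.items()}
    sq = [(length - pm_mean[species]) ** 2 for species, length in organelle]
    total = float(np.sum(sq))
    if normalize:
        total /= len(sq)
    return math.sqrt(total)
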