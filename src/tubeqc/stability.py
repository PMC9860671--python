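"""Water-loss and draw-volume stability testing.

Water evaporating through a tube's stopper shows up as a drift in tube
mass over repeated weighings. With weighing date as the controlled
factor, a one-way ANOVA on the group summaries (count, sum, mean,
within-group variance) decides whether time is significant; when it is,
Fisher's least significant difference

    LSD = t_{1-alpha/2, h(n-1)} * s * sqrt(2/n)

with ``s = sqrt(MS_within)`` the pooled within-group standard
deviation, ``h`` groups and ``n`` weighings per group, separates the
date means: two dates differ significantly iff |mean_i - mean_j| > LSD.
The pairwise rule is rendered as a compact-letter display. LSD is
defined for balanced designs only; the ANOVA itself accepts unbalanced
groups.

Draw volumes are checked against the producer's nominal value with a
symmetric percentage band (10 % by default), boundary inclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .exceptions import DegenerateComputationError, InvalidInputError

__all__ = [
    "GroupSummary",
    "AnovaResult",
    "DrawVolumeResult",
    "summarize",
    "anova_from_summaries",
    "lsd",
    "lsd_grouping",
    "draw_volume_check",
]


@dataclass(frozen=True)
class GroupSummary:
    """Per-date weighing summary: count, sum (g), mean (g) and unbiased
    within-group variance (g^2)."""

    group_id: str
    count: int
    sum: float
    mean: float
    variance: float

    def __post_init__(self) -> None:
        if self.count < 2:
            raise InvalidInputError(
                f"group {self.group_id!r}: need >= 2 observations, got {self.count}"
            )
        if self.variance < 0:
            raise InvalidInputError(
                f"group {self.group_id!r}: variance must be >= 0"
            )
        if abs(self.sum - self.count * self.mean) > 1e-9 * max(1.0, abs(self.sum)):
            raise InvalidInputError(
                f"group {self.group_id!r}: sum and count*mean disagree"
            )


def summarize(group_id: str, values: Sequence[float]) -> GroupSummary:
    """Aggregate raw observations into a :class:`GroupSummary`."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InvalidInputError(f"group {group_id!r}: need >= 2 observations")
    return GroupSummary(
        group_id=group_id,
        count=int(v.size),
        sum=float(v.sum()),
        mean=float(v.mean()),
        variance=float(v.var(ddof=1)),
    )


@dataclass(frozen=True)
class AnovaResult:
    """One-way ANOVA outcome plus the LSD-based pairwise separation.

    ``lsd`` is None for unbalanced designs. ``significant_pairs`` is
    empty unless the omnibus F test is itself significant at ``alpha``
    (unprotected LSD applied only after a significant F).
    ``letters`` maps each group id to its compact-letter label; groups
    sharing a letter do not differ significantly. ``degenerate`` flags
    the no-variation case (all residual variance zero).
    """

    f_statistic: float
    df_between: int
    df_within: int
    ms_between: float
    ms_within: float
    p_value: float
    f_critical: float
    alpha: float
    lsd: float | None
    significant_pairs: frozenset[tuple[str, str]]
    letters: Mapping[str, str]
    group_means: Mapping[str, float]
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return self.p_value <= self.alpha


def anova_from_summaries(
    groups: Sequence[GroupSummary], alpha: float = 0.05
) -> AnovaResult:
    """One-way ANOVA computed from group summaries.

    Algebraically identical to the raw-data ANOVA of the observations
    the summaries aggregate: SS_between = sum n_i (mean_i - grand)^2,
    SS_within = sum (n_i - 1) var_i.
    """
    if len(groups) < 2:
        raise InvalidInputError("ANOVA needs at least 2 groups")
    if not 0 < alpha < 1:
        raise InvalidInputError(f"alpha must be in (0, 1), got {alpha}")
    ids = [g.group_id for g in groups]
    if len(set(ids)) != len(ids):
        raise InvalidInputError("duplicate group ids")

    counts = np.array([g.count for g in groups], dtype=float)
    means = np.array([g.mean for g in groups], dtype=float)
    variances = np.array([g.variance for g in groups], dtype=float)

    n_total = float(counts.sum())
    grand_mean = float(np.dot(counts, means) / n_total)
    ss_between = float(np.dot(counts, (means - grand_mean) ** 2))
    ss_within = float(np.dot(counts - 1, variances))
    df_between = len(groups) - 1
    df_within = int(n_total) - len(groups)
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within

    degenerate = ms_within == 0.0
    if degenerate:
        f_stat = 0.0 if ms_between == 0.0 else math.inf
        p_value = 1.0 if ms_between == 0.0 else 0.0
    else:
        f_stat = ms_between / ms_within
        p_value = float(stats.f.sf(f_stat, df_between, df_within))
    f_critical = float(stats.f.ppf(1 - alpha, df_between, df_within))

    balanced = np.all(counts == counts[0])
    lsd_value: float | None = None
    if balanced and not degenerate:
        lsd_value = lsd(ms_within, len(groups), int(counts[0]), alpha)

    pairs: set[tuple[str, str]] = set()
    letters: Mapping[str, str]
    if lsd_value is not None and p_value <= alpha:
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                if abs(means[i] - means[j]) > lsd_value:
                    pairs.add((ids[i], ids[j]))
        letters = lsd_grouping(dict(zip(ids, means)), lsd_value)
    else:
        # no post-hoc separation: all groups share one label
        letters = {gid: "a" for gid in ids}

    return AnovaResult(
        f_statistic=f_stat,
        df_between=df_between,
        df_within=df_within,
        ms_between=ms_between,
        ms_within=ms_within,
        p_value=p_value,
        f_critical=f_critical,
        alpha=alpha,
        lsd=lsd_value,
        significant_pairs=frozenset(pairs),
        letters=letters,
        group_means=dict(zip(ids, (float(m) for m in means))),
        degenerate=degenerate,
    )


def lsd(ms_within: float, h: int, n: int, alpha: float = 0.05) -> float:
    """Fisher's least significant difference for a balanced design.

    Two-sided Student t quantile at ``1 - alpha/2`` with ``h*(n-1)``
    degrees of freedom, times the pooled within-group standard
    deviation, times ``sqrt(2/n)``.
    """
    if ms_within < 0:
        raise InvalidInputError("ms_within must be >= 0")
    if h < 2 or n < 2:
        raise InvalidInputError("need h >= 2 groups and n >= 2 per group")
    if not 0 < alpha < 1:
        raise InvalidInputError(f"alpha must be in (0, 1), got {alpha}")
    t_crit = float(stats.t.ppf(1 - alpha / 2, h * (n - 1)))
    return t_crit * math.sqrt(ms_within) * math.sqrt(2.0 / n)


def lsd_grouping(means: Mapping[str, float], lsd_value: float) -> dict[str, str]:
    """Compact-letter display of the LSD pairwise rule.

    Groups whose means differ by at most ``lsd_value`` can share a
    letter. Letters label the maximal runs of the means sorted in
    descending order; a group belonging to several overlapping runs
    carries all their letters.
    """
    if lsd_value <= 0:
        raise InvalidInputError("lsd_value must be > 0")
    ids = list(means)
    order = sorted(range(len(ids)), key=lambda i: -means[ids[i]])
    sorted_means = [means[ids[i]] for i in order]

    # maximal windows [i, j] with spread <= LSD over the sorted means;
    # j(i) is nondecreasing, so a window is new iff it extends past the
    # previous one's right edge
    windows: list[tuple[int, int]] = []
    for i in range(len(order)):
        j = i
        while j + 1 < len(order) and sorted_means[i] - sorted_means[j + 1] <= lsd_value:
            j += 1
        if not windows or j > windows[-1][1]:
            windows.append((i, j))

    labels: dict[str, list[str]] = {gid: [] for gid in ids}
    for letter_idx, (lo, hi) in enumerate(windows):
        letter = chr(ord("a") + letter_idx % 26) * (1 + letter_idx // 26)
        for k in range(lo, hi + 1):
            labels[ids[order[k]]].append(letter)
    return {gid: "".join(lets) for gid, lets in labels.items()}


@dataclass(frozen=True)
class DrawVolumeResult:
    """Outcome of checking measured draw volumes against the band
    ``nominal * (1 -/+ tolerance)``, boundary inclusive."""

    nominal: float
    tolerance_pct: float
    lower: float
    upper: float
    within: tuple[bool, ...]

    @property
    def n_within(self) -> int:
        return sum(self.within)

    @property
    def fraction_within(self) -> float:
        return self.n_within / len(self.within) if self.within else math.nan

    @property
    def all_within(self) -> bool:
        return all(self.within)


def draw_volume_check(
    measured: Sequence[float], nominal: float, tolerance_pct: float = 10.0
) -> DrawVolumeResult:
    """Flag each measured draw volume as inside/outside the tolerance band."""
    if nominal <= 0:
        raise InvalidInputError(f"nominal draw volume must be > 0, got {nominal}")
    if tolerance_pct <= 0:
        raise InvalidInputError("tolerance must be > 0")
    vols = np.asarray(measured, dtype=float)
    if vols.size and (np.any(vols <= 0) or not np.all(np.isfinite(vols))):
        raise InvalidInputError("measured draw volumes must be finite and > 0")
    tol = tolerance_pct / 100.0
    lower = nominal * (1 - tol)
    upper = nominal * (1 + tol)
    flags = tuple(bool(lower <= v <= upper) for v in vols)
    return DrawVolumeResult(
        nominal=nominal,
        tolerance_pct=tolerance_pct,
        lower=lower,
        upper=upper,
        within=flags,
    )
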