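"""Control normalization, fold changes and rank-sum group comparison.

Each blastema's mean domain intensity is normalized to the average of the
vehicle (DMSO) controls of the same domain, channel and — when samples were
stained in batches — the same staining round, which absorbs between-round
staining-efficiency differences. Group differences are then tested with the
two-sided Wilcoxon rank-sum (Mann-Whitney) test: exact null distribution
for small samples without ties, normal approximation with tie and
continuity corrections otherwise. No multiple-testing correction is
applied.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


class ParameterError(ValueError):
    pass


class NormalizationError(ValueError):
    """A stratum lacks control samples."""


#: combined sample size at or below which the exact null is used (no ties)
EXACT_N_MAX = 20

#: significance-star thresholds, checked in order
STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    """Map a p value to the conventional star annotation."""
    for cut, stars in STAR_LEVELS:
        if p < cut:
            return stars
    return "ns"


@dataclass
class GroupComparison:
    """Result of one treated-vs-control comparison in one domain/channel."""

    domain: str
    channel: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    statistic_W: float
    p_two_sided: float
    fold_change: float
    stars: str

    def as_row(self) -> dict:
        return asdict(self)


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float]
                      ) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns ``(W, p)`` where W is the rank-sum of group ``a`` (mid-ranks
    for ties). The exact permutation null is used when ``len(a)+len(b) <=
    20`` and the pooled data has no ties; otherwise the normal
    approximation with tie and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    w = float(ranks[: a.size].sum())
    has_ties = np.unique(pooled).size < pooled.size
    if np.ptp(pooled) == 0:
        return w, 1.0  # all observations identical: no evidence either way
    method = "exact" if (pooled.size <= EXACT_N_MAX and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    p = float(min(res.pvalue, 1.0))
    return w, p


def normalize_to_control(
    table: pd.DataFrame,
    control_group: str = "DMSO",
    by_round: bool = True,
) -> pd.DataFrame:
    """Divide every data point by its stratum's control-group mean.

    Strata are (domain, channel) pairs, additionally split by staining
    round when ``by_round`` is set. Control samples are normalized too, so
    each stratum's controls average to 1. A stratum without any control
    sample raises :class:`NormalizationError` naming the stratum.
    """
    keys = ["domain", "channel"] + (["staining_round"] if by_round else [])
    out = table.copy()
    ctrl = out[out["group"] == control_group]
    ctrl_means = ctrl.groupby(keys)["mean_intensity"].mean()
    strata = out.groupby(keys).groups
    missing = [k for k in strata if k not in ctrl_means.index]
    if missing:
        raise NormalizationError(
            f"strata without {control_group!r} controls: {missing}"
        )
    denom = out.set_index(keys).index.map(ctrl_means)
    out["normalized_value"] = out["mean_intensity"].to_numpy() / denom.to_numpy()
    return out


def fold_change(
    table: pd.DataFrame,
    domain: str,
    channel: str,
    group_a: str,
    group_b: str,
) -> float:
    """Ratio of the two groups' mean normalized values in one stratum."""
    if "normalized_value" not in table.columns:
        raise ParameterError("table must be normalized first")
    sub = table[(table["domain"] == domain) & (table["channel"] == channel)]
    means = {}
    for g in (group_a, group_b):
        vals = sub.loc[sub["group"] == g, "normalized_value"]
        if vals.empty:
            raise ParameterError(
                f"group {g!r} absent from stratum ({domain}, {channel})"
            )
        means[g] = float(vals.mean())
    return means[group_a] / means[group_b]


def compare_groups(
    table: pd.DataFrame,
    design: Sequence[tuple[str, str, str, str]],
) -> list[GroupComparison]:
    """Run one rank-sum comparison per (domain, channel, group_a, group_b)."""
    out = []
    for domain, channel, group_a, group_b in design:
        sub = table[(table["domain"] == domain) & (table["channel"] == channel)]
        a = sub.loc[sub["group"] == group_a, "normalized_value"].to_numpy()
        b = sub.loc[sub["group"] == group_b, "normalized_value"].to_numpy()
        if a.size == 0 or b.size == 0:
            raise ParameterError(
                f"missing group in stratum ({domain}, {channel}): "
                f"{group_a}={a.size}, {group_b}={b.size}"
            )
        w, p = wilcoxon_rank_sum(a, b)
        fc = float(a.mean() / b.mean())
        out.append(GroupComparison(
            domain=domain, channel=channel, group_a=group_a, group_b=group_b,
            n_a=int(a.size), n_b=int(b.size), statistic_W=w, p_two_sided=p,
            fold_change=fc, stars=significance_stars(p),
        ))
    return out


def comparisons_to_table(comparisons: list[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame([c.as_row() for c in comparisons])
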