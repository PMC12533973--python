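"""Distribution analytics and statistics for embolus transport campaigns.

Turns per-experiment trajectory tallies into the study's summary quantities:
per-outlet number fractions, left/right hemispheric splits of the six
cerebral outlets, the contralateral fraction (share of brain-bound emboli
landing opposite the release carotid), the left/right common-carotid
recruitment split for cardiogenic emboli, and descriptive statistics, plus
the non-parametric tests used to compare them (one-sample Wilcoxon
signed-rank, Mann-Whitney U, Shapiro-Wilk normality).

Convention: the contralateral denominator is the number of emboli reaching
the six cerebral outlets, not the number released (switchable via the
``denominator`` argument).
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .runner import DistributionRecord
from .transport import TrajectoryRecord
from .vasculature import CEREBRAL_OUTLETS

__all__ = [
    "DistributionRecord",
    "outlet_distribution",
    "hemisphere_split",
    "contralateral_fraction",
    "cca_recruitment_split",
    "descriptive_stats",
    "stats_tests",
    "summary_table",
    "plot_contralateral_fractions",
]


def outlet_distribution(record: DistributionRecord) -> Dict[str, float]:
    """Number fraction of released emboli per outlet; unresolved separate."""
    if record.n_released <= 0:
        raise ValueError("record has no released emboli")
    return record.fractions()


def _cerebral_counts(record: DistributionRecord,
                     hemisphere_map: Dict[str, str]) -> Tuple[int, int]:
    left = sum(
        c for o, c in record.outlet_counts.items()
        if hemisphere_map.get(o) == "left"
    )
    right = sum(
        c for o, c in record.outlet_counts.items()
        if hemisphere_map.get(o) == "right"
    )
    return left, right


def hemisphere_split(record: DistributionRecord,
                     hemisphere_map: Dict[str, str]) -> Tuple[float, float]:
    """Left/right percentages of cerebral-destined emboli (sum to 100)."""
    left, right = _cerebral_counts(record, hemisphere_map)
    total = left + right
    if total == 0:
        raise ValueError(
            f"{record.experiment}: no cerebral emboli; hemisphere split undefined"
        )
    return 100.0 * left / total, 100.0 * right / total


def contralateral_fraction(record: DistributionRecord, release_side: str,
                           hemisphere_map: Dict[str, str],
                           denominator: str = "cerebral") -> float:
    """Share of brain-bound emboli crossing opposite the release carotid."""
    if release_side not in ("left", "right"):
        raise ValueError(
            "contralateral fraction undefined for cardiogenic releases"
        )
    left, right = _cerebral_counts(record, hemisphere_map)
    crossed = right if release_side == "left" else left
    if denominator == "cerebral":
        denom = left + right
    elif denominator == "released":
        denom = record.n_released
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom == 0:
        raise ValueError(f"{record.experiment}: zero cerebral emboli")
    return crossed / denom


def cca_recruitment_split(
    trajectories: Optional[Iterable[TrajectoryRecord]] = None,
    record: Optional[DistributionRecord] = None,
) -> Dict[str, float]:
    """Left/right common-carotid recruitment of cardiogenic emboli (percent).

    Accepts either raw trajectories (counting paths entering each common
    carotid segment) or a :class:`DistributionRecord` carrying pre-tallied
    ``cca_entries``.  Emboli entering neither are excluded from the split
    and reported separately.
    """
    if trajectories is not None:
        n_l = n_r = n_total = 0
        for tr in trajectories:
            n_total += 1
            if "l_common_carotid" in tr.segments_visited:
                n_l += 1
            if "r_common_carotid" in tr.segments_visited:
                n_r += 1
    elif record is not None:
        n_l = record.cca_entries.get("l_common_carotid", 0)
        n_r = record.cca_entries.get("r_common_carotid", 0)
        n_total = record.n_released
    else:
        raise ValueError("need trajectories or a record")
    entered = n_l + n_r
    if entered == 0:
        return {"left_pct": 0.0, "right_pct": 0.0, "excluded": n_total}
    return {
        "left_pct": 100.0 * n_l / entered,
        "right_pct": 100.0 * n_r / entered,
        "excluded": n_total - entered,
    }


def descriptive_stats(values: Sequence[float]) -> Dict[str, float]:
    """Mean, sample SD (n-1) and coefficient of variation."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    mean = float(np.mean(v))
    sd = float(np.std(v, ddof=1))
    cv = sd / mean if mean != 0 else float("nan")
    return {"mean": mean, "sd": sd, "cv": cv}


def stats_tests(
    group_a: Sequence[float],
    group_b: Optional[Sequence[float]] = None,
    test: str = "wilcoxon_one_sample",
    hypothesized_value: float = 0.0,
    alternative: str = "two-sided",
) -> Dict[str, float]:
    """Non-parametric tests with exact small-sample p-values where feasible.

    ``wilcoxon_one_sample``: signed-rank of ``group_a - hypothesized_value``
    (exact for n <= 25 without ties); ``mann_whitney_u``: rank-sum between
    the groups (exact for n*m <= 400 without ties); ``shapiro_wilk``:
    normality of ``group_a``.  Normal approximation with tie correction is
    used outside the exact regimes.
    """
    a = np.asarray(group_a, dtype=float)
    if test == "shapiro_wilk":
        res = sps.shapiro(a)
        return {"statistic": float(res.statistic), "p_value": float(res.pvalue)}
    if test == "wilcoxon_one_sample":
        d = a - hypothesized_value
        if np.all(d == 0):
            return {"statistic": float("nan"), "p_value": float("nan"),
                    "degenerate": True}
        has_ties = len(np.unique(np.abs(d[d != 0]))) < np.count_nonzero(d)
        method = "exact" if (len(d) <= 25 and not has_ties) else "approx"
        res = sps.wilcoxon(d, alternative=alternative, method=method)
        return {"statistic": float(res.statistic), "p_value": float(res.pvalue)}
    if test == "mann_whitney_u":
        b = np.asarray(group_b, dtype=float)
        pooled = np.concatenate([a, b])
        has_ties = len(np.unique(pooled)) < len(pooled)
        method = "exact" if (len(a) * len(b) <= 400 and not has_ties) else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative=alternative, method=method)
        return {"statistic": float(res.statistic), "p_value": float(res.pvalue)}
    raise ValueError(f"unknown test {test!r}")


def summary_table(records: Iterable[DistributionRecord],
                  hemisphere_map: Dict[str, str]) -> pd.DataFrame:
    """One row per experiment: outlet fractions, hemisphere and contralateral
    fractions, unresolved fraction."""
    rows = []
    for rec in records:
        row: Dict[str, object] = {
            "experiment": rec.experiment,
            "model": rec.model_label,
            "source": rec.source,
            "n_released": rec.n_released,
            "unresolved_fraction": rec.unresolved / rec.n_released,
            "extended": rec.extended,
        }
        for outlet, count in sorted(rec.outlet_counts.items()):
            row[f"frac_{outlet}"] = count / rec.n_released
        left, right = _cerebral_counts(rec, hemisphere_map)
        if left + right > 0:
            row["left_hemisphere_pct"] = 100.0 * left / (left + right)
            row["right_hemisphere_pct"] = 100.0 * right / (left + right)
        if rec.source in ("left_carotid", "right_carotid"):
            side = rec.source.split("_")[0]
            if left + right > 0:
                row["contralateral_fraction"] = contralateral_fraction(
                    rec, side, hemisphere_map
                )
        if rec.source == "cardiogenic" and rec.cca_entries:
            split = cca_recruitment_split(record=rec)
            row["cca_left_pct"] = split["left_pct"]
            row["cca_right_pct"] = split["right_pct"]
        rows.append(row)
    return pd.DataFrame(rows)


def plot_contralateral_fractions(table: pd.DataFrame, path: str) -> None:
    """Bar chart of contralateral fractions keyed by model label."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = table.dropna(subset=["contralateral_fraction"]) if (
        "contralateral_fraction" in table
    ) else table.iloc[:0]
    fig, ax = plt.subplots(figsize=(10, 4))
    labels = sub["model"] + ":" + sub["source"].str[0].str.upper()
    ax.bar(labels, 100.0 * sub["contralateral_fraction"], color="steelblue")
    ax.set_ylabel("contralateral distribution (%)")
    ax.set_xlabel("model : release side")
    ax.tick_params(axis="x", rotation=75, labelsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
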