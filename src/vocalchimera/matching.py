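"""Acoustic matching between stimulus categories.

The stimulus selection logic for the voice/instrument contrast: both
categories must span the same pitch set, and the distribution of each
acoustic descriptor (above all HNR) must not differ between the
categories under a one-way ANOVA.  This module provides the ANOVA, a
per-feature match report, a greedy subset-selection heuristic that
trims extreme items until the categories match, and the plain Pearson
correlation used for behavior-BOLD comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MATCH_FEATURES = ("hnr_db", "centroid_hz", "dom_rate_hz", "dom_scale_cpo", "f0_hz")
DEFAULT_ALPHA = 0.05


def one_way_anova(groups: list[np.ndarray]) -> tuple[float, int, int, float]:
    """Between/within mean-square F with exact dfs and its p-value.

    Returns ``(F, df1, df2, p)`` with ``df1 = k - 1`` and
    ``df2 = N - k``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    k = len(groups)
    n_total = sum(g.size for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(float(((g - g.mean()) ** 2).sum()) for g in groups)
    df1, df2 = k - 1, n_total - k
    if ss_within == 0.0:
        if ss_between == 0.0:
            return 0.0, df1, df2, 1.0
        raise ZeroDivisionError("zero within-group variance with nonzero effect")
    f = (ss_between / df1) / (ss_within / df2)
    p = float(stats.f.sf(f, df1, df2))
    return float(f), df1, df2, p


@dataclass
class MatchReport:
    """Per-feature category comparison."""

    table: pd.DataFrame     # feature, mean/sd per group, F, df1, df2, p, matched
    alpha: float

    @property
    def all_matched(self) -> bool:
        return bool(self.table["matched"].all())

    def __str__(self) -> str:
        lines = [f"Acoustic match report (alpha = {self.alpha})"]
        for _, row in self.table.iterrows():
            verdict = "matched" if row["matched"] else "NOT matched"
            lines.append(
                f"  {row['feature']:>13}: voice {row['mean_a']:.3g} (SD {row['sd_a']:.3g})"
                f" vs instrument {row['mean_b']:.3g} (SD {row['sd_b']:.3g});"
                f" F({row['df1']:.0f},{row['df2']:.0f}) = {row['F']:.2f},"
                f" p = {row['p']:.3g} -> {verdict}"
            )
        return "\n".join(lines)


def _profile_frame(profiles) -> pd.DataFrame:
    if isinstance(profiles, pd.DataFrame):
        return profiles
    return pd.DataFrame([vars(p) if not isinstance(p, dict) else p for p in profiles])


def match_report(voice_profiles, instrument_profiles,
                 alpha: float = DEFAULT_ALPHA,
                 features: tuple[str, ...] = MATCH_FEATURES) -> MatchReport:
    """One ANOVA per acoustic feature across the two categories.

    A feature is flagged unmatched when its between-category ANOVA is
    significant at ``alpha``.
    """
    va = _profile_frame(voice_profiles)
    vb = _profile_frame(instrument_profiles)
    if va.empty or vb.empty:
        raise ValueError("profile sets must be nonempty")
    rows = []
    for feat in features:
        a, b = va[feat].to_numpy(float), vb[feat].to_numpy(float)
        f, df1, df2, p = one_way_anova([a, b])
        rows.append(dict(feature=feat, mean_a=a.mean(), sd_a=a.std(ddof=1),
                         mean_b=b.mean(), sd_b=b.std(ddof=1),
                         F=f, df1=df1, df2=df2, p=p, matched=p >= alpha))
    return MatchReport(table=pd.DataFrame(rows), alpha=alpha)


def select_matched_subset(
    voice_candidates: pd.DataFrame,
    instrument_candidates: pd.DataFrame,
    feature: str = "hnr_db",
    alpha: float = DEFAULT_ALPHA,
    max_iter: int = 100,
    seed: int = 0,
    min_per_group: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Greedy trimming of extreme items until categories match.

    Candidates must carry a ``pitch`` column; items whose pitch is not
    present in both categories are dropped first (pitch sets must be
    identical), then the item farthest from the pooled feature mean is
    removed from the offending side until the between-category ANOVA on
    ``feature`` is non-significant at ``alpha``.  Values are never
    altered, only membership.  Deterministic given ``seed`` (used only
    to break exact distance ties).
    """
    rng = np.random.default_rng(seed)
    va = voice_candidates.copy()
    vb = instrument_candidates.copy()
    common = set(va["pitch"]) & set(vb["pitch"])
    va = va[va["pitch"].isin(common)]
    vb = vb[vb["pitch"].isin(common)]
    for _ in range(max_iter):
        if len(va) < min_per_group or len(vb) < min_per_group:
            break
        _, _, _, p = one_way_anova([va[feature].to_numpy(float),
                                    vb[feature].to_numpy(float)])
        if p >= alpha:
            return va.reset_index(drop=True), vb.reset_index(drop=True)
        pooled_mean = np.concatenate([va[feature], vb[feature]]).mean()
        # drop the single most extreme item (jittered argmax for ties)
        frames = {"a": va, "b": vb}
        dist = {k: (f[feature] - pooled_mean).abs() for k, f in frames.items()}
        side = max(dist, key=lambda k: dist[k].max() + rng.uniform(0, 1e-12))
        worst = dist[side].idxmax()
        frames[side] = frames[side].drop(index=worst)
        va, vb = frames["a"], frames["b"]
    _, _, _, p = one_way_anova([va[feature].to_numpy(float), vb[feature].to_numpy(float)])
    if p < alpha:
        raise RuntimeError(f"no matched subset found within {max_iter} iterations")
    return va.reset_index(drop=True), vb.reset_index(drop=True)


def pearson_r(x, y) -> float:
    """Product-moment correlation in [-1, 1]."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    return float(np.clip(stats.pearsonr(x, y).statistic, -1.0, 1.0))
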