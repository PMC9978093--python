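"""Group-comparison statistics on trial features.

Per emotion and per feature, group means +- SD are tabulated over trials (the
analysis unit is the trial, not the participant) and pairwise group contrasts
are tested with Welch's unequal-variance t-test.  P-values are adjusted with
the Benjamini-Hochberg step-up procedure; the adjustment family is all
emotion x group-pair tests within one feature, is configurable, and is always
recorded in the output so results stay auditable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

FEATURES = ("fix_eyes", "fix_mouth", "scan_path_length", "fix_nose", "n_saccades")

STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    for thr, stars in STAR_THRESHOLDS:
        if p < thr:
            return stars
    return "n.s."


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's t with Welch-Satterthwaite df and two-sided p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs >= 2 observations")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise ValueError("both samples are degenerate (zero variance)")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, float)
    if len(p) == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ComparisonResult:
    emotion: str
    feature: str
    group_a: str
    group_b: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t: float
    df: float
    p_raw: float
    p_adjusted: float = np.nan

    @property
    def stars(self) -> str:
        return significance_stars(self.p_adjusted)


DEFAULT_PAIRS = {
    "adult": (("control", "ASD"), ("control", "Sz")),
    "child": (("control", "ASD"),),
}


def emotion_feature_table(
    features: pd.DataFrame,
    pairs: tuple[tuple[str, str], ...] | None = None,
    feature_names: tuple[str, ...] = FEATURES[:3],
    bh_family: str = "per_feature",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-emotion mean +- SD table plus pairwise Welch tests with BH correction.

    ``features`` needs columns: group, emotion, and the feature columns.
    Returns ``(summary, comparisons)``; ``comparisons`` carries the family
    definition in its ``bh_family`` column.  Emotions with fewer than two
    trials in a group are skipped with a warning row in the summary.
    """
    if pairs is None:
        groups = set(features["group"])
        pairs = DEFAULT_PAIRS["adult"] if "Sz" in groups else DEFAULT_PAIRS["child"]
    if bh_family not in ("per_feature", "global"):
        raise ValueError(f"unknown bh_family {bh_family!r}")
    summary_rows, comparisons = [], []
    for emotion, emo_df in features.groupby("emotion", sort=False):
        row = {"emotion": emotion, "n_trials": len(emo_df)}
        for feat in feature_names:
            for grp, g_df in emo_df.groupby("group", sort=False):
                row[f"{feat}_{grp}"] = (
                    f"{g_df[feat].mean():.2f}±{g_df[feat].std(ddof=1):.2f}"
                    if len(g_df) >= 2 else "insufficient trials"
                )
        summary_rows.append(row)
        for a, b in pairs:
            xa = emo_df.loc[emo_df["group"] == a]
            xb = emo_df.loc[emo_df["group"] == b]
            for feat in feature_names:
                if len(xa) < 2 or len(xb) < 2:
                    continue
                t, df, p = welch_t(xa[feat], xb[feat])
                comparisons.append(
                    ComparisonResult(
                        emotion=emotion, feature=feat, group_a=a, group_b=b,
                        mean_a=float(xa[feat].mean()), sd_a=float(xa[feat].std(ddof=1)), n_a=len(xa),
                        mean_b=float(xb[feat].mean()), sd_b=float(xb[feat].std(ddof=1)), n_b=len(xb),
                        t=t, df=df, p_raw=p,
                    )
                )
    comp = pd.DataFrame([vars(c) for c in comparisons])
    if len(comp):
        if bh_family == "per_feature":
            for feat in comp["feature"].unique():
                mask = comp["feature"] == feat
                comp.loc[mask, "p_adjusted"] = bh_adjust(comp.loc[mask, "p_raw"])
        else:
            comp["p_adjusted"] = bh_adjust(comp["p_raw"])
        comp["stars"] = comp["p_adjusted"].map(significance_stars)
        comp["bh_family"] = bh_family
    return pd.DataFrame(summary_rows), comp
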