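"""Genre-vs-neutral significance analysis of the feature sheet.

For every feature and musical genre, each participant's two style
segments of that genre are averaged and compared against the same
participant's neutral-state segment with a paired two-sided Student
t-test.  Features are screened for normality (Shapiro–Wilk) beforehand;
the screen is reported but does not trigger an automatic switch to a
nonparametric test.  No multiple-testing correction is applied by
default (92 raw tests at alpha = 0.05); a Benjamini–Hochberg option
exists for sensitivity analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .io import GENRE_STYLES, NEUTRAL_LABEL
from .features import FEATURE_NAMES

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


def normality_screen(values_by_feature: dict[str, np.ndarray], alpha: float = DEFAULT_ALPHA) -> dict[str, float]:
    """Shapiro–Wilk p-value per feature; constant inputs are flagged NaN."""
    out = {}
    for name, vals in values_by_feature.items():
        vals = np.asarray(vals, dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size < 3:
            raise ValueError(f"feature {name}: need >= 3 finite values")
        if np.ptp(vals) == 0:
            logger.warning("feature %s constant; normality screen flagged", name)
            out[name] = np.nan
            continue
        out[name] = float(spstats.shapiro(vals).pvalue)
    failing = [k for k, p in out.items() if np.isfinite(p) and p < alpha]
    if failing:
        logger.info("normality rejected at %.3g for: %s", alpha, ", ".join(failing))
    return out


def paired_t_test(genre_values: np.ndarray, neutral_values: np.ndarray) -> tuple[float, int, float]:
    """Two-sided paired Student t-test on the per-participant differences.

    Returns (t, df, p) with df = n - 1, computed from the closed form
    t = mean(d) / (sd(d) / sqrt(n)).  Zero difference variance flags
    p = NaN rather than raising.
    """
    g = np.asarray(genre_values, dtype=float)
    r = np.asarray(neutral_values, dtype=float)
    if g.shape != r.shape or g.ndim != 1:
        raise ValueError("paired vectors must be 1-d and equal length")
    n = g.size
    if n < 3:
        raise ValueError("need n >= 3 pairs")
    d = g - r
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0:
        if d.mean() == 0:  # identical vectors
            return 0.0, df, 1.0
        logger.warning("zero difference variance with nonzero mean; p flagged")
        return float(np.sign(d.mean()) * np.inf), df, np.nan
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * spstats.t.sf(abs(t), df)
    return float(t), df, float(p)


@dataclass
class SignificanceTable:
    """Per feature x genre test results (one row each)."""

    table: pd.DataFrame  # feature, genre, means/sds, t, df, p, significant
    alpha: float
    n_flagged: int  # feature x genre cells skipped due to NaN sentinels

    def count_significant(self, genre: str | None = None) -> int:
        t = self.table if genre is None else self.table[self.table.genre == genre]
        return int(t.significant.sum())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.17g")


def _genre_means(sheet: pd.DataFrame, genre: str, feature: str) -> pd.Series:
    """Per-participant mean of the feature over the genre's two styles."""
    styles = GENRE_STYLES[genre]
    sub = sheet[sheet.segment_label.isin(styles)]
    return sub.groupby("participant_id")[feature].mean()


def build_significance_table(
    sheet: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    genres: tuple[str, ...] | None = None,
    correction: str | None = None,
    pairing: str = "paired",
) -> SignificanceTable:
    """Build the feature x genre significance table from a feature sheet.

    The sheet must contain a neutral row per participant; genre values
    are each participant's mean over the two styles of that genre.
    ``correction='bh'`` applies Benjamini–Hochberg across all rows;
    ``pairing='welch'`` switches to an unpaired Welch t-test.
    """
    genres = genres or tuple(GENRE_STYLES)
    neutral = sheet[sheet.segment_label == NEUTRAL_LABEL].set_index("participant_id")
    all_pids = sheet.participant_id.unique()
    missing = sorted(set(all_pids) - set(neutral.index))
    if missing:
        raise ValueError(f"missing neutral segment for participant(s): {missing}")

    rows = []
    n_flagged = 0
    for genre in genres:
        for feature in FEATURE_NAMES:
            gvals = _genre_means(sheet, genre, feature)
            pids = gvals.index.intersection(neutral.index)
            g = gvals.loc[pids].to_numpy()
            r = neutral.loc[pids, feature].to_numpy(dtype=float)
            ok = np.isfinite(g) & np.isfinite(r)
            n_flagged += int((~ok).sum())
            g, r = g[ok], r[ok]
            if g.size < 3:
                logger.warning("feature %s / genre %s: < 3 usable pairs, skipped", feature, genre)
                t, df, p = np.nan, 0, np.nan
            elif pairing == "welch":
                res = spstats.ttest_ind(g, r, equal_var=False)
                t, df, p = float(res.statistic), int(res.df), float(res.pvalue)
            else:
                t, df, p = paired_t_test(g, r)
            rows.append(
                dict(
                    feature=feature,
                    genre=genre,
                    mean_genre=g.mean() if g.size else np.nan,
                    sd_genre=g.std(ddof=1) if g.size > 1 else np.nan,
                    mean_neutral=r.mean() if r.size else np.nan,
                    sd_neutral=r.std(ddof=1) if r.size > 1 else np.nan,
                    t_stat=t,
                    df=df,
                    p_value=p,
                )
            )
    table = pd.DataFrame(rows)
    if correction == "bh":
        p = table.p_value.to_numpy()
        finite = np.isfinite(p)
        adj = np.full_like(p, np.nan)
        if finite.any():
            adj[finite] = _benjamini_hochberg(p[finite])
        table["p_adjusted"] = adj
        table["significant"] = table.p_adjusted < alpha
    else:
        table["significant"] = table.p_value < alpha
    if n_flagged:
        logger.info("skipped %d flagged (NaN) feature cells", n_flagged)
    return SignificanceTable(table=table, alpha=alpha, n_flagged=n_flagged)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out
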