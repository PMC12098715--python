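"""Per-site Spearman correlation of methylation with age, FDR control and
selection of significantly age-associated CpGs.

Site selection runs on adult samples only (tadpole methylation is globally
shifted at many CpGs), while clock training elsewhere uses the full cohort.
Correlations are computed on mid-ranks with the t-distribution approximation
for the two-sided p-value, vectorised across sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

from .io_formats import MethylationMatrix

__all__ = ["SiteStats", "spearman_with_age", "bh_adjust", "select_significant", "ALPHA"]

ALPHA = 0.001


@dataclass
class SiteStats:
    """Per-site age-association statistics."""

    table: pd.DataFrame  # site_id-indexed: r_s, p_raw, p_adj, sig_class, constant
    alpha: float
    n_samples: int

    @property
    def r_s(self) -> pd.Series:
        return self.table["r_s"]


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return stats.false_discovery_control(p, method="bh")


def _spearman_t_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from t = r * sqrt((n-2)/(1-r^2)) on n-2 df; |r|=1 -> 0."""
    r = np.clip(r, -1.0, 1.0)
    p = np.zeros_like(r)
    interior = np.abs(r) < 1.0
    t = r[interior] * np.sqrt((n - 2) / (1.0 - r[interior] ** 2))
    p[interior] = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.minimum(p, 1.0)


def spearman_with_age(
    m: MethylationMatrix,
    samples: pd.DataFrame,
    stages: set[str] | None = frozenset({"adult"}),
    alpha: float = ALPHA,
    exact: bool = False,
) -> SiteStats:
    """Spearman correlation of each site's methylation with age.

    ``stages`` restricts the samples used (None = all). Constant sites get
    r_s = 0, p = 1 and a ``constant`` flag. ``exact=True`` switches to the
    exact permutation null (small n only).
    """
    keep = samples if stages is None else samples[samples["life_stage"].isin(stages)]
    if len(keep) < 3:
        raise ValueError("need at least 3 samples after life-stage filtering")
    sample_ids = keep["sample_id"].tolist()
    beta = m.beta[sample_ids].to_numpy()
    ages = keep["age_years"].to_numpy(dtype=float)
    n = len(ages)

    constant = beta.std(axis=1) == 0
    ranks = np.apply_along_axis(rankdata, 1, beta)
    age_ranks = rankdata(ages)

    rx = ranks - ranks.mean(axis=1, keepdims=True)
    ry = age_ranks - age_ranks.mean()
    denom = np.sqrt((rx**2).sum(axis=1) * (ry**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (rx * ry).sum(axis=1) / denom, 0.0)
    r = np.clip(r, -1.0, 1.0)
    r[constant] = 0.0

    if exact:
        p = np.array(
            [
                stats.spearmanr(
                    beta[i], ages, alternative="two-sided"
                ).pvalue
                if not constant[i]
                else 1.0
                for i in range(beta.shape[0])
            ]
        )
        # scipy's exact path only engages for tiny n without ties; for
        # larger n this falls back to the same t-approximation.
    else:
        p = _spearman_t_pvalue(r, n)
    p[constant] = 1.0

    p_adj = bh_adjust(p)
    sig = np.where(
        (p_adj < alpha) & (r > 0), "positive",
        np.where((p_adj < alpha) & (r < 0), "negative", "none"),
    )
    table = pd.DataFrame(
        {"r_s": r, "p_raw": p, "p_adj": p_adj, "sig_class": sig, "constant": constant},
        index=m.site_ids,
    )
    return SiteStats(table=table, alpha=alpha, n_samples=n)


def select_significant(
    stats_: SiteStats, alpha: float | None = None
) -> tuple[list[str], list[str]]:
    """Split sites into significantly positive / negative lists.

    Lists are ordered by adjusted p-value, ties broken by site order. With an
    explicit ``alpha`` the classification is recomputed at that level.
    """
    t = stats_.table
    if alpha is None:
        sig = t["sig_class"]
    else:
        sig = pd.Series(
            np.where(
                (t["p_adj"] < alpha) & (t["r_s"] > 0), "positive",
                np.where((t["p_adj"] < alpha) & (t["r_s"] < 0), "negative", "none"),
            ),
            index=t.index,
        )
    order = np.lexsort((np.arange(len(t)), t["p_adj"].to_numpy()))
    ordered = t.index.to_numpy()[order]
    sig_ordered = sig.to_numpy()[order]
    positive = [s for s, c in zip(ordered, sig_ordered) if c == "positive"]
    negative = [s for s, c in zip(ordered, sig_ordered) if c == "negative"]
    return positive, negative
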