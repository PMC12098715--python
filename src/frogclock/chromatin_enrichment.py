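"""Chromatin-state enrichment of age-associated CpGs.

For each state, enrichment is the fraction of selected (significantly
positively or negatively age-correlated) CpGs in that state divided by the
fraction of all background CpGs in it, reported as log2. Significance is a
two-sided Fisher exact test on the 2x2 table {selected, background minus
selected} x {in state, not in state}, BH-adjusted across states within each
direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .age_association import bh_adjust
from .io_formats import ChromatinSegmentation

__all__ = [
    "EnrichmentTable",
    "assign_states",
    "state_enrichment",
    "fisher_exact_two_sided",
    "UNANNOTATED",
]

UNANNOTATED = "unannotated"

_FISHER_REL_EPS = 1 + 1e-9  # tolerance when comparing pmf values for ties


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    The p-value is the total hypergeometric probability of all tables with
    the observed margins whose probability does not exceed the observed
    table's (the standard two-sided convention). Computed directly from the
    pmf over the support, which keeps whole-segmentation screening cheap.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    n = a + b + c + d
    if n == 0:
        return 1.0
    r1, c1 = a + b, a + c
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    # hypergeometric pmf via log-binomials (cheap, vectorised over support)
    lg = gammaln
    logpmf = (
        lg(r1 + 1) - lg(support + 1) - lg(r1 - support + 1)
        + lg(n - r1 + 1) - lg(c1 - support + 1) - lg(n - r1 - c1 + support + 1)
        - (lg(n + 1) - lg(c1 + 1) - lg(n - c1 + 1))
    )
    pmf = np.exp(logpmf)
    p_obs = pmf[support == a][0]
    return float(min(pmf[pmf <= p_obs * _FISHER_REL_EPS].sum(), 1.0))


@dataclass
class EnrichmentTable:
    table: pd.DataFrame  # state-indexed: n_selected_in, n_selected,
    #                      n_background_in, n_background, log2_enrichment,
    #                      undefined, fisher_p, p_adj
    direction: str


def assign_states(
    chrom: np.ndarray, pos: np.ndarray, seg: ChromatinSegmentation
) -> np.ndarray:
    """Map each site to the state of the half-open interval containing it.

    Sites outside every interval get the sentinel state ``unannotated``.
    Intervals within a chromosome are non-overlapping (validated on load),
    so a sorted binary search suffices.
    """
    chrom = np.asarray(chrom, dtype=object)
    pos = np.asarray(pos, dtype=np.int64)
    out = np.full(len(pos), UNANNOTATED, dtype=object)
    iv = seg.intervals
    for c, grp in iv.groupby("chrom", sort=False):
        mask = chrom == c
        if not mask.any():
            continue
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        states = grp["state"].to_numpy()
        idx = np.searchsorted(starts, pos[mask], side="right") - 1
        ok = (idx >= 0) & (pos[mask] < ends[np.clip(idx, 0, None)])
        assigned = np.full(mask.sum(), UNANNOTATED, dtype=object)
        assigned[ok] = states[idx[ok]]
        out[mask] = assigned
    return out


def state_enrichment(
    selected: list[str],
    background: list[str],
    assignment: pd.Series,
    direction: str,
    alpha: float = 0.05,
    joint_states: list[str] | None = None,
) -> EnrichmentTable:
    """Per-state log2 enrichment of ``selected`` within ``background``.

    ``assignment`` maps site_id -> state for at least every background site.
    log2 enrichment is flagged undefined when any count in the ratio is zero.
    """
    sel = pd.Index(selected)
    bg = pd.Index(background)
    if not sel.isin(bg).all():
        raise ValueError("selected sites must be a subset of the background")
    sel_states = assignment.loc[sel]
    bg_states = assignment.loc[bg]
    n_sel, n_bg = len(sel), len(bg)
    states = joint_states if joint_states is not None else sorted(bg_states.unique())

    rows = []
    for st in states:
        a = int((sel_states == st).sum())            # selected, in state
        b = n_sel - a                                # selected, not in state
        bg_in = int((bg_states == st).sum())
        c = bg_in - a                                # background \ selected, in
        d = (n_bg - n_sel) - c
        if a > 0 and bg_in > 0 and n_sel > 0 and n_bg > 0:
            log2e = float(np.log2((a / n_sel) / (bg_in / n_bg)))
            undefined = False
        else:
            log2e = np.nan
            undefined = True
        p = fisher_exact_two_sided(a, b, c, d)
        rows.append(
            {
                "state": st,
                "n_selected_in": a,
                "n_selected": n_sel,
                "n_background_in": bg_in,
                "n_background": n_bg,
                "log2_enrichment": log2e,
                "undefined": undefined,
                "fisher_p": p,
            }
        )
    table = pd.DataFrame(rows).set_index("state")
    table["p_adj"] = bh_adjust(table["fisher_p"].to_numpy())
    table["significant"] = table["p_adj"] < alpha
    return EnrichmentTable(table=table, direction=direction)
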