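"""Pairwise genetic divergence between frogs and between tanks.

Divergence between two samples is the number of discordant genotype calls
divided by the total number of callable sites, expressed as a percentage.
Sites with a missing call ('.') in either sample are skipped for that pair;
the denominator stays the global callable-site count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix

__all__ = ["DivergenceMatrix", "pairwise_divergence", "tank_average"]


@dataclass
class DivergenceMatrix:
    """Symmetric sample x sample divergence, percentage scale."""

    matrix: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.matrix.to_numpy()
        if not np.allclose(v, v.T):
            raise ValueError("divergence matrix must be symmetric")
        if (np.diag(v) != 0).any():
            raise ValueError("divergence diagonal must be zero")
        if (v < 0).any():
            raise ValueError("divergence must be non-negative")


def pairwise_divergence(g: GenotypeMatrix) -> DivergenceMatrix:
    """Percent discordant calls over callable sites, for every sample pair."""
    if g.callable_sites <= 0:
        raise ValueError("callable_sites must be positive")
    samples = list(g.calls.columns)
    calls = g.calls.to_numpy(dtype=object)
    # Integer-encode calls; -1 = missing.
    flat = pd.factorize(calls.ravel())[0].reshape(calls.shape)
    labels = pd.factorize(calls.ravel())[1]
    missing_code = -1
    if "." in list(labels):
        dot = list(labels).index(".")
        flat = np.where(flat == dot, missing_code, flat)
    n = len(samples)
    out = np.zeros((n, n))
    for i in range(n):
        a = flat[:, i]
        for j in range(i + 1, n):
            b = flat[:, j]
            both = (a != missing_code) & (b != missing_code)
            disc = int(((a != b) & both).sum())
            out[i, j] = out[j, i] = 100.0 * disc / g.callable_sites
    return DivergenceMatrix(pd.DataFrame(out, index=samples, columns=samples))


def tank_average(d: DivergenceMatrix, samples: pd.DataFrame) -> pd.DataFrame:
    """Tank x tank mean divergence over cross-pairs.

    The diagonal is the mean over distinct within-tank pairs (0 for
    single-frog tanks, which cannot show within-tank variation).
    """
    tank_of = dict(zip(samples["sample_id"], samples["tank_id"]))
    missing = [s for s in d.matrix.index if s not in tank_of]
    if missing:
        raise ValueError(f"samples without tank assignment: {missing[:5]}")
    tanks = pd.unique(samples["tank_id"])
    members = {
        t: [s for s in d.matrix.index if tank_of[s] == t] for t in tanks
    }
    out = pd.DataFrame(0.0, index=tanks, columns=tanks)
    v = d.matrix
    for i, t1 in enumerate(tanks):
        for t2 in tanks[i:]:
            m1, m2 = members[t1], members[t2]
            if t1 == t2:
                pairs = [
                    v.loc[a, b] for k, a in enumerate(m1) for b in m1[k + 1:]
                ]
                val = float(np.mean(pairs)) if pairs else 0.0
            else:
                val = float(v.loc[m1, m2].to_numpy().mean())
            out.loc[t1, t2] = out.loc[t2, t1] = val
    return out
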