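"""Alpha-diversity indices: observed richness, Chao1, Shannon.

Chao1 estimates total richness from the singleton/doubleton tail,

    S_chao1 = S_obs + n1 (n1 - 1) / (2 (n2 + 1)),

where n1 and n2 are the numbers of taxa observed exactly once and twice;
it is defined only on integer counts. Shannon diversity is the natural-log
entropy of the relative abundances, H = -Σ (n_i/N) ln(n_i/N), and applies
to any nonnegative abundance vector. Indices are computed on the table as
given; no rarefaction is applied.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import CommunityTable

__all__ = ["observed_richness", "chao1", "shannon", "alpha_diversity"]


def _as_vector(counts) -> np.ndarray:
    vec = np.asarray(counts, dtype=float)
    if vec.ndim != 1:
        raise ValueError("expected a 1-D abundance vector")
    if (vec < 0).any() or not np.isfinite(vec).all():
        raise ValueError("abundances must be finite and nonnegative")
    if not (vec > 0).any():
        raise ValueError("all-zero abundance vector: index undefined")
    return vec


def observed_richness(counts) -> int:
    """Number of taxa with nonzero abundance (S_obs)."""
    return int((_as_vector(counts) > 0).sum())


def chao1(counts) -> float:
    """Chao1 richness estimate S_obs + n1(n1-1)/(2(n2+1)).

    Requires nonnegative *integer* counts — singletons and doubletons are
    undefined on relative abundances; zeros are ignored.
    """
    vec = _as_vector(counts)
    if not np.all(np.equal(np.mod(vec, 1), 0)):
        raise ValueError(
            "chao1 requires integer counts; supply raw counts, not relative abundances"
        )
    sobs = float((vec > 0).sum())
    n1 = float((vec == 1).sum())
    n2 = float((vec == 2).sum())
    return sobs + n1 * (n1 - 1.0) / (2.0 * (n2 + 1.0))


def shannon(counts) -> float:
    """Shannon diversity in nats; zero-abundance taxa contribute nothing."""
    vec = _as_vector(counts)
    p = vec[vec > 0]
    p = p / p.sum()
    return float(-(p * np.log(p)).sum())


def alpha_diversity(table: CommunityTable) -> pd.DataFrame:
    """Per-sample S_obs, Chao1 and Shannon for a community table.

    Chao1 is reported as NaN (with no error) for samples whose counts are
    non-integer; the other indices are always computed.
    """
    rows = []
    for sample in table.samples:
        vec = table.data.loc[sample].to_numpy()
        try:
            c1 = chao1(vec)
        except ValueError:
            c1 = float("nan")
        rows.append(
            {
                "sample_id": sample,
                "sobs": observed_richness(vec),
                "chao1": c1,
                "shannon": shannon(vec),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")
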