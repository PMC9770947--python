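"""Target-decoy false-discovery-rate estimation and filtering.

Identifications (spectrum-level PrSMs or proteoform-level representatives)
are scored by E-value and carry a decoy flag. The q-value of an item is the
smallest estimated FDR at which it would still be accepted, with the
estimator D/T at each score threshold (decoys over targets, the TopPIC-suite
convention) and monotone smoothing from the bottom of the ranked list.
Ties in E-value are grouped before ranking so the result is independent of
input order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class FdrConfig:
    """FDR thresholds: 5% at the spectrum level and 1% at the proteoform
    level by default; SAAV proteoform searches use 5% at the proteoform level."""

    spectrum_fdr: float = 0.05
    proteoform_fdr: float = 0.01

    def __post_init__(self):
        for name in ("spectrum_fdr", "proteoform_fdr"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")


def q_values(df: pd.DataFrame, *, score_col: str = "e_value",
             decoy_col: str = "is_decoy") -> pd.Series:
    """Per-item q-values for a scored target/decoy collection.

    Items are ranked by ascending score (lower E-value = better). At each
    distinct score s the raw FDR is ``#decoys(score <= s) / max(1,
    #targets(score <= s))``; the q-value is the running minimum of raw FDR
    over all thresholds at or beyond the item's score, capped at 1, so q is
    monotone non-decreasing in E-value and tied scores share one q-value.

    Returns a Series aligned to ``df.index``. Empty input gives an empty
    Series; with no decoys all q-values are 0.
    """
    if len(df) == 0:
        return pd.Series(dtype=float, name="q_value")
    scores = df[score_col].to_numpy(dtype=float)
    if np.any(scores <= 0):
        raise ValueError(f"{score_col} must be > 0 for all items")
    decoy = df[decoy_col].to_numpy(dtype=bool)

    order = np.argsort(scores, kind="stable")
    s_sorted = scores[order]
    d_cum = np.cumsum(decoy[order])
    t_cum = np.cumsum(~decoy[order])
    # collapse ties: evaluate D/T at the last index of each distinct score
    is_last = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    raw = d_cum / np.maximum(1, t_cum)
    raw_at_group = raw.copy()
    # propagate the tie-group value backwards over the group
    group_ids = np.cumsum(np.r_[True, s_sorted[1:] != s_sorted[:-1]]) - 1
    group_raw = raw[is_last]
    raw_at_group = group_raw[group_ids]
    # monotone smoothing: running minimum from the worst score upward; cap at 1
    q_sorted = np.minimum(1.0, np.minimum.accumulate(raw_at_group[::-1])[::-1])
    q = np.empty(len(df), dtype=float)
    q[order] = q_sorted
    return pd.Series(q, index=df.index, name="q_value")


def filter_at_fdr(df: pd.DataFrame, threshold: float, *, score_col: str = "e_value",
                  decoy_col: str = "is_decoy") -> pd.DataFrame:
    """Retain target items with q-value <= threshold; decoys are never returned.

    ``threshold`` must lie in (0, 1).
    """
    if not 0 < threshold < 1:
        raise ValueError(f"FDR threshold must be in (0, 1), got {threshold}")
    if len(df) == 0:
        return df.copy()
    q = q_values(df, score_col=score_col, decoy_col=decoy_col)
    keep = (~df[decoy_col].astype(bool)) & (q <= threshold)
    out = df.loc[keep].copy()
    out["q_value"] = q.loc[keep]
    return out
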