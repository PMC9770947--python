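"""S0-moderated two-sample testing with permutation-based FDR.

The per-proteoform statistic is the SAM-family moderated difference

    d = (mean(x) - mean(y)) / (s + s0),    s = sp * sqrt(1/nx + 1/ny),

where ``sp`` is the pooled standard deviation and ``s0 >= 0`` an
abundance-scale offset (applied on the log2 scale) that damps the
significance of low-variance rows. With ``s0 = 0``, d is exactly Student's
two-sample t statistic.

The false-discovery rate of a cutoff on |d| is estimated by balanced label
permutations: for each row's observed |d|, the median over permutations of
the number of permuted |d| values at or beyond it (the SAM convention for
the expected false-call count; the median is essential when the exhaustive
shuffle set contains the identity relabeling, whose false-call count equals
the observed call count and would otherwise floor every q-value) is divided
by the observed number of rows at or beyond it, capped at 1 and monotonized. All
distinct label shuffles are enumerated exhaustively when there are no more
of them than ``n_permutations`` (a 3-vs-3 design has C(6,3) = 20), which
makes the q-values exactly reproducible; otherwise shuffles are sampled
without replacement from a seeded generator.

The module follows the statsmodels shape: build a
:class:`SamPermutationModel` from a log2 matrix and a two-group design,
call :meth:`~SamPermutationModel.fit` and read the
:class:`SamPermutationResults` table or :meth:`~SamPermutationResults.summary`.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class DiffConfig:
    """Test settings: ``s0`` offset (default 1), FDR threshold (default
    0.05), permutation budget and seed."""

    s0: float = 1.0
    fdr: float = 0.05
    n_permutations: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.s0 < 0:
            raise ValueError("s0 must be >= 0")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0, 1)")


def _pooled_se(x: np.ndarray, y: np.ndarray, axis: int = -1) -> np.ndarray:
    nx, ny = x.shape[axis], y.shape[axis]
    vx = np.var(x, axis=axis, ddof=1)
    vy = np.var(y, axis=axis, ddof=1)
    sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
    return np.sqrt(sp2) * np.sqrt(1.0 / nx + 1.0 / ny)


def s0_statistic(x, y, s0: float = 1.0):
    """Moderated difference d = (mean(x) - mean(y)) / (pooled SE + s0).

    ``x`` and ``y`` are 1-D samples (each of size >= 2) or 2-D arrays with
    rows as features and columns as replicates. ``s0 = 0`` recovers
    Student's t exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[-1] < 2 or y.shape[-1] < 2:
        raise ValueError("each group needs at least 2 values")
    if s0 < 0:
        raise ValueError("s0 must be >= 0")
    num = x.mean(axis=-1) - y.mean(axis=-1)
    den = _pooled_se(x, y) + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(den > 0, num / np.where(den > 0, den, 1.0),
                     np.where(num == 0, 0.0, np.inf * np.sign(num)))
    return d if d.ndim else float(d)


def balanced_shuffles(n1: int, n2: int, n_permutations: int, seed: int) -> list[tuple[int, ...]]:
    """Index sets (into the concatenated columns) taking the role of group 1.

    All C(n1+n2, n1) distinct shuffles are enumerated when there are at most
    ``n_permutations`` of them; otherwise that many distinct shuffles are
    sampled with a generator seeded by ``seed``.
    """
    from math import comb

    total = comb(n1 + n2, n1)
    if total < 2:
        raise ValueError("fewer than 2 distinct label shuffles")
    if total <= n_permutations:
        return list(combinations(range(n1 + n2), n1))
    rng = np.random.default_rng(seed)
    seen: set[tuple[int, ...]] = set()
    while len(seen) < n_permutations:
        seen.add(tuple(sorted(rng.choice(n1 + n2, size=n1, replace=False).tolist())))
    return sorted(seen)


class SamPermutationModel:
    """Two-group moderated test on a log2 abundance matrix.

    Parameters
    ----------
    log2_matrix : DataFrame
        Rows are proteoforms; columns are runs. With MultiIndex columns
        (condition, replicate) the design is inferred from the first level.
    design : mapping or list, optional
        Column -> group label, required when columns are not (condition,
        replicate) pairs. Exactly two groups, each with >= 2 columns.
    config : DiffConfig
    """

    def __init__(self, log2_matrix: pd.DataFrame, design=None,
                 config: DiffConfig | None = None):
        self.config = config or DiffConfig()
        self.matrix = log2_matrix
        if design is None:
            if log2_matrix.columns.nlevels < 2:
                raise ValueError("design required when columns are not "
                                 "(condition, replicate) pairs")
            groups = list(log2_matrix.columns.get_level_values(0))
        else:
            groups = [design[c] for c in log2_matrix.columns]
        labels = list(dict.fromkeys(groups))
        if len(labels) != 2:
            raise ValueError(f"exactly two conditions required, got {labels}")
        self.group_labels = (str(labels[0]), str(labels[1]))
        self._idx1 = [i for i, g in enumerate(groups) if g == labels[0]]
        self._idx2 = [i for i, g in enumerate(groups) if g == labels[1]]
        if len(self._idx1) < 2 or len(self._idx2) < 2:
            raise ValueError("each condition needs at least 2 replicates")

    @classmethod
    def from_quant_matrix(cls, qm, reference_column=None, config: DiffConfig | None = None):
        """Build from a :class:`~tdpq.quant.QuantMatrix`: complete-case
        filter, Perseus-style normalization, then the test."""
        from . import quant

        qm = quant.complete_case_filter(qm)
        if reference_column is None:
            reference_column = qm.data.columns[0]
        log2 = quant.normalize(qm, reference_column)
        return cls(log2, config=config)

    def fit(self) -> "SamPermutationResults":
        cfg = self.config
        vals = self.matrix.to_numpy(dtype=float)
        x = vals[:, self._idx1]
        y = vals[:, self._idx2]
        n1, n2 = x.shape[1], y.shape[1]
        d_obs = np.atleast_1d(s0_statistic(x, y, cfg.s0))
        log2_fc = x.mean(axis=1) - y.mean(axis=1)
        p = stats.ttest_ind(x, y, axis=1, equal_var=True).pvalue
        p = np.where(np.isnan(p), 1.0, p)  # zero-variance, zero-difference rows

        cols = np.concatenate([self._idx1, self._idx2])
        pooled = vals[:, cols]
        shuffles = balanced_shuffles(n1, n2, cfg.n_permutations, cfg.seed)
        n_rows = vals.shape[0]
        abs_obs = np.abs(d_obs)
        # permuted |d|, flattened over all shuffles
        perm_abs = np.empty((len(shuffles), n_rows))
        all_idx = set(range(n1 + n2))
        for k, sh in enumerate(shuffles):
            g1 = np.array(sh, dtype=int)
            g2 = np.array(sorted(all_idx - set(sh)), dtype=int)
            perm_abs[k] = np.abs(s0_statistic(pooled[:, g1], pooled[:, g2], cfg.s0))
        # median over shuffles of #{perm |d| >= t}, and observed #{|d| >= t}
        obs_sorted = np.sort(abs_obs)
        counts = np.empty((len(shuffles), n_rows))
        for k in range(len(shuffles)):
            row_sorted = np.sort(perm_abs[k])
            counts[k] = n_rows - np.searchsorted(row_sorted, abs_obs, side="left")
        expected_false = np.median(counts, axis=0)
        n_obs_ge = n_rows - np.searchsorted(obs_sorted, abs_obs, side="left")
        with np.errstate(divide="ignore", invalid="ignore"):
            q_raw = np.minimum(1.0, expected_false / np.maximum(n_obs_ge, 1))
        # monotonize: q non-decreasing as |d| decreases
        order = np.argsort(-abs_obs, kind="stable")
        q_sorted = np.minimum.accumulate(np.minimum(1.0, q_raw[order])[::-1])[::-1]
        q = np.empty(n_rows)
        q[order] = q_sorted

        significant = q <= cfg.fdr
        direction = np.where(log2_fc >= 0, self.group_labels[0], self.group_labels[1])
        table = pd.DataFrame({
            "log2_fc": log2_fc,
            "d_statistic": d_obs,
            "p_value": p,
            "q_permutation": q,
            "significant": significant,
            "direction": direction,
        }, index=self.matrix.index)
        return SamPermutationResults(self, table, len(shuffles))


class SamPermutationResults:
    """Fitted results: per-proteoform fold changes, moderated statistics,
    Student p-values, permutation q-values and significance calls."""

    def __init__(self, model: SamPermutationModel, table: pd.DataFrame, n_shuffles: int):
        self.model = model
        self.table = table
        self.n_shuffles = n_shuffles

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    def volcano_table(self) -> pd.DataFrame:
        """(log2_fc, -log10 p, flag) per proteoform; flags are
        ``higher_in_<condition>`` for significant rows and ``ns`` otherwise."""
        g1, g2 = self.model.group_labels
        t = self.table
        flag = np.where(~t["significant"], "ns",
                        np.where(t["log2_fc"] > 0, f"higher_in_{g1}", f"higher_in_{g2}"))
        p_floor = np.maximum(t["p_value"].to_numpy(), np.finfo(float).tiny)
        return pd.DataFrame({"log2_fc": t["log2_fc"],
                             "neg_log10_p": -np.log10(p_floor),
                             "flag": flag}, index=t.index)

    def summary(self) -> str:
        cfg = self.model.config
        g1, g2 = self.model.group_labels
        t = self.table
        n_up1 = int((t["significant"] & (t["log2_fc"] > 0)).sum())
        n_up2 = int((t["significant"] & (t["log2_fc"] < 0)).sum())
        lines = [
            "S0-moderated permutation test",
            "=" * 46,
            f"conditions:        {g1} vs {g2}",
            f"proteoforms:       {len(t)}",
            f"s0:                {cfg.s0:g}",
            f"FDR threshold:     {cfg.fdr:g}",
            f"label shuffles:    {self.n_shuffles}"
            + (" (exhaustive)" if self.n_shuffles < cfg.n_permutations else ""),
            f"significant:       {self.n_significant}"
            f"  (higher in {g1}: {n_up1}, higher in {g2}: {n_up2})",
        ]
        return "\n".join(lines)


def permutation_fdr(log2_matrix: pd.DataFrame, design=None,
                    config: DiffConfig | None = None) -> pd.DataFrame:
    """Functional wrapper: fit :class:`SamPermutationModel` and return the
    result table."""
    return SamPermutationModel(log2_matrix, design, config).fit().table


def volcano_table(results: SamPermutationResults) -> pd.DataFrame:
    return results.volcano_table()


def compare_group_means(a, b) -> dict:
    """Classical two-tailed equal-variance two-sample t comparison.

    Returns means and sample SDs per group plus the t statistic and p-value.
    Degenerate zero-variance inputs report p at the floating-point underflow
    floor (identical constant groups give t = 0, p = 1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    mean_a, sd_a = a.mean(), a.std(ddof=1)
    mean_b, sd_b = b.mean(), b.std(ddof=1)
    se = _pooled_se(a, b)
    diff = mean_a - mean_b
    if se == 0:
        if diff == 0:
            t_stat, p = 0.0, 1.0
        else:
            t_stat = np.inf * np.sign(diff)
            p = np.finfo(float).tiny
    else:
        t_stat, p = stats.ttest_ind(a, b, equal_var=True)
        p = max(float(p), np.finfo(float).tiny)
    return {"mean_a": mean_a, "sd_a": sd_a, "mean_b": mean_b, "sd_b": sd_b,
            "t": float(t_stat), "p_value": float(p)}
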