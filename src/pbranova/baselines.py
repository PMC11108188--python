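"""Classical ANOVA comparators for balanced one-way designs.

These are the scalar analyses the functional approach is compared against:

* one-way univariate ANOVA on a per-subject scalar (typically the curve's
  mean over the domain or over one lighting period);
* repeated-measures ANOVA treating time as a within-subject factor, with the
  split-plot decomposition SSA + SSS(A) + SST + SSAT + SSE, F_A tested
  against the between-subject mean square MSS(A) and F_T, F_AT against the
  residual MSE.

Both are implemented directly from the balanced-design sums of squares; the
pointwise functional F statistic reduces to ``univariate_anova`` at a single
grid point, which the test suite uses as an oracle.  p-values use the F
reference distribution and no sphericity correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["AnovaTable", "univariate_anova", "repeated_measures_anova", "collapse_to_means"]


class BalanceError(ValueError):
    """Unequal group sizes; the balanced formulas do not apply."""


@dataclass
class AnovaRow:
    source: str
    df: int
    ss: float
    ms: float
    f: float | None = None
    p: float | None = None


@dataclass
class AnovaTable:
    rows: list

    def __getitem__(self, source: str) -> AnovaRow:
        for row in self.rows:
            if row.source == source:
                return row
        raise KeyError(source)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {"source": r.source, "df": r.df, "ss": r.ss, "ms": r.ms,
                 "f": r.f, "p": r.p}
                for r in self.rows
            ]
        )


def _group_matrix(values: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, int, int]:
    """Stack per-group observations into an (a, n, ...) array."""
    labels = np.asarray(labels)
    uniq, idx = np.unique(labels, return_index=True)
    uniq = labels[np.sort(idx)]
    sizes = [(labels == g).sum() for g in uniq]
    if len(set(sizes)) != 1:
        raise BalanceError(f"unequal group sizes {dict(zip(uniq.tolist(), sizes))}")
    a, n = len(uniq), sizes[0]
    stacked = np.stack([values[labels == g] for g in uniq])
    return stacked, a, n


def univariate_anova(values, labels) -> AnovaTable:
    """One-way ANOVA from the balanced sums of squares.

    ``SSA = n Σ_i (ȳ_i. − ȳ..)²`` and ``SSE = Σ_ij (y_ij − ȳ_i.)²`` with
    dfs q_A = a−1 and q_E = a(n−1).
    """
    values = np.asarray(values, float)
    y, a, n = _group_matrix(values, labels)
    if n < 2:
        raise BalanceError("at least 2 subjects per group are required")
    grand = y.mean()
    gmeans = y.mean(axis=1)
    ssa = n * np.sum((gmeans - grand) ** 2)
    sse = np.sum((y - gmeans[:, None]) ** 2)
    q_a, q_e = a - 1, a * (n - 1)
    msa, mse = ssa / q_a, sse / q_e
    f = msa / mse if mse > 0 else (np.inf if msa > 0 else 0.0)
    p = float(stats.f.sf(f, q_a, q_e)) if np.isfinite(f) else 0.0
    return AnovaTable(
        rows=[
            AnovaRow("factor", q_a, float(ssa), float(msa), float(f), p),
            AnovaRow("residual", q_e, float(sse), float(mse)),
        ]
    )


def repeated_measures_anova(y, labels) -> AnovaTable:
    """Balanced split-plot ANOVA with time as the within-subject factor.

    ``y`` is (subjects, times); ``labels`` assigns each subject to a group.
    Returns rows factor / subjects(factor) / time / factor:time / residual
    with dfs (a−1, a(n−1), t−1, (a−1)(t−1), a(n−1)(t−1)).
    """
    y = np.asarray(y, float)
    if y.ndim != 2 or y.shape[1] < 2:
        raise ValueError("y must be (subjects, times) with at least 2 time points")
    stacked, a, n = _group_matrix(y, labels)  # (a, n, t)
    if n < 2:
        raise BalanceError("at least 2 subjects per group are required")
    t = y.shape[1]
    grand = stacked.mean()
    m_i = stacked.mean(axis=(1, 2))          # group means
    m_ij = stacked.mean(axis=2)              # subject means
    m_k = stacked.mean(axis=(0, 1))          # time means
    m_ik = stacked.mean(axis=1)              # group-by-time means

    ssa = n * t * np.sum((m_i - grand) ** 2)
    sss = t * np.sum((m_ij - m_i[:, None]) ** 2)
    sst = a * n * np.sum((m_k - grand) ** 2)
    ssat = n * np.sum((m_ik - m_i[:, None] - m_k[None, :] + grand) ** 2)
    sse = np.sum(
        (stacked - m_ik[:, None, :] - m_ij[:, :, None] + m_i[:, None, None]) ** 2
    )

    df_a, df_s = a - 1, a * (n - 1)
    df_t, df_at, df_e = t - 1, (a - 1) * (t - 1), a * (n - 1) * (t - 1)
    msa, mss = ssa / df_a, sss / df_s
    mst, msat, mse = sst / df_t, ssat / df_at, sse / df_e
    f_a = msa / mss
    f_t = mst / mse
    f_at = msat / mse
    return AnovaTable(
        rows=[
            AnovaRow("factor", df_a, float(ssa), float(msa), float(f_a),
                     float(stats.f.sf(f_a, df_a, df_s))),
            AnovaRow("subjects(factor)", df_s, float(sss), float(mss)),
            AnovaRow("time", df_t, float(sst), float(mst), float(f_t),
                     float(stats.f.sf(f_t, df_t, df_e))),
            AnovaRow("factor:time", df_at, float(ssat), float(msat), float(f_at),
                     float(stats.f.sf(f_at, df_at, df_e))),
            AnovaRow("residual", df_e, float(sse), float(mse)),
        ]
    )


def collapse_to_means(values: np.ndarray, axis: int = -1) -> np.ndarray:
    """Average each curve over the domain — the scalar-ANOVA reduction that
    discards all temporal structure."""
    return np.asarray(values, float).mean(axis=axis)
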