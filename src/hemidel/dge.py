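"""Moderated two-group differential expression with BH correction.

Implements an empirical-Bayes moderated t-test for deleted vs
normal-karyotype samples on log2-scale expression.  Gene-wise residual
variances :math:`s_g^2` (pooled, equal-variance, :math:`d` residual
degrees of freedom) are shrunk toward a prior variance :math:`s_0^2`
with prior degrees of freedom :math:`d_0`, both estimated by matching
the first two moments of :math:`\\log s_g^2` to the scaled-F model
:math:`s_g^2 \\sim s_0^2 F(d, d_0)`:

.. math::

    \\tilde{s}_g^2 = \\frac{d_0 s_0^2 + d s_g^2}{d_0 + d},
    \\qquad
    \\tilde{t}_g = \\frac{\\Delta_g}{\\tilde{s}_g \\sqrt{1/n_1 + 1/n_2}}

with :math:`\\tilde{t}_g` referred to a t distribution on
:math:`d + d_0` degrees of freedom.  P-values are corrected by the
Benjamini-Hochberg step-up, and genes are called up/down under the
rule ``|log2FC| > 1`` and ``-log10(q) > 5`` (strict inequalities,
logarithm base configurable).
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .hi_expression import DELETED, DIPLOID, ExpressionMatrix

DEFAULT_FC_CUT = 1.0
DEFAULT_NEGLOG_Q_CUT = 5.0


def _trigamma_inverse(y: float) -> float:
    """Solve ``trigamma(x) = y`` for x > 0 (Newton iteration)."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def fit_f_prior(variances: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-matching fit of the variance prior ``(d0, s0^2)``.

    Under ``s_g^2 ~ s0^2 * F(df, d0)``, ``log s_g^2`` has known mean and
    variance in terms of digamma/trigamma functions; matching the
    observed moments of ``log s_g^2`` yields ``d0`` (via trigamma
    inversion) and ``s0^2``.  When the observed spread of log variances
    is no larger than expected from ``F(df, inf)`` alone, ``d0`` is
    infinite (complete shrinkage to ``s0^2``).
    """
    v = np.asarray(variances, dtype=float)
    v = np.maximum(v, 1e-300)
    z = np.log(v)
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        return math.inf, float(math.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0_sq = math.exp(
        e_mean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0)
    )
    return d0, s0_sq


def moderated_test(
    values: pd.DataFrame,
    labels: pd.Series,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated t-test per gene (deleted minus diploid).

    Parameters
    ----------
    values
        Genes x samples matrix on the log2 scale.
    labels
        Karyotype per sample (``deleted`` / ``diploid_NK``).
    prior_df
        Override the estimated prior degrees of freedom; ``0`` disables
        shrinkage (ordinary equal-variance two-sample t), ``inf`` pools
        all genes to one variance.  ``None`` (default) estimates it.

    Returns a frame with columns ``gene``, ``log2_fc``, ``t_mod``, ``p``.
    """
    lab = labels[values.columns]
    g1 = values.loc[:, (lab == DELETED).to_numpy()]
    g2 = values.loc[:, (lab == DIPLOID).to_numpy()]
    n1, n2 = g1.shape[1], g2.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 samples per group")
    df = n1 + n2 - 2
    if df <= 0:
        raise ValueError("zero residual degrees of freedom")
    m1 = g1.mean(axis=1).to_numpy()
    m2 = g2.mean(axis=1).to_numpy()
    fc = m1 - m2
    s2 = (
        g1.var(axis=1, ddof=1).to_numpy() * (n1 - 1)
        + g2.var(axis=1, ddof=1).to_numpy() * (n2 - 1)
    ) / df
    if prior_df is None:
        d0, s0_sq = fit_f_prior(s2, df)
    elif prior_df == 0:
        d0, s0_sq = 0.0, 0.0
    elif math.isinf(prior_df):
        d0, s0_sq = math.inf, float(np.mean(s2))
    else:
        _, s0_sq = fit_f_prior(s2, df)
        d0 = float(prior_df)
    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        total_df = np.inf
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        total_df = df + d0
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, fc / se, 0.0)
    if math.isinf(total_df):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), total_df)
    return pd.DataFrame(
        {"gene": values.index, "log2_fc": fc, "t_mod": t, "p": p}
    ).reset_index(drop=True)


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    ``q_(i) = min_{j >= i} p_(j) * m / j`` over the sorted p-values,
    capped at 1; the output keeps the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def apply_thresholds(
    results: pd.DataFrame,
    fc_cut: float = DEFAULT_FC_CUT,
    neglog_q_cut: float = DEFAULT_NEGLOG_Q_CUT,
    log_base: float = 10.0,
) -> pd.DataFrame:
    """Annotate results with BH q-values and up/down/ns status.

    ``up``: ``log2_fc > fc_cut`` and ``-log_base(q) > neglog_q_cut``;
    ``down``: the mirror image; everything else ``ns``.
    """
    out = results.copy()
    if "q" not in out.columns:
        out["q"] = bh_adjust(out["p"].to_numpy())
    with np.errstate(divide="ignore"):
        neglog_q = -np.log(out["q"].to_numpy()) / math.log(log_base)
    sig = neglog_q > neglog_q_cut
    status = np.where(
        sig & (out["log2_fc"] > fc_cut),
        "up",
        np.where(sig & (out["log2_fc"] < -fc_cut), "down", "ns"),
    )
    out["status"] = status
    return out


def run_dge(
    matrix: ExpressionMatrix,
    cdr_genes: Sequence[str] = (),
    floor: float = 1.0,
    max_low_fraction: float = 0.10,
    fc_cut: float = DEFAULT_FC_CUT,
    neglog_q_cut: float = DEFAULT_NEGLOG_Q_CUT,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Differential expression for genes outside the CDRs.

    Applies the diploid low-expression filter, excludes genes contained
    in the supplied CDR gene list, log2-transforms linear input, and
    runs the moderated test with BH correction and status thresholds.
    """
    from .hi_expression import filter_low_expression

    retained = filter_low_expression(matrix, floor, max_low_fraction)
    tested = [g for g in retained if g not in set(cdr_genes)]
    logm = matrix.to_log2()
    results = moderated_test(logm.values.loc[tested], logm.sample_labels, prior_df)
    return apply_thresholds(results, fc_cut, neglog_q_cut)
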