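"""Empirical-Bayes moderated t-testing and signature extraction.

The moderated two-sample t-statistic shrinks each probe's pooled variance
toward a common prior estimated from all probes. Writing ``s_g^2`` for the
pooled within-group variance of probe *g* on ``d_g = n1 + n2 - 2`` degrees
of freedom, the marginal distribution of the sample variances is modelled
as a scaled F: ``s_g^2 ~ s_0^2 F(d_g, d_0)``. The hyperparameters
``(d_0, s_0^2)`` are estimated by the closed-form method of moments on
``log s_g^2``::

    e_g    = log s_g^2 - digamma(d_g/2) + log(d_g/2)
    d_0    = 2 * trigamma^{-1}( var(e) - trigamma(d_g/2) )
    s_0^2  = exp( mean(e) + digamma(d_0/2) - log(d_0/2) )

with ``trigamma^{-1}`` found by Newton iteration. The posterior variance

    s~_g^2 = (d_0 s_0^2 + d_g s_g^2) / (d_0 + d_g)

yields the moderated statistic ``t~ = (mean2 - mean1) / (s~ sqrt(1/n1 + 1/n2))``
referred to a t distribution on ``d_0 + d_g`` degrees of freedom.

Selection applies the dual criterion used throughout: Benjamini-Hochberg
q < 0.05 on the M-value test *and* an absolute group beta-difference
strictly greater than 0.2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import ValidationError


# ---------------------------------------------------------------------------
# hyperparameter estimation


def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration on 1/trigamma."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if -dif / y < 1e-10:
            break
    return float(y)


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of ``s2 ~ s0^2 F(df, d0)``.

    Returns ``(d0, s0^2)``; ``d0`` may be ``inf`` when the log-variances
    are under-dispersed relative to the chi-square expectation.
    Non-positive variances are excluded from the fit.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        raise ValidationError("need >= 2 positive variances to fit the prior")
    z = np.log(s2[ok])
    if np.ptp(z) == 0.0:
        # degenerate case: no dispersion of the variances at all — the
        # common variance IS the prior and shrinkage is a no-op
        return np.inf, float(s2[ok][0])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_sq = float(np.exp(
            emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
    return d0, s0_sq


# ---------------------------------------------------------------------------
# moderated t


@dataclass
class ModeratedTFit:
    """Result of a two-group moderated t fit, per-probe arrays in ``table``."""

    d0: float
    s0_sq: float
    n1: int
    n2: int
    reference: str
    test: str
    table: pd.DataFrame  # columns: mean_diff, s2, df_resid, s2_post, t, p


def _split_groups(labels, reference, test):
    labels = np.asarray(labels, dtype=object)
    groups = pd.unique(labels)
    if reference is None or test is None:
        if len(groups) != 2:
            raise ValidationError(
                f"expected exactly two groups, got {list(groups)}; "
                "pass reference= and test= explicitly")
        reference, test = groups[0], groups[1]
    g1 = labels == reference
    g2 = labels == test
    if g1.sum() < 2 or g2.sum() < 2:
        raise ValidationError("each group needs >= 2 samples")
    return g1, g2, reference, test


def fit_moderated_t(m_matrix: pd.DataFrame, labels, reference=None, test=None,
                    prior_df: float | None = None) -> ModeratedTFit:
    """Moderated two-sample t-test on an M-value matrix.

    Parameters
    ----------
    m_matrix
        probes x samples M-values, complete (no NaN).
    labels
        group label per column; the contrast is ``test - reference``.
    prior_df
        override the estimated prior degrees of freedom ``d_0``
        (``0`` recovers the ordinary pooled t exactly; ``inf`` a common
        variance z-like statistic).
    """
    if m_matrix.isna().any().any():
        raise ValidationError("M-value matrix contains NaN; handle upstream")
    g1, g2, reference, test = _split_groups(labels, reference, test)
    X = m_matrix.to_numpy(dtype=float)
    n1, n2 = int(g1.sum()), int(g2.sum())
    x1, x2 = X[:, g1], X[:, g2]
    mean_diff = x2.mean(axis=1) - x1.mean(axis=1)
    df_resid = n1 + n2 - 2
    ss = (x1.var(axis=1, ddof=1) * (n1 - 1) + x2.var(axis=1, ddof=1) * (n2 - 1))
    s2 = ss / df_resid

    if prior_df is None:
        d0, s0_sq = fit_f_dist(s2, df_resid)
    else:
        d0 = float(prior_df)
        s0_sq = fit_f_dist(s2, df_resid)[1] if d0 > 0 else 0.0
        if np.isinf(d0):
            s0_sq = float(np.exp(np.mean(np.log(s2[s2 > 0]))))

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2.copy()
        df_total = float(df_resid)
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean_diff / se
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    zero_var = se == 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} zero-variance probe(s) received no "
            "shrinkage (d0=0); their p-values are NaN", stacklevel=2)
        t = np.where(zero_var, np.nan, t)
        p = np.where(zero_var, np.nan, p)

    table = pd.DataFrame({
        "mean_diff": mean_diff, "s2": s2, "df_resid": float(df_resid),
        "s2_post": s2_post, "t": t, "p": p,
    }, index=m_matrix.index)
    return ModeratedTFit(d0=float(d0), s0_sq=float(s0_sq), n1=n1, n2=n2,
                         reference=str(reference), test=str(test), table=table)


# ---------------------------------------------------------------------------
# multiple testing, effect size, selection


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, reported in input order.

    NaN p-values propagate to NaN q-values (with a warning) and do not
    count toward the number of tests.
    """
    p = np.asarray(p_values, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if (~ok).any():
        warnings.warn(f"{int((~ok).sum())} NaN p-value(s) propagated",
                      stacklevel=2)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    qv = np.minimum.accumulate(ranked[::-1])[::-1]
    qv = np.clip(qv, 0.0, 1.0)
    out = np.empty(m)
    out[order] = qv
    q[ok] = out
    return q


def compute_delta_beta(beta_matrix: pd.DataFrame, labels, reference=None,
                       test=None, min_obs: int = 2) -> pd.Series:
    """Per-probe difference of group mean betas, ``test - reference``.

    Missing values are excluded pairwise; probes with fewer than
    ``min_obs`` observed values in either group get NaN with a warning.
    """
    g1, g2, reference, test = _split_groups(labels, reference, test)
    X = beta_matrix.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m1 = np.nanmean(X[:, g1], axis=1)
        m2 = np.nanmean(X[:, g2], axis=1)
    n1_obs = np.sum(~np.isnan(X[:, g1]), axis=1)
    n2_obs = np.sum(~np.isnan(X[:, g2]), axis=1)
    delta = m2 - m1
    thin = (n1_obs < min_obs) | (n2_obs < min_obs)
    if thin.any():
        warnings.warn(
            f"{int(thin.sum())} probe(s) with < {min_obs} observed values "
            "per group dropped from testing", stacklevel=2)
        delta[thin] = np.nan
    return pd.Series(delta, index=beta_matrix.index, name="delta_beta")


def build_dm_table(fit: ModeratedTFit, delta_beta: pd.Series) -> pd.DataFrame:
    """Combine a moderated-t fit with beta-scale effect sizes.

    Columns: ``t, p, q, delta_beta, direction`` (hyper = gain of
    methylation in the test group).
    """
    if not fit.table.index.equals(delta_beta.index):
        delta_beta = delta_beta.reindex(fit.table.index)
    q = adjust_bh(fit.table["p"].to_numpy())
    direction = np.where(delta_beta.to_numpy() >= 0, "hyper", "hypo")
    return pd.DataFrame({
        "t": fit.table["t"], "p": fit.table["p"], "q": q,
        "delta_beta": delta_beta.to_numpy(), "direction": direction,
    }, index=fit.table.index)


@dataclass
class SignatureSet:
    """Differentially methylated probes for one comparison, split by sign."""

    label: str
    hyper: list = field(default_factory=list)
    hypo: list = field(default_factory=list)

    @property
    def probes(self) -> list:
        return list(self.hyper) + list(self.hypo)

    def __len__(self) -> int:
        return len(self.hyper) + len(self.hypo)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "probe_id": self.probes,
            "direction": ["hyper"] * len(self.hyper) + ["hypo"] * len(self.hypo),
        })


def select_dm_cpgs(dm_table: pd.DataFrame, q_threshold: float = 0.05,
                   delta_threshold: float = 0.2,
                   annotation: pd.DataFrame | None = None,
                   exclude_snps: bool = False,
                   label: str = "signature") -> SignatureSet:
    """Apply the dual criterion q < 0.05 and |delta beta| > 0.2 (strict).

    A probe sitting exactly at |delta beta| = 0.2 is excluded. With
    ``exclude_snps`` the annotation's ``known_snp`` flag removes probes
    from the signature.
    """
    q = dm_table["q"].to_numpy(dtype=float)
    d = dm_table["delta_beta"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        keep = (q < q_threshold) & (np.abs(d) > delta_threshold)
    keep &= ~np.isnan(q) & ~np.isnan(d)
    if exclude_snps:
        if annotation is None:
            raise ValidationError("exclude_snps requires an annotation")
        snp = dm_table.index.isin(
            annotation.index[annotation["known_snp"]])
        keep &= ~snp
    idx = dm_table.index[keep]
    sign = d[keep] > 0
    return SignatureSet(label=label,
                        hyper=list(idx[sign]), hypo=list(idx[~sign]))


def signature_overlap(sig_a: SignatureSet, sig_b: SignatureSet) -> float:
    """Percentage of signature A's probes also present in signature B."""
    a = set(sig_a.probes)
    if not a:
        raise ValidationError(
            f"signature {sig_a.label!r} is empty; overlap undefined")
    b = set(sig_b.probes)
    return 100.0 * len(a & b) / len(a)
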