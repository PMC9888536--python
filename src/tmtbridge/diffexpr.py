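"""Per-protein differential abundance with empirical-Bayes variance moderation.

A one-way fixed-effects layout over the growth conditions is fitted to the
log2-normalized matrix (bridges excluded): the condition mean is the replicate
average and the residual variance s_g^2 is pooled within conditions with
d_g = n_samples - n_conditions degrees of freedom (12 for the reference
18-sample / 6-condition layout).  No batch covariate is included because IRS
has already removed the protein-specific batch term.

The per-protein variances are shrunk toward a prior (d0, s0^2) estimated from
all proteins by moment matching on the log variances: with
e_g = ln s_g^2 - psi(d_g/2) + ln(d_g/2), the prior degrees of freedom solve
psi'(d0/2) = var(e) - psi'(d_g/2) (psi, psi' the digamma and trigamma
functions), and s0^2 = exp(mean(e) + psi(d0/2) - ln(d0/2)).  When the
variances are no more dispersed than sampling alone explains, d0 = +inf and
every protein is tested against the common variance.

The moderated statistic for contrast (a, b) is

    t = (mean_a - mean_b) / sqrt(s_post^2 * (1/n_a + 1/n_b)),
    s_post^2 = (d0*s0^2 + d_g*s_g^2) / (d0 + d_g),

with a two-sided p-value on d0 + d_g degrees of freedom (normal limit at
d0 = +inf).  P-values are Benjamini-Hochberg adjusted within each contrast.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .core_io import NormalizedMatrix, StudyDesign

__all__ = [
    "EbayesPriors",
    "fit_condition_means",
    "estimate_priors",
    "moderated_test",
    "bh_adjust",
    "all_pairwise_contrasts",
    "contrast_name",
]


@dataclass
class EbayesPriors:
    """Moderation hyperparameters: prior df (may be +inf) and prior variance.

    ``d0 = 0`` is the no-moderation limit (ordinary pooled-variance t);
    ``d0 = +inf`` tests every protein against the common variance ``s0_sq``.
    """

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not self.d0 >= 0:
            raise ValueError("prior degrees of freedom must be >= 0")
        if not self.s0_sq > 0:
            raise ValueError("prior variance must be > 0")


def contrast_name(a: str, b: str) -> str:
    return f"{a}_vs_{b}"


def fit_condition_means(norm: NormalizedMatrix, design: StudyDesign):
    """One-way OLS fit: condition means, pooled residual variance, residual df.

    Returns ``(means, s2, d_g)`` with ``means`` proteins x conditions,
    ``s2`` the pooled within-condition variance per protein, and
    ``d_g = n_samples - n_conditions``.
    """
    conds = list(design.conditions)
    groups = {}
    for cond in conds:
        cols = design.samples_of(cond)
        if len(cols) < 2:
            raise ValueError(f"condition {cond!r} has {len(cols)} replicate(s); need >= 2")
        groups[cond] = cols
    n_samples = sum(len(c) for c in groups.values())
    d_g = n_samples - len(conds)

    data = norm.data
    means = pd.DataFrame({c: data[cols].mean(axis=1) for c, cols in groups.items()})
    rss = pd.Series(0.0, index=data.index)
    for cond, cols in groups.items():
        resid = data[cols].sub(means[cond], axis=0)
        rss = rss + (resid ** 2).sum(axis=1)
    s2 = rss / d_g
    return means, s2, d_g


def _trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    trigamma is strictly decreasing on (0, inf), so the root is unique.
    """
    if y <= 0:
        raise ValueError("trigamma target must be > 0")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if -dif / x < tol:
            return x
    raise RuntimeError(f"trigamma inversion did not converge for y={y!r} (last x={x!r})")


def estimate_priors(s2, d_g: int) -> EbayesPriors:
    """Moment-matching estimate of the variance prior from all proteins."""
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    n = s2.size
    if n < 10:
        raise ValueError(f"need >= 10 finite positive variances, got {n}")
    half = d_g / 2.0
    e = np.log(s2) - special.digamma(half) + math.log(half)
    e_bar = float(e.mean())
    e_var = float(np.mean((e - e_bar) ** 2) * n / (n - 1))
    target = e_var - float(special.polygamma(1, half))
    if target <= 0:
        return EbayesPriors(d0=math.inf, s0_sq=math.exp(e_bar))
    d0 = 2.0 * _trigamma_inverse(target)
    s0_sq = math.exp(e_bar + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    return EbayesPriors(d0=d0, s0_sq=s0_sq)


def moderated_test(means, s2, d_g: int, priors: EbayesPriors, contrast, design: StudyDesign):
    """Moderated t-test of one pairwise contrast.

    Returns a DataFrame (per protein) with logFC, t, df, p for contrast
    ``(a, b)`` where logFC = mean_a - mean_b.  ``priors.d0 = 0`` is accepted
    as the no-moderation limit (ordinary pooled-variance t).
    """
    a, b = contrast
    for cond in (a, b):
        if cond not in means.columns:
            raise KeyError(f"condition {cond!r} not fitted")
    n_a = len(design.samples_of(a))
    n_b = len(design.samples_of(b))
    d0, s0 = priors.d0, priors.s0_sq
    s2 = np.asarray(s2, dtype=float)
    if math.isinf(d0):
        s_post = np.full_like(s2, s0)
        df_total = math.inf
    else:
        s_post = (d0 * s0 + d_g * s2) / (d0 + d_g)
        df_total = d0 + d_g
    logfc = means[a] - means[b]
    se = np.sqrt(s_post * (1.0 / n_a + 1.0 / n_b))
    t = logfc / se
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return pd.DataFrame(
        {"logFC": logfc, "t": t, "df": df_total, "p": p}, index=means.index
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be finite and within [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def all_pairwise_contrasts(norm: NormalizedMatrix, design: StudyDesign,
                           priors: EbayesPriors | None = None) -> pd.DataFrame:
    """Moderated tests for every unordered condition pair, BH within contrast.

    Each unordered pair is computed once in declared condition order, so
    logFC(a vs b) = -logFC(b vs a) holds by construction.  Returns a tidy
    table: protein, contrast, cond_a, cond_b, logFC, t, df, p, fdr.
    """
    means, s2, d_g = fit_condition_means(norm, design)
    if priors is None:
        priors = estimate_priors(s2, d_g)
    frames = []
    for a, b in itertools.combinations(design.conditions, 2):
        res = moderated_test(means, s2, d_g, priors, (a, b), design)
        res = res.assign(
            contrast=contrast_name(a, b), cond_a=a, cond_b=b, fdr=bh_adjust(res["p"])
        )
        frames.append(res.reset_index())
    out = pd.concat(frames, ignore_index=True)
    return out[["protein", "contrast", "cond_a", "cond_b", "logFC", "t", "df", "p", "fdr"]]
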