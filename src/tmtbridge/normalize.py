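"""Three-step normalization cascade for multi-batch TMT data.

1. **Sample Loading (SL)** -- equal total protein was labeled in every
   channel, so each channel is rescaled to make its column sum equal to the
   grand mean of column sums (applied per batch, bridges included).
2. **Internal Reference Scaling (IRS)** -- the pooled bridge channels are
   identical material in every batch, so for each protein the per-batch
   bridge mean is scaled to the geometric mean of the bridge means across
   batches; this removes protein-specific batch effects.
3. **Trimmed mean of M-values (TMM)** -- a compositional scale factor per
   channel estimated from a doubly trimmed, precision-weighted mean of
   log-ratios against a reference channel, under the assumption that most
   proteins are not differentially abundant.

The final working matrix is log2-transformed; complete-case values are
strictly positive so no pseudocount is needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core_io import IntensityMatrix, NormalizedMatrix, StudyDesign, complete_case_filter

__all__ = [
    "NormalizationFactors",
    "sample_loading_normalize",
    "irs_normalize",
    "tmm_factors",
    "tmm_normalize",
    "normalize_pipeline",
]


@dataclass
class NormalizationFactors:
    """One normalization step's scale factors and the reference they target.

    ``factors`` is a per-channel Series for SL/TMM and a per-protein-per-batch
    DataFrame for IRS.  Factors are multiplicative on the linear intensity
    scale and strictly positive.
    """

    step: str
    factors: object
    reference: str
    extra: dict = field(default_factory=dict)


def sample_loading_normalize(matrix: IntensityMatrix):
    """Scale each channel so its column sum equals the grand mean of sums."""
    sums = matrix.data.sum(axis=0, skipna=False)
    if (sums == 0).any() or sums.isna().any():
        bad = sums.index[(sums == 0) | sums.isna()][0]
        raise ValueError(f"channel {bad!r} has zero or undefined column sum")
    factors = sums.mean() / sums
    out = IntensityMatrix(matrix.batch_id, matrix.data * factors)
    rec = NormalizationFactors("SL", factors, reference="grand mean of column sums")
    return out, rec


def irs_normalize(matrices, design: StudyDesign):
    """Equalize per-protein bridge means across batches (geometric-mean target).

    Input: per-batch matrices restricted to a shared complete-case protein set
    (columns are the raw channel labels of each batch).  For protein ``p`` and
    batch ``b`` the arithmetic mean of p's bridge channels, bridge_mean(p, b),
    is computed; every intensity of ``p`` in ``b`` is multiplied by
    geometric_mean_over_batches(bridge_mean(p, .)) / bridge_mean(p, b).  After
    the step the bridge means of every protein agree across batches.

    Proteins with a zero bridge mean in any batch are dropped with a warning
    (listed in the returned factor record's ``extra['dropped']``).

    Returns the merged matrix (columns '<batch>.<channel>') and the factor
    record whose ``factors`` DataFrame is proteins x batches.
    """
    by_batch = {m.batch_id: m for m in matrices}
    batches = design.batches
    if sorted(by_batch) != batches:
        raise ValueError(f"matrices cover {sorted(by_batch)}, design declares {batches}")
    proteins = by_batch[batches[0]].protein_ids
    for b in batches[1:]:
        if not proteins.equals(by_batch[b].protein_ids):
            raise ValueError("per-batch matrices must share an identical protein index")

    bridge_means = pd.DataFrame(
        {b: by_batch[b].data[design.channels(b, bridges="only")].mean(axis=1) for b in batches}
    )
    dropped = list(bridge_means.index[(~(bridge_means > 0)).any(axis=1)])  # <= 0 or NaN
    if dropped:
        warnings.warn(f"dropping {len(dropped)} protein(s) with zero bridge mean", stacklevel=2)
        bridge_means = bridge_means.drop(index=dropped)
    reference = np.exp(np.log(bridge_means).mean(axis=1))  # geometric mean across batches
    factors = reference.to_frame().values / bridge_means  # proteins x batches

    blocks = []
    for b in batches:
        block = by_batch[b].data.drop(index=dropped).mul(factors[b], axis=0)
        block.columns = [f"{b}.{c}" for c in block.columns]
        blocks.append(block)
    merged = IntensityMatrix("+".join(batches), pd.concat(blocks, axis=1))
    post_means = pd.DataFrame({
        b: merged.data[[f"{b}.{c}" for c in design.channels(b, bridges="only")]].mean(axis=1)
        for b in batches
    })
    post_dev = float(((post_means.max(axis=1) - post_means.min(axis=1))
                      / post_means.mean(axis=1)).max()) if len(post_means) else 0.0
    rec = NormalizationFactors(
        "IRS", factors, reference="geometric mean of per-batch bridge means",
        extra={"dropped": dropped, "bridge_max_rel_disagreement": post_dev},
    )
    return merged, rec


def _tmm_column_factor(y_k, y_r, N_k, N_r, trim_M, trim_A):
    """Single-column TMM factor against the reference column (log2 scale)."""
    p_k, p_r = y_k / N_k, y_r / N_r
    M = np.log2(p_k / p_r)
    A = 0.5 * np.log2(p_k * p_r)
    # binomial-variance precision weights evaluated on proportions (unit
    # depth): intensities carry no natural count scale, and this keeps the
    # factors invariant under global rescaling of any column
    v = (1.0 - p_k) / p_k + (1.0 - p_r) / p_r
    n = len(M)
    lo_M = np.floor(n * trim_M) + 1
    hi_M = n + 1 - lo_M
    lo_A = np.floor(n * trim_A) + 1
    hi_A = n + 1 - lo_A
    rM = rankdata(M)  # average ranks: midpoint tie-breaking
    rA = rankdata(A)
    keep = (rM >= lo_M) & (rM <= hi_M) & (rA >= lo_A) & (rA <= hi_A)
    if keep.sum() < 2:
        warnings.warn("fewer than 2 proteins survive TMM trimming; using untrimmed mean",
                      stacklevel=3)
        keep = np.ones(n, dtype=bool)
    v = np.where(v <= 0, np.finfo(float).tiny, v)
    f = np.sum(M[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(f)


def tmm_factors(matrix: IntensityMatrix, trim_M: float = 0.30, trim_A: float = 0.05):
    """Per-channel TMM scale factors, rescaled to geometric mean 1.

    The reference channel is the one whose 75th-percentile proportion
    (intensity / column sum) is closest to the mean of 75th percentiles.
    Rows in the top/bottom ``trim_M`` quantiles of the log-ratio M or
    ``trim_A`` quantiles of the average log-abundance A are trimmed; the
    factor is 2**(precision-weighted mean of surviving M values).
    """
    y = matrix.data.to_numpy(dtype=float)
    if np.any(~np.isfinite(y)) or np.any(y <= 0):
        raise ValueError("TMM requires a complete, strictly positive matrix")
    N = y.sum(axis=0)
    p = y / N
    q75 = np.quantile(p, 0.75, axis=0)
    ref = int(np.argmin(np.abs(q75 - q75.mean())))
    logf = np.array([
        0.0 if k == ref
        else _tmm_column_factor(y[:, k], y[:, ref], N[k], N[ref], trim_M, trim_A)
        for k in range(y.shape[1])
    ])
    factors = np.power(2.0, logf)
    factors = factors / np.exp(np.mean(np.log(factors)))  # geometric mean 1
    rec = NormalizationFactors(
        "TMM",
        pd.Series(factors, index=matrix.channel_ids),
        reference=f"column {matrix.channel_ids[ref]!r} (75th-percentile rule)",
        extra={"trim_M": trim_M, "trim_A": trim_A},
    )
    return rec


def tmm_normalize(matrix: IntensityMatrix, trim_M: float = 0.30, trim_A: float = 0.05):
    """Apply TMM: divide each column by its factor times its column-sum scale.

    The column-sum scale (column sum / grand mean of column sums) keeps the
    output on the original intensity magnitude while making effective totals
    equal; after SL the column sums are already equal, so the factor term
    dominates.
    """
    rec = tmm_factors(matrix, trim_M=trim_M, trim_A=trim_A)
    sums = matrix.data.sum(axis=0)
    scale = rec.factors * (sums / sums.mean())
    out = IntensityMatrix(matrix.batch_id, matrix.data / scale)
    return out, rec


def normalize_pipeline(
    matrices,
    design: StudyDesign,
    apply_irs: bool = True,
    apply_tmm: bool = True,
    trim_M: float = 0.30,
    trim_A: float = 0.05,
):
    """Complete-case filter, then SL per batch -> IRS across batches -> TMM -> log2.

    Returns (:class:`NormalizedMatrix`, filter report).  Bridge channels are
    carried through (flagged via the design) so bridge agreement can be
    checked downstream, but they are excluded from the statistics modules.
    """
    merged, report = complete_case_filter(matrices, design)
    steps = []

    per_batch = []
    for batch in design.batches:
        cols = [f"{batch}.{c}" for c in design.channels(batch)]
        block = merged.data[cols].copy()
        block.columns = design.channels(batch)
        sl, rec = sample_loading_normalize(IntensityMatrix(batch, block))
        rec.factors.index = pd.Index(cols)
        steps.append(rec)
        per_batch.append(sl)

    if apply_irs:
        combined, irs_rec = irs_normalize(per_batch, design)
        steps.append(irs_rec)
    else:
        blocks = []
        for m in per_batch:
            block = m.data.copy()
            block.columns = [f"{m.batch_id}.{c}" for c in block.columns]
            blocks.append(block)
        combined = IntensityMatrix("+".join(design.batches), pd.concat(blocks, axis=1))

    if apply_tmm:
        combined, tmm_rec = tmm_normalize(combined, trim_M=trim_M, trim_A=trim_A)
        steps.append(tmm_rec)

    log2 = np.log2(combined.data)
    norm = NormalizedMatrix(log2, design, applied_steps=steps)
    return norm, report
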