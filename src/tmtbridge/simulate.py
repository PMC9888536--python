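"""Synthetic two-batch TMT datasets with known ground truth.

The generator emulates the study design the package targets: 6 growth
conditions x 3 biological replicates = 18 samples, split into two TMT batches
of 9 samples each, plus 2 bridge channels per batch.  Each bridge is the
pooled mixture (on the linear intensity scale -- a pool mixes mass, not logs)
of all 18 biological samples.  The signal model on the log2 scale is

    log2 intensity = baseline + condition effect + batch effect
                     + channel loading + noise

with a protein-specific batch effect identical for every channel of a batch
(exactly the structure bridge-based Internal Reference Scaling removes), a
channel-specific loading factor common to all proteins (what Sample Loading
normalization removes), and i.i.d. multiplicative log-normal measurement
noise.  Dropout (failure to quantify) is applied independently per
(protein, channel).

Regulated proteins follow named archetypes mirroring the expression patterns
the downstream set selectors look for (fermentation-specific up/down, electron
donor specific, electron acceptor specific); constitutive proteins have all
condition effects equal to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import BRIDGE, CONDITIONS, IntensityMatrix, StudyDesign

__all__ = ["ARCHETYPES", "SimConfig", "SimTruth", "simulate_dataset", "truth_contrast_table"]

#: archetype -> set of conditions carrying the (signed) effect
ARCHETYPES: dict = {
    "constitutive": {},
    "py-only-up": {"Py-only": +1.0},
    "py-only-down": {"Py-only": -1.0},
    "h2-up": {"H2/Fu": +1.0, "H2/ClOHPA": +1.0},
    "lactate-up": {"La/Fu": +1.0, "La/ClOHPA": +1.0},
    "clohpa-up": {"H2/ClOHPA": +1.0, "La/ClOHPA": +1.0},
}

#: TMT 11-plex reporter tags, in elution order.
TMT11_TAGS = ("126", "127N", "127C", "128N", "128C", "129N", "129C", "130N", "130C", "131N", "131C")


def _default_fractions() -> dict:
    # 5 regulated archetypes at 2% each -> 10% regulated overall.
    return {a: 0.02 for a in ARCHETYPES if a != "constitutive"}


@dataclass
class SimConfig:
    """Parameters of the synthetic two-batch TMT experiment.

    All magnitudes are on the log2 scale unless noted.  Defaults describe a
    realistic bacterial TMT experiment at desk scale (2000 proteins; the
    paper-scale proteome would be ~4851).
    """

    n_proteins: int = 2000
    conditions: tuple = CONDITIONS
    n_replicates: int = 3
    n_bridges_per_batch: int = 2
    fraction_regulated: dict = field(default_factory=_default_fractions)
    effect_size_log2: float = 1.5
    baseline_mean_log2: float = 20.0
    baseline_sd_log2: float = 2.0
    noise_sd_log2: float = 0.25
    channel_loading_sd_log2: float = 0.3
    batch_effect_sd_log2: float = 0.5
    dropout_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("noise_sd_log2", "channel_loading_sd_log2", "batch_effect_sd_log2",
                     "baseline_sd_log2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.dropout_rate <= 1:
            raise ValueError("dropout_rate must be in [0, 1]")
        total = sum(self.fraction_regulated.values())
        if not 0 <= total <= 1:
            raise ValueError("archetype fractions must sum to a value in [0, 1]")
        unknown = set(self.fraction_regulated) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetype(s) {sorted(unknown)}")
        if any(f < 0 for f in self.fraction_regulated.values()):
            raise ValueError("archetype fractions must be >= 0")
        n_cond = len(self.conditions)
        if (n_cond * self.n_replicates) % 2 != 0:
            raise ValueError("sample count must split evenly into two batches")


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset.

    ``effects`` holds the true log2 condition effect per protein x condition;
    ``archetype`` the per-protein pattern label; ``loadings`` the true log2
    channel loading per '<batch>.<channel>' column; ``batch_effects`` the true
    protein-specific log2 offset of batch 2 relative to batch 1.
    """

    archetype: pd.Series
    effects: pd.DataFrame
    baseline: pd.Series
    loadings: pd.Series
    batch_effects: pd.Series

    def regulated(self, a: str, b: str) -> pd.Series:
        """Boolean flag per protein: true |log2 FC| > 0 for contrast a vs b."""
        return (self.effects[a] - self.effects[b]).abs() > 0


def _sample_layout(design_rows: list, conditions, n_replicates: int) -> None:
    """Assign samples to the two batches, balanced across conditions.

    The first half of the conditions place replicates (1, 2) in batch 1 and
    replicate 3 in batch 2; the second half place replicate 1 in batch 1 and
    (2, 3) in batch 2.  Every condition therefore spans both batches, as a
    well-designed multi-plex experiment would arrange.
    """
    half = len(conditions) // 2
    for ci, cond in enumerate(conditions):
        for rep in range(1, n_replicates + 1):
            if ci < half:
                batch = "B1" if rep <= 2 else "B2"
            else:
                batch = "B1" if rep == 1 else "B2"
            design_rows.append((batch, cond, rep))


def _build_design(config: SimConfig) -> StudyDesign:
    rows: list = []
    _sample_layout(rows, config.conditions, config.n_replicates)
    per_batch: dict = {"B1": [], "B2": []}
    for batch, cond, rep in rows:
        per_batch[batch].append((cond, rep))
    records = []
    for batch in ("B1", "B2"):
        entries = per_batch[batch]
        n_total = len(entries) + config.n_bridges_per_batch
        if n_total > len(TMT11_TAGS):
            raise ValueError(
                f"batch {batch} needs {n_total} channels; only {len(TMT11_TAGS)} tags available"
            )
        tags = TMT11_TAGS[:n_total]
        for tag, (cond, rep) in zip(tags, entries):
            safe = cond.replace("/", "-")
            records.append((batch, tag, f"{safe}_r{rep}", cond, rep, False))
        for j in range(config.n_bridges_per_batch):
            tag = tags[len(entries) + j]
            records.append((batch, tag, f"bridge_{batch}_{j + 1}", BRIDGE, j + 1, True))
    table = pd.DataFrame(
        records, columns=["batch", "channel", "sample", "condition", "replicate", "is_bridge"]
    )
    return StudyDesign(table, conditions=config.conditions)


def simulate_dataset(config: SimConfig):
    """Draw one dataset: per-batch intensity matrices, design, and truth.

    Fully reproducible from ``config.seed``.  Linear-scale intensity is
    2**(baseline + condition effect + batch effect + channel loading + noise);
    bridge channels start from the arithmetic linear-scale mean of the 18
    biological true signals, then receive their own batch effect, loading and
    noise; dropout then masks each (protein, channel) cell independently.
    """
    rng = np.random.default_rng(config.seed)
    design = _build_design(config)
    proteins = pd.Index([f"P{i:05d}" for i in range(1, config.n_proteins + 1)], name="protein")

    # archetype assignment: deterministic counts, shuffled positions
    counts = {a: int(round(f * config.n_proteins)) for a, f in config.fraction_regulated.items()}
    labels = []
    for a, c in counts.items():
        labels += [a] * c
    labels += ["constitutive"] * (config.n_proteins - len(labels))
    labels = np.array(labels)
    rng.shuffle(labels)
    archetype = pd.Series(labels, index=proteins, name="archetype")

    effects = pd.DataFrame(0.0, index=proteins, columns=list(config.conditions))
    for a, pattern in ARCHETYPES.items():
        members = archetype.index[archetype == a]
        for cond, sign in pattern.items():
            effects.loc[members, cond] = sign * config.effect_size_log2

    baseline = pd.Series(
        rng.normal(config.baseline_mean_log2, config.baseline_sd_log2, config.n_proteins),
        index=proteins, name="baseline_log2",
    )
    batch_eff = pd.Series(
        rng.normal(0.0, config.batch_effect_sd_log2, config.n_proteins),
        index=proteins, name="batch2_effect_log2",
    )

    ann = design.column_annotation()
    loadings = pd.Series(
        rng.normal(0.0, config.channel_loading_sd_log2, len(ann)),
        index=ann.index, name="loading_log2",
    )

    # true linear signal of each biological sample (no nuisance, no noise)
    bio = ann[~ann["is_bridge"]]
    true_log2 = pd.DataFrame(
        {col: baseline + effects[row["condition"]] for col, row in bio.iterrows()}
    )
    bridge_true_linear = np.power(2.0, true_log2).mean(axis=1)  # pooled mixture

    matrices = []
    for batch in design.batches:
        chans = design.channels(batch)
        cols = {}
        for ch in chans:
            col = f"{batch}.{ch}"
            row = ann.loc[col]
            if row["is_bridge"]:
                sig = np.log2(bridge_true_linear)
            else:
                sig = baseline + effects[row["condition"]]
            log2_val = sig + loadings[col]
            if batch == "B2":
                log2_val = log2_val + batch_eff
            log2_val = log2_val + rng.normal(0.0, config.noise_sd_log2, config.n_proteins)
            cols[ch] = np.power(2.0, log2_val)
        data = pd.DataFrame(cols, index=proteins)
        if config.dropout_rate > 0:
            drop = rng.random(data.shape) < config.dropout_rate
            data = data.mask(drop)
        matrices.append(IntensityMatrix(batch, data))

    truth = SimTruth(
        archetype=archetype,
        effects=effects,
        baseline=baseline,
        loadings=loadings,
        batch_effects=batch_eff,
    )
    return matrices, design, truth


def truth_contrast_table(truth: SimTruth, conditions: tuple = CONDITIONS) -> pd.DataFrame:
    """True log2 fold-change per protein for every unordered condition pair.

    For conditions (a, b) in declared order, true logFC(a vs b) =
    effect_a - effect_b; 6 conditions yield C(6,2) = 15 contrasts.
    """
    out = {}
    conds = list(conditions)
    for i, a in enumerate(conds):
        for b in conds[i + 1:]:
            out[f"{a}_vs_{b}"] = truth.effects[a] - truth.effects[b]
    return pd.DataFrame(out, index=truth.effects.index)
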