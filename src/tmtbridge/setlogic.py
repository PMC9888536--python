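"""Regulated-protein set constructions over the pairwise contrast table.

The selectors implement the comparisons the study design calls for:

* ``select`` -- simple thresholding of one contrast (|logFC| beyond a cutoff
  and FDR below a cutoff; strict inequalities, boundary values excluded);
* ``any_vs_all_partition`` -- a focal condition against each of the others,
  yielding the Venn union (up vs >= 1 other) and intersection (up vs all);
* ``quadrant_select`` -- joint classification in two parallel contrasts
  sharing orientation (both-up / both-down / mixed), the scatter-plot
  quadrant view;
* ``strict_group_select`` -- proteins up in every A x B cross-contrast for
  two disjoint condition groups.

``fold_change_format`` renders log2 fold-changes the way the study's tables
print them: linear ratio, nearest integer at >= 2, one decimal below.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffexpr import contrast_name

__all__ = [
    "SelectionRule",
    "SelectionSet",
    "get_contrast",
    "select",
    "any_vs_all_partition",
    "quadrant_select",
    "strict_group_select",
    "fold_change_format",
]


@dataclass(frozen=True)
class SelectionRule:
    """Thresholds for calling a protein regulated in one contrast."""

    logfc_threshold: float = 1.0
    fdr_threshold: float = 0.05
    direction: str = "up"

    def __post_init__(self) -> None:
        if not self.logfc_threshold > 0:
            raise ValueError("logfc_threshold must be > 0")
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must be in (0, 1)")
        if self.direction not in {"up", "down", "both"}:
            raise ValueError("direction must be 'up', 'down' or 'both'")

    def flipped(self) -> "SelectionRule":
        d = {"up": "down", "down": "up", "both": "both"}[self.direction]
        return SelectionRule(self.logfc_threshold, self.fdr_threshold, d)


@dataclass
class SelectionSet:
    """A named, reproducible protein set with its defining contrasts and rule."""

    name: str
    contrasts: tuple
    rule: SelectionRule
    members: frozenset

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, protein) -> bool:
        return protein in self.members


def get_contrast(contrasts: pd.DataFrame, a: str, b: str) -> pd.DataFrame:
    """Rows of contrast (a vs b), flipping sign if stored as (b vs a)."""
    name = contrast_name(a, b)
    rows = contrasts[contrasts["contrast"] == name]
    if not rows.empty:
        return rows.set_index("protein")
    rows = contrasts[contrasts["contrast"] == contrast_name(b, a)]
    if rows.empty:
        raise KeyError(f"contrast {name!r} not present in table")
    rows = rows.set_index("protein").copy()
    rows["logFC"] = -rows["logFC"]
    rows["t"] = -rows["t"]
    rows["contrast"] = name
    rows[["cond_a", "cond_b"]] = rows[["cond_b", "cond_a"]].to_numpy()
    return rows


def _passes(rows: pd.DataFrame, rule: SelectionRule) -> pd.Series:
    sig = rows["fdr"] < rule.fdr_threshold
    if rule.direction == "up":
        mag = rows["logFC"] > rule.logfc_threshold
    elif rule.direction == "down":
        mag = rows["logFC"] < -rule.logfc_threshold
    else:
        mag = rows["logFC"].abs() > rule.logfc_threshold
    return sig & mag


def select(contrasts: pd.DataFrame, contrast, rule: SelectionRule) -> SelectionSet:
    """Proteins passing the rule in one contrast ``(a, b)``."""
    a, b = contrast
    rows = get_contrast(contrasts, a, b)
    members = frozenset(rows.index[_passes(rows, rule)])
    return SelectionSet(contrast_name(a, b), (contrast_name(a, b),), rule, members)


@dataclass
class AnyVsAllPartition:
    union: SelectionSet
    per_comparison: dict
    intersection: SelectionSet


def any_vs_all_partition(contrasts: pd.DataFrame, focal: str, others,
                         rule: SelectionRule) -> AnyVsAllPartition:
    """Focal condition vs each other condition: Venn union and intersection."""
    others = list(others)
    if not others:
        raise ValueError("'others' must be non-empty")
    if focal in others:
        raise ValueError(f"focal condition {focal!r} cannot appear among others")
    per = {o: select(contrasts, (focal, o), rule) for o in others}
    union = frozenset().union(*(s.members for s in per.values()))
    inter = frozenset.intersection(*(s.members for s in per.values()))
    names = tuple(contrast_name(focal, o) for o in others)
    return AnyVsAllPartition(
        union=SelectionSet(f"{focal}_vs_any", names, rule, union),
        per_comparison=per,
        intersection=SelectionSet(f"{focal}_vs_all", names, rule, inter),
    )


@dataclass
class QuadrantSelection:
    both_up: SelectionSet
    both_down: SelectionSet
    mixed: SelectionSet


def quadrant_select(contrasts: pd.DataFrame, pair1, pair2,
                    rule: SelectionRule) -> QuadrantSelection:
    """Joint classification in two parallel contrasts (scatter-plot quadrants).

    ``both_up`` passes the up-rule in both contrasts, ``both_down`` the
    down-rule in both; proteins significant in both but with opposite
    directions are classified ``mixed``.
    """
    if tuple(pair1) == tuple(pair2):
        raise ValueError("quadrant selection needs two distinct contrasts")
    up = SelectionRule(rule.logfc_threshold, rule.fdr_threshold, "up")
    down = up.flipped()
    names = (contrast_name(*pair1), contrast_name(*pair2))
    up1, up2 = (select(contrasts, p, up).members for p in (pair1, pair2))
    dn1, dn2 = (select(contrasts, p, down).members for p in (pair1, pair2))
    both_up = up1 & up2
    both_down = dn1 & dn2
    mixed = (up1 & dn2) | (dn1 & up2)
    return QuadrantSelection(
        both_up=SelectionSet("both_up", names, up, frozenset(both_up)),
        both_down=SelectionSet("both_down", names, down, frozenset(both_down)),
        mixed=SelectionSet("mixed", names, rule, frozenset(mixed)),
    )


def strict_group_select(contrasts: pd.DataFrame, group_a, group_b,
                        rule: SelectionRule) -> SelectionSet:
    """Proteins passing the up-rule in every (a in A) x (b in B) contrast."""
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both condition groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError("condition groups must be disjoint")
    up = SelectionRule(rule.logfc_threshold, rule.fdr_threshold, "up")
    sets = [select(contrasts, (a, b), up).members for a in group_a for b in group_b]
    names = tuple(contrast_name(a, b) for a in group_a for b in group_b)
    members = frozenset.intersection(*sets)
    return SelectionSet("+".join(group_a) + "_vs_group", names, up, members)


@dataclass(frozen=True)
class FoldChangeDisplay:
    """Linear-ratio rendering of a log2 fold-change, with a down flag."""

    text: str
    down: bool

    def __str__(self) -> str:
        return f"1/{self.text}" if self.down else self.text


def fold_change_format(logfc: float) -> FoldChangeDisplay:
    """Render a log2 fold-change as a linear ratio string.

    Ratios >= 2 print as the nearest integer (logFC 3.3 -> "10"); ratios
    below 2 keep one decimal ("1.8").  Negative log fold-changes render the
    inverse ratio with ``down=True``.
    """
    if not np.isfinite(logfc):
        raise ValueError("logFC must be finite")
    ratio = 2.0 ** abs(float(logfc))
    if ratio >= 2:
        text = str(int(round(ratio)))
    else:
        text = f"{ratio:.1f}"
    return FoldChangeDisplay(text=text, down=logfc < 0)
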