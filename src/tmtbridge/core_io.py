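"""Domain containers and tab-separated readers/writers for TMT reporter tables.

The pipeline starts from protein-level reporter-ion intensity tables, one per
TMT batch (plex): rows are protein accessions, columns are reporter channels,
values are non-negative intensities.  A reporter intensity of zero or an empty
cell both mean "not quantified in that channel" -- zero is not a usable
measurement, and the downstream analysis keeps only fully quantified proteins
(the complete-case set across every channel of every batch).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "BRIDGE",
    "IntensityMatrix",
    "StudyDesign",
    "NormalizedMatrix",
    "ParseError",
    "DesignError",
    "read_intensity_table",
    "write_intensity_table",
    "read_design",
    "write_design",
    "complete_case_filter",
]

#: The six growth conditions of the reference design (electron donor/acceptor
#: combinations for an organohalide-respiring anaerobe): pyruvate fermentation,
#: pyruvate/fumarate, lactate/fumarate, H2/fumarate, and the two organohalide
#: (ClOHPA) respiration conditions.
CONDITIONS = ("Py-only", "Py/Fu", "La/Fu", "H2/Fu", "H2/ClOHPA", "La/ClOHPA")

#: Condition label reserved for pooled bridge (reference) channels.
BRIDGE = "BRIDGE"

DESIGN_COLUMNS = ["batch", "channel", "sample", "condition", "replicate", "is_bridge"]


class ParseError(ValueError):
    """Malformed intensity or design table."""


class DesignError(ValueError):
    """Study design violates a structural invariant."""


@dataclass
class IntensityMatrix:
    """Protein x channel reporter intensities for one TMT batch.

    ``data`` is a float DataFrame indexed by protein accession with channel
    labels as columns; missing measurements are NaN, present values are > 0
    after validation (zeros are converted to NaN on read).
    """

    batch_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ParseError(f"duplicate protein accession {dup!r} in batch {self.batch_id!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ParseError(f"duplicate channel label {dup!r} in batch {self.batch_id!r}")
        vals = self.data.to_numpy(dtype=float)
        if np.any(vals[np.isfinite(vals)] < 0):
            r, c = np.argwhere((vals < 0) & np.isfinite(vals))[0]
            raise ParseError(
                f"negative intensity at protein {self.data.index[r]!r}, "
                f"channel {self.data.columns[c]!r} in batch {self.batch_id!r}"
            )
        self.data = self.data.astype(float)

    @property
    def protein_ids(self) -> pd.Index:
        return self.data.index

    @property
    def channel_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(self.batch_id, self.data.copy())


@dataclass
class StudyDesign:
    """Channel annotations: batch, tag, sample, condition, replicate, bridge flag.

    Bridge channels are pooled mixtures of all biological samples labeled in
    every batch; they carry ``condition == "BRIDGE"`` and ``is_bridge = True``.
    """

    table: pd.DataFrame
    conditions: tuple = CONDITIONS

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in DESIGN_COLUMNS if c not in t.columns]
        if missing:
            raise DesignError(f"design table lacks columns {missing}")
        t = t.loc[:, DESIGN_COLUMNS].copy()
        t["is_bridge"] = t["is_bridge"].astype(bool)
        t["replicate"] = t["replicate"].astype(int)
        for col in ("batch", "channel", "sample", "condition"):
            t[col] = t[col].astype(str)
        if t.duplicated(subset=["batch", "channel"]).any():
            raise DesignError("duplicate (batch, channel) row in design")
        known = set(self.conditions) | {BRIDGE}
        bad = sorted(set(t["condition"]) - known)
        if bad:
            raise DesignError(f"unknown condition label(s) {bad}")
        if (t["is_bridge"] != (t["condition"] == BRIDGE)).any():
            raise DesignError("is_bridge flag inconsistent with BRIDGE condition label")
        for batch, grp in t.groupby("batch"):
            if not grp["is_bridge"].any():
                raise DesignError(f"batch {batch!r} has no bridge channel")
        bio = t[~t["is_bridge"]]
        if bio.duplicated(subset=["batch", "sample"]).any():
            d = bio[bio.duplicated(subset=["batch", "sample"])].iloc[0]
            raise DesignError(f"duplicate (batch, sample) pair ({d['batch']!r}, {d['sample']!r})")
        if bio.duplicated(subset=["condition", "replicate"]).any():
            d = bio[bio.duplicated(subset=["condition", "replicate"])].iloc[0]
            raise DesignError(
                f"duplicate (condition, replicate) pair ({d['condition']!r}, {d['replicate']})"
            )
        self.table = t.reset_index(drop=True)

    @property
    def batches(self) -> list:
        return sorted(self.table["batch"].unique())

    @property
    def n_channels(self) -> int:
        return len(self.table)

    def channels(self, batch: str, bridges: str = "all") -> list:
        """Channel labels of one batch; ``bridges`` in {'all','only','none'}."""
        grp = self.table[self.table["batch"] == str(batch)]
        if bridges == "only":
            grp = grp[grp["is_bridge"]]
        elif bridges == "none":
            grp = grp[~grp["is_bridge"]]
        return list(grp["channel"])

    def merged_columns(self, bridges: str = "all") -> list:
        """Batch-qualified '<batch>.<channel>' labels in design order."""
        cols = []
        for batch in self.batches:
            cols += [f"{batch}.{ch}" for ch in self.channels(batch, bridges)]
        return cols

    def column_annotation(self) -> pd.DataFrame:
        """Design table indexed by the merged '<batch>.<channel>' label."""
        t = self.table.copy()
        t.index = pd.Index(t["batch"] + "." + t["channel"], name="column")
        return t

    def samples_of(self, condition: str) -> list:
        grp = self.table[(self.table["condition"] == condition) & ~self.table["is_bridge"]]
        return list(grp["batch"] + "." + grp["channel"])


@dataclass
class NormalizedMatrix:
    """Merged log2-scale protein x channel matrix with normalization provenance.

    Columns are batch-qualified '<batch>.<channel>' labels covering all
    channels (bridges retained for QC, flagged through the design).
    ``applied_steps`` records every normalization factor set in order.
    """

    data: pd.DataFrame
    design: StudyDesign
    applied_steps: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ValueError("normalized matrix must be complete (no missing values)")

    @property
    def protein_ids(self) -> pd.Index:
        return self.data.index

    def biological(self) -> pd.DataFrame:
        """Log2 matrix restricted to non-bridge channels."""
        return self.data.loc[:, self.design.merged_columns(bridges="none")]

    def bridges(self) -> pd.DataFrame:
        return self.data.loc[:, self.design.merged_columns(bridges="only")]


# ---------------------------------------------------------------------------
# TSV readers / writers


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)


def read_intensity_table(path, batch_id: str) -> IntensityMatrix:
    """Parse a tab-separated reporter table (first column = accession).

    Empty cells and zeros are recorded as missing; duplicate accessions,
    duplicate channel labels and negative values raise :class:`ParseError`
    naming the offending row/column.
    """
    raw = _read_tsv(path)
    if raw.shape[1] < 2:
        raise ParseError(f"{path}: need an accession column plus >=1 channel column")
    acc = raw.iloc[:, 0]
    body = raw.iloc[:, 1:]
    parsed = {}
    for col in body.columns:
        cells = body[col].str.strip()
        try:
            vals = pd.to_numeric(cells.replace("", np.nan))
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: non-numeric value in channel {col!r}: {exc}") from exc
        parsed[col] = vals
    data = pd.DataFrame(parsed)
    data.index = pd.Index(acc, name="protein")
    data = data.mask(data == 0)  # zero reporter intensity == not quantified
    return IntensityMatrix(str(batch_id), data)


def write_intensity_table(matrix: IntensityMatrix, path, header_comment: str | None = None) -> None:
    """Write a reporter table as TSV; missing values become empty cells."""
    buf = io.StringIO()
    if header_comment:
        buf.write(f"# {header_comment}\n")
    matrix.data.to_csv(buf, sep="\t", na_rep="")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def read_design(path, conditions: tuple = CONDITIONS) -> StudyDesign:
    """Parse and validate a study-design TSV (batch/channel/sample/condition/...)."""
    raw = _read_tsv(path)
    missing = [c for c in DESIGN_COLUMNS if c not in raw.columns]
    if missing:
        raise DesignError(f"{path}: design table lacks columns {missing}")
    t = raw.copy()
    t["is_bridge"] = t["is_bridge"].str.strip().str.lower().isin({"1", "true", "yes"})
    t["replicate"] = pd.to_numeric(t["replicate"]).astype(int)
    return StudyDesign(t, conditions=conditions)


def write_design(design: StudyDesign, path, header_comment: str | None = None) -> None:
    buf = io.StringIO()
    if header_comment:
        buf.write(f"# {header_comment}\n")
    out = design.table.copy()
    out["is_bridge"] = out["is_bridge"].astype(int)
    out.to_csv(buf, sep="\t", index=False)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# Complete-case filter


def complete_case_filter(matrices, design: StudyDesign):
    """Keep proteins with a positive intensity in every channel of every batch.

    Returns the merged matrix (columns '<batch>.<channel>') restricted to the
    complete-case set, plus a report dict with ``detected`` (union of protein
    ids over batches) and ``quantified`` (retained) counts.

    Raises ``ValueError`` when no protein is complete in all channels.
    """
    by_batch = {m.batch_id: m for m in matrices}
    if sorted(by_batch) != design.batches:
        raise DesignError(
            f"matrices cover batches {sorted(by_batch)} but design declares {design.batches}"
        )
    detected: set = set()
    blocks = []
    for batch in design.batches:
        m = by_batch[batch]
        want = design.channels(batch)
        missing_ch = [c for c in want if c not in m.channel_ids]
        if missing_ch:
            raise DesignError(f"batch {batch!r} matrix lacks design channels {missing_ch}")
        detected |= set(m.protein_ids)
        block = m.data.loc[:, want].copy()
        block.columns = [f"{batch}.{c}" for c in want]
        blocks.append(block)
    shared = blocks[0].index
    for block in blocks[1:]:
        shared = shared.intersection(block.index)
    merged = pd.concat([b.loc[shared] for b in blocks], axis=1)
    complete = merged.notna().all(axis=1) & (merged > 0).all(axis=1)
    retained = merged.loc[complete]
    if retained.empty:
        raise ValueError("no complete cases: every protein is missing in at least one channel")
    report = {
        "detected": len(detected),
        "quantified": int(complete.sum()),
        "channels": int(merged.shape[1]),
    }
    out = IntensityMatrix("+".join(design.batches), retained)
    return out, report
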