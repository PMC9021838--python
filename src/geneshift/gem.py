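"""Gene expression matrix (GEM) I/O, normalization and trajectory extraction.

A GEM is a genes x samples table of FPKM values read from tab-separated
text. Sample names (or an explicit sample sheet) encode the experimental
design: condition (e.g. control vs. rhizobia-treated), time point in hours
and biological replicate. Downstream clustering operates on per-replicate
trajectories -- one expression series per (gene, condition, replicate) over
the ordered time grid -- never on replicate averages.

Preprocessing follows the usual order for this kind of analysis:

1. unexpressed ("off") gene-condition profiles are flagged on the raw FPKM
   scale, where a profile counts as off when at least ``min_zero_replicates``
   replicates are exactly 0.00 at every measured time point;
2. quantile normalization equalizes the per-sample value distributions;
3. a log2(x + 1) transform stabilizes the variance.

The off test runs before normalization because quantile normalization does
not preserve exact zeros.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleMeta",
    "Trajectory",
    "ExpressionMatrix",
    "read_gem",
    "parse_sample_names",
    "quantile_normalize",
    "log_transform",
    "extract_off_genes",
    "build_trajectories",
]

#: sample-name tokens conventionally denoting the untreated condition
CONTROL_ALIASES = frozenset(
    {"control", "ctrl", "ctl", "mock", "uninoculated", "untreated"}
)


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one GEM column."""

    sample_id: str
    condition: str
    time: float
    replicate: int

    def __post_init__(self):
        if self.time < 0:
            raise ValueError(f"negative time for sample {self.sample_id!r}")
        if self.replicate < 1:
            raise ValueError(
                f"replicate index must be >= 1 for sample {self.sample_id!r}"
            )


@dataclass
class Trajectory:
    """One gene x condition x replicate expression series on the time grid."""

    gene_id: str
    condition: str
    replicate: int
    t: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.shape != self.y.shape:
            raise ValueError("time grid and values must have equal length")
        if len(self.t) and np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")


class ExpressionMatrix:
    """Validated genes x samples expression table with parsed design metadata.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by gene id, columns by sample id.
    samples : sequence of SampleMeta
        One entry per column, in column order.
    scale : {"fpkm", "quantile_log2"}
        Whether values are raw FPKM or quantile-normalized log2(x+1).
    """

    SCALES = ("fpkm", "quantile_log2")

    def __init__(self, values: pd.DataFrame, samples: Sequence[SampleMeta],
                 scale: str = "fpkm"):
        if scale not in self.SCALES:
            raise ValueError(f"unknown scale {scale!r}")
        values = values.copy()
        if list(values.columns) != [s.sample_id for s in samples]:
            raise ValueError("sample metadata does not match column order")
        if values.index.duplicated().any():
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene id: {dups}")
        if values.isna().any().any():
            bad = values.columns[values.isna().any()].tolist()
            raise ValueError(f"missing values in samples {bad}")
        arr = values.to_numpy(dtype=float)
        if scale == "fpkm" and (arr < 0).any():
            raise ValueError("negative values on FPKM scale")
        triples = [(s.condition, s.time, s.replicate) for s in samples]
        if len(set(triples)) != len(triples):
            raise ValueError("duplicate (condition, time, replicate) sample")
        self.values = values.astype(float)
        self.samples = list(samples)
        self.scale = scale
        self._validate_design()

    # -- design -----------------------------------------------------------
    def _validate_design(self):
        grids = {}
        for cond in self.conditions:
            sub = [s for s in self.samples if s.condition == cond]
            grids[cond] = (
                tuple(sorted({s.time for s in sub})),
                tuple(sorted({s.replicate for s in sub})),
            )
        if len({g for g in grids.values()}) > 1:
            raise ValueError(
                "conditions do not share an identical time grid / replicate "
                f"set: {grids}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.condition, None)
        return list(seen)

    @property
    def time_grid(self) -> np.ndarray:
        return np.array(sorted({s.time for s in self.samples}), dtype=float)

    @property
    def n_replicates(self) -> int:
        return len({s.replicate for s in self.samples
                    if s.condition == self.conditions[0]})

    def sample_columns(self, condition: str, replicate: int) -> list[SampleMeta]:
        """Columns of one (condition, replicate) profile, time-ordered."""
        sub = [s for s in self.samples
               if s.condition == condition and s.replicate == replicate]
        return sorted(sub, key=lambda s: s.time)

    def guess_control(self) -> str | None:
        """Return the condition whose name looks like a control, if any."""
        for cond in self.conditions:
            if cond.lower() in CONTROL_ALIASES:
                return cond
        return None

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", float_format="%.6g")

    def __repr__(self):  # pragma: no cover - cosmetic
        return (f"<ExpressionMatrix {self.values.shape[0]} genes x "
                f"{self.values.shape[1]} samples, scale={self.scale}>")


def _pattern_to_regex(label_pattern: str) -> re.Pattern:
    """Compile a ``{condition}_{time}h_r{rep}``-style template to a regex."""
    placeholders = {
        "{condition}": r"(?P<condition>[A-Za-z0-9]+?)",
        "{time}": r"(?P<time>\d+(?:\.\d+)?)",
        "{rep}": r"(?P<rep>\d+)",
    }
    out = ""
    i = 0
    while i < len(label_pattern):
        for ph, rx in placeholders.items():
            if label_pattern.startswith(ph, i):
                out += rx
                i += len(ph)
                break
        else:
            out += re.escape(label_pattern[i])
            i += 1
    for name in ("condition", "time", "rep"):
        if f"(?P<{name}>" not in out:
            raise ValueError(f"label_pattern is missing {{{name}}}")
    return re.compile("^" + out + "$")


def parse_sample_names(names: Iterable[str], label_pattern: str) -> list[SampleMeta]:
    """Parse condition/time/replicate out of sample names via a template.

    Raises ``ValueError`` naming the first sample that does not match.
    """
    rx = _pattern_to_regex(label_pattern)
    metas = []
    for name in names:
        m = rx.match(name)
        if m is None:
            raise ValueError(
                f"sample name {name!r} does not match pattern {label_pattern!r}"
            )
        metas.append(SampleMeta(sample_id=name,
                                condition=m.group("condition"),
                                time=float(m.group("time")),
                                replicate=int(m.group("rep"))))
    return metas


def read_gem(path, label_pattern: str = "{condition}_{time}h_r{rep}",
             sample_sheet=None) -> ExpressionMatrix:
    """Read a tab-separated GEM (first column gene id, header sample names).

    ``sample_sheet``, if given, is a TSV with columns sample_id, condition,
    time, replicate and overrides name parsing.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"ragged GEM file {path}: {exc}") from exc
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene id: {dups}")
    if sample_sheet is not None:
        sheet = pd.read_csv(sample_sheet, sep="\t")
        required = {"sample_id", "condition", "time", "replicate"}
        if not required.issubset(sheet.columns):
            raise ValueError(f"sample sheet must have columns {sorted(required)}")
        by_id = {r.sample_id: r for r in sheet.itertuples()}
        metas = []
        for name in df.columns:
            if name not in by_id:
                raise ValueError(f"sample {name!r} missing from sample sheet")
            r = by_id[name]
            metas.append(SampleMeta(name, str(r.condition), float(r.time),
                                    int(r.replicate)))
    else:
        metas = parse_sample_names(df.columns, label_pattern)
    return ExpressionMatrix(df, metas, scale="fpkm")


def quantile_normalize(gem: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize so every sample shares one value distribution.

    The reference distribution is the across-sample mean of the per-rank
    sorted values; ties within a sample receive the mean of the reference
    values over their tied ranks ("average ties" dialect). Idempotent.
    """
    if gem.values.size == 0:
        raise ValueError("cannot quantile-normalize an empty matrix")
    arr = gem.values.to_numpy(dtype=float)
    n, p = arr.shape
    ref = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(p):
        order = np.argsort(arr[:, j], kind="mergesort")
        col_sorted = arr[order, j]
        normed = ref.copy()
        start = 0
        while start < n:
            end = start + 1
            while end < n and col_sorted[end] == col_sorted[start]:
                end += 1
            if end - start > 1:
                normed[start:end] = ref[start:end].mean()
            start = end
        out[order, j] = normed
    df = pd.DataFrame(out, index=gem.values.index, columns=gem.values.columns)
    return ExpressionMatrix(df, gem.samples, scale=gem.scale)


def log_transform(gem: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Apply v -> log2(v + pseudocount); marks the matrix as analysis scale."""
    arr = gem.values.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("negative value in log transform input")
    df = pd.DataFrame(np.log2(arr + pseudocount), index=gem.values.index,
                      columns=gem.values.columns)
    out = ExpressionMatrix.__new__(ExpressionMatrix)
    out.values = df
    out.samples = list(gem.samples)
    out.scale = "quantile_log2"
    return out


def extract_off_genes(gem: ExpressionMatrix, condition: str,
                      min_zero_replicates: int = 1) -> tuple[set, set]:
    """Split genes into off vs. active sets for one condition.

    A gene is *off* (unexpressed) under a condition when at least
    ``min_zero_replicates`` of its replicates are exactly 0 FPKM at every
    measured time point. Runs on the raw FPKM scale, before normalization.

    Returns ``(off_gene_ids, active_gene_ids)``; the two sets partition the
    gene list.
    """
    if gem.scale != "fpkm":
        raise ValueError("off-gene extraction requires the raw FPKM scale")
    if condition not in gem.conditions:
        raise ValueError(f"condition {condition!r} not present in GEM")
    reps = sorted({s.replicate for s in gem.samples if s.condition == condition})
    zero_counts = np.zeros(len(gem.gene_ids), dtype=int)
    for rep in reps:
        cols = [s.sample_id for s in gem.sample_columns(condition, rep)]
        sub = gem.values[cols].to_numpy(dtype=float)
        zero_counts += (sub == 0).all(axis=1)
    mask = zero_counts >= min_zero_replicates
    genes = np.asarray(gem.gene_ids, dtype=object)
    off = set(genes[mask])
    return off, set(genes[~mask])


def build_trajectories(gem: ExpressionMatrix, genes: Iterable[str],
                       conditions: Sequence[str] | None = None) -> list[Trajectory]:
    """One Trajectory per (gene, condition, replicate), time-ordered.

    ``genes`` may be any iterable of gene ids present in the GEM; requesting
    an absent gene is an error. Expects the analysis (quantile_log2) scale.
    """
    if gem.scale != "quantile_log2":
        raise ValueError("trajectories are built on the quantile_log2 scale")
    genes = list(genes)
    missing = [g for g in genes if g not in gem.values.index]
    if missing:
        raise ValueError(f"genes absent from GEM: {missing}")
    conditions = list(conditions) if conditions is not None else gem.conditions
    t = gem.time_grid
    out: list[Trajectory] = []
    for cond in conditions:
        reps = sorted({s.replicate for s in gem.samples if s.condition == cond})
        for rep in reps:
            cols = [s.sample_id for s in gem.sample_columns(cond, rep)]
            sub = gem.values.loc[genes, cols].to_numpy(dtype=float)
            for gi, g in enumerate(genes):
                out.append(Trajectory(g, cond, rep, t, sub[gi]))
    return out
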