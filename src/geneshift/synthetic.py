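"""Synthetic GEM generator with known trajectory truth.

Emulates the experimental design the workflow targets -- five ordered time
points (0, 12, 24, 48, 72 h), three biological replicates, two conditions
-- with a parametric library of temporal shapes drawn from the pattern
families seen in real time-course data (late induction, early induction,
transient peaks, monotone decay, dip-and-recover, flat low/high). Each
gene-condition profile is either OFF (exact 0.00 FPKM in every replicate
at every time point) or a shape mean plus i.i.d. Gaussian noise on the
log2(FPKM+1) scale, mapped back to FPKM by 2^x - 1 (clipped at 0), so the
analysis-scale noise model is exactly the stated Gaussian.

Condition-dependent pattern shifts are injected by construction:

    A  control OFF, treated dynamic
    B  control dynamic, treated OFF
    C  control and treated drawn from two different shapes

with the remaining genes either off in both conditions or sharing one
shape (non-shift). Replicate discordance -- the failure mode replicate
sorting is designed to catch -- is modelled as a whole-replicate swap:
with probability ``replicate_discordance_prob`` per dynamic gene-condition
profile, one randomly chosen replicate is drawn from a different shape.

Everything is deterministic given the seed, down to byte-identical TSV
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .gem import ExpressionMatrix, SampleMeta

__all__ = ["SyntheticConfig", "SyntheticTruth", "make_shape_library",
           "generate_gem", "null_config"]

DEFAULT_TIME_GRID = (0.0, 12.0, 24.0, 48.0, 72.0)

#: ordered parametric shape slots; (name, builder) over normalized time s in [0,1]
_SHAPE_SLOTS = (
    "late_up", "early_up", "transient_peak_24", "transient_peak_48",
    "monotone_down", "down_then_up", "flat_low", "flat_high",
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults mirror the targeted study design."""

    n_genes: int = 500
    time_grid: tuple = DEFAULT_TIME_GRID
    m_replicates: int = 3
    n_shapes: int = 7
    frac_off_control: float = 0.30
    frac_off_treated: float = 0.30
    frac_shift_A: float = 0.05
    frac_shift_B: float = 0.03
    frac_shift_C: float = 0.02
    noise_sd: float = 0.1
    replicate_discordance_prob: float = 0.05
    seed: int = 0

    def __post_init__(self):
        fr = (self.frac_off_control, self.frac_off_treated, self.frac_shift_A,
              self.frac_shift_B, self.frac_shift_C)
        if any(f < 0 for f in fr):
            raise ValueError("fractions must be non-negative")
        if self.frac_shift_A + self.frac_shift_B + self.frac_shift_C \
                + max(self.frac_off_control, self.frac_off_treated) > 1:
            raise ValueError("off/shift fractions sum above 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.replicate_discordance_prob <= 1:
            raise ValueError("replicate_discordance_prob must be in [0, 1]")
        if len(self.time_grid) < 2 or np.any(np.diff(self.time_grid) <= 0):
            raise ValueError("time_grid must be strictly increasing")


@dataclass
class SyntheticTruth:
    """Ground truth for one generated GEM."""

    control_shape: dict      # gene -> shape id or None (OFF)
    treated_shape: dict      # gene -> shape id or None (OFF)
    category: dict           # gene -> shift category string
    trajectory_shape: dict   # (gene, condition, replicate) -> shape id or None

    def shift_genes(self) -> set:
        return {g for g, c in self.category.items()
                if c in ("A_off_to_dynamic", "B_dynamic_to_off",
                         "C_dynamic_to_dynamic")}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in sorted(self.category):
            rows.append({
                "gene_id": g,
                "control_shape": self._fmt(self.control_shape[g]),
                "treated_shape": self._fmt(self.treated_shape[g]),
                "category": self.category[g],
            })
        return pd.DataFrame(rows)

    @staticmethod
    def _fmt(v):
        return "OFF" if v is None else f"shape{v}"

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def make_shape_library(n_shapes: int = 7, time_grid=DEFAULT_TIME_GRID,
                       seed: int | None = None,
                       baseline: float = 1.0,
                       amplitude: float = 4.0) -> np.ndarray:
    """Parametric mean-trajectory library on the log2(FPKM+1) scale.

    Shapes are deterministic functions of the time grid drawn in a fixed
    family order (late-up, early-up, transient peaks, monotone down,
    down-then-up, flat low, flat high); ``seed`` is accepted for interface
    symmetry but the library itself is not randomized. Requesting more
    shapes than there are parameter slots is an error. Pairwise L2
    separations comfortably exceed several times the default noise sd.
    """
    if n_shapes < 2:
        raise ValueError("need at least 2 shapes")
    if n_shapes > len(_SHAPE_SLOTS):
        raise ValueError(
            f"n_shapes={n_shapes} exceeds the {len(_SHAPE_SLOTS)} available "
            "parameter slots")
    t = np.asarray(time_grid, dtype=float)
    s = (t - t[0]) / (t[-1] - t[0])
    lo, hi = baseline, baseline + amplitude

    def bump(center, width=0.18):
        return np.exp(-((s - center) ** 2) / (2 * width ** 2))

    builders = {
        "late_up": lo + amplitude * s ** 3,
        "early_up": lo + amplitude * (1 - np.exp(-6 * s)),
        "transient_peak_24": lo + amplitude * bump(s[np.searchsorted(t, 24.0)]
                                                   if 24.0 in t else 1 / 3),
        "transient_peak_48": lo + amplitude * bump(s[np.searchsorted(t, 48.0)]
                                                   if 48.0 in t else 2 / 3),
        "monotone_down": hi - amplitude * s ** 0.7,
        "down_then_up": hi - amplitude * bump(0.35, 0.25),
        "flat_low": np.full_like(s, lo),
        "flat_high": np.full_like(s, hi),
    }
    lib = np.array([builders[name] for name in _SHAPE_SLOTS[:n_shapes]])
    return lib


def _allocate(cfg: SyntheticConfig) -> dict[str, int]:
    n = cfg.n_genes
    nA = round(cfg.frac_shift_A * n)
    nB = round(cfg.frac_shift_B * n)
    nC = round(cfg.frac_shift_C * n)
    need_off_c = max(0, round(cfg.frac_off_control * n) - nA)
    need_off_t = max(0, round(cfg.frac_off_treated * n) - nB)
    n_off_both = min(need_off_c, need_off_t)
    n_non_shift = n - nA - nB - nC - n_off_both
    if n_non_shift < 0:
        raise ValueError("fractions leave no room for non-shift genes")
    return {"A": nA, "B": nB, "C": nC, "off_both": n_off_both,
            "non_shift": n_non_shift}


def null_config(**overrides) -> SyntheticConfig:
    """Config with no injected shifts and no off profiles (the null)."""
    base = SyntheticConfig(frac_off_control=0.0, frac_off_treated=0.0,
                           frac_shift_A=0.0, frac_shift_B=0.0,
                           frac_shift_C=0.0)
    return replace(base, **overrides)


def generate_gem(cfg: SyntheticConfig) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate an FPKM-scale GEM plus its ground truth, seeded."""
    rng = np.random.default_rng(cfg.seed)
    t = np.asarray(cfg.time_grid, dtype=float)
    T, m = len(t), cfg.m_replicates
    lib = make_shape_library(cfg.n_shapes, cfg.time_grid)
    alloc = _allocate(cfg)
    n = cfg.n_genes
    width = max(5, len(str(n)))
    genes = [f"G{str(i).zfill(width)}" for i in range(n)]

    cats = (["A_off_to_dynamic"] * alloc["A"]
            + ["B_dynamic_to_off"] * alloc["B"]
            + ["C_dynamic_to_dynamic"] * alloc["C"]
            + ["off_both"] * alloc["off_both"]
            + ["non_shift"] * alloc["non_shift"])
    rng.shuffle(cats)

    control_shape: dict = {}
    treated_shape: dict = {}
    category: dict = {}
    for g, cat in zip(genes, cats):
        category[g] = cat
        if cat == "A_off_to_dynamic":
            control_shape[g] = None
            treated_shape[g] = int(rng.integers(cfg.n_shapes))
        elif cat == "B_dynamic_to_off":
            control_shape[g] = int(rng.integers(cfg.n_shapes))
            treated_shape[g] = None
        elif cat == "C_dynamic_to_dynamic":
            a = int(rng.integers(cfg.n_shapes))
            b = int(rng.integers(cfg.n_shapes - 1))
            control_shape[g] = a
            treated_shape[g] = b if b < a else b + 1
        elif cat == "off_both":
            control_shape[g] = None
            treated_shape[g] = None
        else:
            shape = int(rng.integers(cfg.n_shapes))
            control_shape[g] = shape
            treated_shape[g] = shape

    conditions = ("control", "treated")
    samples = [SampleMeta(f"{cond}_{int(tp)}h_r{rep}", cond, float(tp), rep)
               for cond in conditions for rep in range(1, m + 1) for tp in t]
    values = np.zeros((n, len(samples)))
    col_of = {(s.condition, s.replicate, s.time): j
              for j, s in enumerate(samples)}

    traj_shape: dict = {}
    for gi, g in enumerate(genes):
        for cond, shape in (("control", control_shape[g]),
                            ("treated", treated_shape[g])):
            if shape is None:
                for rep in range(1, m + 1):
                    traj_shape[(g, cond, rep)] = None
                continue  # OFF: exact zeros in every replicate
            rep_shapes = np.full(m, shape)
            if cfg.replicate_discordance_prob > 0 and \
                    rng.random() < cfg.replicate_discordance_prob:
                rep = int(rng.integers(m))
                other = int(rng.integers(cfg.n_shapes - 1))
                rep_shapes[rep] = other if other < shape else other + 1
            for rep in range(1, m + 1):
                sh = int(rep_shapes[rep - 1])
                traj_shape[(g, cond, rep)] = sh
                log2_vals = lib[sh] + rng.normal(0.0, cfg.noise_sd, size=T)
                fpkm = np.clip(np.exp2(log2_vals) - 1.0, 0.0, None)
                for ti, tp in enumerate(t):
                    values[gi, col_of[(cond, rep, float(tp))]] = fpkm[ti]

    df = pd.DataFrame(values, index=genes,
                      columns=[s.sample_id for s in samples])
    gem = ExpressionMatrix(df, samples, scale="fpkm")
    truth = SyntheticTruth(control_shape, treated_shape, category, traj_shape)
    return gem, truth
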