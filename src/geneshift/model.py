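"""Model/results interface for the pattern-shift workflow.

`GeneShiftModel` is built from an FPKM-scale expression matrix (plus an
optional annotation table) and a configuration; `fit()` executes the whole
workflow -- off-gene extraction, quantile/log2 normalization, pooled
soft-DTW K-means over a k grid, validity-index consensus k selection,
DP-GP refinement of each initial cluster, replicate sorting, shift
classification, trajectory-set grouping, hold-out classifier validation
and (when annotations are supplied) Fisher/BH enrichment -- and returns a
`GeneShiftResults` carrying every intermediate product, a tabular summary
and deterministic writers.

    >>> model = GeneShiftModel(gem, config=GeneShiftConfig(k_grid=(4, 6, 8)))
    >>> res = model.fit()
    >>> print(res.summary())

One global seed fans out to fixed per-stage seeds so identical configs
reproduce identical outputs byte for byte.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster_eval, dpgp, enrich as enrich_mod, gem as gem_mod, sdtw, shift

logger = logging.getLogger(__name__)

__all__ = ["GeneShiftConfig", "GeneShiftModel", "GeneShiftResults"]


@dataclass(frozen=True)
class GeneShiftConfig:
    """Tunable settings of the workflow.

    The defaults follow the protocol the workflow was designed around
    (k grid 35-90 step 5, 1,000 DP-GP sweeps, 3/3 replicate sorting,
    enrichment threshold 0.001); desk-scale runs on small synthetic data
    usually pass a smaller ``k_grid`` and fewer DP-GP sweeps.
    """

    k_grid: tuple = tuple(range(35, 95, 5))
    gamma: float = 1.0
    n_init: int = 5
    kmeans_max_iter: int = 50
    min_agree: int = 3
    min_zero_replicates: int = 1
    dpgp_alpha: float = 1.0
    dpgp_max_iterations: int = 1000
    dpgp_burn_frac: float = 0.5
    dpgp_thin: int = 1
    enrich_alpha: float = 0.001
    enrich_per_vocabulary: bool = True
    set_prefix: str = "T"
    filter_t0_driven: bool = False
    t0_threshold: float = 0.8
    eval_after_fine: bool = False
    validation_split: float = 0.30
    seed: int = 0

    def __post_init__(self):
        if not self.k_grid:
            raise ValueError("k_grid must be nonempty")
        if any(k < 2 for k in self.k_grid):
            raise ValueError("k grid values must be >= 2")
        if self.min_agree < 2:
            raise ValueError("min_agree must be >= 2")


def _stage_seeds(seed: int) -> dict[str, int]:
    rng = np.random.default_rng(seed)
    names = ("kmeans", "dpgp", "validation")
    return {n: int(v) for n, v in
            zip(names, rng.integers(0, 2 ** 31 - 1, size=len(names)))}


class GeneShiftModel:
    """Two-condition temporal pattern-shift model for a replicated GEM.

    Parameters
    ----------
    gem : ExpressionMatrix on the raw FPKM scale with exactly two
        conditions sharing one time grid and replicate count.
    annotations : optional AnnotationTable for functional enrichment.
    config : GeneShiftConfig.
    control, treated : condition names; if omitted the control is guessed
        from conventional aliases (ctrl/mock/uninoculated/...).
    """

    def __init__(self, gem, annotations=None, config: GeneShiftConfig | None = None,
                 control: str | None = None, treated: str | None = None):
        if gem.scale != "fpkm":
            raise ValueError("GeneShiftModel expects a raw FPKM-scale GEM")
        conds = gem.conditions
        if len(conds) != 2:
            raise ValueError(f"exactly two conditions required, found {conds}")
        if control is None:
            control = gem.guess_control()
            if control is None:
                raise ValueError(
                    f"cannot identify the control condition among {conds}; "
                    "pass control=...")
        if control not in conds:
            raise ValueError(f"control condition {control!r} not in {conds}")
        treated = treated or next(c for c in conds if c != control)
        if treated == control or treated not in conds:
            raise ValueError(f"invalid treated condition {treated!r}")
        self.gem = gem
        self.annotations = annotations
        self.config = config or GeneShiftConfig()
        self.control = control
        self.treated = treated

    @classmethod
    def from_tsv(cls, gem_path, annotations_path=None,
                 label_pattern: str = "{condition}_{time}h_r{rep}",
                 sample_sheet=None, **kwargs) -> "GeneShiftModel":
        gem = gem_mod.read_gem(gem_path, label_pattern=label_pattern,
                               sample_sheet=sample_sheet)
        ann = (enrich_mod.AnnotationTable.read_tsv(annotations_path)
               if annotations_path else None)
        return cls(gem, annotations=ann, **kwargs)

    # -- fitting ----------------------------------------------------------
    def fit(self, seed: int | None = None) -> "GeneShiftResults":
        cfg = self.config if seed is None else replace(self.config, seed=seed)
        seeds = _stage_seeds(cfg.seed)
        gem = self.gem

        # 1. off-profile extraction on the raw FPKM scale
        off_control, _ = gem_mod.extract_off_genes(
            gem, self.control, cfg.min_zero_replicates)
        off_treated, _ = gem_mod.extract_off_genes(
            gem, self.treated, cfg.min_zero_replicates)

        # 2. quantile normalization then log2(x+1)
        normalized = gem_mod.log_transform(gem_mod.quantile_normalize(gem))

        # 3. per-replicate trajectories of active gene-condition profiles
        trajs: list[gem_mod.Trajectory] = []
        for cond, off in ((self.control, off_control),
                          (self.treated, off_treated)):
            active = [g for g in gem.gene_ids if g not in off]
            trajs.extend(gem_mod.build_trajectories(normalized, active, [cond]))
        if not trajs:
            raise ValueError("all gene-condition profiles are off; nothing to fit")
        X = np.asarray([tr.y for tr in trajs])
        t = gem.time_grid

        # replicate-residual noise estimate on the analysis scale: pooled
        # variance across replicates within each (gene, condition, time)
        noise_var = self._replicate_noise_var(trajs)

        # 4. coarse clustering over the k grid + consensus k selection
        grid = [k for k in cfg.k_grid if k <= len(trajs)]
        if not grid:
            raise ValueError(
                f"every k in the grid exceeds the {len(trajs)} trajectories")
        initials: dict[int, sdtw.InitialClustering] = {}
        db_scores, ch_scores, sil_scores = {}, {}, {}
        for k in grid:
            init = sdtw.sdtw_kmeans(trajs, k, gamma=cfg.gamma,
                                    seed=seeds["kmeans"], n_init=cfg.n_init,
                                    max_iter=cfg.kmeans_max_iter)
            initials[k] = init
            labels = init.assignment
            if cfg.eval_after_fine:
                labels = self._fine_labels(X, t, init, cfg, seeds["dpgp"],
                                           noise_var=noise_var)[0]
                labels = pd.factorize(labels)[0]
            db_scores[k] = cluster_eval.davies_bouldin(X, labels)
            ch_scores[k] = cluster_eval.calinski_harabasz(X, labels)
            sil_scores[k] = cluster_eval.silhouette(X, labels)
        k_report = cluster_eval.select_k(db_scores, ch_scores, sil_scores)
        chosen = initials[k_report.chosen_k]

        # 5. DP-GP refinement of each initial cluster -> composite labels
        composite, fine_results, label_means = self._fine_labels(
            X, t, chosen, cfg, seeds["dpgp"], noise_var=noise_var)

        # 6. replicate sorting and shift classification
        m = gem.n_replicates
        reps = sorted({s.replicate for s in gem.samples})
        traj_label: dict[tuple, str] = {}
        for tr, lab in zip(trajs, composite):
            traj_label[(tr.gene_id, tr.condition, tr.replicate)] = lab
        OFF = shift.TrajectoryLabel.off()

        def labels_for(g, cond, off_set):
            if g in off_set:
                return [OFF] * m
            return [shift.TrajectoryLabel.dynamic(traj_label[(g, cond, r)])
                    for r in reps]

        control_labels = {g: labels_for(g, self.control, off_control)
                          for g in gem.gene_ids}
        treated_labels = {g: labels_for(g, self.treated, off_treated)
                          for g in gem.gene_ids}
        records, summary = shift.compile_shift_table(
            gem.gene_ids, control_labels, treated_labels, cfg.min_agree)

        # optional heuristic: drop shifts explained by the first time point
        t0_dropped: list[str] = []
        if cfg.filter_t0_driven:
            zero = np.zeros(len(t))
            kept = []
            for rec in records:
                if rec.category in ("A_off_to_dynamic", "B_dynamic_to_off",
                                    "C_dynamic_to_dynamic"):
                    c_mean = (zero if rec.control_label.kind == "OFF"
                              else label_means[rec.control_label.composite_id])
                    t_mean = (zero if rec.treated_label.kind == "OFF"
                              else label_means[rec.treated_label.composite_id])
                    if shift.is_t0_driven(c_mean, t_mean, cfg.t0_threshold):
                        t0_dropped.append(rec.gene_id)
                        continue
                kept.append(rec)
            records = kept
            _, summary = self._recount(records, summary, cfg)

        sets = shift.group_trajectory_sets(records, prefix=cfg.set_prefix)

        # 7. hold-out validation of the final dynamic labelling
        dyn_mask = [i for i, tr in enumerate(trajs)]
        try:
            validation = cluster_eval.validate_with_classifier(
                X[dyn_mask], np.asarray(composite)[dyn_mask],
                split_frac=cfg.validation_split, seed=seeds["validation"],
                classifier=cluster_eval.SoftDTW1NN(cfg.gamma))
        except ValueError as exc:
            warnings.warn(f"classifier validation skipped: {exc}")
            validation = None

        # 8. optional functional enrichment of the trajectory sets
        enrichment = None
        if self.annotations is not None:
            enrichment = enrich_mod.enrich_sets(
                sets, self.annotations, set(gem.gene_ids),
                alpha=cfg.enrich_alpha,
                per_vocabulary=cfg.enrich_per_vocabulary)

        return GeneShiftResults(
            model=self, config=cfg, normalized=normalized,
            off_control=off_control, off_treated=off_treated,
            trajectories=trajs, k_report=k_report, initial=chosen,
            fine=fine_results, composite_labels=list(composite),
            label_means=label_means, records=records, summary_counts=summary,
            trajectory_sets=sets, validation=validation,
            enrichment=enrichment, t0_dropped=t0_dropped,
            stage_seeds=seeds)

    @staticmethod
    def _replicate_noise_var(trajs) -> float:
        """Pooled across-replicate variance per (gene, condition, time)."""
        groups: dict[tuple, list] = {}
        for tr in trajs:
            groups.setdefault((tr.gene_id, tr.condition), []).append(tr.y)
        residual_ss, dof = 0.0, 0
        for ys in groups.values():
            if len(ys) < 2:
                continue
            Y = np.asarray(ys)
            residual_ss += float(((Y - Y.mean(axis=0)) ** 2).sum())
            dof += (Y.shape[0] - 1) * Y.shape[1]
        if dof == 0:
            return 1e-4
        return max(residual_ss / dof, 1e-4)

    @staticmethod
    def _fine_labels(X, t, initial, cfg, base_seed, noise_var=None):
        """DP-GP refine each initial cluster; return composite labels.

        Each parent cluster gets its own empirical-Bayes hyperparameters;
        when the replicate-residual ``noise_var`` is available it replaces
        the default noise fraction and the signal variance is the pooled
        member variance in excess of that noise.
        """
        composite = np.empty(len(X), dtype=object)
        fine_results: dict[int, dpgp.FineClustering] = {}
        label_means: dict[str, np.ndarray] = {}
        for parent in range(initial.k):
            idx = np.flatnonzero(initial.assignment == parent)
            if idx.size == 0:
                continue
            hp = dpgp.estimate_hyperparams(X[idx], t)
            if noise_var is not None:
                sf2 = max(hp.signal_var - noise_var, 1e-4)
                hp = dpgp.GPHyperparams(signal_var=sf2,
                                        length_scale=hp.length_scale,
                                        noise_var=noise_var)
            fc = dpgp.dpgp_cluster(
                X[idx], t, hp=hp, alpha=cfg.dpgp_alpha,
                max_num_iterations=cfg.dpgp_max_iterations,
                burn_frac=cfg.dpgp_burn_frac,
                seed=(base_seed + parent) % (2 ** 31 - 1),
                parent_cluster=parent, thin=cfg.dpgp_thin)
            fine_results[parent] = fc
            for sub, mean in fc.mean_series(X[idx]).items():
                label_means[f"K{parent}_D{sub}"] = mean
            for local, gi in enumerate(idx):
                composite[gi] = f"K{parent}_D{fc.partition[local]}"
        return composite, fine_results, label_means

    @staticmethod
    def _recount(records, old_summary, cfg):
        from collections import Counter
        counts = Counter(r.category for r in records)
        n_shift = (counts["A_off_to_dynamic"] + counts["B_dynamic_to_off"]
                   + counts["C_dynamic_to_dynamic"])
        summary = dict(old_summary)
        summary.update({
            "n_shift": n_shift,
            "n_shift_A_off_to_dynamic": counts["A_off_to_dynamic"],
            "n_shift_B_dynamic_to_off": counts["B_dynamic_to_off"],
            "n_shift_C_dynamic_to_dynamic": counts["C_dynamic_to_dynamic"],
            "n_non_shift": counts["non_shift"],
            "n_qualified_both": n_shift + counts["non_shift"],
        })
        return records, summary


@dataclass
class GeneShiftResults:
    """Everything the fitted workflow produced."""

    model: GeneShiftModel
    config: GeneShiftConfig
    normalized: object
    off_control: set
    off_treated: set
    trajectories: list
    k_report: cluster_eval.KSelectionReport
    initial: sdtw.InitialClustering
    fine: dict
    composite_labels: list
    label_means: dict
    records: list
    summary_counts: dict
    trajectory_sets: list = field(default_factory=list)
    validation: object = None
    enrichment: list | None = None
    t0_dropped: list = field(default_factory=list)
    stage_seeds: dict = field(default_factory=dict)

    # -- views ------------------------------------------------------------
    def shift_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_row() for r in self.records])

    def assignment_frame(self) -> pd.DataFrame:
        rows = []
        for tr, init, comp in zip(self.trajectories,
                                  self.initial.assignment,
                                  self.composite_labels):
            rows.append({"gene_id": tr.gene_id, "condition": tr.condition,
                         "replicate": tr.replicate,
                         "initial_cluster": int(init),
                         "composite_label": comp})
        return pd.DataFrame(rows)

    def sets_frame(self) -> pd.DataFrame:
        rows = []
        for ts in self.trajectory_sets:
            for g in sorted(ts.member_genes):
                rows.append({"set_id": ts.set_id,
                             "control_label": ts.condition_pair_signature[0],
                             "treated_label": ts.condition_pair_signature[1],
                             "gene_id": g})
        return pd.DataFrame(rows)

    def shift_genes(self) -> set:
        return {r.gene_id for r in self.records
                if r.category in ("A_off_to_dynamic", "B_dynamic_to_off",
                                  "C_dynamic_to_dynamic")}

    def summary(self) -> str:
        """Human-readable run summary in the workflow's report schema."""
        c = self.summary_counts
        lines = [
            "GeneShift pattern-shift summary",
            "=" * 47,
            f"{'Genes in matrix':40s}{c['n_genes']:>7d}",
            f"{'Off in control (all time points)':40s}{c['n_off_control']:>7d}",
            f"{'Off in treated (all time points)':40s}{c['n_off_treated']:>7d}",
            f"{'Off in both conditions':40s}{c['n_off_both']:>7d}",
            (f"{'Qualified in both (%d/%d sorting)' % (self.config.min_agree, self.model.gem.n_replicates):40s}"
             f"{c['n_qualified_both']:>7d}"),
            f"{'Shift genes (A+B+C)':40s}{c['n_shift']:>7d}",
            f"{'  A: off -> dynamic':40s}{c['n_shift_A_off_to_dynamic']:>7d}",
            f"{'  B: dynamic -> off':40s}{c['n_shift_B_dynamic_to_off']:>7d}",
            f"{'  C: dynamic -> dynamic':40s}{c['n_shift_C_dynamic_to_dynamic']:>7d}",
            f"{'Non-shift genes':40s}{c['n_non_shift']:>7d}",
            f"{'Unqualified genes':40s}{c['n_unqualified']:>7d}",
            f"{'Chosen k':40s}{self.k_report.chosen_k:>7d}",
            f"{'Trajectory sets':40s}{len(self.trajectory_sets):>7d}",
        ]
        if self.validation is not None:
            lines.append(f"{'Hold-out weighted F1':40s}"
                         f"{self.validation.f1_weighted:>7.3f}")
        return "\n".join(lines)

    def summary_json(self) -> str:
        payload = {
            "counts": {k: int(v) for k, v in self.summary_counts.items()},
            "chosen_k": int(self.k_report.chosen_k),
            "n_trajectory_sets": len(self.trajectory_sets),
            "t0_dropped": sorted(self.t0_dropped),
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(self.config).items()},
        }
        if self.validation is not None:
            payload["f1_weighted"] = self.validation.f1_weighted
        return json.dumps(payload, indent=2, sort_keys=True)

    # -- persistence ------------------------------------------------------
    def save(self, outdir) -> Path:
        """Write every table of the run into ``outdir`` deterministically."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.normalized.to_tsv(out / "normalized_gem.tsv")
        off_rows = ([{"gene_id": g, "condition": self.model.control}
                     for g in sorted(self.off_control)]
                    + [{"gene_id": g, "condition": self.model.treated}
                       for g in sorted(self.off_treated)])
        pd.DataFrame(off_rows, columns=["gene_id", "condition"]).to_csv(
            out / "off_genes.tsv", sep="\t", index=False)
        self.k_report.to_frame().to_csv(out / "k_selection.tsv", sep="\t",
                                        index=False)
        self.assignment_frame().to_csv(out / "assignments.tsv", sep="\t",
                                       index=False)
        self.shift_frame().to_csv(out / "shift_table.tsv", sep="\t",
                                  index=False)
        self.sets_frame().to_csv(out / "trajectory_sets.tsv", sep="\t",
                                 index=False)
        (out / "summary.json").write_text(self.summary_json() + "\n")
        if self.validation is not None:
            (out / "validation.json").write_text(
                json.dumps(self.validation.to_dict(), indent=2,
                           sort_keys=True) + "\n")
        if self.enrichment is not None:
            pd.DataFrame([r.to_row() for r in self.enrichment]).to_csv(
                out / "enrichment.tsv", sep="\t", index=False)
        return out

    # -- plotting ---------------------------------------------------------
    def plot_trajectory_set(self, set_id: str, ax=None):
        """Plain per-replicate trajectory plot of one set (control vs treated)."""
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        ts = next((s for s in self.trajectory_sets if s.set_id == set_id), None)
        if ts is None:
            raise KeyError(f"no trajectory set {set_id!r}")
        if ax is None:
            _, ax = plt.subplots(figsize=(4, 3))
        t = self.model.gem.time_grid
        colors = {self.model.control: "tab:blue", self.model.treated: "tab:green"}
        for tr, _ in zip(self.trajectories, self.composite_labels):
            if tr.gene_id in ts.member_genes:
                ax.plot(tr.t, tr.y, color=colors[tr.condition], alpha=0.5, lw=0.8)
        for g in sorted(ts.member_genes):
            for cond, off in ((self.model.control, self.off_control),
                              (self.model.treated, self.off_treated)):
                if g in off:
                    ax.plot(t, np.zeros_like(t), color=colors[cond],
                            alpha=0.5, lw=0.8)
        ax.set_xlabel("time (h)")
        ax.set_ylabel("log2(FPKM + 1)")
        ax.set_title(f"{set_id}: {ts.condition_pair_signature[0]} vs "
                     f"{ts.condition_pair_signature[1]}")
        return ax
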