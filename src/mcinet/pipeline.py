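"""End-to-end orchestration: simulate -> connectivity -> metrics ->
hubs -> communities -> statistics -> classification.

Each stage is a plain function over the library modules that writes its
tables under the run directory, so the numbered analysis drivers, the CLI
and `run_full` share one code path.  A master seed plus fixed per-stage
offsets determines every stochastic stage; re-running with the same
config and seed reproduces every table byte for byte.  Completed stages
are skipped on re-runs when their outputs and the stored config match.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as ch
from . import community as cm
from . import connectivity as cn
from . import graph_metrics as gm
from . import group_stats as gs
from . import nodal_hubs as nh
from . import rf_classifier as rf

log = logging.getLogger("mcinet")

# seed-derivation rule: stage seed = master seed + fixed stage offset
STAGE_OFFSETS = {
    "simulate": 0,
    "global_metrics": 1000,
    "hubs": 2000,
    "community": 3000,
    "stats": 4000,
    "classify": 5000,
}


@dataclass
class RunConfig:
    """Configuration of one full synthetic-study run.

    The default ("demo") profile keeps a 30+30 cohort sweep within a few
    CPU-minutes by evaluating small-worldness on a 10-point sub-grid with
    a reduced null count and using a compact classifier grid; the
    ``study_profile`` constructor restores the study-scale settings
    (1,000 nulls and permutations, full 5-30 feature sweep).
    """

    out_dir: str = "results/run"
    seed: int = 42
    n_per_group: int = 30
    classifier_sparsity: float = 0.16
    sw_grid: tuple[float, ...] = tuple(np.round(np.arange(5, 51, 5) / 100, 2))
    n_random_sw_group: int = 50
    n_random_sw_subject: int = 20
    n_perm: int = 200
    detect_restarts: int = 20
    perm_restarts: int = 3
    top_n_values: tuple[int, ...] = (5, 10, 15, 20, 25, 30)
    n_estimators_grid: tuple[int, ...] = (100, 200)
    max_depth_grid: tuple[int | None, ...] = (3, None)
    ranking_n_estimators: int = 200
    global_ranking: bool = False
    make_figures: bool = False
    cohort_overrides: dict = field(default_factory=dict)

    @staticmethod
    def study_profile(**kwargs) -> "RunConfig":
        base = dict(
            sw_grid=tuple(cn.sparsity_grid().tolist()),
            n_random_sw_group=1000,
            n_random_sw_subject=1000,
            n_perm=1000,
            top_n_values=tuple(range(5, 31)),
            n_estimators_grid=rf.DEFAULT_N_ESTIMATORS_GRID,
            max_depth_grid=rf.DEFAULT_MAX_DEPTH_GRID,
            ranking_n_estimators=500,
        )
        base.update(kwargs)
        return RunConfig(**base)

    def cohort_spec(self) -> ch.CohortSpec:
        return ch.CohortSpec(
            n_per_group=self.n_per_group,
            seed=self.seed + STAGE_OFFSETS["simulate"],
            **self.cohort_overrides,
        )

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, default=str, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass
class RunReport:
    config: RunConfig
    outputs: dict[str, str]
    timings: dict[str, float]
    summary: dict

    def write(self, path: Path) -> None:
        path.write_text(
            json.dumps(
                {
                    "config": json.loads(self.config.to_json()),
                    "outputs": self.outputs,
                    "timings_s": {k: round(v, 2) for k, v in self.timings.items()},
                    "summary": self.summary,
                },
                indent=2,
                default=float,
            )
        )


def _stage_done(out: Path, stage: str, files: list[Path], digest: str) -> bool:
    marker = out / f".{stage}.done"
    return marker.exists() and marker.read_text() == digest and all(f.exists() for f in files)


def _mark_done(out: Path, stage: str, digest: str) -> None:
    (out / f".{stage}.done").write_text(digest)


# --- stages ---------------------------------------------------------------


def stage_simulate(config: RunConfig, out: Path):
    spec = config.cohort_spec()
    subjects, truth = ch.generate_cohort(spec)
    ch.write_cohort(subjects, truth, out / "cohort")
    return subjects, truth


def stage_connectivity(subjects: list[ch.SubjectRecord], out: Path):
    """Individual FC matrices and the two group-mean networks."""
    names = ch.roi_names(subjects[0].timeseries.shape[1])
    fcs = {s.subject_id: cn.compute_fc(s.timeseries, names) for s in subjects}
    group_fc = {}
    for g in ch.GROUPS:
        members = [fcs[s.subject_id] for s in subjects if s.group == g]
        group_fc[g] = cn.group_mean_network(members)
        cn.write_matrix_csv(group_fc[g].values, names, out / f"group_fc_{g}.csv")
        cn.write_matrix_mtx(group_fc[g].values, out / f"group_fc_{g}.mtx")
    return fcs, group_fc


def stage_global_metrics(
    config: RunConfig,
    subjects: list[ch.SubjectRecord],
    fcs: dict[str, cn.FCMatrix],
    group_fc: dict[str, cn.FCMatrix],
    out: Path,
) -> dict[str, pd.DataFrame]:
    """Group-level metric curves over the grid + per-subject metrics at
    the classifier sparsity."""
    seed = config.seed + STAGE_OFFSETS["global_metrics"]
    sw_points = {round(float(v), 2) for v in config.sw_grid}
    sw_points.add(round(float(config.classifier_sparsity), 2))
    rows = []
    for g, fc in group_fc.items():
        for s in cn.sparsity_grid():
            net = cn.threshold_by_sparsity(fc, s)
            sw = None
            if round(float(s), 2) in sw_points:
                sw, _ = gm.small_worldness(
                    net, n_random=config.n_random_sw_group, seed=seed + int(s * 100)
                )
            l, unreach = gm.characteristic_path_length(net)
            rows.append(
                {
                    "group": g,
                    "sparsity": float(s),
                    "C": gm.clustering_coefficient(net),
                    "L": l,
                    "GE": gm.global_efficiency(net),
                    "SW": sw,
                    "unreachable_pair_fraction": unreach,
                    "isolated_fraction": cn.isolated_fraction(net),
                }
            )
    group_curves = pd.DataFrame(rows)
    group_curves.to_csv(out / "group_global_metrics.csv", index=False)

    srows = []
    for k, subj in enumerate(subjects):
        net = cn.threshold_by_sparsity(fcs[subj.subject_id], config.classifier_sparsity)
        sw, _ = gm.small_worldness(net, n_random=config.n_random_sw_subject, seed=seed + 500 + k)
        l, _ = gm.characteristic_path_length(net)
        srows.append(
            {
                "subject_id": subj.subject_id,
                "C": gm.clustering_coefficient(net),
                "L": l,
                "GE": gm.global_efficiency(net),
                "SW": sw,
            }
        )
    subject_metrics = pd.DataFrame(srows)
    subject_metrics.to_csv(out / "subject_global_metrics.csv", index=False)
    return {"group_curves": group_curves, "subject_metrics": subject_metrics}


def stage_hubs(
    config: RunConfig,
    subjects: list[ch.SubjectRecord],
    fcs: dict[str, cn.FCMatrix],
    group_fc: dict[str, cn.FCMatrix],
    out: Path,
) -> dict[str, pd.DataFrame]:
    """Group-level hub stability over the grid + per-subject nodal bc."""
    grid = cn.sparsity_grid()
    stability = {}
    for g, fc in group_fc.items():
        tab = nh.hub_stability(fc, grid)
        nh.hub_table_long(tab).to_csv(out / f"hub_sweep_{g}.csv", index=False)
        stability[g] = tab
    n = subjects[0].timeseries.shape[1]
    srows = []
    for subj in subjects:
        net = cn.threshold_by_sparsity(fcs[subj.subject_id], config.classifier_sparsity)
        bc = nh.betweenness(net)
        srows.append({"subject_id": subj.subject_id, **{f"bc_{i + 1}": bc[i] for i in range(n)}})
    subject_bc = pd.DataFrame(srows)
    subject_bc.to_csv(out / "subject_nodal_bc.csv", index=False)
    return {"stability": stability, "subject_bc": subject_bc}


def stage_community(
    config: RunConfig, group_fc: dict[str, cn.FCMatrix], out: Path
) -> dict:
    seed = config.seed + STAGE_OFFSETS["community"]
    s = config.classifier_sparsity
    partitions = {}
    perm = {}
    for g, fc in group_fc.items():
        net = cn.threshold_by_sparsity(fc, s)
        partitions[g] = cm.detect_modules(net, seed=seed, n_restarts=config.detect_restarts)
        perm[g] = cm.permutation_test_q(
            net, n_perm=config.n_perm, seed=seed + 17, n_restarts=config.perm_restarts
        )
    names = group_fc[ch.NC].roi_names
    table, flows = cm.module_crosswalk(partitions[ch.NC], partitions[ch.MCI], names)
    table.to_csv(out / "module_crosswalk_table.csv")
    flows.to_csv(out / "module_crosswalk_flows.csv", index=False)
    payload = {
        g: {
            "sparsity": s,
            "Q": partitions[g].Q,
            "n_modules": partitions[g].n_modules,
            "assignment": partitions[g].assignment.tolist(),
            "perm_p": perm[g].p_value,
            "n_perm": perm[g].n_perm,
        }
        for g in partitions
    }
    (out / "community.json").write_text(json.dumps(payload, indent=2))
    return {"partitions": partitions, "perm": perm, "crosswalk": (table, flows)}


def stage_stats(
    config: RunConfig,
    meta: pd.DataFrame,
    subject_metrics: pd.DataFrame,
    subject_bc: pd.DataFrame,
    out: Path,
) -> dict[str, pd.DataFrame]:
    demo = gs.demographics_table(meta, ch.SCORE_NAMES)
    demo.to_csv(out / "demographics.csv", index=False)

    merged = meta.merge(subject_metrics, on="subject_id").merge(subject_bc, on="subject_id")
    group = merged["group"].to_numpy()
    gender = merged["gender"].to_numpy()
    n_rois = sum(c.startswith("bc_") for c in subject_bc.columns)
    rows = []
    for name in ["C", "L", "GE", "SW"] + [f"bc_{i + 1}" for i in range(n_rois)]:
        res = gs.logistic_group_test(
            merged[name].to_numpy(float), group, gender,
            metric_name=name, sparsity=config.classifier_sparsity, n_comparisons=n_rois,
        )
        rows.append(dataclasses.asdict(res))
    group_tests = pd.DataFrame(rows)
    group_tests.to_csv(out / "group_tests.csv", index=False)

    prows = []
    for metric in ("C", "L", "GE", "SW"):
        for score in ch.SCORE_NAMES:
            res = gs.partial_correlation(
                merged[metric].to_numpy(float), merged[score].to_numpy(float), gender,
                metric_name=metric, score_name=score, sparsity=config.classifier_sparsity,
            )
            prows.append(dataclasses.asdict(res))
    partial = pd.DataFrame(prows)
    partial.to_csv(out / "partial_correlations.csv", index=False)
    return {"demographics": demo, "group_tests": group_tests, "partial_correlations": partial}


def stage_classify(
    config: RunConfig,
    meta: pd.DataFrame,
    subject_metrics: pd.DataFrame,
    subject_bc: pd.DataFrame,
    out: Path,
) -> dict:
    seed = config.seed + STAGE_OFFSETS["classify"]
    table = rf.build_feature_table(meta, subject_metrics, subject_bc, config.classifier_sparsity)
    table.features.assign(
        subject_id=meta["subject_id"].to_numpy(), group=meta["group"].to_numpy()
    ).to_csv(out / "feature_table.csv", index=False)
    cv_kwargs = dict(
        n_estimators_grid=config.n_estimators_grid,
        max_depth_grid=config.max_depth_grid,
        ranking_n_estimators=config.ranking_n_estimators,
        global_ranking=config.global_ranking,
    )
    reports, best = rf.sweep_top_n(
        table, n_values=list(config.top_n_values), seed=seed, **cv_kwargs
    )
    scores_only = rf.compare_scores_only(table, seed=seed, **{
        k: v for k, v in cv_kwargs.items() if k != "global_ranking"
    })
    pd.DataFrame([r.summary() for r in reports]).to_csv(out / "cv_sweep.csv", index=False)
    pd.DataFrame(best.ranking, columns=["feature", "importance"]).to_csv(
        out / "feature_ranking.csv", index=False
    )
    (out / "classification.json").write_text(
        json.dumps(
            {
                "best": best.summary(),
                "scores_only": scores_only.summary(),
                "top10_features": [f for f, _ in best.ranking[:10]],
            },
            indent=2,
            default=float,
        )
    )
    return {"reports": reports, "best": best, "scores_only": scores_only, "table": table}


# --- full run -------------------------------------------------------------


def run_full(config: RunConfig, resume: bool = True) -> RunReport:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    digest = config.digest()
    if resume and _stage_done(out, "run", [out / "run_report.json"], digest):
        log.info("outputs in %s match config digest %s; skipping recompute", out, digest)
        stored = json.loads((out / "run_report.json").read_text())
        return RunReport(
            config=config, outputs=stored["outputs"], timings={}, summary=stored["summary"]
        )
    (out / "run_config.json").write_text(config.to_json())
    timings: dict[str, float] = {}

    def timed(name, fn, *args):
        t0 = time.perf_counter()
        result = fn(*args)
        timings[name] = time.perf_counter() - t0
        log.info("stage %s finished in %.1fs", name, timings[name])
        return result

    try:
        subjects, truth = timed("simulate", stage_simulate, config, out)
        meta = pd.read_csv(out / "cohort" / "metadata.tsv", sep="\t")
        fcs, group_fc = timed("connectivity", stage_connectivity, subjects, out)
        metrics = timed("global_metrics", stage_global_metrics, config, subjects, fcs, group_fc, out)
        hubs = timed("hubs", stage_hubs, config, subjects, fcs, group_fc, out)
        comm = timed("community", stage_community, config, group_fc, out)
        stats = timed(
            "stats", stage_stats, config, meta, metrics["subject_metrics"], hubs["subject_bc"], out
        )
        cls = timed(
            "classify", stage_classify, config, meta, metrics["subject_metrics"],
            hubs["subject_bc"], out,
        )
    except Exception as err:
        raise RuntimeError(f"pipeline halted: {err}") from err

    curves = metrics["group_curves"]
    at_s = curves[np.isclose(curves["sparsity"], config.classifier_sparsity)]
    summary = {
        "n_subjects": len(subjects),
        "sw_at_classifier_sparsity": {
            g: float(at_s[at_s.group == g]["SW"].iloc[0]) if at_s[at_s.group == g]["SW"].notna().any() else None
            for g in ch.GROUPS
        },
        "community": {
            g: {"Q": comm["partitions"][g].Q, "n_modules": comm["partitions"][g].n_modules,
                "perm_p": comm["perm"][g].p_value}
            for g in ch.GROUPS
        },
        "stable_hubs": {
            g: [r for r, frac in hubs["stability"][g].mean(axis=1).items() if frac >= 2 / 3]
            for g in ch.GROUPS
        },
        "classification": {
            "best": cls["best"].summary(),
            "scores_only": cls["scores_only"].summary(),
        },
    }
    outputs = {p.name: str(p) for p in sorted(out.glob("*.csv")) + sorted(out.glob("*.json"))}
    report = RunReport(config=config, outputs=outputs, timings=timings, summary=summary)
    report.write(out / "run_report.json")
    if config.make_figures:
        make_figures(out)
    _mark_done(out, "run", digest)
    return report


def make_figures(run_dir: str | Path) -> list[Path]:
    """Metric-vs-sparsity curves, hub grid and accuracy-vs-N figures."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run_dir = Path(run_dir)
    made = []

    curves = pd.read_csv(run_dir / "group_global_metrics.csv")
    fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharex=True)
    for ax, metric in zip(axes.ravel(), ["C", "L", "GE", "SW"]):
        for g, sub in curves.groupby("group"):
            sub = sub.dropna(subset=[metric])
            ax.plot(sub["sparsity"], sub[metric], marker=".", label=g)
        ax.set_title(metric)
        ax.set_xlabel("sparsity")
    axes[0, 0].legend()
    fig.tight_layout()
    p = run_dir / "fig_global_metrics.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    made.append(p)

    for g in ("NC", "MCI"):
        path = run_dir / f"hub_sweep_{g}.csv"
        if not path.exists():
            continue
        long = pd.read_csv(path)
        grid = long.pivot(index="roi", columns="sparsity", values="hub_flag")
        hubs_any = grid[grid.any(axis=1)]
        fig, ax = plt.subplots(figsize=(9, max(2, 0.3 * len(hubs_any))))
        ax.imshow(hubs_any.to_numpy(), aspect="auto", cmap="Greys", interpolation="none")
        ax.set_yticks(range(len(hubs_any)), hubs_any.index)
        ax.set_xticks(range(0, grid.shape[1], 5), [f"{s:.2f}" for s in grid.columns[::5]])
        ax.set_title(f"global hubs, {g}")
        fig.tight_layout()
        p = run_dir / f"fig_hubs_{g}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        made.append(p)

    sweep = run_dir / "cv_sweep.csv"
    if sweep.exists():
        df = pd.read_csv(sweep)
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(df["top_n"], df["accuracy"], marker="o")
        ax.set_xlabel("top N features")
        ax.set_ylabel("nested-CV accuracy")
        fig.tight_layout()
        p = run_dir / "fig_accuracy_vs_topn.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        made.append(p)
    return made
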