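"""Group statistics: demographics, logistic metric tests, partial correlations.

Demographics use the Lilliefors-gated t/Wilcoxon tests and Fisher's
exact test for gender; network metrics (global + 116 nodal bc) enter
per-metric logistic regressions of group controlling gender; metric-
score associations are gender-controlled partial correlations.
Depends on the per-subject metric tables from drivers 03 and 04 (they
are recomputed here if absent).
"""

from pathlib import Path

import pandas as pd

from mcinet import pipeline as pl

from common import load_study, parse_args, study_config


def main() -> None:
    args = parse_args(__doc__)
    config = study_config(args.seed, args.out)
    out = Path(config.out_dir)
    subjects, _, fcs, group_fc = load_study(config)
    if not (out / "subject_global_metrics.csv").exists():
        pl.stage_global_metrics(config, subjects, fcs, group_fc, out)
    if not (out / "subject_nodal_bc.csv").exists():
        pl.stage_hubs(config, subjects, fcs, group_fc, out)
    meta = pd.read_csv(out / "cohort" / "metadata.tsv", sep="\t")
    metrics = pd.read_csv(out / "subject_global_metrics.csv")
    bc = pd.read_csv(out / "subject_nodal_bc.csv")

    tables = pl.stage_stats(config, meta, metrics, bc, out)
    print("demographics:")
    print(tables["demographics"].to_string(index=False))
    gt = tables["group_tests"]
    sig = gt[gt.significant_unadjusted]
    print(f"\nmetrics separating the groups (p < 0.05, gender-controlled): "
          f"{sig.metric.tolist()[:12]}{'...' if len(sig) > 12 else ''}")
    bonf = gt[gt.significant_bonferroni & gt.metric.str.startswith('bc_')]
    print(f"nodal bc surviving Bonferroni 0.05/116: {bonf.metric.tolist()}")
    pc = tables["partial_correlations"]
    strong = pc[pc.p_value < 0.05]
    print("\nsignificant metric-score partial correlations (controlling gender):")
    print(strong[["metric", "score", "r_partial", "p_value"]].round(3).to_string(index=False))


if __name__ == "__main__":
    main()
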