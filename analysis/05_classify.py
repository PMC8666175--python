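"""Evaluate nested ANOVA-ranked biomarker panels (1..13 proteins) with
LDA, QDA, multinomial logistic regression, and random forests under
leave-one-out cross-validation; report the selected model's confusion
matrix and per-class ROC/AUC.  Run 03_quantify.py first."""

import argparse

from srmquant.pipeline import PipelineConfig, stage_classify
from srmquant.srm_data import read_classification_report


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", default="results/pipeline")
    ap.add_argument("--rank-once", action="store_true",
                    help="Rank proteins once on all data instead of "
                         "re-ranking inside each LOOCV training fold.")
    args = ap.parse_args()
    cfg = PipelineConfig(out_dir=args.out_dir, seed=args.seed,
                         rank_once=args.rank_once)
    info = stage_classify(cfg)
    rep = read_classification_report(
        f"{args.out_dir}/classification_report.json")
    aucs = ", ".join(f"{k} {v:.4f}" for k, v in rep.auc.items())
    print(f"best model: {info['best_algorithm']} with a "
          f"{info['best_panel_size']}-protein panel "
          f"({', '.join(rep.selected_panel)}); "
          f"LOOCV accuracy {rep.out_of_sample_accuracy:.2f}%, in-sample "
          f"{rep.in_sample_accuracy:.2f}%; one-vs-rest AUC: {aucs}")


if __name__ == "__main__":
    main()
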