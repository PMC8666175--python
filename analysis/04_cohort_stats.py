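"""Differential abundance across control/cirrhosis/HCC with BH-FDR
control, PCA of the centered/scaled protein estimators, and Ward
clustering of protein profiles.  Run 03_quantify.py first."""

import argparse

import pandas as pd

from srmquant.pipeline import PipelineConfig, stage_diff


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", default="results/pipeline")
    args = ap.parse_args()
    info = stage_diff(PipelineConfig(out_dir=args.out_dir, seed=args.seed))
    var = pd.read_csv(f"{args.out_dir}/pca_variance.csv")
    clusters = pd.read_csv(f"{args.out_dir}/protein_clusters.csv")
    sizes = clusters["cluster"].value_counts().sort_index()
    print(f"{info['n_significant']} significant (q < 0.05) pairwise "
          f"contrasts; PC1 explains "
          f"{100 * var['variance_fraction'].iloc[0]:.1f}% of variance; "
          f"protein clusters of sizes {[int(v) for v in sizes.values]}")


if __name__ == "__main__":
    main()
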