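"""Roll the accepted peptides' cohort abundances up into per-protein
log2 estimators (inverse-variance weighted sums).  Run 02_assay_qc.py
first."""

import argparse

from srmquant.pipeline import PipelineConfig, stage_quantify


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", default="results/pipeline")
    args = ap.parse_args()
    info = stage_quantify(PipelineConfig(out_dir=args.out_dir, seed=args.seed))
    print(f"rolled {info['n_peptides_used']} peptides up into "
          f"{info['n_proteins']} protein estimators "
          f"-> {args.out_dir}/protein_matrix.csv")


if __name__ == "__main__":
    main()
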