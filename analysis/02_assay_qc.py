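"""Characterize the assay: LLOD/LLOQ per peptide, calibration linearity
at peptide and protein level, intra-/inter-/total CV at each spike level,
and the CV < 20% acceptance filter.  Run 01_simulate.py first."""

import argparse

import pandas as pd

from srmquant.pipeline import PipelineConfig, stage_qc


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", default="results/pipeline")
    args = ap.parse_args()
    cfg = PipelineConfig(out_dir=args.out_dir, seed=args.seed)
    info = stage_qc(cfg)
    peptides = pd.read_csv(f"{args.out_dir}/assay_report_peptides.csv")
    print(f"accepted {info['n_accepted']}/{info['n_peptides']} peptides; "
          f"LLOD {peptides['llod_fmol'].min():.2f}-"
          f"{peptides['llod_fmol'].max():.2f} fmol, "
          f"LLOQ {peptides['lloq_fmol'].min():.2g}-"
          f"{peptides['lloq_fmol'].max():.2g} fmol, "
          f"{info['n_excluded_transitions']} transitions excluded for "
          f"interference")


if __name__ == "__main__":
    main()
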