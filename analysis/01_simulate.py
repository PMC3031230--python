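#!/usr/bin/env python
"""Generate the synthetic field-transcriptome datasets.

Emits the organ/tissue panel (48 conditions, 143 arrays), the
17-timepoint weekly leaf series, the fertile/sterile flag-leaf series,
upstream promoter sequences and a GO annotation fixture — all with
planted ground truth recorded in truth.json.
"""

import argparse
from pathlib import Path

from fieldtx.pipeline import PipelineConfig, run_stage


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/run"))
    args = ap.parse_args()

    cfg = PipelineConfig(seed=args.seed)
    summary = run_stage("simulate", cfg, args.outdir)
    print(f"wrote datasets under {args.outdir}")
    print(f"  organ/tissue panel : {summary['n_genes']} genes x "
          f"{summary['n_field_samples']} arrays (48 conditions)")
    print(f"  weekly leaf series : {summary['n_timecourse_samples']} arrays "
          f"(17 timepoints x 3 replicates)")
    print(f"  fertile/sterile    : {summary['n_fs_samples']} arrays "
          f"(4 weeks x 2 genotypes x 3 lines)")


if __name__ == "__main__":
    main()
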