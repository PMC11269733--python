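"""Memorability correlates: recover memorability-modulated voxels.

Ten simulated participants view the full design; betas are pooled across
training (3 reps) and testing (10 reps) videos, rank-correlated with the
per-video memorability scores, and tested one-sided across subjects with
FDR correction.  Writes results/memorability_summary.csv.
"""

from pathlib import Path

import pandas as pd

from vidbold import pipeline

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    out = pipeline.memorability_experiment(seed=1)
    summary = pd.DataFrame(
        [{k: v for k, v in out.items() if isinstance(v, (int, float))}]
    )
    OUT.mkdir(exist_ok=True)
    summary.to_csv(OUT / "memorability_summary.csv", index=False)
    print(summary.to_string(index=False))
    print(
        f"\n{out['sensitivity']:.0%} of memorability-modulated voxels are recovered "
        f"after FDR; {out['null_fdr_rate']:.1%} of unmodulated signal voxels are "
        f"flagged.  Mean correlation at effect voxels: {out['mean_corr_effect']:.2f}."
    )


if __name__ == "__main__":
    main()
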