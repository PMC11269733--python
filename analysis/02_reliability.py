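"""Split-half reliability recovery through the full BOLD + FIR pipeline.

Simulates a test-set-only participant (24 videos x 10 repetitions, 8^3
voxels, 30% signal), estimates trial-wise FIR betas, and applies the
Spearman-Brown split-half criterion with the 100-iteration permutation
test.  Writes results/reliability_summary.csv.
"""

from pathlib import Path

import pandas as pd

from vidbold import pipeline

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    out = pipeline.reliability_experiment(seed=1)
    summary = pd.DataFrame(
        [{k: v for k, v in out.items() if isinstance(v, (int, float))}]
    )
    OUT.mkdir(exist_ok=True)
    summary.to_csv(OUT / "reliability_summary.csv", index=False)
    print(summary.to_string(index=False))
    print(
        f"\nThe criterion recovers {out['sensitivity']:.0%} of true signal voxels; "
        f"{out['false_positive_rate']:.1%} of pure-noise voxels pass at alpha=0.05 "
        f"(nominal 5%).  Mean corrected reliability in signal voxels: "
        f"{out['mean_sb_signal']:.2f}."
    )


if __name__ == "__main__":
    main()
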