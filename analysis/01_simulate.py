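"""Generate the synthetic study bundle: a CARLS-like condition hierarchy
(catabolic limitation covered by three datasets, one dataset each for
anabolic limitation, ribosome limitation, rich medium and stationary
phase), replicated peptide intensities with 100 planted survival proteins,
gene sets, and noisy viability series for every condition.

Writes results/fixtures/ and prints what was planted.
"""

import sys
from pathlib import Path

from survscore.pipeline import PipelineConfig, simulate_bundle

SEED = 20260926
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cfg = PipelineConfig(
        outdir=str(OUT),
        seed=SEED,
        simulate={
            "n_proteins": 2000,
            "n_planted": 100,
            "effect_size": 1.0,
            "replicate_noise_sd": 0.5,
            "n_replicates": 4,
            "missing_rate": 0.1,
            "n_decoy_sets": 40,
        },
    )
    paths = simulate_bundle(cfg)
    print(f"seed {SEED}: synthetic bundle written to {OUT / 'fixtures'}")
    for name, p in sorted(paths.items()):
        print(f"  {name:12s} {p.name}")
    print("planted: 100 of 2000 proteins, effect +1 log2-unit per survival unit")


if __name__ == "__main__":
    sys.exit(main())
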