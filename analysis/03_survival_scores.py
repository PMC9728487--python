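"""Scoring stage: Z-transform every pair statistic, merge pairs within a
dataset with the covariance-corrected normalization, datasets within a
perturbation, and perturbations into the per-protein Survival score.
Also classifies proteins between perturbation pairs at |Z| >= 1.28 the way
the condition-vs-condition correlograms do.

Reads results/pair_stats.tsv (+ the fixture ground truth), writes
results/survival_scores.tsv and results/pairwise_classification.tsv.
"""

import itertools
import sys
from pathlib import Path

import pandas as pd

from survscore import io as sio
from survscore import scoring as sc

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    pair_path = OUT / "pair_stats.tsv"
    if not pair_path.exists():
        sys.exit("run analysis/02_differential.py first")
    stats = sio.read_pair_stats(pair_path)
    ztab = sc.score_proteins(stats, rule="paper", tail="two")
    table = ztab.table()
    table.index.name = "protein_id"
    sio.write_scores(table, OUT / "survival_scores.tsv", meta={"covariance": "paper"})
    print(f"scored {len(table)} proteins -> {OUT / 'survival_scores.tsv'}")

    truth = sio.read_scores(OUT / "fixtures" / "ground_truth.tsv")
    merged = table.join(truth, how="inner")
    planted = merged["planted"] == 1
    print(
        "median Survival score: planted "
        f"{merged.loc[planted, 'survival_score'].median():.2f} vs null "
        f"{merged.loc[~planted, 'survival_score'].median():.2f} "
        f"(null 99th pct {merged.loc[~planted, 'survival_score'].quantile(0.99):.2f})"
    )

    rows = []
    perts = [c[2:] for c in table.columns if c.startswith("Z_")]
    for a, b in itertools.combinations(perts, 2):
        _, frac = sc.classify_pairwise(table[f"Z_{a}"], table[f"Z_{b}"])
        rows.append({"pert_a": a, "pert_b": b, **frac})
    cls = pd.DataFrame(rows)
    sio._write_tsv(cls, OUT / "pairwise_classification.tsv", {"threshold": 1.28}, False)
    print(
        f"perturbation-pair classification (mean correlated fraction "
        f"{cls['correlated'].mean():.3f}, anticorrelated "
        f"{cls['anticorrelated'].mean():.3f}) -> pairwise_classification.tsv"
    )


if __name__ == "__main__":
    sys.exit(main())
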