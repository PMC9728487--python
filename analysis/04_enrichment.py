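"""Enrichment stage: restrict the background to proteins scored in at
least 3 of the 5 perturbations, then test every gene set for a shift of
its Survival scores toward higher values (two-sample KS, signed scores)
with BH correction.

Reads results/survival_scores.tsv + results/fixtures/gene_sets.gmt,
writes results/enrichment.tsv.
"""

import sys
from pathlib import Path

from survscore import enrichment as en
from survscore import io as sio

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    scores_path = OUT / "survival_scores.tsv"
    if not scores_path.exists():
        sys.exit("run analysis/03_survival_scores.py first")
    scores = sio.read_scores(scores_path)
    background = en.filter_min_perturbations(scores, k=3)
    sets = sio.read_gmt(OUT / "fixtures" / "gene_sets.gmt")
    result = en.enrich_gene_sets(sets, background, side="greater", min_size=5)
    sio.write_enrichment(result, OUT / "enrichment.tsv", meta={"min_k": 3})
    print(f"background: {len(background)} proteins with n_P >= 3")
    top = result.sort_values("pvalue").head(3)
    print("top sets by p-value:")
    for r in top.itertuples(index=False):
        print(
            f"  {r.set_id:16s} n={r.n:3d} delta={r.delta_survival_score:+.2f} "
            f"p={r.pvalue:.2e} FDR={r.fdr:.2e}"
        )
    n_sig = int((result["fdr"] < 0.05).sum())
    print(f"{n_sig} of {len(result)} sets at FDR < 0.05 -> {OUT / 'enrichment.tsv'}")


if __name__ == "__main__":
    sys.exit(main())
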