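"""Structural characterization of differentially included exons.

Maps probesets one-to-one onto exons, labels them Up / Down / background
at moderated p <= 0.01, and compares the eight structural features
(splice-site scores, intron and exon lengths, A+T content, gene length,
3'-end distance) between each direction group and the remaining tested
exons with rank-sum tests and BH correction; also reports short-intron /
long-exon class fractions and ESE hexamer prevalence.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from study_config import OUTDIR, study_config  # noqa: E402

from exoninclusion import io  # noqa: E402
from exoninclusion.pipeline import run_pipeline  # noqa: E402


def main() -> None:
    report = run_pipeline(study_config(["characterize"]))
    outdir = Path(OUTDIR)
    counts = report.stage_counts["characterize"]
    print(f"{counts['exons']} exons characterized: {counts['up']} Up, "
          f"{counts['down']} Down at moderated p <= 0.01")
    comp = io.read_table(outdir / "feature_comparisons.tsv",
                         index_col=None)
    up = comp[comp["group"] == "Up"].set_index("feature")
    for feature in ("exon_length", "intron_up", "at_fraction",
                    "gene_length", "dist3"):
        if feature not in up.index:
            continue
        row = up.loc[feature]
        print(f"  Up vs rest, {feature}: median {row['group_median']:.3g} "
              f"vs {row['baseline_median']:.3g}, "
              f"BH-adjusted p = {row['adjusted']:.2e}")
    classes = io.read_table(outdir / "length_classes.tsv")
    print("short upstream introns (<250 bp): "
          + ", ".join(f"{g}: {classes.at[g, 'frac_short_intron_up']:.3f}"
                      for g in classes.index))
    prev = io.read_table(outdir / "ese_prevalence.tsv")
    print("ESE prevalence (hits/bp): "
          + ", ".join(f"{g}: {prev.at[g, 'prevalence']:.2e}"
                      for g in prev.index))


if __name__ == "__main__":
    main()
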