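"""Filter probesets by detection/cross-hybridization and compute inclusion.

Applies the three filters (probeset detected in at least half the samples;
cross-hybridizing probesets dropped; metaprobesets keep at least half of
their probesets detected in all samples) and writes the normalized
inclusion matrix I = probeset - metaprobeset (log2).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from study_config import OUTDIR, study_config  # noqa: E402

from exoninclusion.pipeline import run_pipeline  # noqa: E402


def main() -> None:
    report = run_pipeline(study_config(["include"]))
    f = report.filter_report
    print(f"input probesets:                {f['n_input']}")
    print(f"removed (detected < half):      {f['n_removed_detection']}")
    print(f"removed (cross-hybridization):  {f['n_removed_cross_hyb']}")
    print(f"removed (metaprobeset rule):    "
          f"{f['n_removed_metaprobeset_rule']}")
    print(f"retained for analysis:          {f['n_output']}")
    print(f"inclusion matrix at {OUTDIR}/inclusion.tsv")


if __name__ == "__main__":
    main()
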