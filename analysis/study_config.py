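"""Shared configuration for the numbered analysis scripts.

One fixed-seed synthetic study emulating the paired design: 4 case/control
sibling pairs, ~40,000 probesets across 5,800 genes, 20% of probesets with
a planted inclusion shift (exponential magnitude, mean 0.35 log2 units ~
1.4x the measurement noise, 80% positive = higher inclusion in cases).
Every script reads and writes under results/study/ so they can be run in
order, one stage each.
"""

from exoninclusion.pipeline import PipelineConfig
from exoninclusion.simulate import SimulationParams

OUTDIR = "results/study"
SEED = 20140627


def study_config(stages) -> PipelineConfig:
    return PipelineConfig(
        outdir=OUTDIR,
        stages=tuple(stages),
        seed=SEED,
        simulation=SimulationParams(
            n_pairs=4,
            n_genes=5800,
            pi0_true=0.8,
            effect_size=0.35,
            direction_bias=0.8,
            pair_sd=0.5,
            gene_sd=1.0,
            noise_sd=0.25,
            detect_fraction=0.95,
        ),
    )
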