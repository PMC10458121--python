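"""Shared configuration for the numbered analysis drivers.

One desk-scale study configuration: the full 2068-point grid and 64-sample
design, with the selector/tuner sampling counts scaled down (every 10th
wavelength enters selection; 100 bootstrap/WBMS samples; small PSO swarm) so
the whole analysis chain runs in minutes on one CPU. docs/methods.md
discusses what the scaling does and does not change.
"""

from adulterspec.pipeline import PipelineConfig

SEED = 1

STUDY = PipelineConfig(
    wavelength_step=10,
    n_mc=50,
    n_boot=100,
    n_wbms=100,
    spa_max_vars=25,
    pso_swarm=10,
    pso_iterations=10,
    seed=SEED,
)
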