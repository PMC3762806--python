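"""Shared study configuration for the analysis scripts.

One synthetic "tournament": two groups (expert / intermediate) of three
matches, six scenes per match, planted with two-mode attractor chains
whose mode persistence differs between groups (experts hold the
"farthest apart" high-velocity mode more often).
"""

from retmap.pipeline import PipelineConfig

SEED = 20240917

STUDY = dict(
    seed=SEED,
    sim_mode="fn_mixture",
    n_matches=3,
    scenes_per_match=6,
    noise_sigma=0.01,
    groups=("expert", "intermediate"),
    p_stay_high={"expert": 0.7, "intermediate": 0.45},
)


def study_config(**overrides) -> PipelineConfig:
    cfg = dict(STUDY)
    cfg.update(overrides)
    return PipelineConfig(**cfg)
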