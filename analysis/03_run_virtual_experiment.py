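#!/usr/bin/env python
"""Simulate the localization experiment through the Bayesian observer.

Replays the study design — 25 spectral-contrast stimuli at 48 random
frontal directions, 1200 trials in 8 blocks — with 3 dB per-bin sensory
noise and the 30 dB SPL room noise floor.  Writes the trial table and
the full artifact bundle (HRTF table, stimuli, per-condition summary,
contrast/level profiles, manifest) under results/.
"""

from pathlib import Path

from specloc.pipeline import PipelineConfig, run_pipeline

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cfg = PipelineConfig(seed=1, use_noise=True, make_plots=False)
    manifest = run_pipeline(cfg, OUT)
    print(f"simulated {manifest['n_trials']} trials over "
          f"{manifest['n_conditions']} stimulus conditions (seed {cfg.seed})")
    print(f"stage seeds: {manifest['stage_seeds']}")
    print(f"template uniqueness margin: {manifest['uniqueness_margin']:.2e}")
    print(f"artifacts: {', '.join(manifest['files'])} -> {OUT}")


if __name__ == "__main__":
    main()
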