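#!/usr/bin/env python
"""Run the full pipeline end to end (simulation, two-round MS selection,
syntenic scoring, evolutionary inference, latent classes, expression support,
priority ranking) and write the consolidated reports."""

import json
from pathlib import Path

from utorf.pipeline import PipelineConfig, run_end_to_end
from utorf.simulate import SimConfig

OUT = Path(__file__).resolve().parents[1] / "results" / "end_to_end"
SEED = 0


def main() -> None:
    result = run_end_to_end(
        config=PipelineConfig(seed=SEED),
        sim=SimConfig(seed=SEED, n_loci=60),
        out_dir=OUT,
        calibrate=True,
    )
    print(json.dumps(result.recovery, indent=2))


if __name__ == "__main__":
    main()
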