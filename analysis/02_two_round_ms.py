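#!/usr/bin/env python
"""Two-round discovery/verification selection on the simulated PSM tables."""

import json
from pathlib import Path

import pandas as pd

from utorf import io as io_mod
from utorf.proteomics import two_round_select

ROOT = Path(__file__).resolve().parents[1] / "results"
INP = ROOT / "inputs"
OUT = ROOT / "two_round"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    round1 = io_mod.read_psm_table(INP / "synthetic_round1_psms.tsv")
    round2 = io_mod.read_psm_table(INP / "synthetic_round2_psms.tsv")
    db_ids = set((INP / "synthetic_db_ids.txt").read_text().split())
    verified = two_round_select(round1, db_ids, round2, fdr1=0.2, fdr2=0.01)
    (OUT / "verified_candidates.txt").write_text(
        "\n".join(sorted(verified)) + "\n"
    )
    summary = {"n_round1_psms": len(round1), "n_round2_psms": len(round2),
               "n_verified": len(verified)}
    (OUT / "summary.json").write_text(json.dumps(summary, indent=2))
    print(summary)


if __name__ == "__main__":
    main()
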