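#!/usr/bin/env python
"""Generate the synthetic input set (MSA loci, truth table, PSM tables)."""

from pathlib import Path

import pandas as pd

from utorf import io as io_mod
from utorf.simulate import SimConfig, simulate_msa_loci, simulate_two_round_tables

OUT = Path(__file__).resolve().parents[1] / "results" / "inputs"
SEED = 0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(seed=SEED, n_loci=60)
    blocks, _, truths = simulate_msa_loci(cfg)
    io_mod.write_maf(OUT / "synthetic_loci.maf", blocks)
    (OUT / "synthetic_tree.nwk").write_text(cfg.tree_newick + "\n")
    pd.DataFrame(
        {
            "locus": [t.locus_id for t in truths],
            "kind": [t.scenario.kind for t in truths],
            "orf_aa": [t.orf_aa for t in truths],
            "orf_start": [t.orf_interval.start for t in truths],
            "orf_end": [t.orf_interval.end for t in truths],
            "is_de_novo": [t.is_de_novo for t in truths],
            "n_losses": [t.n_losses for t in truths],
        }
    ).to_csv(OUT / "synthetic_truth.tsv", sep="\t", index=False)
    tables = simulate_two_round_tables(cfg)
    io_mod.write_psm_table(OUT / "synthetic_round1_psms.tsv", tables["round1"])
    io_mod.write_psm_table(OUT / "synthetic_round2_psms.tsv", tables["round2"])
    (OUT / "synthetic_db_ids.txt").write_text(
        "\n".join(sorted(tables["full_db_ids"])) + "\n"
    )
    print(f"wrote synthetic inputs for {cfg.n_loci} loci to {OUT}")


if __name__ == "__main__":
    main()
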