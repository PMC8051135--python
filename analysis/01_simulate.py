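"""Generate the synthetic paired-condition dataset used by the analyses.

Writes the full dataset (segmentations, peaks, genes, expression, genome,
signal tracks, truth tables) under scratch/dataset/ and a compact summary
table under results/.
"""

from pathlib import Path

import pandas as pd

from chromenh.simulate import SimulationConfig, simulate_dataset, write_dataset

ROOT = Path(__file__).resolve().parents[1]
SEED = 1


def main() -> None:
    cfg = SimulationConfig(seed=SEED)
    ds = simulate_dataset(cfg)
    outdir = ROOT / "scratch" / "dataset"
    write_dataset(ds, outdir)

    rows = []
    for cond in cfg.conditions:
        eset = ds.enhancers[cond]
        rows.append(
            {
                "condition": cond,
                "n_segments": len(ds.segmentations[cond].segments()),
                "n_enhancers": len(eset),
                "n_stretch_enhancers": len(eset.stretch()),
                "n_peaks": len(ds.peaks[cond]),
            }
        )
    summary = pd.DataFrame(rows)
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    summary.to_csv(results / "dataset_summary.tsv", sep="\t", index=False)
    print(f"dataset written to {outdir}")
    print(summary.to_string(index=False))
    print(
        f"planted: {len(ds.gene_truth['bound_ids'])} bound genes, "
        f"{len(ds.gene_truth['signature_ids'])} signature genes, "
        f"{len(ds.motif_truth)} surviving motif plants"
    )


if __name__ == "__main__":
    main()
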