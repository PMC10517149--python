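#!/usr/bin/env python
"""Generate the synthetic 2D and 3D reference datasets.

Produces the monolayer-style (2D) and organotypic/multi-spheroid-style
(3D) assay readouts used by the downstream calibration and validation
steps, together with the drug-input table (IC50 values and concentration
ladders). Real measurements in the same CSV schema can be dropped in
place of these files.
"""

from pathlib import Path

from omensim.synthetic_data import (
    dataset_to_csv,
    default_spec,
    generate_dataset,
    generate_drug_inputs,
)

OUT = Path("results/datasets")
SEED_2D, SEED_3D = 101, 202


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for setting, seed in (("2D", SEED_2D), ("3D", SEED_3D)):
        ds = generate_dataset(default_spec(setting, rng_seed=seed))
        path = OUT / f"dataset_{setting.lower()}.csv"
        dataset_to_csv(ds, path)
        print(
            f"{setting}: EG={ds.eg:.2f}  invasion={ds.invasion_count:.1f} cells  "
            f"adhesion(2/3/4 h)={ds.adhesion[2]:.3f}/{ds.adhesion[3]:.3f}/{ds.adhesion[4]:.3f}"
            f"  -> {path}"
        )
    drugs = generate_drug_inputs()
    drugs.to_csv(OUT / "drug_inputs.csv", index=False)
    print(f"drug inputs (IC50 + concentration ladders) -> {OUT/'drug_inputs.csv'}")
    print(
        "note: 3D invasion is ~2x the 2D mean and 3D replicate scatter is larger, "
        "matching the structure of the wet-lab readouts these stand in for"
    )


if __name__ == "__main__":
    main()
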