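#!/usr/bin/env python
"""Derive geometry predictors and assemble the standardized design.

Reads the simulated fixture from results/sim, deduplicates repeat
locations (<= 10 m), computes fetch / boat-travel access predictors,
applies the < 9.14 m depth filter, and writes the standardized occupancy
and detection design matrices with their scaling sidecar to
results/prepared.
"""

from pathlib import Path

from stonewort import config as cfg, simulate

IN = Path("results/sim")
OUT = Path("results/prepared")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    c = cfg.PipelineConfig(
        lakes_path=str(IN / "lakes.geojson"),
        points_path=str(IN / "points.csv"),
        visits_path=str(IN / "visits.csv"),
        lake_meta_path=str(IN / "lake_meta.csv"),
        output_dir=str(OUT),
        characeae_taxa=list(simulate.CHARACEAE_TAXA),
    )
    design = cfg.prepare_stage(c, OUT)
    print(f"design written to {OUT}/design/")
    print(
        f"X: {design.X.shape[0]} point-years x {design.X.shape[1]} covariates "
        f"({', '.join(design.x_names)})"
    )
    print(f"V: {design.V.shape[0]} visits x {design.V.shape[1]} covariates")
    lo, hi = design.scaling["dist_access"]
    print(f"distance-to-access scaling: mean {lo:.1f} m, sd {hi:.1f} m")


if __name__ == "__main__":
    main()
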