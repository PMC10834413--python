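#!/usr/bin/env python
"""Generate the desk-scale synthetic survey dataset.

Five lakes (circle/ellipse/island shapes), 65 m survey grids, three
survey years with 1-2 visits, and latent occupancy/detection drawn from
the occupancy model with known coefficients.  Writes the GeoJSON/CSV
fixture the rest of the analysis ingests, plus truth.json for the
recovery check in 03_fit.py.
"""

from pathlib import Path

from stonewort import simulate

SEED = 1
OUT = Path("results/sim")


def main() -> None:
    sim = simulate.simulate_dataset(seed=SEED)
    paths = simulate.write_fixture(sim, OUT)
    d = sim.design
    print(f"wrote {len(paths)} files to {OUT}/")
    print(
        f"dataset: {d.n_lakes} lakes, {d.n_points} retained points "
        f"(deeper points filtered), {len(d.py)} point-years, {len(d.y)} visits"
    )
    print(
        f"overall naive detection rate {d.y.mean():.3f}; "
        f"true occupancy rate {sim.truth['z'].mean():.3f}"
    )


if __name__ == "__main__":
    main()
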