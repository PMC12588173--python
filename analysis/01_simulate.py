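#!/usr/bin/env python
"""Generate the specimen-calibrated synthetic cochlea and export its point sets.

Writes BM/SG centerlines, dendrite traces and the round-window center to
results/synthetic/ as CSV and Slicer markups, exactly as a traced SR-style
segmentation would be exported.
"""

from pathlib import Path

from cochleomap.io import LabeledPointSet, write_dendrites_csv, write_markups, write_points_csv
from cochleomap.synthetic import generate, paper_preset

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    bundle = generate(paper_preset())
    for name, line in (("bm", bundle.bm), ("sg", bundle.sg)):
        pset = LabeledPointSet(
            name=name.upper(),
            labels=[f"{name}_{i:04d}" for i in range(len(line.points))],
            points=line.points,
        )
        write_points_csv(pset, OUT / f"{name}.csv")
        write_markups(pset, OUT / f"{name}.mrk.json")
    write_dendrites_csv(bundle.dendrites, OUT / "dendrites.csv")
    rw = LabeledPointSet("RW", ["rw_center"], bundle.rw_center.reshape(1, 3))
    write_points_csv(rw, OUT / "rw_center.csv")
    write_markups(rw, OUT / "rw_center.mrk.json")

    print(f"BM centerline: {bundle.bm.total_length:.2f} mm "
          f"({len(bundle.bm.points)} points)")
    print(f"SG centerline: {bundle.sg.total_length:.2f} mm "
          f"({len(bundle.sg.points)} points)")
    print(f"dendrites: {len(bundle.dendrites)}; output in {OUT}")


if __name__ == "__main__":
    main()
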