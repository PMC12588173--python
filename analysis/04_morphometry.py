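#!/usr/bin/env python
"""Innervation-density estimates for the apical cochlea.

Scales the counted apical myelinated axons to the 20-500 Hz basilar-membrane
span, estimates the inner-hair-cell count from the linear density, derives
the axons-per-IHC ratio, and reports the cylinder-packing capacity of the
apical spiral-ganglion cell mass alongside it.
"""

from pathlib import Path

from cochleomap.morphometry import MorphometryParams, estimate_neurons_cylinder, morphometry_summary

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    params = MorphometryParams()
    table = morphometry_summary(params)
    out = ROOT / "morphometry"
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "morphometry.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    capacity = estimate_neurons_cylinder(params)
    print(f"\ncylinder capacity (pure volume ratio, no packing correction): "
          f"{capacity} somata — a capacity bound, to be read next to the "
          f"density-scaled count above")
    print(f"table in {out}")


if __name__ == "__main__":
    main()
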