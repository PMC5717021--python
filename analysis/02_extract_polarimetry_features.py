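"""Validate the imaging-feature extractors against known ground truth.

Builds Stokes tomograms whose polarized fraction decays at a known rate
and birefringence maps with increasing spot heterogeneity, then runs the
extraction pipeline (DOP -> cylinder depth profile -> slope; quantize ->
GLCM -> homogeneity) and reports recovered vs true values.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from scarpol.polarimetry import CylinderROI, compute_dop, dop_depth_profile, fit_dop_slope
from scarpol.synthetic_data import BirefFieldSpec, TomogramSpec, synth_biref_map, synth_stokes_volume
from scarpol.texture import homogeneity_feature

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=7)
    parser.add_argument("--n-volumes", type=int, default=5)
    args = parser.parse_args()
    RESULTS.mkdir(exist_ok=True)

    rows = []
    for true_slope in (0.15, 0.25):
        spec = TomogramSpec(slope=true_slope)
        roi = CylinderROI(
            center_x=spec.n_x * spec.spacing_x / 2, center_y=0.0,
            diameter=1000.0, z_top=0.0, z_bottom=spec.n_z * spec.spacing_z,
        )
        for i in range(args.n_volumes):
            vol = synth_stokes_volume(spec, seed=args.seed + i)
            slope = fit_dop_slope(dop_depth_profile(compute_dop(vol), roi))
            rows.append({"true_slope": true_slope, "seed": args.seed + i,
                         "recovered_slope": slope})
    slopes = pd.DataFrame(rows)
    slopes.to_csv(RESULTS / "dop_slope_recovery.csv", index=False)
    err = (slopes.recovered_slope - slopes.true_slope).abs().max()
    print("DOP slope recovery (1/mm):")
    print(slopes.round(4).to_string(index=False))
    print(f"max |error| = {err:.4f} /mm\n")

    rows = []
    for amplitude in (0.0, 0.1, 0.2, 0.4):
        homs = [
            homogeneity_feature(
                synth_biref_map(BirefFieldSpec(amplitude=amplitude), seed=args.seed + s)
            )
            for s in range(10)
        ]
        rows.append({"spot_amplitude": amplitude,
                     "hom_median": float(np.median(homs)),
                     "hom_min": min(homs), "hom_max": max(homs)})
    homs = pd.DataFrame(rows)
    homs.to_csv(RESULTS / "homogeneity_vs_heterogeneity.csv", index=False)
    print("GLCM homogeneity vs spot amplitude (deg/um):")
    print(homs.round(4).to_string(index=False))
    print("homogeneity decreases as the birefringence field grows more spot-like")


if __name__ == "__main__":
    main()
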