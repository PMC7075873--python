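#!/usr/bin/env python
"""Generate the synthetic inputs for the whole analysis.

Stands in for the upstream molecular-dynamics trajectories and microscopy:
angle time series for the nucleotide states and mutants, rigid subunit pairs
with planted bend/twist, and membrane phosphate clouds of known curvature.
Every artefact gets a ground-truth JSON sidecar.

Outputs under results/synthetic/.
"""

import argparse
import math
from pathlib import Path

from mrebtwist import synthetic_data as sd

#: per-strain intrinsic twist means (deg per monomer step): two low-twist
#: mutants, wild type, two high-twist mutants, mirroring the mutant panel
STRAIN_TWISTS = {"mutLow1": 3.0, "mutLow2": 5.0, "WT": 10.3,
                 "mutHigh1": 12.0, "mutHigh2": 14.0}
TWIST_SD_DEG = 2.1
BEND_MEAN_DEG = math.degrees(2.3e-3 * 5.0)   # theta1 mean matching k0
BEND_SD_DEG = 0.33


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results/synthetic"))
    args = ap.parse_args()
    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)

    print("angle series (theta3 twist + theta1/theta2 bending) per strain:")
    for i, (strain, twist) in enumerate(STRAIN_TWISTS.items()):
        for name, mean, sdev in (("theta3", twist, TWIST_SD_DEG),
                                 ("theta1", BEND_MEAN_DEG, BEND_SD_DEG),
                                 ("theta2", 0.0, BEND_SD_DEG)):
            series, truth = sd.gen_angle_series(
                mean, sdev, seed=args.seed + 17 * i + hash(name) % 7, name=name)
            path = out / f"{strain}_{name}.tsv"
            series.to_tsv(path)
            sd.write_truth_sidecar(path, truth)
        print(f"  {strain}: planted twist {twist:.1f} deg / monomer")

    print("rigid subunit pair with planted (theta1, theta2, theta3):")
    frame, ref, _, truth = sd.gen_rigid_pair(2.0, 0.0, 10.3, noise_nm=0.02,
                                             seed=args.seed)
    import numpy as np

    np.savetxt(out / "rigid_pair.xyz",
               np.column_stack([frame.coords, frame.radii]),
               header="x_nm y_nm z_nm radius_nm", comments="")
    sd.write_truth_sidecar(out / "rigid_pair.xyz", truth)
    print(f"  planted: {truth['theta1_deg']}, {truth['theta2_deg']}, "
          f"{truth['theta3_deg']} deg")

    print("membrane phosphate clouds (flat + 0.8 um cell-width cylinder):")
    for tag, curv in (("flat", 0.0), ("r400", 2.5e-3)):
        pts, truth = sd.gen_membrane_cloud(curv, noise_nm=0.2,
                                           seed=args.seed + 5)
        np.savetxt(out / f"phosphates_{tag}.xyz", pts,
                   header="x_nm y_nm z_nm", comments="")
        sd.write_truth_sidecar(out / f"phosphates_{tag}.xyz", truth)
        print(f"  {tag}: curvature {curv} /nm, 0.2 nm jitter")

    print(f"wrote synthetic inputs to {out}/")


if __name__ == "__main__":
    main()
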