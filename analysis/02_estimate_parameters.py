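#!/usr/bin/env python
"""Estimate the coarse-grained model parameters from the synthetic series.

Fits Gaussians to the equilibrium windows written by 01_generate_synthetic_inputs,
converts fluctuations to moduli (K, C), means to intrinsic rates (k0, omega0)
per strain, and the per-monomer energies to V and mu0.  Writes a per-strain
parameter table and a core-model-ready TOML for the wild type.
"""

import argparse
import json
import math
from pathlib import Path

import pandas as pd

from mrebtwist import parameter_estimation as pe
from mrebtwist.core_model import FilamentParams
from mrebtwist.trajectory_geometry import AngleSeries

BINDING_ENERGY_KT = 10.0      # per monomer, from membrane-interface burial
POLYMERIZATION_DG_KT = 5.0    # per monomer, actin-derived


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--in-dir", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    strains = sorted({p.name.split("_")[0]
                      for p in args.in_dir.glob("*_theta3.tsv")})
    if not strains:
        raise SystemExit(f"no angle series in {args.in_dir}; run 01 first")

    rows = []
    for strain in strains:
        fits = {}
        for name in ("theta1", "theta2", "theta3"):
            series = AngleSeries.from_tsv(args.in_dir / f"{strain}_{name}.tsv",
                                          name)
            fits[name] = pe.equilibrium_window_fit(series)
        K = pe.torsional_modulus(fits["theta3"].sd)
        C = pe.bending_modulus(fits["theta1"].sd, fits["theta2"].sd)
        k0, omega0 = pe.intrinsic_rates(fits["theta1"].mean,
                                        fits["theta2"].mean,
                                        fits["theta3"].mean)
        rows.append({"strain": strain,
                     "twist_mean_deg": fits["theta3"].mean,
                     "twist_sd_deg": fits["theta3"].sd,
                     "K_kBT_nm": K, "C_kBT_nm": C,
                     "k0_rad_nm": k0, "omega0_rad_nm": omega0})
    table = pd.DataFrame(rows).set_index("strain")
    V = pe.binding_potential_per_length(BINDING_ENERGY_KT)
    mu0 = pe.polymerization_density(POLYMERIZATION_DG_KT)
    print(table.round(5))
    print(f"V = {V} kBT/nm, mu0 = {mu0} kBT/nm (per-monomer energy inputs)")

    args.out_dir.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out_dir / "strain_parameters.tsv", sep="\t")
    wt = table.loc["WT"]
    params = FilamentParams(C=float(wt.C_kBT_nm), K=float(wt.K_kBT_nm), V=V,
                            k0=float(wt.k0_rad_nm),
                            omega0=float(wt.omega0_rad_nm), mu0=mu0)
    params.to_toml(args.out_dir / "params_wild_type.toml")
    (args.out_dir / "energy_densities.json").write_text(
        json.dumps({"V_kBT_per_nm": V, "mu0_kBT_per_nm": mu0}, indent=1))
    print(f"wrote {args.out_dir}/strain_parameters.tsv and params_wild_type.toml")


if __name__ == "__main__":
    main()
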