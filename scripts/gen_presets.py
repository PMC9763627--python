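"""Regenerate the shipped YAML presets (developer utility).

Run from the repository root:  python scripts/gen_presets.py
"""

import pathlib

import yaml

ROOT = pathlib.Path(__file__).resolve().parents[1] / "src/rbc_cbmm/presets"

MEMBRANE = {
    "es0": "6.54 uN/m",
    "eb": "2.4e-19 J",
    "ka": "0.288 N/m",
    "kd": "0.144 N/m",
    "k0": "0.432 N/m",
    "k_omega": "220 J/m^3",
    "eta_m": "0.7 uN.s/m",
    "mass_total": "1.0 mg",
}

FRICTION_OPT = {"beta": "0.05 nm^-1", "r0": "20 nm", "r_cutoff": "100 nm",
                "r_glyco": "5 nm", "mu_gap": "3.6 cP"}
LOW_FRICTION = {"beta": "0.05 nm^-1", "r0": "20 nm", "r_cutoff": "100 nm",
                "r_glyco": "0 nm", "mu_gap": "1.8 cP"}
LONG_RANGE = {"beta": "0.05 nm^-1", "r0": "500 nm", "r_cutoff": "2000 nm",
              "r_glyco": "0 nm", "mu_gap": "1.8 cP"}


def uj(x):
    return f"{x} uJ/m^2"


def formation_protocol(nave0):
    return {"protocol": "formation", "duration": "24 s", "n_vertices": 642,
            "snapshot_interval": "0.25 s", "nave0": nave0}


def disagg_protocol(nave0, escape=None):
    p = {"protocol": "disaggregation", "duration": "40 s",
         "pulling_rate": "0.15 um/s", "equilibration": "1.5 s",
         "initial_offset_fraction": 0.3,
         "n_vertices": 642, "snapshot_interval": "0.1 s", "nave0": nave0}
    if escape:
        p["escape_threshold"] = escape
    return p


def write(group, name, cfg):
    path = ROOT / group / f"{name}.yaml"
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def main():
    # --- doublet formation: cross-bridge scheme groups -------------------
    # pure mobile non-specific (mFgB, VTS) at three total affinities
    for tot, gm in ((0.5, 0.25), (1.0, 0.5), (1.5, 0.75)):
        write("formation", f"mobile_nonspecific_{tot}", {
            "name": f"formation mFgB VTS, affinity {tot} uJ/m^2",
            "membrane": MEMBRANE,
            "adhesion": {"gamma_mfg": uj(gm), "scheme": "vts", **FRICTION_OPT},
            "transport": {"d_mfg": "1e-15 m^2/s", "adsorption_on": False},
            "protocol": formation_protocol(2.0),
        })
    # pure immobile non-specific (iFgB, VTS) -> uniform affinity
    for tot in (0.5, 1.0, 1.5):
        write("formation", f"immobile_nonspecific_{tot}", {
            "name": f"formation iFgB VTS (UAM), affinity {tot} uJ/m^2",
            "membrane": MEMBRANE,
            "adhesion": {"gamma_ifg": uj(tot), "scheme": "vts", **FRICTION_OPT},
            "protocol": formation_protocol(0.0),
        })
    # mixed mobile + specific (mFgB VTS + iFgRB VTV)
    for tot, gr, gm in ((0.5, 0.25, 0.125), (1.0, 0.5, 0.25), (1.5, 0.5, 0.5)):
        write("formation", f"mixed_mobile_specific_{tot}", {
            "name": f"formation mFgB VTS + iFgRB VTV, affinity {tot} uJ/m^2",
            "membrane": MEMBRANE,
            "adhesion": {"gamma_ifgr": uj(gr), "gamma_mfg": uj(gm),
                         "scheme": "mixed", **FRICTION_OPT},
            "transport": {"d_mfg": "1e-15 m^2/s", "adsorption_on": False},
            "protocol": formation_protocol(2.0),
        })
    # mixed immobile + specific (iFgB VTS + iFgRB VTV)
    for tot, gr, gi in ((0.5, 0.25, 0.25), (1.0, 0.5, 0.5), (1.5, 0.5, 1.0)):
        write("formation", f"mixed_immobile_specific_{tot}", {
            "name": f"formation iFgB VTS + iFgRB VTV, affinity {tot} uJ/m^2",
            "membrane": MEMBRANE,
            "adhesion": {"gamma_ifgr": uj(gr), "gamma_ifg": uj(gi),
                         "scheme": "mixed", **FRICTION_OPT},
            "protocol": formation_protocol(0.0),
        })
    # pure specific (iFgRB, VTV)
    for tot in (0.5, 1.0, 1.5):
        write("formation", f"specific_vtv_{tot}", {
            "name": f"formation iFgRB VTV, affinity {tot} uJ/m^2",
            "membrane": MEMBRANE,
            "adhesion": {"gamma_ifgr": uj(tot), "scheme": "vtv", **FRICTION_OPT},
            "protocol": formation_protocol(0.0),
        })
    # friction variants at affinity 1.0
    write("formation", "low_friction", {
        "name": "formation iFgB VTS, low-friction variant",
        "membrane": MEMBRANE,
        "adhesion": {"gamma_ifg": uj(1.0), "scheme": "vts", **LOW_FRICTION},
        "protocol": formation_protocol(0.0),
    })
    write("formation", "long_range", {
        "name": "formation iFgB VTS, long-range Morse variant",
        "membrane": MEMBRANE,
        "adhesion": {"gamma_ifg": uj(1.0), "scheme": "vts", **LONG_RANGE},
        "protocol": formation_protocol(0.0),
    })

    # --- disaggregation --------------------------------------------------
    for tot in (0.5, 1.0, 1.5, 2.0, 3.5, 5.0):
        write("disagg", f"uam_{tot}", {
            "name": f"disaggregation UAM, affinity {tot} uJ/m^2",
            "membrane": MEMBRANE,
            "adhesion": {"gamma_ifg": uj(tot), "scheme": "vts", **FRICTION_OPT},
            "protocol": disagg_protocol(0.0),
        })
    for label, d in (("high_diffusivity", "1.8e-11 m^2/s"),
                     ("moderate_diffusivity", "1e-14 m^2/s"),
                     ("low_diffusivity", "1e-15 m^2/s")):
        write("disagg", f"cbmm_{label}", {
            "name": f"disaggregation CBMM, {label.replace('_', ' ')}",
            "membrane": MEMBRANE,
            "adhesion": {"gamma_ifg": uj(1.0), "gamma_mfg": uj(0.25),
                         "scheme": "vts", **FRICTION_OPT},
            "transport": {"d_mfg": d, "adsorption_on": False},
            "protocol": disagg_protocol(2.0, escape="32 pN"),
        })
    for phi0 in (0.001, 0.01, 0.1, 2, 10):
        write("disagg", f"cbmm_adsorption_phi{phi0}", {
            "name": f"disaggregation CBMM with bulk exchange, phi0={phi0}",
            "membrane": MEMBRANE,
            "adhesion": {"gamma_ifg": uj(1.0), "gamma_mfg": uj(0.25),
                         "scheme": "vts", **FRICTION_OPT},
            "transport": {"d_mfg": "1e-15 m^2/s", "adsorption_on": True,
                          "phi0": phi0, "n0": 1.0},
            "protocol": disagg_protocol(2.0, escape="32 pN"),
        })

    # --- pathophysiology -------------------------------------------------
    cases = [
        ("healthy_lower", 1.0, 1.0),
        ("healthy_median", 1.25, 1.0),
        ("healthy_upper", 1.5, 1.0),
        ("elevated_n2", 2.0, 1.0),
        ("sle_median", 1.5, 2.0),
    ]
    for label, n_star, g_star in cases:
        write("patho", label, {
            "name": f"disaggregation pathophysiology {label} "
                    f"(N*={n_star}, Gamma*={g_star})",
            "membrane": MEMBRANE,
            "adhesion": {"gamma_ifg": uj(1.0), "gamma_mfg": uj(0.25 * g_star),
                         "scheme": "vts", **FRICTION_OPT},
            "transport": {"d_mfg": "1e-15 m^2/s", "adsorption_on": True,
                          "phi0": 0.001, "n0": n_star},
            "pathophys": {"n_star": n_star, "gamma_star": g_star,
                          "n_b_rbc1": 1.0, "n_b_rbc2": 1.0,
                          "gamma_mfg_b": "0.25 uJ/m^2"},
            "protocol": disagg_protocol(2.0 * n_star),
        })
    print(f"presets written under {ROOT}")


if __name__ == "__main__":
    main()
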