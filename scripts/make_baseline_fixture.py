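#!/usr/bin/env python
"""Regenerate the shipped baseline data files (maintainer tool).

The baseline fixture is a synthetic stand-in for a rat calibration
dataset: plausible steady-state pool sizes plus a designed Delta15N
pattern (all N fractions 15N-enriched over the diet except muscle free AA
and body urea; urinary urea at the dietary value; protein-minus-AA
differences of 4.8 / 4.1 / 0.6 permil in muscle / heart / kidney).  The
five pattern values that the model's balance equations determine (stomach
content, plasma free AA, hair, caeco-colonic content, feces) are computed
here exactly, which makes the pattern exactly attainable at steady state
and the 19 free fractionation factors exactly identifiable.

Writes:
  src/isoflux/data/rat_constraints.yaml   literature constraint set
  src/isoflux/data/rat_measurements.csv   baseline measurement fixture
  src/isoflux/data/rat_model.yaml          calibrated topology (k and eps)
"""
import numpy as np
import pandas as pd

from isoflux import calibration as cal
from isoflux import io as iio
from isoflux import rat
from isoflux.dynamics import find_steady_state, flux_report

#: steady-state pool sizes, mmol N per 100 g body weight
POOLS = {
    "St": 0.6, "SIl": 1.5, "CC": 1.6,
    "SIp": 1.05, "SIa": 0.35, "Lp": 12.4, "La": 1.6,
    "Plp": 2.2, "Pla": 0.85,
    "Mp": 95.0, "Ma": 5.5, "Kp": 3.2, "Ka": 0.45,
    "Hp": 1.9, "Ha": 0.22, "Rp": 11.5, "Ra": 1.1,
    "Skp": 52.0, "Ska": 2.4, "Hair": 14.0, "U": 2.4,
}

CONSTRAINTS = cal.CalibrationConstraints(
    intake=10.0, diet_delta=3.5,
    fsr={"SIp": 1.5, "Lp": 0.5, "Plp": 0.25, "Mp": 0.11, "Kp": 0.42,
         "Hp": 0.20, "Rp": 0.03, "Skp": 0.07},
    ti={"M": 1.5, "K": 1.5, "H": 1.5, "R": 1.5, "Sk": 0.8},
)

# Freely designed Delta15N values (permil over diet).  Splanchnic free-AA
# pools sit close to their luminal/portal/plasma supply so the implied
# oxidation epsilons stay in the few-permil range plausible for enzymatic
# amino-group transfers.
DESIGN = {
    "SIl": 0.3, "SIp": 2.3, "SIa": 0.3,
    "Lp": 2.45, "La": 0.35, "Plp": 3.2,
    "Mp": 3.8, "Ma": -1.0,
    "Kp": 1.3, "Ka": 0.7,
    "Hp": 4.6, "Ha": 0.5,
    "Rp": 3.4, "Ra": 0.4,
    "Skp": 3.2, "Ska": 1.2,
    "U": -0.6,
    "urine_urea": 0.0, "urine_NH4": -1.5,
}


def main() -> None:
    meas_pools = pd.DataFrame({
        "compartment": list(POOLS), "N_mmol_per_100g": list(POOLS.values()),
        "Delta15N_permil": np.nan, "sd_N": np.nan, "sd_delta": np.nan,
    })
    rc = cal.calibrate_rates(meas_pools, CONSTRAINTS)
    f = rc.fluxes

    d = dict(DESIGN)
    d["St"] = 0.0
    # plasma free AA: no fractionation on any of its own fluxes, so its
    # steady value is the flux-weighted mean of its inputs
    aa_of = {"M": "Ma", "K": "Ka", "H": "Ha", "R": "Ra", "Sk": "Ska"}
    num = (f["outL"] * d["La"] + f["dPl"] * d["Plp"]
           + sum(f[f"out{t}"] * d[aa_of[t]] for t in rat.TI_TISSUES))
    den = f["outL"] + f["dPl"] + sum(f[f"out{t}"] for t in rat.TI_TISSUES)
    d["Pla"] = num / den
    d["Hair"] = d["Ska"]
    # caeco-colonic content closes the whole-body isotope balance
    d["CC"] = (-(f["UE"] * d["urine_urea"] + f["NH4"] * d["urine_NH4"]
                 + f["lHa"] * d["Hair"] + f["lSk"] * d["Skp"]) / f["FL"])
    d["feces"] = d["CC"]

    rows = []
    for cid in list(POOLS) + list(cal.OBSERVABLE_FLUXES):
        rows.append({
            "compartment": cid,
            "N_mmol_per_100g": POOLS.get(cid, np.nan),
            "Delta15N_permil": d[cid],
            "sd_N": 0.05 * POOLS[cid] if cid in POOLS else np.nan,
            "sd_delta": 0.1,
        })
    meas = pd.DataFrame(rows)

    eps = cal.calibrate_fractionation(meas, rc.topology)
    assert eps.residuals.abs().max() < 1e-9, "designed pattern not attainable"
    topo = eps.topology(rc.topology)
    st = find_steady_state(topo)
    err = max(abs(st.delta[topo.index(c)] - CONSTRAINTS.diet_delta - d[c])
              for c in POOLS)
    assert err < 1e-9, "steady state deviates from the designed pattern"

    CONSTRAINTS.to_yaml("src/isoflux/data/rat_constraints.yaml")
    cal.write_measurements(meas, "src/isoflux/data/rat_measurements.csv")
    iio.save_model_config(topo, "src/isoflux/data/rat_model.yaml")
    print("baseline fixture regenerated; %ox =", round(rc.pct_ox, 6))


if __name__ == "__main__":
    main()
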