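"""Two-phase steady-state calibration of the rat nitrogen model.

Phase 1 (:func:`calibrate_rates`) closes the under-determined elemental
mass balance with literature rules: tissue protein synthesis and
degradation are pinned to fractional synthesis rates (``f_sT = f_dT =
FSR_T * T_P``), plasma-to-tissue AA inflows to transport indices
(``f_inT = TI_T * f_sT``), and a tissue-uniform oxidation share ``%ox``
is chosen so that total urea production equals the dietary N intake.
The remaining gastrointestinal and hepatic fluxes are solved
per-compartment in a declared resolution order.  Rate constants follow as
``k = f / N_source`` from the measured pool sizes.

Phase 2 (:func:`calibrate_fractionation`) estimates the minimal
(parsimonious) set of fractionation factors from the measured Delta15N
pattern.  At fixed rates the isotopic steady state is linear in the
epsilons, so the free factors are obtained by one weighted linear
least-squares solve -- exact and deterministic.  Protein degradation and
plasma/tissue AA transport carry no isotope effect by convention
(``eps_d = eps_in = eps_out = 0``); all fitting is done in diet-referenced
Delta15N space so the dietary baseline cancels.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import rat
from .dynamics import flux_report, steady_state_delta, steady_state_N
from .topology import DIET, ModelTopology, compile_structure

#: elimination observables: measured excreta deltas are instantaneous-flux
#: abundances (delta_source + epsilon of the sink-bound flux)
OBSERVABLE_FLUXES = {"urine_urea": "UE", "urine_NH4": "NH4", "feces": "FL"}

#: the parsimonious free set: synthesis and oxidation per tissue plus the
#: four gastrointestinal/urinary effects needed for the excreta pattern
DEFAULT_FREE_EPSILONS = (
    tuple(f"s{t}" for t in rat.OX_TISSUES) + ("sPl",)
    + tuple(f"ox{t}" for t in rat.OX_TISSUES)
    + ("secSI", "absCC", "UE", "NH4")
)


class CalibrationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# measurement table
# ---------------------------------------------------------------------------

MEASUREMENT_COLUMNS = ["compartment", "N_mmol_per_100g", "Delta15N_permil",
                       "sd_N", "sd_delta"]


def read_measurements(path) -> pd.DataFrame:
    """Read a measurement table CSV (pool sizes and Delta15N values).

    Rows are compartment ids plus the elimination observables
    ``urine_urea``, ``urine_NH4`` and ``feces`` (whose N column may be
    empty).  SD columns are optional.
    """
    with resources_open(path) as fh:
        df = pd.read_csv(fh, comment="#")
    missing = {"compartment", "N_mmol_per_100g", "Delta15N_permil"} - set(df.columns)
    if missing:
        raise CalibrationError(f"measurement table missing columns: {sorted(missing)}")
    for col in ("sd_N", "sd_delta"):
        if col not in df.columns:
            df[col] = np.nan
    return df[MEASUREMENT_COLUMNS]


def resources_open(path):
    """Open a filesystem path or an importlib.resources traversable."""
    if hasattr(path, "open"):
        return path.open("r")
    return open(path, "r")


def write_measurements(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def measured_pools(measurements: pd.DataFrame) -> dict[str, float]:
    pools = {
        row.compartment: float(row.N_mmol_per_100g)
        for row in measurements.itertuples()
        if row.compartment not in OBSERVABLE_FLUXES
    }
    bad = [c for c, n in pools.items() if not np.isfinite(n) or n <= 0]
    if bad:
        raise CalibrationError(f"non-positive pool sizes for: {bad}")
    return pools


def measured_deltas(measurements: pd.DataFrame, diet_delta: float) -> dict[str, float]:
    """Absolute delta15N per measured compartment/observable."""
    return {
        row.compartment: float(row.Delta15N_permil) + diet_delta
        for row in measurements.itertuples()
        if np.isfinite(row.Delta15N_permil)
    }


# ---------------------------------------------------------------------------
# constraints
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationConstraints:
    """Literature rules that close the elemental mass balance.

    ``fsr`` maps protein-pool ids to fractional synthesis rates (d^-1);
    ``ti`` maps tissue codes to transport indices (dimensionless).  The
    gastrointestinal rules are fractions of the dietary intake except
    ``ileal_digestibility`` (fraction of total small-intestinal flow
    absorbed proximally).
    """

    intake: float
    diet_delta: float
    fsr: Mapping[str, float]
    ti: Mapping[str, float]
    secretion_frac_intake: float = 0.5
    ileal_digestibility: float = 0.9
    fecal_frac_intake: float = 0.099
    ammonia_frac_intake: float = 0.051
    hair_loss_frac_intake: float = 0.02
    desquamation_frac_intake: float = 0.01
    delivery_frac_intake: float = 2.5

    def __post_init__(self):
        if self.intake <= 0:
            raise CalibrationError("intake must be positive")
        if any(v <= 0 for v in self.fsr.values()):
            raise CalibrationError("FSR values must be positive")
        if any(v <= 0 for v in self.ti.values()):
            raise CalibrationError("transport indices must be positive")

    @classmethod
    def from_yaml(cls, path) -> "CalibrationConstraints":
        with resources_open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self, path) -> None:
        payload = {
            "intake": float(self.intake),
            "diet_delta": float(self.diet_delta),
            "fsr": {k: float(v) for k, v in self.fsr.items()},
            "ti": {k: float(v) for k, v in self.ti.items()},
            "secretion_frac_intake": float(self.secretion_frac_intake),
            "ileal_digestibility": float(self.ileal_digestibility),
            "fecal_frac_intake": float(self.fecal_frac_intake),
            "ammonia_frac_intake": float(self.ammonia_frac_intake),
            "hair_loss_frac_intake": float(self.hair_loss_frac_intake),
            "desquamation_frac_intake": float(self.desquamation_frac_intake),
            "delivery_frac_intake": float(self.delivery_frac_intake),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# phase 1: rates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RateCalibration:
    """Result of phase 1: fluxes, rate constants and the closed %ox."""

    topology: ModelTopology           # rates populated, epsilons zero
    fluxes: dict[str, float]
    pct_ox: float


_P_POOL = {"SI": "SIp", "L": "Lp", "M": "Mp", "K": "Kp", "H": "Hp",
           "R": "Rp", "Sk": "Skp"}
_AA_POOL = {"SI": "SIa", "L": "La", "M": "Ma", "K": "Ka", "H": "Ha",
            "R": "Ra", "Sk": "Ska"}


def calibrate_rates(measurements: pd.DataFrame,
                    constraints: CalibrationConstraints,
                    topology: ModelTopology | None = None) -> RateCalibration:
    """Solve the steady-state elemental balance for all 49 fluxes.

    Resolution order (each step closes one balance or applies one rule):

    1. gastric emptying = intake; endogenous secretion, fecal, ammonia,
       hair and desquamation losses as intake fractions; proximal
       absorption from ileal digestibility; ileal transit closes the SI
       lumen.
    2. ``f_sT = f_dT = FSR_T * T_P`` per tissue (skin degradation nets out
       desquamation; hair deposition equals hair loss).
    3. uniform %ox such that total urea production equals intake
       (liver output counts hepatic + plasma protein synthesis).
    4. ``f_inT = TI_T * f_sT``; tissue AA balances close ``f_outT``.
    5. urinary urea from whole-body balance, recycling from the urea
       balance, caeco-colonic absorption from the colon balance, portal
       flux from the mucosal balance, hepatic AA inflow from the liver
       balance (delivery ``f_outL`` is pinned to the literature value);
       the plasma AA balance is the redundant consistency check.

    The measured pool sizes become the exact elemental steady state and
    ``k = f / N_source``.
    """
    c = constraints
    N = measured_pools(measurements)
    intake = c.intake
    f: dict[str, float] = {"diet": intake, "tSt": intake}
    f["secSI"] = c.secretion_frac_intake * intake
    f["absSI"] = c.ileal_digestibility * (f["tSt"] + f["secSI"])
    f["tSI"] = f["tSt"] + f["secSI"] - f["absSI"]
    f["FL"] = c.fecal_frac_intake * intake
    f["NH4"] = c.ammonia_frac_intake * intake
    f["lHa"] = c.hair_loss_frac_intake * intake
    f["lSk"] = c.desquamation_frac_intake * intake

    for t in rat.OX_TISSUES:
        p = _P_POOL[t]
        if p not in c.fsr:
            raise CalibrationError(f"no FSR for tissue pool {p}")
        f[f"s{t}"] = c.fsr[p] * N[p]
        f[f"d{t}"] = f[f"s{t}"]
    f["dSk"] = f["sSk"] - f["lSk"]        # skin protein nets out desquamation
    f["sPl"] = c.fsr["Plp"] * N["Plp"]
    f["dPl"] = f["sPl"]
    f["sHa"] = f["lHa"]                   # hair deposition balances loss

    syn = {t: f[f"s{t}"] + (f["sPl"] if t == "L" else 0.0) for t in rat.OX_TISSUES}
    total_syn = sum(syn.values())
    pct_ox = intake / (intake + total_syn)
    ox_ratio = pct_ox / (1.0 - pct_ox)    # = intake / total_syn
    for t in rat.OX_TISSUES:
        f[f"ox{t}"] = ox_ratio * syn[t]

    for t in rat.TI_TISSUES:
        f[f"in{t}"] = c.ti[t] * f[f"s{t}"]
        f[f"out{t}"] = f[f"in{t}"] + f[f"d{t}"] - f[f"s{t}"] - f[f"ox{t}"]
    f["outSk"] -= f["sHa"]                # hair keratin drawn from skin AA

    f_up = sum(f[f"ox{t}"] for t in rat.OX_TISSUES)
    f["UE"] = intake - f["NH4"] - f["FL"] - f["lHa"] - f["lSk"]
    f["UH"] = f_up - f["UE"]
    f["absCC"] = f["tSI"] + f["UH"] - f["FL"]
    f["PV"] = f["absSI"] + f["dSI"] - f["sSI"] - f["oxSI"] - f["secSI"]
    f["outL"] = c.delivery_frac_intake * intake
    f["inL"] = (f["sL"] + f["sPl"] + f["oxL"] + f["outL"] + f["NH4"]
                - f["PV"] - f["absCC"] - f["dL"])

    negative = {fid: val for fid, val in f.items() if val < 0}
    if negative:
        raise CalibrationError(
            "infeasible closure, negative solved fluxes "
            f"{negative}; check the FSR/TI/%ox constraint stack against the "
            "measured pool sizes"
        )

    template = topology or rat.build_rat_topology(
        rat.RatTopologyConfig(rates={fid: 0.0 for fid, _s, _t in rat._FLUX_EDGES})
    )
    rates = {}
    for fl in template.fluxes:
        rates[fl.id] = f[fl.id] if fl.source == DIET else f[fl.id] / N[fl.source]
    calibrated = rat.build_rat_topology(
        rat.RatTopologyConfig(rates=rates, diet_delta=c.diet_delta)
    )
    # consistency: measured pools must be the exact elemental steady state
    ss = steady_state_N(calibrated)
    target = np.array([N[cid] for cid in calibrated.ids])
    if np.max(np.abs(ss - target)) > 1e-6 * max(target.max(), 1.0):
        raise CalibrationError(
            "calibrated rates do not reproduce the measured pools; the plasma "
            "balance residual indicates an inconsistent constraint set"
        )
    return RateCalibration(topology=calibrated, fluxes=f, pct_ox=pct_ox)


# ---------------------------------------------------------------------------
# phase 2: fractionation factors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EpsilonSet:
    """Estimated fractionation factors with the free/pinned mask."""

    values: dict[str, float]          # epsilon per flux (pinned ones are 0)
    free: tuple[str, ...]
    residuals: pd.Series              # permil, per measured quantity

    def topology(self, rated: ModelTopology) -> ModelTopology:
        return rated.with_epsilons(self.values)


def calibrate_fractionation(measurements: pd.DataFrame,
                            rated_model: ModelTopology,
                            free: Sequence[str] = DEFAULT_FREE_EPSILONS,
                            diet_delta: float | None = None) -> EpsilonSet:
    """Estimate the free fractionation factors by linear least squares.

    Builds the isotopic steady-state balance of every measured compartment
    (normalized by its inflow so residuals are in permil) plus one
    observation equation per measured excretum, then solves for the free
    epsilons.  Raises on rank deficiency, listing the unidentifiable
    subset.
    """
    dd = rated_model.diet_delta if diet_delta is None else diet_delta
    deltas = measured_deltas(measurements, dd)
    pools = measured_pools(measurements)
    missing = set(rated_model.ids) - set(deltas)
    if missing:
        raise CalibrationError(f"Delta15N missing for compartments: {sorted(missing)}")
    free = tuple(free)
    fidx = {fid: j for j, fid in enumerate(free)}
    src, tgt, k, eps0 = compile_structure(rated_model)
    Nvec = np.array([pools[cid] for cid in rated_model.ids])
    f = np.where(src >= 0, k * Nvec[np.clip(src, 0, None)], k)
    dvec = np.array([deltas[cid] for cid in rated_model.ids])

    rows, rhs, labels = [], [], []
    n_free = len(free)
    for i, cid in enumerate(rated_model.ids):
        row = np.zeros(n_free)
        const = 0.0
        inflow = 0.0
        for j, fl in enumerate(rated_model.fluxes):
            if tgt[j] == i:
                dsrc = dd if src[j] < 0 else dvec[src[j]]
                const += f[j] * (dsrc - dvec[i])
                inflow += f[j]
                if fl.id in fidx:
                    row[fidx[fl.id]] += f[j]
            if src[j] == i:
                if fl.id in fidx:
                    row[fidx[fl.id]] -= f[j]
        if inflow <= 0:
            continue
        rows.append(row / inflow)
        rhs.append(-const / inflow)
        labels.append(cid)
    for name, fid in OBSERVABLE_FLUXES.items():
        if name not in deltas:
            continue
        fl = rated_model.flux(fid)
        dsrc = dvec[rated_model.index(fl.source)]
        row = np.zeros(n_free)
        if fid in fidx:
            row[fidx[fid]] = 1.0
        rows.append(row)
        rhs.append(deltas[name] - dsrc)
        labels.append(name)

    G = np.array(rows)
    h = np.array(rhs)
    rank = np.linalg.matrix_rank(G, tol=1e-10)
    if rank < n_free:
        _u, s, vt = np.linalg.svd(G)
        null = vt[rank:]
        involved = sorted(
            {free[j] for row in null for j in np.nonzero(np.abs(row) > 1e-8)[0]}
        )
        raise CalibrationError(
            f"fractionation factors not identifiable from these measurements; "
            f"unidentifiable subset: {involved}"
        )
    est, *_ = np.linalg.lstsq(G, h, rcond=None)
    values = {fl.id: 0.0 for fl in rated_model.fluxes}
    values.update(dict(zip(free, est)))

    fitted = rated_model.with_epsilons(values)
    pred = steady_state_delta(fitted, Nvec)
    resid = {cid: pred[i] - dvec[i] for i, cid in enumerate(rated_model.ids)}
    rep = flux_report(fitted, fitted.state(Nvec, pred))
    dflux = dict(zip(rep["flux"], rep["delta_flux"]))
    for name, fid in OBSERVABLE_FLUXES.items():
        if name in deltas:
            resid[name] = dflux[fid] - deltas[name]
    return EpsilonSet(values=values, free=free,
                      residuals=pd.Series(resid, name="residual_permil"))


# ---------------------------------------------------------------------------
# fit summary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationReport:
    residuals: pd.DataFrame           # per compartment: N and Delta15N
    indices: "rat.DerivedIndices"
    pct_ox: float
    flags: dict[str, bool]


def calibration_report(model: ModelTopology, measurements: pd.DataFrame,
                       pct_ox: float | None = None) -> CalibrationReport:
    """Residuals of a calibrated model against a measurement table."""
    from .dynamics import find_steady_state
    state = find_steady_state(model)
    pools = measured_pools(measurements)
    deltas = measured_deltas(measurements, model.diet_delta)
    rows = []
    for i, cid in enumerate(model.ids):
        rows.append({
            "compartment": cid,
            "N_model": state.N[i],
            "N_measured": pools.get(cid, np.nan),
            "N_residual": state.N[i] - pools.get(cid, np.nan),
            "delta_model": state.delta[i],
            "delta_measured": deltas.get(cid, np.nan),
            "delta_residual": state.delta[i] - deltas.get(cid, np.nan),
        })
    rep = flux_report(model, state)
    dflux = dict(zip(rep["flux"], rep["delta_flux"]))
    for name, fid in OBSERVABLE_FLUXES.items():
        if name in deltas:
            rows.append({
                "compartment": name, "N_model": np.nan, "N_measured": np.nan,
                "N_residual": np.nan, "delta_model": dflux[fid],
                "delta_measured": deltas[name],
                "delta_residual": dflux[fid] - deltas[name],
            })
    resid = pd.DataFrame(rows)
    idx = rat.derived_indices(rep, intake=model.intake)
    if pct_ox is None:
        pct_ox = idx.pct_ox["M"]
    flags = {
        "urea_production_equals_intake": bool(
            abs(idx.urea_production / model.intake - 1.0) < 1e-6
        ),
        "delta_residuals_within_noise": bool(
            np.nanmax(np.abs(resid["delta_residual"])) < 0.1
        ),
    }
    return CalibrationReport(residuals=resid, indices=idx, pct_ox=pct_ox, flags=flags)
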