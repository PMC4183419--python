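"""The 21-compartment, 49-flux rat nitrogen topology and derived indices.

Pools and pathways
------------------
Absorptive subsystem: stomach lumen (St), small-intestine lumen (SIl) and
caeco-colonic lumen (CC).  Splanchnic: protein (P) and free amino-acid (AA)
fractions of the small-intestine mucosa (SIp/SIa) and liver (Lp/La).
Peripheral: P and AA fractions of plasma (Plp/Pla), muscle (Mp/Ma), kidney
(Kp/Ka), heart (Hp/Ha), red blood cells (Rp/Ra) and skin (Skp/Ska), plus
hair.  Body urea (U) closes the graph.

Dietary N enters the stomach, transits the gut (tSt, tSI) and is absorbed
into the mucosa (absSI) against endogenous secretion (secSI); mucosal AA
reach the liver through the portal vein (PV).  Each tissue turns protein
over (sT/dT), oxidizes free AA (oxT, the aggregate transfer to liver and
deamination to urea) and exchanges AA with plasma (inT/outT).  Plasma
proteins are synthesized in the liver (sPl, from liver AA) and release AA
into plasma on degradation (dPl); hair keratin is laid down from skin AA
(sHa).  Urea is excreted in urine (UE) or recycled to the colon (UH) where
part is salvaged by caeco-colonic absorption into the liver AA pool
(absCC); losses also occur as urinary ammonia drawn from hepatic AA (NH4),
fecal N (FL), hair (lHa) and desquamated skin protein (lSk).

Contested edges (the drawing is the only authority on the exact roster;
these choices satisfy the 21/49 counts and per-compartment balance):
heart and RBC do carry oxidation fluxes; hair has no free-AA pool and no
oxidation; plasma P carries no oxidation flux; ammonia is drawn from the
hepatic AA pool; portal flux moves mucosal (not luminal) AA to liver.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .topology import DIET, SINK, CompartmentSpec, FluxSpec, ModelTopology, TopologyError

#: tissues with protein + free-AA pools and an oxidation flux
OX_TISSUES = ("SI", "L", "M", "K", "H", "R", "Sk")
#: tissues exchanging free AA with plasma via the transport-index rule
TI_TISSUES = ("M", "K", "H", "R", "Sk")

_COMPARTMENTS = [
    ("St", "stomach lumen", "absorptive", "luminal-N"),
    ("SIl", "small-intestine lumen", "absorptive", "luminal-N"),
    ("CC", "caeco-colonic lumen", "absorptive", "luminal-N"),
    ("SIp", "SI mucosa protein", "splanchnic", "protein"),
    ("SIa", "SI mucosa free AA", "splanchnic", "free-AA"),
    ("Lp", "liver protein", "splanchnic", "protein"),
    ("La", "liver free AA", "splanchnic", "free-AA"),
    ("Plp", "plasma protein", "peripheral", "protein"),
    ("Pla", "plasma free AA", "peripheral", "free-AA"),
    ("Mp", "muscle protein", "peripheral", "protein"),
    ("Ma", "muscle free AA", "peripheral", "free-AA"),
    ("Kp", "kidney protein", "peripheral", "protein"),
    ("Ka", "kidney free AA", "peripheral", "free-AA"),
    ("Hp", "heart protein", "peripheral", "protein"),
    ("Ha", "heart free AA", "peripheral", "free-AA"),
    ("Rp", "RBC protein", "peripheral", "protein"),
    ("Ra", "RBC free AA", "peripheral", "free-AA"),
    ("Skp", "skin protein", "peripheral", "protein"),
    ("Ska", "skin free AA", "peripheral", "free-AA"),
    ("Hair", "hair", "peripheral", "protein"),
    ("U", "body urea", "urea", "urea"),
]

#: (flux id, source, target); rate constants and epsilons are attached at
#: build time.
_FLUX_EDGES = [
    ("diet", DIET, "St"),
    ("tSt", "St", "SIl"),
    ("tSI", "SIl", "CC"),
    ("absSI", "SIl", "SIa"),
    ("secSI", "SIa", "SIl"),
    ("PV", "SIa", "La"),
    ("absCC", "CC", "La"),
    ("UH", "U", "CC"),
    ("UE", "U", SINK),
    ("NH4", "La", SINK),
    ("FL", "CC", SINK),
    ("lHa", "Hair", SINK),
    ("lSk", "Skp", SINK),
    ("sSI", "SIa", "SIp"),
    ("dSI", "SIp", "SIa"),
    ("oxSI", "SIa", "U"),
    ("sL", "La", "Lp"),
    ("dL", "Lp", "La"),
    ("oxL", "La", "U"),
    ("inL", "Pla", "La"),
    ("outL", "La", "Pla"),
    ("sPl", "La", "Plp"),
    ("dPl", "Plp", "Pla"),
    ("sHa", "Ska", "Hair"),
] + [
    edge
    for t, (aa, pp) in {
        "M": ("Ma", "Mp"), "K": ("Ka", "Kp"), "H": ("Ha", "Hp"),
        "R": ("Ra", "Rp"), "Sk": ("Ska", "Skp"),
    }.items()
    for edge in [
        (f"s{t}", aa, pp),
        (f"d{t}", pp, aa),
        (f"ox{t}", aa, "U"),
        (f"in{t}", "Pla", aa),
        (f"out{t}", aa, "Pla"),
    ]
]

N_COMPARTMENTS = 21
N_FLUXES = 49


@dataclass(frozen=True)
class RatTopologyConfig:
    """Rate constants and fractionation factors for the canonical roster.

    ``rates`` maps flux id -> k (d^-1; the ``diet`` entry is the constant
    intake in mmol N.100 g BW^-1.d^-1); ``epsilons`` maps flux id ->
    epsilon (permil), omitted fluxes get 0.
    """

    rates: Mapping[str, float]
    epsilons: Mapping[str, float] = field(default_factory=dict)
    diet_delta: float = 0.0


def build_rat_topology(config: RatTopologyConfig) -> ModelTopology:
    """Instantiate and structurally validate the rat topology.

    Raises
    ------
    TopologyError
        Listing missing/extra fluxes if the roster is incomplete, or if
        the urea-recycling loop or oxidation routing is broken.
    """
    expected = {fid for fid, _s, _t in _FLUX_EDGES}
    got = set(config.rates)
    if got != expected:
        missing = sorted(expected - got)
        extra = sorted(got - expected)
        raise TopologyError(
            f"flux roster mismatch: missing={missing}, extra={extra}"
        )
    bad_eps = set(config.epsilons) - expected
    if bad_eps:
        raise TopologyError(f"epsilons for unknown fluxes: {sorted(bad_eps)}")
    comps = [CompartmentSpec(*c) for c in _COMPARTMENTS]
    fluxes = [
        FluxSpec(fid, s, t, float(config.rates[fid]),
                 float(config.epsilons.get(fid, 0.0)))
        for fid, s, t in _FLUX_EDGES
    ]
    topo = ModelTopology(tuple(comps), tuple(fluxes), diet_delta=config.diet_delta)
    assert topo.n == N_COMPARTMENTS and len(topo.fluxes) == N_FLUXES
    # every oxidation flux must feed body urea, and the recycling loop
    # urea -> colon -> liver AA must be closed
    for t in OX_TISSUES:
        f = topo.flux(f"ox{t}")
        if f.target != "U":
            raise TopologyError(f"ox{t} must route tissue AA to body urea")
    if topo.flux("UH").target != "CC" or topo.flux("absCC").target != "La":
        raise TopologyError("urea recycling loop (U -> CC -> La) is not closed")
    return topo


# ---------------------------------------------------------------------------
# derived physiological indices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DerivedIndices:
    """Flux-derived physiological indices; undefined ratios are NaN."""

    pct_ox: dict[str, float]          # per tissue, f_ox / (f_ox + f_s)
    p: dict[str, float]               # per tissue, f_ox/(f_out+f_ox+f_s-f_d)
    urea_production: float            # f_UP = sum of tissue oxidation fluxes
    recycling_efficiency: float       # R = f_UH / f_UP
    peripheral_delivery: float        # f_outL, mmol N.100 g BW^-1.d^-1
    peripheral_delivery_pct_intake: float
    splanchnic_share: float           # (f_sL+f_sPl+f_sSI) / whole-body synthesis
    splanchnic_pct_ox: float          # f_oxSpl / (f_oxSpl + f_sSpl)

    def to_dict(self) -> dict:
        d = {f"pct_ox_{t}": v for t, v in self.pct_ox.items()}
        d.update({f"p_{t}": v for t, v in self.p.items()})
        d.update(
            urea_production=self.urea_production,
            recycling_efficiency=self.recycling_efficiency,
            peripheral_delivery=self.peripheral_delivery,
            peripheral_delivery_pct_intake=self.peripheral_delivery_pct_intake,
            splanchnic_share=self.splanchnic_share,
            splanchnic_pct_ox=self.splanchnic_pct_ox,
        )
        return d


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def derived_indices(fluxes: pd.DataFrame, intake: float | None = None) -> DerivedIndices:
    """Compute the physiological indices from a flux report.

    ``fluxes`` is the frame returned by :func:`isoflux.dynamics.flux_report`
    (only the ``flux`` and ``value`` columns are used).  Liver synthesis
    counts both hepatic and plasma protein output (plasma proteins are
    liver-made), which keeps the tissue-uniform %ox rule exact.
    """
    v = dict(zip(fluxes["flux"], fluxes["value"]))
    missing = {f"ox{t}" for t in OX_TISSUES} - set(v)
    if missing:
        raise ValueError(f"flux report incomplete: missing {sorted(missing)}")

    def syn(t: str) -> float:
        return v[f"s{t}"] + (v["sPl"] if t == "L" else 0.0)

    pct_ox = {t: _ratio(v[f"ox{t}"], v[f"ox{t}"] + syn(t)) for t in OX_TISSUES}
    p = {}
    for t in OX_TISSUES:
        if t == "SI":
            continue  # mucosal AA export is portal, not plasma-bound
        out = v["outL"] if t == "L" else v[f"out{t}"]
        den = out + v[f"ox{t}"] + syn(t) - v[f"d{t}"] - (v["dPl"] if t == "L" else 0.0)
        p[t] = _ratio(v[f"ox{t}"], den)
    f_up = sum(v[f"ox{t}"] for t in OX_TISSUES)
    whole_body_syn = sum(v[f"s{t}"] for t in OX_TISSUES) + v["sPl"] + v["sHa"]
    f_s_spl = v["sL"] + v["sPl"] + v["sSI"]
    f_ox_spl = v["oxL"] + v["oxSI"]
    intake = v["diet"] if intake is None else intake
    return DerivedIndices(
        pct_ox=pct_ox,
        p=p,
        urea_production=f_up,
        recycling_efficiency=_ratio(v["UH"], f_up),
        peripheral_delivery=v["outL"],
        peripheral_delivery_pct_intake=100.0 * _ratio(v["outL"], intake),
        splanchnic_share=_ratio(f_s_spl, whole_body_syn),
        splanchnic_pct_ox=_ratio(f_ox_spl, f_ox_spl + f_s_spl),
    )


def muscle_closed_form(topology: ModelTopology, state) -> float:
    """Predicted muscle-protein Delta15N from the branch-point closed form.

    At a joint steady state the muscle protein enrichment depends only on
    the plasma free-AA supply, the oxidative routing index p and the two
    muscle fractionation factors:

        Delta15N_MP = Delta15N_PlAA - p * eps_oxM + eps_sM,

    with p = f_oxM / (f_outM + f_oxM + f_sM - f_dM).  Synthesis enriches
    the protein fraction by eps_sM (the flux into protein carries
    delta_AA + eps_sM while degradation returns nitrogen unfractionated),
    and the oxidative drain offsets the free-AA pool from plasma by
    -p * eps_oxM.
    """
    from .dynamics import flux_report
    rep = flux_report(topology, state)
    v = dict(zip(rep["flux"], rep["value"]))
    eps = topology.epsilons()
    p = v["oxM"] / (v["outM"] + v["oxM"] + v["sM"] - v["dM"])
    delta_pla = state.delta[topology.index("Pla")]
    return delta_pla - p * eps["oxM"] + eps["sM"]


# ---------------------------------------------------------------------------
# shipped baseline (calibration constants and measurement fixture)
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("isoflux.data").joinpath(name)


def baseline_constraints():
    """Shipped literature constraint set (FSR, TI, gastrointestinal rules)."""
    from .calibration import CalibrationConstraints
    return CalibrationConstraints.from_yaml(_data_path("rat_constraints.yaml"))


def baseline_measurements() -> pd.DataFrame:
    """Shipped baseline measurement table (pool sizes and Delta15N)."""
    from .calibration import read_measurements
    return read_measurements(_data_path("rat_measurements.csv"))


def baseline_topology() -> ModelTopology:
    """The shipped calibrated rat model (rates and fractionation factors)."""
    from .io import load_model_config
    return load_model_config(_data_path("rat_model.yaml"))
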