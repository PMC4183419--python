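"""Compartment/flux graph for dual-state (N, delta15N) nitrogen models.

A :class:`ModelTopology` couples a list of nitrogen pools (compartments)
with directed first-order fluxes between them.  Every flux ``j -> i``
carries a rate constant ``k`` (fraction of the source pool transferred per
day) and a fractionation factor ``epsilon`` (permil): the instantaneous
flux leaving pool ``j`` has isotopic abundance ``delta_j + epsilon``, so a
negative epsilon marks a pathway that prefers the lighter isotope.

Two pseudo-compartments close the graph: ``DIET`` (constant external input;
for a DIET-sourced flux ``k`` is the constant delivery in
mmol N.100 g BW^-1.d^-1, not a rate) and ``SINK`` (irreversible loss,
e.g. excretion).  Units are fixed package-wide: pools in
mmol N.100 g BW^-1, rates in d^-1, deltas in permil vs atmospheric N2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

DIET = "DIET"
SINK = "SINK"

SUBSYSTEMS = ("absorptive", "splanchnic", "peripheral", "urea", "elimination")
FRACTIONS = ("protein", "free-AA", "urea", "luminal-N", "excreta")


class TopologyError(ValueError):
    """Structural problem in a compartment/flux graph."""


@dataclass(frozen=True)
class CompartmentSpec:
    """One kinetically homogeneous nitrogen pool."""

    id: str
    label: str = ""
    subsystem: str = "peripheral"
    fraction: str = "free-AA"

    def __post_init__(self) -> None:
        if self.subsystem not in SUBSYSTEMS:
            raise TopologyError(
                f"compartment {self.id!r}: unknown subsystem {self.subsystem!r}"
            )
        if self.fraction not in FRACTIONS:
            raise TopologyError(
                f"compartment {self.id!r}: unknown fraction {self.fraction!r}"
            )


@dataclass(frozen=True)
class FluxSpec:
    """One directed nitrogen flux with its rate and isotope effect.

    ``k`` is in d^-1 except for DIET-sourced fluxes, where it is the
    constant input itself (mmol N.100 g BW^-1.d^-1).
    """

    id: str
    source: str
    target: str
    k: float
    epsilon: float = 0.0

    def __post_init__(self) -> None:
        if self.k < 0:
            raise TopologyError(f"flux {self.id!r}: negative rate constant")
        if not np.isfinite(self.epsilon):
            raise TopologyError(f"flux {self.id!r}: epsilon must be finite")
        if self.source == SINK:
            raise TopologyError(f"flux {self.id!r}: SINK can only be a target")
        if self.target == DIET:
            raise TopologyError(f"flux {self.id!r}: DIET can only be a source")
        if self.source == self.target:
            raise TopologyError(f"flux {self.id!r}: self-loop")


@dataclass(frozen=True)
class ModelState:
    """Paired pool sizes and isotopic abundances, aligned with a topology."""

    N: np.ndarray
    delta: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "N", np.asarray(self.N, dtype=float))
        object.__setattr__(self, "delta", np.asarray(self.delta, dtype=float))
        if self.N.shape != self.delta.shape or self.N.ndim != 1:
            raise ValueError("N and delta must be aligned 1-d vectors")
        if np.any(self.N < 0):
            raise ValueError("pool sizes must be non-negative")

    @property
    def n(self) -> int:
        return self.N.size


@dataclass(frozen=True)
class ModelTopology:
    """Validated compartment/flux graph plus the dietary forcing.

    Parameters
    ----------
    compartments, fluxes:
        The graph.  Compartment and flux ids must be unique; fluxes may
        reference the DIET and SINK pseudo-compartments.
    diet_delta:
        delta15N of the dietary input (permil).
    allow_accumulators:
        If False (default) every compartment must have at least one inflow
        and one outflow; set True for deliberately absorbing pools.
    """

    compartments: tuple[CompartmentSpec, ...]
    fluxes: tuple[FluxSpec, ...]
    diet_delta: float = 0.0
    allow_accumulators: bool = False
    _index: Mapping[str, int] = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        comps = tuple(
            c if isinstance(c, CompartmentSpec) else CompartmentSpec(**c)
            for c in self.compartments
        )
        flx = tuple(
            f if isinstance(f, FluxSpec) else FluxSpec(**f) for f in self.fluxes
        )
        object.__setattr__(self, "compartments", comps)
        object.__setattr__(self, "fluxes", flx)
        ids = [c.id for c in comps]
        if len(set(ids)) != len(ids):
            raise TopologyError("duplicate compartment ids")
        if DIET in ids or SINK in ids:
            raise TopologyError("DIET/SINK are reserved ids")
        fids = [f.id for f in flx]
        if len(set(fids)) != len(fids):
            raise TopologyError("duplicate flux ids")
        object.__setattr__(self, "_index", {cid: i for i, cid in enumerate(ids)})
        known = set(ids) | {DIET, SINK}
        inflow = {cid: 0 for cid in ids}
        outflow = {cid: 0 for cid in ids}
        for f in flx:
            if f.source not in known or f.target not in known:
                raise TopologyError(
                    f"flux {f.id!r} references undeclared compartment "
                    f"({f.source!r} -> {f.target!r})"
                )
            if f.target != SINK:
                inflow[f.target] += 1
            if f.source != DIET:
                outflow[f.source] += 1
        if not self.allow_accumulators:
            bad = [c for c in ids if inflow[c] == 0 or outflow[c] == 0]
            if bad:
                raise TopologyError(
                    "compartments without both inflow and outflow: " + ", ".join(bad)
                )

    # -- lookups ---------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.compartments)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(c.id for c in self.compartments)

    def index(self, cid: str) -> int:
        try:
            return self._index[cid]
        except KeyError:
            raise KeyError(f"unknown compartment {cid!r}") from None

    def flux(self, fid: str) -> FluxSpec:
        for f in self.fluxes:
            if f.id == fid:
                return f
        raise KeyError(f"unknown flux {fid!r}")

    @property
    def intake(self) -> float:
        """Total constant dietary N input (sum of DIET-sourced fluxes)."""
        return float(sum(f.k for f in self.fluxes if f.source == DIET))

    # -- functional updates ---------------------------------------------
    def with_rates(self, updates: Mapping[str, float]) -> "ModelTopology":
        """Return a copy with rate constants replaced (``{flux_id: k}``)."""
        unknown = set(updates) - {f.id for f in self.fluxes}
        if unknown:
            raise KeyError(f"unknown flux ids: {sorted(unknown)}")
        new = tuple(
            replace(f, k=float(updates[f.id])) if f.id in updates else f
            for f in self.fluxes
        )
        return replace(self, fluxes=new)

    def with_scaled_rates(self, factors: Mapping[str, float]) -> "ModelTopology":
        """Return a copy with rate constants multiplied (``{flux_id: factor}``)."""
        return self.with_rates(
            {fid: self.flux(fid).k * fac for fid, fac in factors.items()}
        )

    def with_epsilons(self, updates: Mapping[str, float]) -> "ModelTopology":
        """Return a copy with fractionation factors replaced."""
        unknown = set(updates) - {f.id for f in self.fluxes}
        if unknown:
            raise KeyError(f"unknown flux ids: {sorted(unknown)}")
        new = tuple(
            replace(f, epsilon=float(updates[f.id])) if f.id in updates else f
            for f in self.fluxes
        )
        return replace(self, fluxes=new)

    def rates(self) -> dict[str, float]:
        return {f.id: f.k for f in self.fluxes}

    def epsilons(self) -> dict[str, float]:
        return {f.id: f.epsilon for f in self.fluxes}

    def state(self, N: Mapping[str, float] | Sequence[float],
              delta: Mapping[str, float] | Sequence[float] | float = 0.0) -> ModelState:
        """Build a :class:`ModelState` from per-compartment mappings or vectors."""
        if isinstance(N, Mapping):
            N = [N[c] for c in self.ids]
        if isinstance(delta, Mapping):
            delta = [delta[c] for c in self.ids]
        elif np.isscalar(delta):
            delta = np.full(self.n, float(delta))
        return ModelState(np.asarray(N, float), np.asarray(delta, float))


def compile_structure(topology: ModelTopology):
    """Index arrays for fast vectorized right-hand sides.

    Returns (src, tgt, k, eps) where src/tgt are compartment indices with
    -1 standing for DIET (in src) or SINK (in tgt).
    """
    idx = topology._index
    src = np.array(
        [-1 if f.source == DIET else idx[f.source] for f in topology.fluxes], dtype=int
    )
    tgt = np.array(
        [-1 if f.target == SINK else idx[f.target] for f in topology.fluxes], dtype=int
    )
    k = np.array([f.k for f in topology.fluxes], dtype=float)
    eps = np.array([f.epsilon for f in topology.fluxes], dtype=float)
    return src, tgt, k, eps


def flux_values(topology: ModelTopology, N: np.ndarray,
                k: np.ndarray | None = None) -> np.ndarray:
    """Instantaneous flux magnitudes ``f = k * N_source`` (DIET fluxes are
    constant), ordered like ``topology.fluxes``."""
    src, _tgt, k_def, _eps = compile_structure(topology)
    kk = k_def if k is None else np.asarray(k, dtype=float)
    N = np.asarray(N, dtype=float)
    f = np.where(src >= 0, kk * N[np.clip(src, 0, None)], kk)
    return f
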