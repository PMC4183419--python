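import numpy as np
import pytest

from isoflux import (
    CompartmentSpec,
    FluxSpec,
    ModelTopology,
    baseline_constraints,
    baseline_measurements,
    baseline_topology,
    find_steady_state,
)


@pytest.fixture(scope="session")
def rat_model():
    return baseline_topology()


@pytest.fixture(scope="session")
def rat_steady(rat_model):
    return find_steady_state(rat_model)


@pytest.fixture(scope="session")
def constraints():
    return baseline_constraints()


@pytest.fixture(scope="session")
def measurements():
    return baseline_measurements()


def one_pool_model(delta_diet=5.0, eps_in=2.0, eps_out=-1.5, k_out=0.3,
                   intake=4.0):
    """Single pool with fractionated inflow and outflow; closed-form
    steady state delta = delta_diet + eps_in - eps_out."""
    return ModelTopology(
        compartments=(CompartmentSpec("A", "pool"),),
        fluxes=(
            FluxSpec("fin", "DIET", "A", intake, eps_in),
            FluxSpec("fout", "A", "SINK", k_out, eps_out),
        ),
        diet_delta=delta_diet,
    )


def random_topology(rng, n_max=6, eps_scale=10.0):
    """Random well-posed compartment graph (every pool drains to the sink
    directly or transitively) with |eps| <= eps_scale."""
    n = int(rng.integers(2, n_max + 1))
    ids = [f"C{i}" for i in range(n)]
    comps = tuple(CompartmentSpec(c) for c in ids)
    fluxes = [FluxSpec("diet", "DIET", ids[0], float(rng.uniform(1, 5)),
                       float(rng.uniform(-eps_scale, eps_scale)))]
    # chain guarantees connectivity and an eventual sink path
    for i in range(n - 1):
        fluxes.append(FluxSpec(f"chain{i}", ids[i], ids[i + 1],
                               float(rng.uniform(0.2, 3.0)),
                               float(rng.uniform(-eps_scale, eps_scale))))
    fluxes.append(FluxSpec("loss", ids[-1], "SINK", float(rng.uniform(0.2, 2.0)),
                           float(rng.uniform(-eps_scale, eps_scale))))
    # random extra edges (may create cycles and parallel sinks)
    for j in range(int(rng.integers(0, 2 * n))):
        a, b = rng.integers(0, n, size=2)
        if a == b:
            continue
        fluxes.append(FluxSpec(f"x{j}", ids[a], ids[b],
                               float(rng.uniform(0.05, 2.0)),
                               float(rng.uniform(-eps_scale, eps_scale))))
    return ModelTopology(comps, tuple(fluxes),
                         diet_delta=float(rng.uniform(-20, 20)))
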