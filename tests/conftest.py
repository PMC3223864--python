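import numpy as np
import pytest
from scipy.optimize import minimize

from devstate import SimulationConfig, TimeCourse, fit_state_line, simulate_trajectory


@pytest.fixture
def worked_tc():
    """The 2-gene hand-derived example: centroids (0,0), (1,0), (2,1)."""
    return TimeCourse(
        gene_ids=["g1", "g2"],
        time_labels=["d1", "d2", "d3"],
        centroids=np.array([[0.0, 1.0, 2.0], [0.0, 0.0, 1.0]]),
    )


@pytest.fixture
def worked_line(worked_tc):
    return fit_state_line(worked_tc)


@pytest.fixture
def curved_truth():
    """A fixed-seed curved noiseless trajectory used across diagnostics tests."""
    config = SimulationConfig(
        n_genes=40,
        time_labels=[f"d{j}" for j in range(6)],
        segment_lengths=[1.5, 1.0, 2.0, 1.2, 0.8],
        turn_angles_deg=[40.0, 60.0, 30.0, 75.0],
        replicates_per_point=1,
        noise_sd=0.0,
        seed=20260929,
    )
    _, _, truth = simulate_trajectory(config)
    return truth


def random_time_course(rng, n_genes, n_times):
    """Generic-position Gaussian centroids (segments independent a.s.)."""
    labels = [f"t{j}" for j in range(n_times)]
    centroids = rng.normal(size=(n_genes, n_times))
    return TimeCourse(gene_ids=[f"g{i}" for i in range(n_genes)],
                      time_labels=labels, centroids=centroids)


def cobisector_oracle(unit_segments):
    """Numerically maximize the common cosine under equal-angle constraints.

    Independent of the closed form: optimize over the full gene space with
    a generic constrained solver (SLSQP), maximizing the cosine against the
    first segment subject to the unit-norm constraint and the equal-angle
    constraints (u_i - u_1) . e = 0.  Returns the optimal unit vector.
    """
    U = np.asarray(unit_segments, dtype=float)
    n, m = U.shape

    def objective(e):
        return -(U[:, 0] @ e)

    constraints = [{"type": "eq", "fun": lambda e: e @ e - 1.0}]
    constraints += [
        {"type": "eq", "fun": (lambda e, i=i: (U[:, i] - U[:, 0]) @ e)}
        for i in range(1, m)
    ]
    rng = np.random.default_rng(0)
    starts = [U.sum(axis=1)] + [rng.normal(size=n) for _ in range(3)]
    best = None
    for e0 in starts:
        e0 = e0 / np.linalg.norm(e0)
        res = minimize(objective, e0, method="SLSQP", constraints=constraints,
                       options={"maxiter": 1000, "ftol": 1e-14})
        if not res.success:
            continue
        e = res.x / np.linalg.norm(res.x)
        if best is None or objective(e) < objective(best):
            best = e
    assert best is not None, "oracle optimizer failed on every start"
    return best
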