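import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from modelrank.promethee import Criterion, DecisionMatrix

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def random_decision_matrix(rng, n_alt=None, n_crit=None, spread="auto"):
    """Random instance for property tests: mixed directions, weights sum 1."""
    n_alt = n_alt or int(rng.integers(3, 9))
    n_crit = n_crit or int(rng.integers(2, 11))
    values = rng.normal(0, 10, size=(n_alt, n_crit))
    weights = rng.random(n_crit) + 0.05
    weights /= weights.sum()
    directions = rng.choice(["maximize", "minimize"], size=n_crit)
    criteria = [
        Criterion(name=f"c{j}", direction=directions[j], weight=weights[j],
                  spread=spread if spread == "auto" else float(spread))
        for j in range(n_crit)
    ]
    names = [f"alt{i}" for i in range(n_alt)]
    return DecisionMatrix(names, criteria, values)


def naive_flows(matrix):
    """Triple-loop PROMETHEE II reference, independent of the vectorized path."""
    from modelrank.promethee import resolve_spreads

    n, m = matrix.values.shape
    spreads = resolve_spreads(matrix)
    w = matrix.weights

    def pref(d, s):
        import math
        return 0.0 if d <= 0 else 1.0 - math.exp(-d * d / (2 * s * s))

    phi_plus = np.zeros(n)
    phi_minus = np.zeros(n)
    uni = np.zeros((n, m))
    for i in range(n):
        for k in range(n):
            if i == k:
                continue
            pi_ik = pi_ki = 0.0
            for j in range(m):
                d = matrix.values[i, j] - matrix.values[k, j]
                if matrix.criteria[j].direction == "minimize":
                    d = -d
                p_ik, p_ki = pref(d, spreads[j]), pref(-d, spreads[j])
                pi_ik += w[j] * p_ik
                pi_ki += w[j] * p_ki
                uni[i, j] += (p_ik - p_ki) / (n - 1)
            phi_plus[i] += pi_ik / (n - 1)
            phi_minus[i] += pi_ki / (n - 1)
    return phi_plus, phi_minus, phi_plus - phi_minus, uni


@pytest.fixture(scope="session")
def small_dataset():
    """Well-separated WDBC-like synthetic table, small enough for fast CV."""
    from modelrank.synthetic import SyntheticConfig, generate
    return generate(SyntheticConfig(n_class0=150, n_class1=90, n_features=12,
                                    n_informative=6, class_separation=5.0,
                                    seed=11))
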