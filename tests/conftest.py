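import numpy as np
import pandas as pd
import pytest

from megsurv.io import AlterationMatrix, ClinicalTable


@pytest.fixture
def perfect_me_matrix():
    """4 patients x 2 genes, perfectly exclusive rows (1,0)/(0,1)."""
    return np.array([[1, 0], [0, 1], [1, 0], [0, 1]], dtype=np.int8)


@pytest.fixture
def planted_matrix():
    """A planted exclusive triple among Bernoulli passengers (261 x 10)."""
    rng = np.random.default_rng(42)
    N, n_pass = 261, 7
    passengers = (rng.random((N, n_pass)) < 0.05).astype(np.int8)
    members = np.zeros((N, 3), dtype=np.int8)
    covered = rng.random(N) < 0.9
    fired = rng.integers(0, 3, size=int(covered.sum()))
    members[np.flatnonzero(covered), fired] = 1
    labels = ["A", "B", "C"] + [f"P{j}" for j in range(n_pass)]
    values = np.concatenate([members, passengers], axis=1)
    return AlterationMatrix([f"PT{i}" for i in range(N)], labels, values)


@pytest.fixture
def survival_clinical():
    """250 patients, planted HR 2.5 on a binary profile plus age effect."""
    rng = np.random.default_rng(7)
    N = 250
    profile = (rng.random(N) < 0.35).astype(float)
    age = rng.uniform(30, 85, N)
    gender = (rng.random(N) < 0.6).astype(float)
    lam = 0.05 * np.exp(np.log(2.5) * profile + 0.4 * (age >= 50))
    t_event = rng.exponential(1.0 / lam)
    t_cens = rng.uniform(0, 80, N)
    time = np.maximum(np.minimum(t_event, t_cens), 0.01)
    event = (t_event <= t_cens).astype(int)
    clin = ClinicalTable([f"P{i}" for i in range(N)], time, event,
                         age=age, gender=gender,
                         extra=pd.DataFrame({"megs": profile}))
    return clin
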