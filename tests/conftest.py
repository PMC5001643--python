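import numpy as np
import pytest

import twostep as ts


@pytest.fixture(scope="session")
def daw_task():
    return ts.make_task("daw")


@pytest.fixture(scope="session")
def doll_task():
    return ts.make_task("doll")


@pytest.fixture(scope="session")
def novel_task():
    return ts.make_task("novel")


@pytest.fixture(scope="session")
def novel_human_task():
    return ts.make_task("novel_human")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def pooled_stay_probs(task, w, n_sessions, seed, table_fn, alpha=0.5, beta=5.0,
                      lam=0.5):
    """Cell-wise stay probabilities pooled over many simulated agents."""
    params = ts.AgentParams(alpha=alpha, beta=beta, lam=lam, w=w)
    probs = np.zeros((2, 2))
    counts = np.zeros((2, 2))
    for i in range(n_sessions):
        sched = ts.make_schedule(task, seed=np.random.SeedSequence([seed, 2 * i]))
        sess = ts.run_session(
            task, sched, params, seed=np.random.SeedSequence([seed, 2 * i + 1])
        )
        t = table_fn(sess)
        probs += np.nan_to_num(t.probs) * t.counts
        counts += t.counts
    return probs / counts
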