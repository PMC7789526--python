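import numpy as np
import pandas as pd
import pytest

from methylink import synthetic_data as sd
from methylink.methylome import CytosineTable


def make_table(pos, meth, total, chrom="chr1", strand="+", context="CpG", samples=None):
    """Build a CytosineTable from plain lists/arrays (one chromosome)."""
    pos = np.asarray(pos)
    meth = np.atleast_2d(np.asarray(meth))
    total = np.atleast_2d(np.asarray(total))
    if meth.shape[0] != len(pos):
        meth, total = meth.T, total.T
    if samples is None:
        samples = [f"s{i}" for i in range(meth.shape[1])]
    sites = pd.DataFrame(
        {"chrom": chrom, "pos": pos, "strand": strand, "context": context}
    )
    return CytosineTable(sites.reset_index(drop=True), meth.astype(np.int64),
                         total.astype(np.int64), list(samples))


def bb_table(
    n_sites=2000,
    cov=30,
    phi=0.05,
    mu_case=0.7,
    mu_control=None,
    n_reps=4,
    seed=0,
    spacing=1000,
    pos=None,
):
    """Beta-binomial two-group fixture with isolated (or given) positions.

    ``mu_case``/``mu_control`` may be scalars or per-site arrays; default
    control mean equals the case mean (null data).
    """
    rng = np.random.default_rng(seed)
    if pos is None:
        pos = np.arange(1, n_sites + 1) * spacing
    pos = np.asarray(pos)
    n_sites = len(pos)
    if mu_control is None:
        mu_control = mu_case
    mu_case = np.broadcast_to(np.asarray(mu_case, float), (n_sites,))
    mu_control = np.broadcast_to(np.asarray(mu_control, float), (n_sites,))
    samples = [f"case_{i}" for i in range(n_reps)] + [f"control_{i}" for i in range(n_reps)]
    mu = np.column_stack([np.tile(mu_case, (n_reps, 1)).T, np.tile(mu_control, (n_reps, 1)).T])
    total = rng.poisson(cov, size=(n_sites, 2 * n_reps))
    if phi > 0:
        a = mu * (1 - phi) / phi
        b = (1 - mu) * (1 - phi) / phi
        p = rng.beta(a, b)
    else:
        p = mu
    meth = rng.binomial(total, p)
    groups = {s: ("case" if s.startswith("case") else "control") for s in samples}
    return make_table(pos, meth, total, samples=samples), groups


@pytest.fixture(scope="session")
def default_sim():
    """One full default-parameter simulation, shared read-only by tests."""
    return sd.simulate(sd.SimConfig(seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
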