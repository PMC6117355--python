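import numpy as np
import pytest

from cea import ActiveGeneSet, AnnotationDB, CEAConfig, OntologyDAG, run_cea
from cea.simulate import make_planted_instance


@pytest.fixture
def tiny_db():
    """Two overlapping terms over three genes."""
    return AnnotationDB({"A": {"g1", "g2"}, "B": {"g2", "g3"}}, names={"A": "a", "B": "b"})


@pytest.fixture
def worked_db():
    """Five-term instance whose deterministic greedy path is hand-traceable.

    Universe g1..g10, actives g1..g5.  Weights: g6 in {TB, TC} (w=1/2), the
    other inactive genes each in one term (w=1).  Cost-effectiveness at the
    start: TA=0 (no inactive members), TB=0.5, TC=1.5/2, TD=2, TE=0.5, and
    every later step has a unique minimum, so the d=0 path is
    (TA) -> (TA,TB) -> (TA,TB,TC).
    """
    terms = {
        "TA": {"g1", "g2", "g3"},
        "TB": {"g4", "g6"},
        "TC": {"g4", "g5", "g6", "g7"},
        "TD": {"g5", "g8", "g9"},
        "TE": {"g2", "g3", "g10"},
    }
    return AnnotationDB(terms, universe=[f"g{i}" for i in range(1, 11)])


@pytest.fixture
def worked_ag(worked_db):
    return ActiveGeneSet.from_genes({"g1", "g2", "g3", "g4", "g5"}, worked_db)


@pytest.fixture
def toy_dag():
    """Two-branch tree: a <- {b, c}, b <- d, c <- e."""
    return OntologyDAG.from_edges([("b", "a"), ("c", "a"), ("d", "b"), ("e", "c")])


@pytest.fixture
def diamond_dag():
    """Diamond with a short (x->root) and a long (x->m->root) route."""
    return OntologyDAG.from_edges([("m", "root"), ("x", "root"), ("x", "m")])


def small_instance_params(seed: int, m_max: int = 15):
    """Instance dimensions for oracle-certification tests (m<=15, |U|<=40, |U_G|<=8)."""
    rng = np.random.default_rng(seed)
    m = int(rng.integers(8, m_max + 1))
    n_active = int(rng.integers(4, 9))
    return m, n_active


@pytest.fixture(scope="session")
def planted_runs():
    """Twenty full-scale planted instances with their pooled CEA solutions.

    Shared by the recovery and landscape-shape checks so the search runs once.
    """
    out = []
    for seed in range(20):
        inst = make_planted_instance(seed=seed)
        sols = run_cea(inst.active, inst.db, CEAConfig(d=1.0, T=500, seed=seed))
        out.append((inst, sols))
    return out
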