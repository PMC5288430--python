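import numpy as np
import pytest

from silnet.metrics import SchoolNetwork
from silnet.types import NominationEdge, StudentRecord


def make_student(sid, school="S1", **kwargs):
    base = dict(
        student_id=sid,
        school_id=school,
        country="BE",
        grade=1,
        sex="female",
        age=15,
        father_edu="medium",
        mother_edu="high",
        subjective_rank=7,
        father_working=True,
        mother_working=True,
        fas_ratio=1.0,
        housing="owner",
        tried_smoking=False,
        regular_smoker=False,
        dependence_score=0,
        household_smokers=0,
    )
    base.update(kwargs)
    return StudentRecord(**base)


def make_network(edge_pairs, n=None, smokers=(), groups=None, school="S1"):
    """Small directed network from (ego, alter) index pairs."""
    nodes = sorted({i for e in edge_pairs for i in e} | set(range(n or 0)))
    n = max(nodes) + 1 if nodes else (n or 0)
    roster = [f"v{i}" for i in range(n)]
    adj = np.zeros((n, n), dtype=np.int8)
    for i, j in edge_pairs:
        adj[i, j] = 1
    smoking = np.zeros(n, dtype=np.int8)
    for s in smokers:
        smoking[s] = 1
    if groups is None:
        groups = ["g0"] * n
    return SchoolNetwork(school_id=school, roster=roster, adjacency=adj,
                         smoking=smoking, groups=np.array(groups, dtype=object))


@pytest.fixture
def student_factory():
    return make_student


@pytest.fixture
def network_factory():
    return make_network


@pytest.fixture(scope="session")
def default_cohort():
    """One mid-sized cohort generated under default study conditions."""
    from silnet import GeneratorConfig, generate_cohort

    cfg = GeneratorConfig(n_schools=6, roster_size_range=(120, 160), seed=20130)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_metrics(default_cohort):
    from silnet import compute_metrics_table, score_cohort

    records, edges = default_cohort
    records, composites = score_cohort(records)
    return compute_metrics_table(records, edges, composites)
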