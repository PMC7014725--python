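import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lmb():
    from tucast.lmb import lmb_fixture

    return lmb_fixture()


@pytest.fixture(scope="session")
def lmb_stages(lmb):
    """Stage-wise TU partitions of the cluster fixture."""
    from tucast import tu

    s1 = tu.stage1_coupling_partition(lmb.genes, lmb.links)
    s2 = tu.stage2_boundary_fpkm_merge(s1, lmb.genes, lmb.boundaries, lmb.fpkm)
    s3 = tu.stage3_junction_refine(s2, lmb.genes, lmb.evidence)
    return s1, s2, s3
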