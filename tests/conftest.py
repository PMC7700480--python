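import pytest
from hypothesis import HealthCheck, settings

from periogrm.chart import PeriodontalChart, SiteMeasurement, full_dentition_sites
from periogrm.simulate import CohortConfig, generate_cohort

settings.register_profile(
    "suite",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_uniform_chart(
    patient_id: str = "toy",
    cal: int = 3,
    pd_mm: int = 2,
    bop: bool = False,
    pli: int = 0,
    mobility: int = 0,
    teeth: list[int] | None = None,
) -> PeriodontalChart:
    """A chart with identical measurements at every site of the given teeth."""
    sites = {}
    for site in full_dentition_sites():
        if teeth is not None and site.tooth not in teeth:
            continue
        sites[site] = SiteMeasurement(cal, pd_mm, bop, pli, mobility)
    return PeriodontalChart(patient_id, sites)


@pytest.fixture(scope="session")
def cohort60():
    """Small default-preset cohort shared by pipeline-level tests."""
    return generate_cohort(CohortConfig(n_subjects=60, seed=11))


@pytest.fixture(scope="session")
def cohort254():
    """Study-sized default-preset cohort."""
    return generate_cohort(CohortConfig(n_subjects=254, seed=5))


@pytest.fixture(scope="session")
def chain60(cohort60):
    """One CAL selection chain on the small cohort, reused across tests."""
    import warnings

    from periogrm.selection import build_model_chain

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_model_chain(cohort60, "CAL", tol=1e-3, max_iter=80, seed=0)
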