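import numpy as np
import pytest

import scalehub as sh


@pytest.fixture(scope="session")
def ico0():
    return sh.make_icosphere(0)


@pytest.fixture(scope="session")
def ico2():
    return sh.make_icosphere(2)


@pytest.fixture(scope="session")
def ico3():
    return sh.make_icosphere(3)


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-size cohort for integration-style tests (642 vertices)."""
    cfg = sh.SimulationConfig(subdivisions=3, n_subjects=4, n_tracts=8000)
    return sh.simulate_cohort(cfg, master_seed=11)


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    model = sh.ScaleIntegratedHubModel(small_cohort, scales=(30, 60), n_repeats=3)
    return model.fit()


@pytest.fixture(scope="session")
def small_matrices(small_cohort):
    """Per-subject fiber-count matrices at one scale (2 repeats each)."""
    cohort = small_cohort
    ens = sh.parcellation_ensemble(cohort.sphere, scales=(40,), n_repeats=2,
                                   master_seed=5)
    parcs = [ens[(40, r)] for r in range(2)]
    per_subject = []
    for ts in cohort.tracts:
        snapped = sh.snap_endpoints(ts, cohort.mesh)
        mats = [
            sh.build_connectivity(
                sh.map_endpoints(ts, cohort.mesh, p, snapped=snapped))
            for p in parcs
        ]
        per_subject.append(mats)
    return cohort, parcs, per_subject
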