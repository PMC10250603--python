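import pytest

from pzapk import (
    CovariateSet,
    DosingRegimen,
    Observation,
    PopPKModel,
    PopulationParameters,
    SubjectRecord,
    final_model_spec,
    impute_blq,
    recovery_design,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def reference_params() -> PopulationParameters:
    return PopulationParameters.from_cv_percent()


@pytest.fixture(scope="session")
def small_cohort(reference_params):
    """80 subjects simulated under the final model (1/2/5 h design)."""
    subjects, truth = simulate_dataset(
        recovery_design(n_subjects=80), reference_params, seed=42
    )
    return impute_blq(subjects), truth


@pytest.fixture(scope="session")
def small_fit(small_cohort, reference_params):
    """FOCE-I fit of the 80-subject cohort (no SEs, for speed)."""
    subjects, _ = small_cohort
    model = PopPKModel(subjects, spec=final_model_spec(reference_params))
    return model.fit(compute_se=False)


def make_subject(sid="s1", times_concs=((2.0, 28.0),), dose=1500.0, age=50.0,
                 dm=False, lbw=48.0, weight=60.0) -> SubjectRecord:
    cov = CovariateSet(age=age, sex="M", body_weight=weight, lean_body_weight=lbw, dm=dm)
    obs = tuple(Observation(time=t, conc=c) for t, c in times_concs)
    return SubjectRecord(id=sid, covariates=cov, regimen=DosingRegimen(dose=dose),
                         observations=obs)


@pytest.fixture
def typical_subject():
    return make_subject()
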