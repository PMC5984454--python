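import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rankcbr.profiles import FeatureVector, Thermogram
from rankcbr.simulate import CohortSpec, PeakParams

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20180531)


def make_case(rng, n_grid=25, informative=None, label=0, effect=8.0):
    """One random FeatureVector on a short grid.

    With ``informative`` set to a scalar feature name, that feature is
    shifted by ``effect`` for label-1 cases; everything else is noise.
    """
    temps = np.linspace(45.0, 90.0, n_grid)
    vals = {
        "IR": int(rng.integers(0, 2)),
        "T1": 50.0 + rng.normal(0, 1.5),
        "T2": 62.0 + rng.normal(0, 1.5),
        "PEAK1": abs(1.0 + rng.normal(0, 0.3)),
        "PEAK2": abs(0.7 + rng.normal(0, 0.3)),
    }
    if informative is not None and label == 1:
        vals[informative] = vals[informative] + effect
    dcp = np.clip(np.abs(rng.normal(0.5, 0.2)) * np.exp(
        -0.5 * ((temps - 60.0) / 5.0) ** 2
    ) + rng.normal(0, 0.05, n_grid), 0, None)
    return FeatureVector(
        ir=vals["IR"], t1=vals["T1"], t2=vals["T2"],
        peak1=vals["PEAK1"], peak2=vals["PEAK2"],
        ind=Thermogram(temps=temps, dcp=dcp),
    )


def make_training_set(rng, n=20, informative=None, effect=8.0, n_grid=25):
    """Balanced labelled list of random FeatureVectors."""
    labels = np.array([i % 2 for i in range(n)])
    cases = [
        make_case(rng, n_grid=n_grid, informative=informative,
                  label=l, effect=effect)
        for l in labels
    ]
    return cases, labels


@pytest.fixture
def random_training_set(rng):
    return make_training_set(rng)


def separable_spec(seed=0, n_subjects=70, grid_length=451):
    """Zero-variance two-class spec: within-class curves identical, classes
    distinct in second-peak location and amplitudes."""
    return CohortSpec(
        n_subjects=n_subjects,
        cancer_fraction=0.5,
        grid_length=grid_length,
        class_params={
            "control": PeakParams(mu1=50.0, mu2=62.0, sd1=2.5, sd2=4.0,
                                  amp1=1.0, amp2=0.65),
            "cancer": PeakParams(mu1=52.0, mu2=75.0, sd1=3.0, sd2=5.0,
                                 amp1=0.8, amp2=0.9),
        },
        noise_sd=0.0,
        subject_sd=0.0,
        seed=seed,
    )


@pytest.fixture
def tiny_cohort():
    """Small noisy default-structure cohort on a coarse grid (fast)."""
    spec = CohortSpec(n_subjects=20, grid_length=91, seed=7)
    from rankcbr.simulate import generate_cohort

    curves, labels = generate_cohort(spec)
    return curves, labels, spec
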