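import hypothesis
import pytest

import replinorm as rn

hypothesis.settings.register_profile(
    "suite", derandomize=True, max_examples=60, deadline=None
)
hypothesis.settings.load_profile("suite")


@pytest.fixture
def std_env():
    """Standard-Gaussian environment X ~ N(0, 1)."""
    return rn.gaussian_environment(0.0, 1.0)


@pytest.fixture
def flat_design():
    """Single flat-norm genotype, pure additive-offset multi-lab design."""
    return rn.StudyDesign(
        n_labs=5, n_per_arm=4,
        genotypes=(rn.flat_norm(0.0, "g1"),),
        within_noise_sd=1.0, delta0=1.0,
    )


def make_study(mean_effect, se=1.0, x=None, lab="lab01", genotype="g1",
               n1=10, n2=10, s2=None):
    """StudyResult builder with sensible defaults for criterion tests."""
    if s2 is None:
        s2 = se ** 2 / (1.0 / n1 + 1.0 / n2)
    return rn.StudyResult(lab_id=lab, genotype_label=genotype,
                          mean_effect=mean_effect, se=se, n1=n1, n2=n2,
                          x=x, s2=s2)


@pytest.fixture
def study_factory():
    return make_study
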