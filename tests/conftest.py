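import numpy as np
import pytest

from midseg.phantoms import make_cohort, make_midbrain_phantom
from midseg.template_pipeline import (SITKBackend, build_template,
                                      compare_to_truth, segment_subject)

TEMPLATE_SEED = 0
SUBJECT_SEEDS = tuple(range(50, 60))


@pytest.fixture(scope="session")
def backend():
    return SITKBackend()


@pytest.fixture(scope="session")
def template_bundle(backend):
    """Template built from 5 synthetic subjects (best case unwarped)."""
    cohort = make_cohort(5, seed=TEMPLATE_SEED, first_unwarped=True)
    return build_template([(p.nm, p.chi) for p in cohort],
                          cohort[0].truth, backend)


@pytest.fixture(scope="session")
def cohort_results(template_bundle, backend):
    """Segmentations of 10 held-out warped subjects with evaluation tables."""
    out = []
    for seed in SUBJECT_SEEDS:
        sub = make_midbrain_phantom(seed=seed, warped=True)
        res = segment_subject(sub.nm, sub.chi, template_bundle, backend)
        report = compare_to_truth(res, sub.truth, sub.nm, sub.chi)
        out.append((sub, res, report))
    return out
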