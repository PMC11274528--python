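import numpy as np
import pytest

from gliogrowth import synthetic_cohort as sc
from gliogrowth.mask_measures import LesionMask


def make_mask(spec: sc.LesionSpec, spacing=(1.0, 1.0, 1.0),
              shape=(96, 96, 96)) -> LesionMask:
    labels = sc.generate_lesion_mask(spec, spacing, shape)
    return LesionMask(labels=labels, spacing=tuple(float(s) for s in spacing))


@pytest.fixture
def sphere_spec():
    return sc.LesionSpec(center=(48.0, 48.0, 48.0),
                         semi_axes=(15.0, 15.0, 15.0))


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A tiny deterministic cohort on disk, shared across tests."""
    out = tmp_path_factory.mktemp("cohort")
    config = sc.CohortConfig(n_patients=3, scans_per_patient=(3, 4),
                             image_shape=(72, 72, 72), mtd_range=(20.0, 28.0),
                             seed=7)
    masks, manifest, truth = sc.generate_cohort(config, out)
    return {"config": config, "masks": masks, "manifest": manifest,
            "truth": truth, "dir": out}
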