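import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("fixed", derandomize=True, deadline=None)
settings.load_profile("fixed")

from painmap.nlp import annotate_directory
from painmap.pipeline import extract_cohort_features
from painmap.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def study_cohort(tmp_path_factory):
    """A cohort at the documented study conditions: ~200 lesions, 84/16."""
    root = tmp_path_factory.mktemp("cohort")
    spec = CohortSpec(n_patients=60, pain_fraction=0.84, seed=11)
    paths = generate_cohort(spec, root)
    return paths


@pytest.fixture(scope="session")
def cohort_tables(study_cohort):
    """EN3/EN6 feature tables plus NLP labels for the study cohort."""
    tables = extract_cohort_features(study_cohort.volumes_dir,
                                     study_cohort.points_csv)
    labels = annotate_directory(study_cohort.notes_dir)
    truth = pd.read_csv(study_cohort.truth_csv)
    return {"tables": tables, "labels": labels, "truth": truth}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
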