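import pandas as pd
import pytest

import coatmorph as cm


@pytest.fixture(scope="session")
def small_survey() -> cm.Survey:
    """A seeded 300-site, four-month synthetic survey shared across tests.

    Large enough that every coat category is the modal type somewhere and the
    spatial multinomial fit is well separated from the divergence guard.
    """
    return cm.simulate_survey(cm.SimConfig(n_sites=300, n_nights=120, seed=11))


@pytest.fixture(scope="session")
def survey_dir(small_survey, tmp_path_factory):
    """The small survey written out as CSV inputs for pipeline runs."""
    d = tmp_path_factory.mktemp("survey")
    small_survey.write(d)
    return d


def detections_frame(rows) -> pd.DataFrame:
    """Build a detection table from (site, timestamp, pattern, colour, white, id)."""
    return pd.DataFrame(
        rows, columns=["site_id", "timestamp", "pattern", "colour", "white", "individual_id"]
    )
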