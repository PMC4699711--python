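import numpy as np
import pytest

import benpipe as bp
from benpipe.pipeline import RunConfig, _series_from_array, preprocess_subject
import benpipe.entropy as ent

# Reduced-size study used by unit and property tests: the grid and group
# sizes shrink but the temporal dimension stays at the full 240 volumes —
# with far fewer timepoints the band-limited series has too few spectral
# degrees of freedom for nuisance regression to be harmless.
SMALL_GRID = (14, 14, 10)


def small_cohort_config(seed=3, n=8, **kw):
    return bp.CohortConfig(
        seed=seed,
        n_patients=n,
        n_controls=n,
        grid_shape=SMALL_GRID,
        n_timepoints=240,
        **kw,
    )


@pytest.fixture(scope="session")
def small_cohort():
    return bp.generate_cohort(small_cohort_config())


@pytest.fixture(scope="session")
def small_cohort_ben(small_cohort):
    """Preprocessed series and raw (unstandardized) BEN ROI means per
    subject for the session's small cohort."""
    cfg = RunConfig()
    preprocessed = {}
    for rec in small_cohort.subjects:
        series = _series_from_array(
            small_cohort.bold[rec.subject_id], cfg, small_cohort.affine
        )
        ben_in, _ = preprocess_subject(
            series,
            rec.motion_params,
            small_cohort.tissue_probs["wm"],
            small_cohort.tissue_probs["csf"],
            cfg,
        )
        preprocessed[rec.subject_id] = ben_in
    maps = {
        sid: ent.ben_map(s, small_cohort.brain_mask)
        for sid, s in preprocessed.items()
    }
    return {"preprocessed": preprocessed, "maps": maps}


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
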