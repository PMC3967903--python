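import datetime as dt

import numpy as np
import pandas as pd
import pytest


def make_visits(rows):
    """Build a visit table from (tag, feeder, date, n_visits) tuples.

    Each tuple expands into ``n_visits`` one-second visits spaced a
    minute apart, which is all the metrics and permutation modules need.
    """
    recs = []
    for tag, feeder, date, n in rows:
        for k in range(n):
            start = dt.datetime.combine(date, dt.time(6, 0)) \
                + dt.timedelta(minutes=k)
            recs.append({"tag_id": tag, "feeder_id": feeder,
                         "start": start, "duration_s": 1,
                         "n_readings": 1, "date": date})
    return pd.DataFrame(recs)


def make_detections(spec):
    """Build a detection table from (tag, feeder, [second offsets])."""
    t0 = dt.datetime(2008, 6, 1, 6, 0, 0)
    recs = [{"timestamp": t0 + dt.timedelta(seconds=int(s)),
             "tag_id": tag, "feeder_id": feeder}
            for tag, feeder, secs in spec for s in secs]
    return pd.DataFrame(recs)


D1 = dt.date(2008, 6, 1)
D2 = dt.date(2008, 6, 2)
D3 = dt.date(2008, 6, 3)


@pytest.fixture(scope="session")
def grid():
    from feederdef.simdata import make_grid
    return make_grid(seed=0)


@pytest.fixture(scope="session")
def individuals():
    """Metadata for the small hand-built examples."""
    return pd.DataFrame({
        "tag": ["i", "j", "k", "juv", "f"],
        "sex": ["M", "M", "M", "M", "F"],
        "age_class": ["adult", "adult", "adult", "juvenile", "adult"],
    })


@pytest.fixture(scope="session")
def schedule_2008():
    from feederdef.simdata import make_treatment_schedule
    return make_treatment_schedule(2008)


@pytest.fixture(scope="session")
def small_stream():
    """A small but realistic simulated season (8 birds, 10 days)."""
    from feederdef import simdata
    g = simdata.make_grid(seed=0)
    sched = simdata.make_treatment_schedule(2008)
    pop = simdata.make_population(8, g, 2008, seed=4, juvenile_fraction=0.0)
    pop["first_day"] = dt.date(2008, 6, 1)
    pop["last_day"] = dt.date(2008, 6, 10)
    cfg = simdata.SimConfig(seed=4, dropout_prob=0.1)
    return simdata.simulate_detection_stream(pop, g, sched, cfg)


@pytest.fixture(scope="session")
def small_analysis_table():
    """A small bird-feeder-day table from the generative mixed model."""
    from feederdef import simdata
    design = simdata.make_nvc_design(n_rows=800, n_individuals=15,
                                     n_feeders=10, seed=21)
    coefs = {"Intercept": 2.0, "spatial_concentration": -0.3,
             "n_competitors": 0.3,
             "spatial_concentration:spatial_stability": -0.8}
    vc = dict(var_feeder=0.05, var_ind_intercept=0.08, var_ind_slope=0.3,
              cov_ind=-0.05, var_residual=0.3)
    return simdata.simulate_nvc_table(coefs, vc, design, seed=21)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
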