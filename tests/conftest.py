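import numpy as np
import pytest

import wqsource as wq


@pytest.fixture(scope="session")
def specs():
    return wq.default_specs()


@pytest.fixture(scope="session")
def small_dataset(specs):
    """2 stations x 36 months study-condition dataset (fast, with truth)."""
    model = wq.default_source_model(
        seed=11,
        config=wq.default_config(
            n_stations=2,
            station_gradient={j: g[:2] for j, g in
                              wq.synthetic.DEFAULT_STATION_GRADIENT.items()},
        ),
    )
    ds = wq.simulate_monitoring(model, n_stations=2, n_months=36, seed=12)
    return wq.apply_detection_limits(ds, {n: s.mdl for n, s in specs.items()})


@pytest.fixture(scope="session")
def study_dataset(specs):
    """Full study-condition dataset: 4 stations x 107 months, 5 sources."""
    model = wq.default_source_model(seed=1)
    ds = wq.simulate_monitoring(model, n_stations=4, n_months=107, seed=2)
    return wq.apply_detection_limits(ds, {n: s.mdl for n, s in specs.items()})


def random_record(rng, specs):
    """A random concentration record spanning each parameter's curve domain."""
    rec = {}
    for name, s in specs.items():
        lo = s.curve.points[0][0]
        hi = s.curve.points[-1][0]
        span = hi - lo
        rec[name] = rng.uniform(max(0.0, lo - 0.2 * span), hi + 0.2 * span)
    return rec
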