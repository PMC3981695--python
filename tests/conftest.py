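import numpy as np
import pandas as pd
import pytest

from divebout.trace import DepthTrace


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def trace_from_depths(depths, dt=10.0, pad=3, **kw):
    """Wrap a depth sequence in surface samples so it forms one dive window."""
    d = np.concatenate([np.zeros(pad), np.asarray(depths, float), np.zeros(pad)])
    return DepthTrace(depth=d, dt=dt, **kw)


def square_dive_df(n=4, depth=40.0, duration=300.0, bottom=180.0,
                   interval=60.0, animal="A", shape="square", t0=0.0):
    """A hand-built dive table of identical dives at fixed intervals."""
    rows = []
    t = t0
    for _ in range(n):
        rows.append(
            dict(animal_id=animal, start_s=t, end_s=t + duration,
                 max_depth=depth, duration=duration, bottom_time=bottom,
                 shape_class=shape)
        )
        t += duration + interval
    return pd.DataFrame(rows)
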