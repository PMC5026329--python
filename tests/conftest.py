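import numpy as np
import pandas as pd
import pytest

from ts2sls import Sample


@pytest.fixture
def toy_sample1():
    """Scalar toy: z=(1,1,2), y=(1,2,3) -> pi_y1=1.5, HC0 var 1/72."""
    return Sample(pd.DataFrame({"y": [1.0, 2.0, 3.0], "z": [1.0, 1.0, 2.0]}),
                  {"y": "outcome", "z": "instrument"}, label="sample1")


@pytest.fixture
def toy_sample2():
    """Scalar toy: z=(1,2), x=(1,3) -> Pi=1.4, HC0 var 0.0128."""
    return Sample(pd.DataFrame({"x": [1.0, 3.0], "z": [1.0, 2.0]}),
                  {"x": "exposure", "z": "instrument"}, label="sample2")


def random_design(rng, n1=60, n2=50, kz=3, kx=2, noise=0.5):
    """Small random two-sample dataset with a well-conditioned first stage."""
    Pi = rng.normal(size=(kz, kx)) + 2 * np.eye(kz, kx)
    beta = rng.normal(size=kx)
    Z1 = rng.normal(size=(n1, kz))
    Z2 = rng.normal(size=(n2, kz))
    X2 = Z2 @ Pi + noise * rng.normal(size=(n2, kx))
    X1 = Z1 @ Pi + noise * rng.normal(size=(n1, kx))
    y1 = X1 @ beta + noise * rng.normal(size=n1)
    znames = [f"z{a}" for a in range(kz)]
    xnames = [f"x{r}" for r in range(kx)]
    df1 = pd.DataFrame(np.column_stack([y1, Z1]), columns=["y"] + znames)
    df2 = pd.DataFrame(np.column_stack([X2, Z2]), columns=xnames + znames)
    roles1 = {"y": "outcome", **{z: "instrument" for z in znames}}
    roles2 = {**{x: "exposure" for x in xnames},
              **{z: "instrument" for z in znames}}
    s1 = Sample(df1, roles1, label="sample1")
    s2 = Sample(df2, roles2, label="sample2")
    return s1, s2, beta, Pi
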