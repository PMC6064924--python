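import numpy as np
import pytest

from aortashear.metrics import WallShearRecord
from aortashear.oracles import FluidProperties


@pytest.fixture
def props() -> FluidProperties:
    """Blood-model constants (rho = 1235 kg/m^3, eta = 0.004 Pa*s)."""
    return FluidProperties()


def make_record(tau_fn, n_times=256, period_T=0.1, normal=(0.0, 0.0, 1.0),
                region="non-ostial", point_id=0):
    """Build a tangential 3-D record from tau_fn(t) -> (n, 3) vectors."""
    t = np.arange(n_times) * (period_T / n_times)
    tau = np.asarray(tau_fn(t), dtype=float)
    return WallShearRecord(
        point_id=point_id,
        position=np.zeros(3),
        outward_normal=np.asarray(normal, dtype=float),
        region_label=region,
        times=t,
        tau_vectors=tau,
        period_T=period_T,
    )


@pytest.fixture
def record_factory():
    return make_record


def random_trig_record(rng, n_times=256, period_T=0.1, n_harmonics=6, allow_reversal=True):
    """Random band-limited tangential WSS record (normal along +z).

    Components are trigonometric polynomials, so cycle integrals of smooth
    functionals converge spectrally and dense quadrature is a sharp oracle.
    """
    t = np.arange(n_times) * (period_T / n_times)
    w = 2 * np.pi / period_T

    def trig(mean_lo, mean_hi):
        coef_c = rng.normal(0, 0.5, n_harmonics)
        coef_s = rng.normal(0, 0.5, n_harmonics)
        mean = rng.uniform(mean_lo, mean_hi)

        def f(x):
            out = np.full(np.shape(x), mean)
            for n in range(1, n_harmonics + 1):
                out = out + coef_c[n - 1] * np.cos(n * w * x) + coef_s[n - 1] * np.sin(n * w * x)
            return out

        return f

    lo = -1.0 if allow_reversal else 2.0
    fx, fy = trig(lo, 3.0), trig(-0.5, 0.5)
    tau = np.stack([fx(t), fy(t), np.zeros_like(t)], axis=1)
    rec = WallShearRecord(
        point_id=0,
        position=np.zeros(3),
        outward_normal=np.array([0.0, 0.0, 1.0]),
        region_label="non-ostial",
        times=t,
        tau_vectors=tau,
        period_T=period_T,
    )
    return rec, (fx, fy)
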