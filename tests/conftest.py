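import numpy as np
import pytest

from nremspec import SpectrumSpec, synth_spectrum


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def make_spectrum():
    """Factory for noiseless model spectra on the default 0.25-48 Hz grid."""

    def _make(alpha=-2.5, lnC=4.0, bumps=(), noise_sd=0.0, seed=0, **kw):
        spec, truth = synth_spectrum(
            SpectrumSpec(alpha=alpha, lnC=lnC, bumps=tuple(bumps),
                         noise_sd=noise_sd, seed=seed, **kw),
            channel="C3",
        )
        return spec, truth

    return _make


def dense_local_maxima(alpha, lnC, bumps, band=(9.0, 18.0), step=1e-4):
    """Independent oracle: interior local maxima of the generating curve.

    Evaluates ln P(f) = lnC + alpha ln f + sum of Gaussian bumps on a dense
    grid and returns (frequency, whitened value) of each strict interior
    local maximum, sorted by whitened value (descending).
    """
    f = np.arange(band[0], band[1] + step / 2, step)
    curve = lnC + alpha * np.log(f)
    for c, h, w in bumps:
        curve = curve + h * np.exp(-((f - c) ** 2) / (2 * w * w))
    interior = np.nonzero((curve[1:-1] > curve[:-2]) & (curve[1:-1] > curve[2:]))[0] + 1
    out = [(f[i], curve[i] - (lnC + alpha * np.log(f[i]))) for i in interior]
    return sorted(out, key=lambda t: -t[1])
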