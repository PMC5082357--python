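import numpy as np
import pytest

from ewavekit import DetectionSettings, PDFParameters
from ewavekit.synthetic import SyntheticSpec


@pytest.fixture
def worked_example_a() -> PDFParameters:
    """First worked-example parameter set (normal-range E-wave)."""
    return PDFParameters(c=17.3, k=135.0, x0=11.4)


@pytest.fixture
def worked_example_b() -> PDFParameters:
    """Second worked-example parameter set (stiffer, higher-velocity wave)."""
    return PDFParameters(c=17.7, k=226.0, x0=16.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160)


def random_underdamped(rng: np.random.Generator, n: int) -> list[PDFParameters]:
    """Underdamped parameter draws spanning the physiological cohort ranges."""
    out = []
    while len(out) < n:
        c = rng.uniform(5.0, 33.0)
        k = rng.uniform(100.0, 300.0)
        x0 = rng.uniform(7.0, 18.0)
        if c * c < 4.0 * k:
            out.append(PDFParameters(c=c, k=k, x0=x0))
    return out


def plain_settings(t_end: float, **kw) -> DetectionSettings:
    """Detection over [t_start, t_end] with both shortening corrections off."""
    kw.setdefault("zero_tail", False)
    kw.setdefault("tangent_shorten", False)
    kw.setdefault("t_start", 0.0)
    return DetectionSettings(t_end=t_end, **kw)


def strip_spec(params: PDFParameters, **kw) -> SyntheticSpec:
    """Synthetic strip spec with a velocity scale that fits the wave."""
    from ewavekit.model import peak_characteristics

    vmax = peak_characteristics(params)[1]
    head = kw.pop("headroom_cm_s", 20.0)
    kw.setdefault("dv_per_row", max(0.5, (vmax + head) / 150.0))
    return SyntheticSpec(params=params, **kw)
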