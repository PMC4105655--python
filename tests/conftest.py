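"""Shared fixtures: a desk-scale sweep, virtual rigs and simulated tracts.

The measurement-chain fixtures run at 48 kHz with a 2 s sweep — small enough
for fast tests while keeping the full 20 Hz – 20 kHz band of the default
measurement sweep.
"""

import numpy as np
import pytest
from scipy.signal import firwin2

import sweeptract as st
from sweeptract.rig import RigSpec, measure_tract
from sweeptract.tubes import AirModel, TubeSpec
from sweeptract.waveguide import AreaFunction, SideBranch, WallModel, simulate_tf

FS = 48_000.0


@pytest.fixture(scope="session")
def air5():
    return AirModel(temperature_c=5.0)


@pytest.fixture(scope="session")
def spec48():
    return st.SweepSpec(f1=20.0, f2=20_000.0, T=2.0, fs=FS,
                        f_env_lo=50.0, f_env_hi=18_000.0)


@pytest.fixture(scope="session")
def ess48(spec48):
    """Faded sweep at half amplitude (headroom for the distorting rigs)."""
    ess = st.apply_fade_out(st.apply_fade_in(st.generate_ess(spec48), spec48),
                            spec48)
    return st.SampledSignal(ess.samples * 0.5, FS)


@pytest.fixture(scope="session")
def inverse48(ess48, spec48):
    return st.build_inverse_filter(ess48, spec48)


@pytest.fixture(scope="session")
def tract_fir():
    """A known, smooth 513-tap tract stand-in with full in-band support."""
    return firwin2(513, [0.0, 0.05, 0.1, 0.3, 0.6, 1.0],
                   [0.1, 0.9, 1.0, 0.5, 0.4, 0.0])


@pytest.fixture(scope="session")
def rigs(tract_fir):
    """Three distinct rigs: clean, distorted, and a different strongly
    distorted driver (2nd/3rd-order products at -20 dB)."""
    driver1 = firwin2(63, [0.0, 0.02, 0.5, 0.95, 1.0], [0.2, 1.0, 0.8, 0.3, 0.0])
    driver2 = firwin2(95, [0.0, 0.03, 0.2, 0.7, 1.0], [0.1, 0.7, 1.0, 0.5, 0.0])
    return {
        "clean": RigSpec(driver_ir=driver1, distortion_coeffs=[0.0, 1.0],
                         tract_fir=tract_fir, noise_snr_db=60.0, seed=11, fs=FS),
        "distorted": RigSpec(driver_ir=driver1,
                             distortion_coeffs=[0.0, 1.0, 0.1, 0.03],
                             tract_fir=tract_fir, noise_snr_db=60.0, seed=11,
                             fs=FS),
        "driver2-strong": RigSpec(driver_ir=driver2,
                                  distortion_coeffs=[0.0, 1.0, 0.1, 0.1],
                                  tract_fir=tract_fir, noise_snr_db=60.0,
                                  seed=11, fs=FS),
    }


@pytest.fixture(scope="session")
def recovered_tfs(ess48, spec48, rigs):
    """Driver-subtracted tract spectra recovered through the full pipeline."""
    return {name: measure_tract(ess48, spec48, rig, repeats=3)
            for name, rig in rigs.items()}


@pytest.fixture(scope="session")
def benchmark_tube():
    return TubeSpec(L=142.0, a=15.0, w=2.0)


@pytest.fixture(scope="session")
def vowel_tract():
    """A plausible 175 mm vowel-like area function (glottis to lips)."""
    return AreaFunction(
        np.array([0.0, 20, 40, 60, 80, 100, 120, 140, 160, 175]),
        np.array([50.0, 120, 260, 340, 300, 220, 160, 220, 300, 340]))


@pytest.fixture(scope="session")
def fossa_branch():
    """A 19 mm closed side branch near the glottis, like a piriform fossa."""
    return SideBranch(attach_x=15.0, length=19.0, area=40.0)


@pytest.fixture(scope="session")
def vowel_tfs(vowel_tract, fossa_branch, air5):
    wall = WallModel(alpha=0.02, air=air5)
    f_grid = np.arange(50.0, 10_000.0, 2.0)
    return {
        "with": simulate_tf(vowel_tract, [fossa_branch], wall, f_grid),
        "without": simulate_tf(vowel_tract, [], wall, f_grid),
    }
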