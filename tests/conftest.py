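import numpy as np
import pytest

import wexsim as w

TAU = 500e-6
LIBOR_FRF = 780.0


@pytest.fixture
def libor_sweep_pulse():
    """1 ms LIBOR at the published optimum phase (-45 deg), set angle 10."""
    return w.make_libor(TAU, LIBOR_FRF, -45.0, 10.0)


@pytest.fixture(scope="session")
def libor_phase_sweep():
    """The 73 x 321 phase-modulation sweep of the 1 ms LIBOR at set 10 deg."""
    return w.phase_sweep(lambda d: w.make_libor(TAU, LIBOR_FRF, d, 10.0))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240914)


def brute_force_pulse(m, pulse, f_tissue, dt=1e-6):
    """Independent water-frame integrator: exact small rotations about the
    instantaneous effective axis, with the ramping B1 phase evaluated at each
    substep midpoint.  Never uses the per-segment closed form."""
    m = np.asarray(m, float).copy()
    t0 = 0.0
    for seg in pulse.segments:
        n = max(1, int(round(seg.duration / dt)))
        h = seg.duration / n
        for k in range(n):
            tm = t0 + (k + 0.5) * h
            phi = np.deg2rad(seg.phase + 360.0 * seg.freq_offset * tm)
            om = np.array(
                [seg.amplitude * np.cos(phi), seg.amplitude * np.sin(phi), f_tissue]
            )
            nrm = np.linalg.norm(om)
            if nrm == 0.0:
                continue
            ax = om / nrm
            ang = 2.0 * np.pi * nrm * h
            m = (
                m * np.cos(ang)
                + np.cross(ax, m) * np.sin(ang)
                + ax * np.dot(ax, m) * (1.0 - np.cos(ang))
            )
        t0 += seg.duration
    return m
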