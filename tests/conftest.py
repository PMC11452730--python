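import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from curvilinea import geometry as geo
from curvilinea import simulate as sim
from curvilinea import stimuli as sti

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# the magic number for cubic Bézier approximation of a 90-degree arc
KAPPA90 = 0.5522847498307936


def quarter_circle_cubic(r: float = 100.0) -> geo.BezierSegment:
    """Cubic approximating the quarter circle centered at (r, 0), from
    (0, 0) up to (r, r) in screen coordinates."""
    k = KAPPA90 * r
    return geo.BezierSegment([(0, 0), (0, k), (r - k, r), (r, r)])


def eighth_circle_cubic(r: float = 100.0) -> geo.BezierSegment:
    """Cubic approximating a 45-degree arc of radius r (much more uniform
    curvature than the 90-degree approximation)."""
    k = 4.0 / 3.0 * np.tan(np.pi / 16.0)
    a = np.pi / 4.0
    p0 = np.array([r, 0.0])
    p3 = r * np.array([np.cos(a), np.sin(a)])
    t0 = np.array([0.0, 1.0])
    t3 = np.array([-np.sin(a), np.cos(a)])
    return geo.BezierSegment([p0, p0 + k * r * t0, p3 - k * r * t3, p3])


@pytest.fixture(scope="session")
def quarter_circle() -> geo.BezierSegment:
    return quarter_circle_cubic()


@pytest.fixture(scope="session")
def straight_segment() -> geo.BezierSegment:
    return geo.BezierSegment([(0.0, 0.0), (3.0, 4.0)])


@pytest.fixture(scope="session")
def contour_family() -> list[sti.Contour]:
    return sim.generate_contour_family()


@pytest.fixture(scope="session")
def stimulus_set(contour_family) -> sti.StimulusSet:
    return sti.build_stimulus_set(contour_family, sim.DEFAULT_WIDTHS)


@pytest.fixture(scope="session")
def default_ratings(stimulus_set):
    cfg = sim.SimulationConfig()
    return sim.simulate_ratings(cfg, stimulus_set, seed=11)


def random_smooth_cubic(rng: np.random.Generator) -> geo.BezierSegment:
    """A random regular cubic with well-separated control points."""
    while True:
        pts = rng.uniform(-100, 100, size=(4, 2))
        seg = geo.BezierSegment(pts)
        t = np.linspace(0, 1, 257)
        d1, _ = seg.derivatives(t)
        speed = np.hypot(d1[:, 0], d1[:, 1])
        if speed.min() > 1e-3 * seg.bbox_diagonal():
            return seg
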