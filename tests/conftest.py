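import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pfas_screen import run_from_paths
from pfas_screen.msio import EIC
from pfas_screen.synth import groundwater_scenario, simulate_runs

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def make_eic(intensity, spacing=0.01, target_mz=300.0, tol_ppm=5.0):
    y = np.asarray(intensity, dtype=float)
    return EIC(
        target_mz=target_mz,
        tol_ppm=tol_ppm,
        rt=np.arange(y.size) * spacing,
        intensity=y,
    )


def gaussian_eic(height=1e6, sigma=0.05, spacing=0.01, span=2.0, center=None, baseline=0.0):
    rt = np.arange(0.0, span, spacing)
    c = center if center is not None else span / 2
    y = baseline + height * np.exp(-0.5 * ((rt - c) / sigma) ** 2)
    return EIC(target_mz=300.0, tol_ppm=5.0, rt=rt, intensity=y)


@pytest.fixture(scope="session")
def scenario():
    return groundwater_scenario(seed=7)


@pytest.fixture(scope="session")
def scenario_dir(tmp_path_factory, scenario):
    d = tmp_path_factory.mktemp("runs")
    manifest = simulate_runs(scenario, d)
    return d, manifest


@pytest.fixture(scope="session")
def pipeline_result(scenario_dir):
    d, manifest = scenario_dir
    return run_from_paths(
        manifest,
        str(d / "suspects.csv"),
        str(d / "standards.csv"),
        str(d / "fragments.csv"),
    )
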