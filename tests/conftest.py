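import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim_cfg():
    """A fast, narrow-window simulated experiment for integration tests."""
    from wcmaldi import AnalytePeak, SimConfig

    return SimConfig(
        seed=42,
        mz_range=(600.0, 900.0),
        analytes=[
            AnalytePeak(826.6, 60.0, "descending", log_ic50=-6.3, hill_slope=1.0,
                        top=1.0, bottom=0.28, name="marker"),
            AnalytePeak(703.6, 75.0, "none", name="inert_a"),
            AnalytePeak(760.6, 66.0, "none", name="inert_b"),
            AnalytePeak(849.5, 30.0, "none", name="inert_c"),
        ],
        matrix_ions=[(616.9, 40.0), (650.3, 25.0)],
        n_tech=3,
        n_bio=3,
        baseline_amplitude=1.0,
    )


@pytest.fixture(scope="session")
def flagship_run():
    """One full default-scale simulated experiment run through the pipeline."""
    import wcmaldi as w

    cfg = w.SimConfig(seed=7)
    spectra, sheet, truth = w.simulate_experiment(cfg)
    fm = w.preprocess_pipeline(spectra, sheet, w.PreprocessConfig())
    result = w.find_markers(fm)
    return {"cfg": cfg, "sheet": sheet, "truth": truth, "fm": fm, "result": result}
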