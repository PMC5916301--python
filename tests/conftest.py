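import numpy as np
import pandas as pd
import pytest

import trapstat as ts


@pytest.fixture(scope="session")
def small_landscape():
    """150 stations with three spatially structured covariates."""
    spec = ts.LandscapeSpec(
        n_stations=150, extent=(0.0, 0.0, 50000.0, 50000.0),
        min_spacing=2000.0, seed=42,
    )
    stations, pixels = ts.simulate_landscape(spec)
    return stations, pixels


@pytest.fixture(scope="session")
def small_survey(small_landscape):
    """Simulated daily detections plus truth on the small landscape."""
    stations, _ = small_landscape
    covs, std = ts.zscore(stations, ["elevation", "forest", "dist_river"])
    daily, truth = ts.simulate_occupancy_detections(
        covs, beta_psi=[-0.4, -0.25, 0.3, 0.25], beta_p=[-1.3],
        tau=1.0, seed=7,
    )
    occ = ts.collapse_occasions(daily, 15)
    return covs, occ, truth


@pytest.fixture(scope="session")
def fixture_survey():
    """The bundled study-scale synthetic survey (849 stations)."""
    from trapstat.synthetic import fixture_daily

    stations, daily = fixture_daily()
    return stations, daily


@pytest.fixture(scope="session")
def small_scr():
    """Simulated capture-recapture dataset with generous captures."""
    gx, gy = np.meshgrid(np.arange(6), np.arange(6))
    traps = np.column_stack([gx.ravel(), gy.ravel()]) * 4000.0
    mask = ts.build_mask(traps, buffer=15000.0, spacing=2000.0)
    truth = ts.simulate_scr_population(
        mask, traps, D_per_100km2=2.0, lambda0=0.12, sigma=5000.0,
        n_occasions=50, seed=11,
    )
    assert truth.captures is not None
    return mask, traps, truth
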