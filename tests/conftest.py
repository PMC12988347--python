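import pandas as pd
import pytest

from dielflux import GeneratorConfig, SiteMeta, generate_site
from dielflux.solar import label_hours


@pytest.fixture(scope="session")
def default_cfg():
    return GeneratorConfig(seed=1)


@pytest.fixture(scope="session")
def default_meta(default_cfg):
    c = default_cfg
    return SiteMeta("SYN001", c.site_lat, c.site_lon, c.utc_offset, "MF")


@pytest.fixture(scope="session")
def mechanism_run(default_cfg, default_meta):
    """One default (lag-mechanism) site-summer, labelled day/night."""
    flux, gpp_daily, truth = generate_site(default_cfg)
    labeled = label_hours(flux, default_meta)
    return labeled, gpp_daily, truth


@pytest.fixture(scope="session")
def noiseless_run(default_cfg, default_meta):
    flux, _, truth = generate_site(default_cfg.replace(noise_cv=0.0))
    return label_hours(flux, default_meta), truth


def make_labeled(cfg: GeneratorConfig, igbp: str = "MF") -> pd.DataFrame:
    meta = SiteMeta("S", cfg.site_lat, cfg.site_lon, cfg.utc_offset, igbp)
    flux, _, _ = generate_site(cfg)
    return label_hours(flux, meta)
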