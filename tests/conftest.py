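import dataclasses

import pandas as pd
import pytest

from climaffect.lexicon import load_toy_lexicon, load_toy_proenv_lexicon
from climaffect.merging import merge_analysis
from climaffect.simulate import (
    SyntheticConfig,
    generate_posts,
    generate_vulnerability,
    generate_weather,
)
from climaffect.weather import build_climatology, compute_indicators


def build_analysis(cfg: SyntheticConfig):
    """Run the synthetic chain weather -> indicators -> posts -> merge."""
    wx = generate_weather(cfg)
    clim = build_climatology(
        wx, cfg.baseline_start, pd.Timestamp(cfg.date_start) - pd.Timedelta(days=1)
    )
    ind = compute_indicators(wx, clim)
    posts = generate_posts(cfg, ind)
    vuln = generate_vulnerability(cfg)
    analysis, report = merge_analysis(posts, ind, vuln)
    return analysis, ind, report


@pytest.fixture(scope="session")
def toy_lexicon():
    return load_toy_lexicon()


@pytest.fixture(scope="session")
def proenv_lexicon():
    return load_toy_proenv_lexicon()


@pytest.fixture(scope="session")
def medium_truth_config():
    """~16k posts over 3 regions with the default structural truth."""
    return SyntheticConfig(
        n_regions=3, baseline_years=3, posts_per_region_day_mean=15.0, seed=2
    )


@pytest.fixture(scope="session")
def medium_analysis(medium_truth_config):
    analysis, _, _ = build_analysis(medium_truth_config)
    return analysis


def replace(cfg, **kw):
    return dataclasses.replace(cfg, **kw)
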