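"""Bundled reference tables from a published post-fire soil survey.

Four 50 m x 50 m plots in burned lodgepole-pine / spruce-fir forest in
Greater Yellowstone (two fires x two burn severities: glade_crown,
moran_crown, glade_surface, moran_surface; 81 cores per plot) were sampled
two years after stand-replacing fire.  The tables carry the published
plot-level values: per-lipid mean mole percents, community-metric means,
posterior spatial-model summaries, and pool-dilution rates at the two
crown-fire plots.  Per-core raw data were never deposited, so these plot
means serve as targets for the synthetic generator and as worked-example
inputs; the loaders return plain pandas DataFrames.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "PLOTS",
    "load_lipid_profiles",
    "load_community_metrics",
    "load_posterior_ranges",
    "load_pool_dilution",
]

PLOTS = ("glade_crown", "moran_crown", "glade_surface", "moran_surface")


def _read(name: str, **kwargs) -> pd.DataFrame:
    with resources.files("firekrige.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, **kwargs)


def load_lipid_profiles() -> pd.DataFrame:
    """Per-lipid mean mole percent (and 1 SE) per plot; 26 lipids, indexed by
    lipid name.  A missing entry means the lipid was not detected there."""
    return _read("lipid_profiles.csv", index_col="lipid")


def load_community_metrics() -> pd.DataFrame:
    """Plot-mean community metrics (mean and 1 SE over n = 81 cores):
    abundance_nmol, fb_ratio, gm_pos, gm_neg, stress_ratio."""
    return _read("community_metrics.csv", index_col="metric")


def load_posterior_ranges() -> pd.DataFrame:
    """Posterior spatial-model summaries per variable and plot: trend mean,
    autocorrelation range (mean, 5%, 95%; metres, = 3 phi), sill, nugget,
    nugget ratio and the leave-one-out cross-validation adjusted R²."""
    return _read("posterior_ranges.csv")


def load_pool_dilution() -> pd.DataFrame:
    """Pool-dilution rates (µg N g⁻¹ d⁻¹, plot mean ± 1 SE) at the two
    crown-fire plots: gross nitrification, NH4+/NO3- consumption and the
    published net rates."""
    return _read("pool_dilution.csv", index_col="plot")
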