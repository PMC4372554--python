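"""Reference inputs from a captive gray wolf feeding trial.

Ten adult gray wolves were fed white-tailed deer, beaver and Canada goose
over a monitored year; prey tissues and wolf guard hair were assayed for
d13C and d15N.  The constants here are the published summary statistics of
that trial and are the default worked example throughout the package: prey
muscle summaries, wolf hair summaries, item counts, literature body-mass
ranges, the two candidate trophic discrimination factor (TDF) sets, and the
maximum-likelihood Dirichlet fitted to the bootstrap diet.
"""

from __future__ import annotations

import datetime as dt

from .core import DirichletSpec, SourceDistribution, TDFSet

__all__ = [
    "SOURCE_NAMES",
    "CAPTIVE_SOURCES",
    "DEER_HAIR",
    "WOLF_RUMP_MEAN",
    "WOLF_RUMP_SD",
    "WOLF_SHOULDER_MEAN",
    "WOLF_SHOULDER_SD",
    "N_WOLVES",
    "ITEM_COUNTS",
    "MASS_RANGES_KG",
    "FEEDING_START",
    "HAIR_GROWTH_CUTOFF",
    "FOX_TDF",
    "WOLF_TDF",
    "DIET_ALPHA",
    "BOOTSTRAP_DIET_MEAN",
]

#: Source order used everywhere: most data exist for deer, then beaver, goose.
SOURCE_NAMES: tuple[str, ...] = ("deer", "beaver", "goose")

#: Prey muscle tissue summaries (lipid-extracted), per isotope: mean, SD, n.
CAPTIVE_SOURCES: tuple[SourceDistribution, ...] = (
    SourceDistribution(
        "deer", {"d13C": -22.12, "d15N": 4.24}, {"d13C": 2.35, "d15N": 0.99},
        n=20, tissue="muscle",
    ),
    SourceDistribution(
        "beaver", {"d13C": -24.80, "d15N": 2.32}, {"d13C": 0.34, "d15N": 1.60},
        n=13, tissue="muscle",
    ),
    SourceDistribution(
        "goose", {"d13C": -25.57, "d15N": 4.00}, {"d13C": 1.46, "d15N": 1.18},
        n=15, tissue="muscle",
    ),
)

#: Deer guard hair summary (not used downstream; hair and muscle were similar).
DEER_HAIR = SourceDistribution(
    "deer", {"d13C": -21.92, "d15N": 4.69}, {"d13C": 3.03, "d15N": 1.13},
    n=23, tissue="hair",
)

#: Wolf rump guard-hair summary (the consumer tissue used in the analysis).
WOLF_RUMP_MEAN: dict[str, float] = {"d13C": -20.38, "d15N": 7.16}
WOLF_RUMP_SD: dict[str, float] = {"d13C": 0.64, "d15N": 0.30}
WOLF_SHOULDER_MEAN: dict[str, float] = {"d13C": -20.04, "d15N": 7.09}
WOLF_SHOULDER_SD: dict[str, float] = {"d13C": 0.53, "d15N": 0.26}

N_WOLVES = 10

#: Food items fed during the hair-growth window.
ITEM_COUNTS: dict[str, int] = {"deer": 106, "beaver": 14, "goose": 121}

#: Literature whole-body mass ranges (kg) per prey species.
MASS_RANGES_KG: dict[str, tuple[float, float]] = {
    "deer": (41.0, 223.0),
    "beaver": (5.0, 35.0),
    "goose": (3.0, 6.0),
}

FEEDING_START = dt.date(2011, 6, 7)
#: Food eaten after this date is assumed not to contribute to hair growth.
HAIR_GROWTH_CUTOFF = dt.date(2011, 10, 31)

#: Experimentally derived red fox TDFs, commonly borrowed for wolf studies.
FOX_TDF = TDFSet(
    "fox", {"d13C": 2.6, "d15N": 3.4}, {"d13C": 0.282, "d15N": 0.204}
)

#: Gray wolf TDFs estimated from this trial (posterior mean and SD).
WOLF_TDF = TDFSet(
    "wolf", {"d13C": 1.97, "d15N": 3.04}, {"d13C": 0.70, "d15N": 0.31}
)

#: Maximum-likelihood Dirichlet fitted to the bootstrap diet proportions.
DIET_ALPHA = DirichletSpec(SOURCE_NAMES, (582.1, 12.4, 24.3))

#: Bootstrap mean diet proportions (deer, beaver, goose).
BOOTSTRAP_DIET_MEAN: dict[str, float] = {
    "deer": 0.941, "beaver": 0.020, "goose": 0.039,
}
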