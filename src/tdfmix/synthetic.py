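"""Synthetic feeding records and isotope datasets.

The generator reproduces the statistical structure the downstream analysis
assumes, so that every stage is testable without the original raw data:

* feeding histories as per-individual item counts over a date window, with
  per-item body masses Uniform(min, max) by species;
* source tissue samples Normal(mu_jk, omega_jk^2) per isotope;
* consumer isotope values drawn from the marginal Normal implied by the
  mixing model: mean ``sum_k p_k (mu_jk + c_j)`` and variance
  ``sum_k p_k^2 omega_jk^2 + sigma_j^2``.

Drawing consumers from that marginal (rather than simulating individual
meals) makes parameter recovery a clean test: the simulated data follow
exactly the likelihood the mixing model fits.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_ISOTOPES,
    ConsumerData,
    IsotopeSample,
    SourceDistribution,
    TDFSet,
    source_arrays,
)

__all__ = [
    "FeedingRecord",
    "MassRange",
    "SyntheticScenario",
    "generate_feeding_records",
    "generate_isotope_dataset",
    "simulate_consumers",
    "mixture_moments",
    "read_feeding_csv",
    "write_feeding_csv",
]


@dataclass(frozen=True)
class FeedingRecord:
    """Count of items of one prey species eaten by one individual on a date."""

    individual_id: str
    species: str
    date: dt.date
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"count must be >= 1, got {self.count}")


@dataclass(frozen=True)
class MassRange:
    """Uniform body-mass range (kg) for one prey species."""

    species: str
    min_kg: float
    max_kg: float

    def __post_init__(self) -> None:
        if not (0 < self.min_kg <= self.max_kg):
            raise ValueError(
                f"need 0 < min_kg <= max_kg, got ({self.min_kg}, {self.max_kg})"
            )


@dataclass
class SyntheticScenario:
    """Full generative configuration for one synthetic isotope dataset."""

    sources: Sequence[SourceDistribution]
    proportions: Sequence[float]
    tdf: TDFSet
    n_consumers: int
    residual_sd: Mapping[str, float]
    seed: int = 0
    n_source_samples: int = 15
    isotopes: Sequence[str] = DEFAULT_ISOTOPES

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, float)
        if p.shape != (len(self.sources),):
            raise ValueError("proportions length must match number of sources")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("proportions must be >= 0 and sum to 1")
        if self.n_consumers < 1:
            raise ValueError("need at least one consumer")
        self.proportions = p

    @classmethod
    def from_dict(cls, cfg: Mapping) -> "SyntheticScenario":
        """Build a scenario from a plain config mapping (YAML/JSON-friendly)."""
        isotopes = tuple(cfg.get("isotopes", DEFAULT_ISOTOPES))
        sources = [
            SourceDistribution(
                species=name,
                mean=spec["mean"],
                sd=spec["sd"],
                n=spec.get("n"),
                tissue=spec.get("tissue", ""),
            )
            for name, spec in cfg["sources"].items()
        ]
        tdf_cfg = cfg["tdf"]
        tdf = TDFSet(tdf_cfg.get("label", "tdf"), tdf_cfg["mean"], tdf_cfg["sd"])
        return cls(
            sources=sources,
            proportions=[cfg["proportions"][s.species] for s in sources],
            tdf=tdf,
            n_consumers=int(cfg["n_consumers"]),
            residual_sd=dict(cfg.get("residual_sd", {iso: 0.0 for iso in isotopes})),
            seed=int(cfg.get("seed", 0)),
            n_source_samples=int(cfg.get("n_source_samples", 15)),
            isotopes=isotopes,
        )


def generate_feeding_records(
    counts: Mapping[str, int],
    start: dt.date,
    end: dt.date,
    n_individuals: int,
    seed: int | np.random.Generator = 0,
) -> list[FeedingRecord]:
    """Partition per-species item counts across individuals and dates.

    Items of each species are split as evenly as possible across the
    individuals (emulating a trial in which every animal has equal access to
    each food item), with any remainder assigned to randomly chosen
    individuals; each item gets a uniform date inside ``[start, end]``.
    Records aggregate items sharing (individual, species, date); totals per
    species equal the requested counts exactly.
    """
    if end < start:
        raise ValueError(f"empty date window: {start} .. {end}")
    if n_individuals < 1:
        raise ValueError("need at least one individual")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n_days = (end - start).days + 1
    tallies: dict[tuple[str, str, dt.date], int] = {}
    for species in counts:
        c = int(counts[species])
        if c < 0:
            raise ValueError(f"negative count for {species!r}")
        per_ind = np.full(n_individuals, c // n_individuals)
        extra = rng.choice(n_individuals, c % n_individuals, replace=False)
        per_ind[extra] += 1
        for i, n_items in enumerate(per_ind):
            ind = f"individual_{i + 1}"
            for _ in range(int(n_items)):
                date = start + dt.timedelta(days=int(rng.integers(n_days)))
                key = (ind, species, date)
                tallies[key] = tallies.get(key, 0) + 1
    return [
        FeedingRecord(individual_id=ind, species=sp, date=date, count=n)
        for (ind, sp, date), n in sorted(tallies.items())
    ]


def mixture_moments(
    proportions: Sequence[float],
    sources: Sequence[SourceDistribution],
    tdf: TDFSet,
    residual_sd: Mapping[str, float],
    isotopes: Sequence[str] = DEFAULT_ISOTOPES,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and variance of consumer values under the mixing model.

    Per isotope j: mean ``sum_k p_k (mu_jk + c_j)`` and combined variance
    ``sum_k p_k^2 omega_jk^2 + sigma_j^2``.
    """
    p = np.asarray(proportions, float)
    _, mu, omega = source_arrays(sources, isotopes)
    c = np.array([tdf.mean[iso] for iso in isotopes])
    sig = np.array([float(residual_sd.get(iso, 0.0)) for iso in isotopes])
    mean = mu @ p + c * p.sum()
    var = (omega**2) @ (p**2) + sig**2
    return mean, var


def simulate_consumers(
    mean: Mapping[str, float],
    sd: Mapping[str, float],
    n: int,
    seed: int | np.random.Generator = 0,
    isotopes: Sequence[str] = DEFAULT_ISOTOPES,
    prefix: str = "consumer",
) -> ConsumerData:
    """Draw ``n`` consumers i.i.d. Normal per isotope from summary statistics.

    Used to stand in for unpublished per-individual consumer values when only
    a (mean, SD) tissue summary is available.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    m = np.array([mean[iso] for iso in isotopes])
    s = np.array([sd[iso] for iso in isotopes])
    values = rng.normal(m, s, size=(n, len(isotopes)))
    return ConsumerData(values, isotopes, [f"{prefix}_{i + 1}" for i in range(n)])


def generate_isotope_dataset(
    scenario: SyntheticScenario,
) -> tuple[ConsumerData, list[IsotopeSample]]:
    """Generate a consumer matrix and raw source samples for a scenario.

    Reproducible: the scenario seed drives independent sub-streams for the
    source samples and the consumer matrix, so changing the number of
    consumers does not perturb the source draws.
    """
    isotopes = tuple(scenario.isotopes)
    ss = np.random.SeedSequence(scenario.seed)
    src_rng, con_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    source_samples: list[IsotopeSample] = []
    for src in scenario.sources:
        for i in range(scenario.n_source_samples):
            delta = {
                iso: float(src_rng.normal(src.mean[iso], src.sd[iso]))
                for iso in isotopes
            }
            source_samples.append(
                IsotopeSample(
                    individual_id=f"{src.species}_{i + 1}",
                    species=src.species,
                    tissue=src.tissue or "muscle",
                    delta=delta,
                )
            )

    mean, var = mixture_moments(
        scenario.proportions,
        scenario.sources,
        scenario.tdf,
        scenario.residual_sd,
        isotopes,
    )
    values = con_rng.normal(mean, np.sqrt(var), size=(scenario.n_consumers, len(isotopes)))
    consumers = ConsumerData(values, isotopes)
    return consumers, source_samples


def write_feeding_csv(records: Iterable[FeedingRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "individual_id": r.individual_id,
                "species": r.species,
                "date": r.date.isoformat(),
                "count": r.count,
            }
            for r in records
        ]
    ).to_csv(path, index=False, encoding="utf-8")


def read_feeding_csv(path) -> list[FeedingRecord]:
    df = pd.read_csv(path, encoding="utf-8")
    required = {"individual_id", "species", "date", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"feeding CSV {path} missing columns: {sorted(missing)}")
    return [
        FeedingRecord(
            individual_id=str(r["individual_id"]),
            species=str(r["species"]),
            date=dt.date.fromisoformat(str(r["date"])),
            count=int(r["count"]),
        )
        for _, r in df.iterrows()
    ]
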