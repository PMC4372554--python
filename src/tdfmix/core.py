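"""Domain types and elementary isotope arithmetic.

Everything downstream of the raw mass-spectrometer ratios works in delta
notation: the per-mil (‰) deviation of a sample's heavy/light isotope ratio
from an international standard.  The types here carry per-individual isotope
values (:class:`IsotopeSample`, :class:`ConsumerData`), per-source summary
distributions (:class:`SourceDistribution`), trophic discrimination factors
(:class:`TDFSet`) and Dirichlet priors over diet proportions
(:class:`DirichletSpec`).

Isotope labels are an ordered list fixed once per analysis
(``("d13C", "d15N")`` by default); every matrix in the package uses that
order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_ISOTOPES",
    "IsotopeSample",
    "SourceDistribution",
    "ConsumerData",
    "TDFSet",
    "DirichletSpec",
    "delta_from_ratio",
    "summarize_sources",
    "source_arrays",
    "read_isotope_csv",
    "write_isotope_csv",
]

#: Default ordered isotope labels: carbon-13 and nitrogen-15 delta values.
DEFAULT_ISOTOPES: tuple[str, ...] = ("d13C", "d15N")


def delta_from_ratio(r_sample: float, r_standard: float) -> float:
    """Convert a raw isotope abundance ratio to delta notation (‰).

    ``delta = (r_sample / r_standard - 1) * 1000``, where the ratio is
    heavy/light (e.g. 13C/12C against PDB, 15N/14N against atmospheric N2).

    Raises
    ------
    ValueError
        If either ratio is not strictly positive.
    """
    if not (r_sample > 0.0) or not (r_standard > 0.0):
        raise ValueError(
            f"isotope ratios must be > 0, got r_sample={r_sample!r}, "
            f"r_standard={r_standard!r}"
        )
    return (r_sample / r_standard - 1.0) * 1000.0


def _validate_delta(delta: Mapping[str, float]) -> dict[str, float]:
    out = {}
    for k, v in delta.items():
        v = float(v)
        if not math.isfinite(v):
            raise ValueError(f"non-finite delta value for isotope {k!r}: {v}")
        out[str(k)] = v
    return out


@dataclass(frozen=True)
class IsotopeSample:
    """One tissue sample from one individual: a point in isotope space."""

    individual_id: str
    species: str
    tissue: str
    delta: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "delta", _validate_delta(self.delta))


@dataclass(frozen=True)
class SourceDistribution:
    """Per-isotope Normal summary of one prey source's tissue values.

    The mixing model treats source values as Normal(mean, sd**2) per isotope;
    ``sd`` is the among-individual standard deviation of the source tissue,
    not a standard error.
    """

    species: str
    mean: Mapping[str, float]
    sd: Mapping[str, float]
    n: int | None = None
    tissue: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", _validate_delta(self.mean))
        sd = _validate_delta(self.sd)
        for iso, v in sd.items():
            if v < 0:
                raise ValueError(f"source SD must be >= 0, got {v} for {iso!r}")
        if set(sd) != set(self.mean):
            raise ValueError("mean and sd must cover the same isotopes")
        object.__setattr__(self, "sd", sd)


class ConsumerData:
    """Consumer isotope values as an I x J matrix (consumers x isotopes)."""

    def __init__(
        self,
        values: np.ndarray,
        isotopes: Sequence[str] = DEFAULT_ISOTOPES,
        ids: Sequence[str] | None = None,
    ) -> None:
        values = np.atleast_2d(np.asarray(values, dtype=float))
        if values.ndim != 2:
            raise ValueError("consumer values must be a 2-D matrix")
        if values.shape[0] < 1 or values.shape[1] < 1:
            raise ValueError("need at least one consumer and one isotope")
        if values.shape[1] != len(isotopes):
            raise ValueError(
                f"{values.shape[1]} columns but {len(isotopes)} isotope labels"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("consumer matrix contains missing/non-finite cells")
        self.values = values
        self.isotopes = tuple(isotopes)
        if ids is None:
            ids = [f"consumer_{i + 1}" for i in range(values.shape[0])]
        if len(ids) != values.shape[0]:
            raise ValueError("ids length must match number of consumers")
        self.ids = tuple(str(i) for i in ids)

    @property
    def n_consumers(self) -> int:
        return self.values.shape[0]

    @property
    def n_isotopes(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_samples(
        cls, samples: Iterable[IsotopeSample], isotopes: Sequence[str] = DEFAULT_ISOTOPES
    ) -> "ConsumerData":
        samples = list(samples)
        rows = [[s.delta[iso] for iso in isotopes] for s in samples]
        return cls(np.array(rows, float), isotopes, [s.individual_id for s in samples])

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, isotopes: Sequence[str] = DEFAULT_ISOTOPES
    ) -> "ConsumerData":
        ids = (
            df["individual_id"].astype(str).tolist()
            if "individual_id" in df.columns
            else None
        )
        return cls(df[list(isotopes)].to_numpy(float), isotopes, ids)

    def to_dataframe(self) -> pd.DataFrame:
        out = pd.DataFrame(self.values, columns=list(self.isotopes))
        out.insert(0, "individual_id", list(self.ids))
        return out

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ConsumerData(I={self.n_consumers}, isotopes={list(self.isotopes)})"
        )


@dataclass(frozen=True)
class TDFSet:
    """Trophic discrimination factors: per-isotope mean offset and SD.

    One value per isotope, shared across sources (the convention under which
    a single experimentally derived pair like the red fox 2.6/3.4 ‰ values is
    applied to every prey species).
    """

    label: str
    mean: Mapping[str, float]
    sd: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", _validate_delta(self.mean))
        sd = _validate_delta(self.sd)
        for iso, v in sd.items():
            if v < 0:
                raise ValueError(f"TDF SD must be >= 0, got {v} for {iso!r}")
        object.__setattr__(self, "sd", sd)


class DirichletSpec:
    """A Dirichlet distribution over diet proportions of named sources."""

    def __init__(self, sources: Sequence[str], alpha: Sequence[float]) -> None:
        self.sources = tuple(str(s) for s in sources)
        alpha = np.asarray(alpha, dtype=float)
        if alpha.shape != (len(self.sources),):
            raise ValueError("alpha length must match the number of sources")
        if not np.all(np.isfinite(alpha)) or np.any(alpha <= 0):
            raise ValueError("all Dirichlet alpha entries must be finite and > 0")
        self.alpha = alpha

    @property
    def mean(self) -> np.ndarray:
        """Prior mean proportions alpha_k / sum(alpha)."""
        return self.alpha / self.alpha.sum()

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` proportion vectors, shape (n, K)."""
        return rng.dirichlet(self.alpha, size=n)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        pairs = ", ".join(f"{s}={a:g}" for s, a in zip(self.sources, self.alpha))
        return f"DirichletSpec({pairs})"

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, DirichletSpec)
            and self.sources == other.sources
            and np.array_equal(self.alpha, other.alpha)
        )


def summarize_sources(
    samples: Iterable[IsotopeSample],
    isotopes: Sequence[str] = DEFAULT_ISOTOPES,
) -> list[SourceDistribution]:
    """Summarise raw tissue samples into per-(species, tissue) distributions.

    Sample mean and sample SD (n-1 denominator) per isotope.  Groups with
    fewer than two samples cannot yield an SD and raise ``ValueError`` naming
    the group.
    """
    samples = list(samples)
    groups: dict[tuple[str, str], list[IsotopeSample]] = {}
    for s in samples:
        groups.setdefault((s.species, s.tissue), []).append(s)
    out = []
    for (species, tissue), members in groups.items():
        if len(members) < 2:
            raise ValueError(
                f"group (species={species!r}, tissue={tissue!r}) has "
                f"{len(members)} sample(s); need >= 2 to estimate an SD"
            )
        mean, sd = {}, {}
        for iso in isotopes:
            vals = np.array([m.delta[iso] for m in members], float)
            mean[iso] = float(vals.mean())
            sd[iso] = float(vals.std(ddof=1))
        out.append(
            SourceDistribution(
                species=species, tissue=tissue, mean=mean, sd=sd, n=len(members)
            )
        )
    return out


def source_arrays(
    sources: Sequence[SourceDistribution], isotopes: Sequence[str]
) -> tuple[tuple[str, ...], np.ndarray, np.ndarray]:
    """Stack source summaries into (names, mu[J, K], omega[J, K]) arrays."""
    names = tuple(s.species for s in sources)
    if len(set(names)) != len(names):
        raise ValueError("duplicate source species in source list")
    J, K = len(isotopes), len(sources)
    mu = np.empty((J, K))
    omega = np.empty((J, K))
    for k, s in enumerate(sources):
        for j, iso in enumerate(isotopes):
            try:
                mu[j, k] = s.mean[iso]
                omega[j, k] = s.sd[iso]
            except KeyError:
                raise KeyError(
                    f"source {s.species!r} has no value for isotope {iso!r}"
                ) from None
    return names, mu, omega


def read_isotope_csv(
    path, isotopes: Sequence[str] = DEFAULT_ISOTOPES
) -> list[IsotopeSample]:
    """Read an isotope table (individual_id, species, tissue, d13C, d15N)."""
    df = pd.read_csv(path, encoding="utf-8")
    required = {"individual_id", "species", "tissue", *isotopes}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"isotope CSV {path} missing columns: {sorted(missing)}")
    return [
        IsotopeSample(
            individual_id=str(row["individual_id"]),
            species=str(row["species"]),
            tissue=str(row["tissue"]),
            delta={iso: float(row[iso]) for iso in isotopes},
        )
        for _, row in df.iterrows()
    ]


def write_isotope_csv(
    samples: Iterable[IsotopeSample], path, isotopes: Sequence[str] = DEFAULT_ISOTOPES
) -> None:
    rows = [
        {
            "individual_id": s.individual_id,
            "species": s.species,
            "tissue": s.tissue,
            **{iso: s.delta[iso] for iso in isotopes},
        }
        for s in samples
    ]
    pd.DataFrame(rows).to_csv(path, index=False, encoding="utf-8")
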