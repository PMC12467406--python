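"""Core containers shared across the analysis stages.

Genotypes are stored as alternate-allele dosage (0, 1, 2) in a compact
``int8`` matrix with ``-1`` marking missing calls; half-called diploid
genotypes are treated as missing.  Sample metadata travels as a pandas
DataFrame with one row per individual (id, population, patch, coordinates,
DBH, age class).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

#: metadata columns required by every stage
META_COLUMNS = ("id", "population", "patch", "dbh")


class ConfigurationError(ValueError):
    """Raised when a simulation or pipeline configuration is invalid."""


class InputError(ValueError):
    """Raised when user-supplied data violate a precondition."""


@dataclass(frozen=True)
class GeoSample:
    """One georeferenced individual.

    Coordinates are either planar metres (``x``/``y``) or decimal degrees
    (``lon``/``lat``); which convention applies is carried by the metadata
    frame, not the sample itself.
    """

    id: str
    population: str
    patch: str
    x: float
    y: float
    dbh: float
    age_class: str = ""


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic loci dosage matrix.

    Parameters
    ----------
    samples : list of str
        Ordered sample identifiers (rows).
    loci : list of str
        Ordered locus identifiers (columns).
    calls : ndarray of int8, shape (n_samples, n_loci)
        Alternate-allele dosage; ``-1`` is missing.
    site_info : DataFrame or None
        Optional per-locus annotations (FS, MQ, QD, ReadPosRankSum,
        MQRankSum, HaplotypeScore, ...), indexed like ``loci``.
    """

    samples: list[str]
    loci: list[str]
    calls: np.ndarray
    site_info: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.loci)):
            raise InputError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        bad = ~np.isin(self.calls, (MISSING, 0, 1, 2))
        if bad.any():
            raise InputError("genotype codes must be in {-1, 0, 1, 2}")
        if self.site_info is not None and len(self.site_info) != len(self.loci):
            raise InputError("site_info length does not match loci")

    # -- basic shape ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    # -- derived quantities ----------------------------------------------
    def allele_freqs(self) -> np.ndarray:
        """Alternate-allele frequency per locus over non-missing calls.

        Loci with no calls at all get ``nan``.
        """
        calls = self.calls
        obs = calls != MISSING
        n = obs.sum(axis=0).astype(float)
        alt = np.where(obs, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, alt / (2.0 * n), np.nan)

    # -- subsetting -------------------------------------------------------
    def take_samples(self, index: np.ndarray | list[int]) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            [self.samples[i] for i in index],
            list(self.loci),
            self.calls[index],
            self.site_info,
        )

    def take_loci(self, index: np.ndarray | list[int]) -> "GenotypeMatrix":
        index = np.asarray(index)
        info = self.site_info.iloc[index].reset_index(drop=True) if self.site_info is not None else None
        return GenotypeMatrix(
            list(self.samples),
            [self.loci[i] for i in index],
            self.calls[:, index],
            info,
        )

    def select_samples(self, ids: list[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise InputError(f"samples not in genotype matrix: {missing}")
        return self.take_samples([pos[s] for s in ids])


@dataclass
class SimulatedDataset:
    """Output of the forward simulator: genotypes + metadata + truth.

    ``pedigree`` has columns ``offspring mother father seed_dist_m
    pollen_dist_m``; every distance equals the Euclidean distance between
    the recorded planar coordinates of the individuals involved.
    """

    metadata: pd.DataFrame
    genotypes: GenotypeMatrix
    pedigree: pd.DataFrame
    true_calls: np.ndarray = field(repr=False, default=None)

    @property
    def samples(self) -> list[GeoSample]:
        return [
            GeoSample(r.id, r.population, r.patch, r.x, r.y, r.dbh, r.age_class)
            for r in self.metadata.itertuples(index=False)
        ]
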