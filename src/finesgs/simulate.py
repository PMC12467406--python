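"""Spatially explicit forward simulator of patchy tree populations.

The simulator produces the sampling universe the estimators assume: a few
clustered patches of georeferenced trees spanning three DBH age classes,
with restricted seed and pollen movement, partial selfing, and an explicit
observation layer (per-allele genotyping error and missingness).  Because
the true pedigree and the true dispersal events are recorded, every
downstream estimator can be validated by parameter recovery.

Model
-----
* Founders are placed uniformly at random inside each patch rectangle and
  receive Hardy-Weinberg genotypes from per-locus founder allele
  frequencies (default: uniform on [0.05, 0.5]).
* Each non-overlapping generation, mothers are drawn uniformly from all
  previously created individuals (the reproductive adults).  The father is
  the mother herself with probability ``selfing_rate``; otherwise he is
  drawn among the other adults with weight proportional to an isotropic
  bivariate-Gaussian pollen kernel of scale ``sigma_pollen`` evaluated at
  the mother-candidate distance.
* The offspring position is the mother's position plus an isotropic
  bivariate-Gaussian displacement of scale ``sigma_seed`` per axis,
  resampled until it falls inside the mother's patch rectangle (this keeps
  patches from bleeding into each other and avoids boundary pile-up).
* Alleles are transmitted by Mendelian sampling.  The observed genotype of
  every individual (founders included) is its true genotype with each
  allele flipped independently with probability ``genotyping_error`` and
  the whole call masked with probability ``missing_rate``.
* Founders are 'mature', intermediate generations 'adult', the final
  generation 'sapling'; DBH values are synthesized per class so that the
  DBH -> age-class rule round-trips.

Under an isotropic bivariate Gaussian of axial scale sigma the planar
displacement length is Rayleigh(sigma), so the realized mean dispersal
distance should approach ``sigma * sqrt(pi / 2)`` — a closed-form check
used by the test-suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .datatypes import MISSING, ConfigurationError, GenotypeMatrix, InputError, SimulatedDataset

logger = logging.getLogger(__name__)

_DBH_RANGES = {"sapling": (1.0, 7.5), "adult": (7.5, 22.5), "mature": (22.5, 60.0)}
_MAX_RESAMPLE = 10_000


@dataclass
class Landscape:
    """Rectangular patches of identical extent laid out on given offsets."""

    patch_width: float = 200.0
    patch_height: float = 200.0
    offsets: tuple[tuple[float, float], ...] = ((0.0, 0.0), (1000.0, 0.0), (2000.0, 0.0))

    def rect(self, patch: int) -> tuple[float, float, float, float]:
        ox, oy = self.offsets[patch]
        return ox, oy, ox + self.patch_width, oy + self.patch_height


@dataclass
class SimConfig:
    """Simulation parameters; defaults emulate one surveyed population.

    The defaults mirror the sampling design the estimators target: three
    patches of a single population (patches ~200 m across, >= 1 km apart),
    on the order of a hundred trees in three age classes, restricted
    dispersal of tens of metres, low selfing, and 1% per-allele
    genotyping error.
    """

    n_founders: int = 36
    n_patches: int = 3
    landscape: Landscape | None = None
    sigma_seed: float = 25.0
    sigma_pollen: float = 35.0
    selfing_rate: float = 0.1
    n_loci: int = 200
    founder_maf: tuple[float, float] = (0.05, 0.5)
    n_generations: int = 2
    offspring_per_generation: int = 36
    genotyping_error: float = 0.01
    missing_rate: float = 0.05
    population: str = "SIM"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.landscape is None:
            spacing = 1000.0
            self.landscape = Landscape(
                offsets=tuple((i * spacing, 0.0) for i in range(self.n_patches))
            )
        problems = self.validate()
        if problems:
            raise ConfigurationError("; ".join(problems))

    def validate(self) -> list[str]:
        problems = []
        for name in ("n_founders", "n_patches", "n_loci", "offspring_per_generation"):
            if getattr(self, name) < 1:
                problems.append(f"{name} must be >= 1")
        if self.n_generations < 0:
            problems.append("n_generations must be >= 0")
        if self.sigma_seed <= 0 or self.sigma_pollen <= 0:
            problems.append("sigma_seed and sigma_pollen must be > 0")
        for name in ("selfing_rate", "genotyping_error", "missing_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                problems.append(f"{name} must be in [0, 1]")
        lo, hi = self.founder_maf
        if not (0.0 < lo <= hi <= 0.5):
            problems.append("founder_maf must satisfy 0 < low <= high <= 0.5")
        if len(self.landscape.offsets) < self.n_patches:
            problems.append("landscape offsets shorter than n_patches")
        return problems


def _observe(true_calls: np.ndarray, error: float, missing: float, rng: np.random.Generator) -> np.ndarray:
    """Apply the observation layer: per-allele flips then missingness."""
    g = true_calls.astype(np.int8)
    if error > 0:
        # dosage g has g alt alleles and 2-g ref alleles, each flipping
        # independently with probability `error`
        kept_alt = rng.binomial(g, 1.0 - error)
        gained_alt = rng.binomial(2 - g, error)
        g = (kept_alt + gained_alt).astype(np.int8)
    if missing > 0:
        mask = rng.random(g.shape) < missing
        g = np.where(mask, MISSING, g).astype(np.int8)
    return g


def simulate_population(config: SimConfig) -> SimulatedDataset:
    """Run the forward simulation and return genotypes, metadata and truth.

    Identical configurations (including ``rng_seed``) yield identical
    datasets.
    """
    rng = np.random.default_rng(config.rng_seed)
    ls = config.landscape
    n_loci = config.n_loci

    freqs = rng.uniform(config.founder_maf[0], config.founder_maf[1], size=n_loci)

    # --- founders --------------------------------------------------------
    patch_of: list[int] = [i % config.n_patches for i in range(config.n_founders)]
    xs, ys = [], []
    for p in patch_of:
        x0, y0, x1, y1 = ls.rect(p)
        xs.append(rng.uniform(x0, x1))
        ys.append(rng.uniform(y0, y1))
    true = rng.binomial(2, freqs, size=(config.n_founders, n_loci)).astype(np.int8)
    generation = [0] * config.n_founders

    pedigree_rows: list[tuple[int, int, int, float, float]] = []

    # --- generations ------------------------------------------------------
    for g in range(1, config.n_generations + 1):
        n_adults = len(xs)
        adult_xy = np.column_stack([xs, ys])
        adult_true = true
        for _ in range(config.offspring_per_generation):
            mother = int(rng.integers(n_adults))
            if n_adults > 1 and rng.random() >= config.selfing_rate:
                d2 = np.sum((adult_xy - adult_xy[mother]) ** 2, axis=1)
                w = np.exp(-(d2 - d2.min()) / (2.0 * config.sigma_pollen**2))
                w[mother] = 0.0
                total = w.sum()
                if total <= 0:  # pathological numeric underflow; uniform fallback
                    w = np.ones(n_adults)
                    w[mother] = 0.0
                    total = w.sum()
                father = int(rng.choice(n_adults, p=w / total))
            else:
                father = mother
            mpatch = patch_of[mother]
            x0, y0, x1, y1 = ls.rect(mpatch)
            mx, my = adult_xy[mother]
            for _ in range(_MAX_RESAMPLE):
                dx, dy = rng.normal(0.0, config.sigma_seed, size=2)
                ox, oy = mx + dx, my + dy
                if x0 <= ox <= x1 and y0 <= oy <= y1:
                    break
            else:  # sigma far larger than the patch: clamp (logged)
                logger.warning("seed displacement resampling exhausted; clamping to patch")
                ox = float(np.clip(mx + dx, x0, x1))
                oy = float(np.clip(my + dy, y0, y1))
            child_true = (
                rng.binomial(1, adult_true[mother] / 2.0)
                + rng.binomial(1, adult_true[father] / 2.0)
            ).astype(np.int8)
            seed_d = float(np.hypot(ox - mx, oy - my))
            pollen_d = float(np.hypot(*(adult_xy[mother] - adult_xy[father])))
            idx = len(xs)
            pedigree_rows.append((idx, mother, father, seed_d, pollen_d))
            xs.append(float(ox))
            ys.append(float(oy))
            patch_of.append(mpatch)
            generation.append(g)
            true = np.vstack([true, child_true[None, :]])

    n = len(xs)
    ids = [f"t{i:04d}" for i in range(n)]
    last = config.n_generations
    age_class = [
        "mature" if g == 0 else ("sapling" if g == last else "adult") for g in generation
    ]
    dbh = np.array([rng.uniform(*_DBH_RANGES[a]) for a in age_class])

    observed = _observe(true, config.genotyping_error, config.missing_rate, rng)

    meta = pd.DataFrame(
        {
            "id": ids,
            "population": config.population,
            "patch": [f"P{p + 1}" for p in patch_of],
            "x": xs,
            "y": ys,
            "dbh": np.round(dbh, 2),
            "age_class": age_class,
            "generation": generation,
        }
    )
    loci = [f"L{j:05d}" for j in range(n_loci)]
    info = pd.DataFrame(
        {
            "FS": 10.0,
            "MQ": 60.0,
            "QD": 20.0,
            "ReadPosRankSum": 0.0,
            "MQRankSum": 0.0,
            "HaplotypeScore": 5.0,
        },
        index=range(n_loci),
    )
    gm = GenotypeMatrix(ids, loci, observed, info)
    ped = pd.DataFrame(
        [
            (ids[o], ids[m], ids[f], sd, pd_) for o, m, f, sd, pd_ in pedigree_rows
        ],
        columns=["offspring", "mother", "father", "seed_dist_m", "pollen_dist_m"],
    )
    return SimulatedDataset(metadata=meta, genotypes=gm, pedigree=ped, true_calls=true)


# ---------------------------------------------------------------------------
# Mendelian consistency
# ---------------------------------------------------------------------------

def mendelian_check(
    offspring: np.ndarray, mother: np.ndarray, father: np.ndarray
) -> np.ndarray:
    """Per-locus Mendelian consistency of a trio of dosage vectors.

    Returns an int8 array: ``1`` consistent, ``0`` inconsistent, ``-1``
    skipped because at least one member is missing at that locus.
    """
    o = np.asarray(offspring, dtype=np.int8)
    m = np.asarray(mother, dtype=np.int8)
    f = np.asarray(father, dtype=np.int8)
    if not (o.shape == m.shape == f.shape):
        raise InputError("trio genotype vectors must share the same loci")
    # transmissible allele sets by dosage: 0 -> {0}, 1 -> {0,1}, 2 -> {1}
    lo = (m > 1).astype(np.int8) + (f > 1).astype(np.int8)  # least alt dosage
    hi = (m >= 1).astype(np.int8) + (f >= 1).astype(np.int8)  # most alt dosage
    consistent = ((o >= lo) & (o <= hi)).astype(np.int8)
    skipped = (o == MISSING) | (m == MISSING) | (f == MISSING)
    consistent[skipped] = -1
    return consistent


# ---------------------------------------------------------------------------
# Writing a dataset to standard text formats
# ---------------------------------------------------------------------------

_INFO_FIELDS = (
    ("FS", "Float", "Phred-scaled Fisher strand-bias p-value"),
    ("MQ", "Float", "RMS mapping quality"),
    ("QD", "Float", "Quality by depth"),
    ("ReadPosRankSum", "Float", "Read position rank-sum"),
    ("MQRankSum", "Float", "Mapping-quality rank-sum"),
    ("HaplotypeScore", "Float", "Haplotype score"),
)

_GT_BY_DOSAGE = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}


def write_dataset(dataset: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write VCF v4.2, metadata TSV and pedigree-truth TSV.

    Round-trips losslessly through :func:`finesgs.io.read_vcf`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "genotypes.vcf",
        "metadata": out / "metadata.tsv",
        "pedigree": out / "pedigree.tsv",
    }

    gm = dataset.genotypes
    header = pysam.VariantHeader()
    header.contigs.add("1", length=max(gm.n_loci, 1) + 1)
    for name, typ, desc in _INFO_FIELDS:
        header.info.add(name, 1, typ, desc)
    header.formats.add("GT", 1, "String", "Genotype")
    for s in gm.samples:
        header.add_sample(s)

    with pysam.VariantFile(str(paths["vcf"]), "w", header=header) as vcf:
        info = gm.site_info
        for j, locus in enumerate(gm.loci):
            rec = vcf.new_record(contig="1", start=j, alleles=("A", "T"), id=locus)
            rec.qual = 100.0
            if info is not None:
                for name, _, _ in _INFO_FIELDS:
                    if name in info.columns:
                        rec.info[name] = float(info[name].iloc[j])
            for i, s in enumerate(gm.samples):
                rec.samples[s]["GT"] = _GT_BY_DOSAGE[int(gm.calls[i, j])]
            vcf.write(rec)

    meta = dataset.metadata[["id", "population", "patch", "x", "y", "dbh"]]
    meta.to_csv(paths["metadata"], sep="\t", index=False)
    dataset.pedigree.to_csv(paths["pedigree"], sep="\t", index=False)
    return paths
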