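"""VCF/metadata input, site filtering, diversity statistics and the
patch-level HO-vs-HE t-test.

Only biallelic SNPs are retained on read; genotypes become alternate-allele
dosages.  Hard filtering applies the usual GATK-style site annotations
(FS, HaplotypeScore, MQ, QD, ReadPosRankSum, MQRankSum); annotations that
are absent from the VCF are skipped with a warning rather than failing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF
from scipy import stats

from .datatypes import MISSING, GenotypeMatrix, InputError

logger = logging.getLogger(__name__)

_ANNOTATIONS = ("FS", "MQ", "QD", "ReadPosRankSum", "MQRankSum", "HaplotypeScore")

# cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
_GT_TYPE_TO_DOSAGE = np.array([0, 1, MISSING, 2], dtype=np.int8)


class SampleMismatchError(InputError):
    """A VCF sample is absent from the metadata table."""

    def __init__(self, missing_ids: list[str]):
        self.missing_ids = list(missing_ids)
        super().__init__(f"VCF samples absent from metadata: {self.missing_ids}")


@dataclass(frozen=True)
class FilterThresholds:
    """GATK-style hard-filter thresholds plus the MAF cut-off.

    A site is retained iff FS <= fs_max, HaplotypeScore <=
    haplotype_score_max, MQ >= mq_min, QD >= qd_min, ReadPosRankSum >=
    read_pos_rank_sum_min, and MQRankSum > mq_rank_sum_min (note the
    strict inequality on MQRankSum).
    """

    fs_max: float = 60.0
    haplotype_score_max: float = 13.0
    mq_min: float = 40.0
    qd_min: float = 2.0
    read_pos_rank_sum_min: float = -8.0
    mq_rank_sum_min: float = -12.5
    maf_min: float = 0.05


def read_metadata(metadata_path: str | Path) -> tuple[pd.DataFrame, str]:
    """Read the sample metadata TSV.

    Accepts either planar ``x``/``y`` (metres) or geographic ``lon``/``lat``
    (decimal degrees) coordinate columns; returns the frame with coordinate
    columns normalized to ``x``/``y`` plus the coordinate mode
    (``'planar'`` or ``'geographic'``).  An ``age_class`` column is derived
    from DBH if not already present.
    """
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"id": str})
    required = {"id", "population", "patch", "dbh"}
    if not required.issubset(meta.columns):
        raise InputError(f"metadata missing columns: {sorted(required - set(meta.columns))}")
    if {"x", "y"}.issubset(meta.columns):
        mode = "planar"
    elif {"lon", "lat"}.issubset(meta.columns):
        meta = meta.rename(columns={"lon": "x", "lat": "y"})
        mode = "geographic"
    else:
        raise InputError("metadata needs either x/y or lon/lat columns")
    if "age_class" not in meta.columns:
        meta["age_class"] = classify_age(meta["dbh"].to_numpy())
    return meta, mode


def read_vcf(
    vcf_path: str | Path, metadata_path: str | Path
) -> tuple[GenotypeMatrix, pd.DataFrame, str]:
    """Read a VCF plus its metadata into a genotype matrix.

    Multiallelic and non-SNP records are dropped (counted in the log).
    Returns ``(genotypes, metadata, coord_mode)`` with metadata reordered
    to match the VCF sample order.
    """
    meta, mode = read_metadata(metadata_path)
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    known = set(meta["id"])
    absent = [s for s in samples if s not in known]
    if absent:
        raise SampleMismatchError(absent)

    rows: list[np.ndarray] = []
    loci: list[str] = []
    info_rows: list[dict] = []
    dropped = 0
    for idx, var in enumerate(vcf):
        if len(var.ALT) != 1 or not var.is_snp:
            dropped += 1
            continue
        loci.append(var.ID or f"{var.CHROM}:{var.POS}")
        rows.append(_GT_TYPE_TO_DOSAGE[var.gt_types])
        info_rows.append({k: var.INFO.get(k) for k in _ANNOTATIONS})
    if dropped:
        logger.info("read_vcf: dropped %d multiallelic/non-SNP records", dropped)

    calls = (
        np.array(rows, dtype=np.int8).T
        if rows
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    info = pd.DataFrame(info_rows) if info_rows else None
    if info is not None and info.isna().all().all():
        info = None
    gm = GenotypeMatrix(samples, loci, calls, info)
    meta = meta.set_index("id").loc[samples].reset_index()
    if meta["age_class"].isna().any():
        meta["age_class"] = classify_age(meta["dbh"].to_numpy())
    return gm, meta, mode


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def hard_filter(gm: GenotypeMatrix, thr: FilterThresholds | None = None) -> GenotypeMatrix:
    """Apply the site-annotation hard filters; returns the retained loci.

    Annotation columns absent from ``gm.site_info`` (or an absent
    ``site_info`` altogether) skip their criterion with a warning.
    Idempotent: filtering an already-filtered matrix changes nothing.
    """
    thr = thr or FilterThresholds()
    if gm.site_info is None:
        logger.warning("hard_filter: no site annotations; all loci retained")
        return gm
    info = gm.site_info
    keep = np.ones(gm.n_loci, dtype=bool)
    rules = (
        ("FS", lambda v: v <= thr.fs_max),
        ("HaplotypeScore", lambda v: v <= thr.haplotype_score_max),
        ("MQ", lambda v: v >= thr.mq_min),
        ("QD", lambda v: v >= thr.qd_min),
        ("ReadPosRankSum", lambda v: v >= thr.read_pos_rank_sum_min),
        ("MQRankSum", lambda v: v > thr.mq_rank_sum_min),  # strict, as specified
    )
    for name, rule in rules:
        if name not in info.columns or info[name].isna().all():
            logger.warning("hard_filter: annotation %s absent; criterion skipped", name)
            continue
        vals = info[name].to_numpy(dtype=float)
        ok = np.where(np.isnan(vals), True, rule(np.nan_to_num(vals)))
        keep &= ok.astype(bool)
    if not keep.all():
        logger.info("hard_filter: removed %d of %d loci", int((~keep).sum()), gm.n_loci)
    return gm.take_loci(np.flatnonzero(keep))


def maf_filter(gm: GenotypeMatrix, maf_min: float = 0.05) -> GenotypeMatrix:
    """Retain loci whose minor allele frequency strictly exceeds ``maf_min``.

    Frequencies are computed over the non-missing calls of the matrix at
    hand (the analysis group).  Loci with all calls missing are dropped.
    """
    p = gm.allele_freqs()
    with np.errstate(invalid="ignore"):
        maf = np.minimum(p, 1.0 - p)
    keep = maf > maf_min
    keep &= ~np.isnan(p)
    n_all_missing = int(np.isnan(p).sum())
    if n_all_missing:
        logger.info("maf_filter: dropped %d loci with no calls", n_all_missing)
    return gm.take_loci(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# Age classes
# ---------------------------------------------------------------------------

def classify_age(dbh):
    """DBH (cm) -> age class: sapling < 7.5 <= adult < 22.5 <= mature."""
    arr = np.asarray(dbh, dtype=float)
    if np.any(arr <= 0) or np.any(~np.isfinite(arr)):
        raise InputError("dbh must be positive and finite")
    out = np.where(arr < 7.5, "sapling", np.where(arr < 22.5, "adult", "mature"))
    if np.isscalar(dbh) or arr.ndim == 0:
        return str(out)
    return out.astype(object)


# ---------------------------------------------------------------------------
# Diversity statistics
# ---------------------------------------------------------------------------

def _per_locus_stats(calls: np.ndarray):
    """Per-locus n, HO, unbiased HE over non-missing calls."""
    obs = calls != MISSING
    n = obs.sum(axis=0).astype(float)
    alt = np.where(obs, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2.0 * n), np.nan)
        ho = np.where(n > 0, np.where(obs, calls == 1, False).sum(axis=0) / n, np.nan)
        # Nei's unbiased expected heterozygosity: 2n/(2n-1) * (1 - p^2 - q^2)
        he = np.where(n > 0, (2 * n / (2 * n - 1)) * (1 - p**2 - (1 - p) ** 2), np.nan)
    return n, p, ho, he


def diversity(gm: GenotypeMatrix, meta: pd.DataFrame, group: str = "patch") -> pd.DataFrame:
    """Per-group diversity table: num_indv, HO, HE, Fis.

    For each group the per-locus observed heterozygosity ``HO_l``,
    unbiased expected heterozygosity ``HE_l = 2n/(2n-1) (1 - p^2 - q^2)``
    and ``Fis_l = 1 - HO_l/HE_l`` are computed from that group's own
    calls; group values are unweighted means over loci polymorphic within
    the group.  ``num_indv`` is the mean number of genotyped individuals
    per locus.  Groups where every locus is monomorphic report HO = HE = 0
    and missing Fis.
    """
    if group not in meta.columns:
        raise InputError(f"grouping column {group!r} not in metadata")
    out = []
    for name, sub in meta.groupby(group, sort=True):
        ids = sub["id"].tolist()
        if len(ids) < 2:
            logger.warning("diversity: group %s has < 2 individuals; skipped", name)
            continue
        sub_gm = gm.select_samples(ids)
        n, p, ho, he = _per_locus_stats(sub_gm.calls)
        poly = (n > 0) & (p > 0) & (p < 1)
        num_indv = float(n[n > 0].mean()) if (n > 0).any() else 0.0
        if not poly.any():
            logger.warning("diversity: group %s is monomorphic at every locus", name)
            out.append(
                {"population": sub["population"].iloc[0], group: name,
                 "num_indv": num_indv, "ho": 0.0, "he": 0.0, "fis": np.nan,
                 "n_samples": len(ids)}
            )
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            fis_l = np.where(he[poly] > 0, 1.0 - ho[poly] / he[poly], np.nan)
        out.append(
            {
                "population": sub["population"].iloc[0],
                group: name,
                "num_indv": num_indv,
                "ho": float(ho[poly].mean()),
                "he": float(he[poly].mean()),
                "fis": float(np.nanmean(fis_l)),
                "n_samples": len(ids),
            }
        )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# HO vs HE t-test
# ---------------------------------------------------------------------------

class DegenerateVarianceError(InputError):
    """Both groups have zero pooled variance; t is undefined."""


@dataclass(frozen=True)
class TTestResult:
    mean_difference: float  # mean(HO) - mean(HE)
    t_value: float
    df: int
    p_value: float
    significance: str


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def ho_he_ttest(ho_values, he_values) -> TTestResult:
    """Pooled-variance two-sample t-test of HO vs HE across patches."""
    ho = np.asarray(ho_values, dtype=float)
    he = np.asarray(he_values, dtype=float)
    if ho.size < 2 or he.size < 2:
        raise InputError("need >= 2 values per group")
    if np.allclose(ho, ho.mean(), rtol=0, atol=1e-12) and np.allclose(
        he, he.mean(), rtol=0, atol=1e-12
    ):
        raise DegenerateVarianceError("zero pooled variance")
    t, p = stats.ttest_ind(ho, he, equal_var=True)
    df = ho.size + he.size - 2
    return TTestResult(
        mean_difference=float(ho.mean() - he.mean()),
        t_value=float(t),
        df=int(df),
        p_value=float(p),
        significance=_stars(float(p)),
    )
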