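"""Seed/pollen dispersal summaries and the cubic ln-distance curve.

Direct estimation summarizes parentage-derived dispersal events per patch
(mean and maximum seed and pollen distance) and combines them into the
effective gene-dispersal distance under the axial variance decomposition

    sigma_g^2 = sigma_seed^2 + sigma_pollen^2 / 2,

reflecting that a pollen grain moves only a haploid genome.  Population
rows are unweighted arithmetic means over the patches with data.

Indirect estimation fits the correlogram with a cubic in ln distance,

    F(r) = a + b ln r + c ln^2 r + d ln^3 r,

whose real roots inside the spanned distance range, together with the
interpolated correlogram x-intercept, bound the effective gene-dispersal
distance.  The companion curvature statistic is reported in two forms:
the literal K = 2c + 6 ln(r1) and the second-derivative form
K = 2c + 6 d ln(r1) (r1 = midpoint of the first distance class); the
literal form omits the cubic coefficient, so both are exposed and neither
is interpreted further.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datatypes import InputError

logger = logging.getLogger(__name__)


def effective_gene_dispersal(seed_mean: float, pollen_mean: float) -> float:
    """Combined gene-dispersal distance sqrt(s^2 + p^2 / 2), metres."""
    if seed_mean < 0 or pollen_mean < 0:
        raise InputError("dispersal distances must be >= 0")
    return float(np.sqrt(seed_mean**2 + pollen_mean**2 / 2.0))


def direct_summary(
    events: pd.DataFrame, patch_to_population: dict[str, str] | None = None
) -> pd.DataFrame:
    """Per-patch dispersal summary plus a per-population means row.

    ``events`` needs columns ``kind`` ('seed'/'pollen'), ``distance`` and
    ``patch``.  Patches without events appear only implicitly (their rows
    are absent, mirroring blank table rows); means rows average the
    patch-level values over patches with data.
    """
    if events.empty:
        return pd.DataFrame(
            columns=[
                "population", "patch", "seed_max", "seed_mean",
                "pollen_max", "pollen_mean", "gene_effective",
            ]
        )
    rows = []
    for patch, sub in events.groupby("patch", sort=True):
        seed = sub.loc[sub["kind"] == "seed", "distance"]
        pollen = sub.loc[sub["kind"] == "pollen", "distance"]
        if seed.empty and pollen.empty:
            continue
        pop = patch_to_population.get(patch, "") if patch_to_population else ""
        row = {
            "population": pop,
            "patch": patch,
            "seed_max": float(seed.max()) if not seed.empty else np.nan,
            "seed_mean": float(seed.mean()) if not seed.empty else np.nan,
            "pollen_max": float(pollen.max()) if not pollen.empty else np.nan,
            "pollen_mean": float(pollen.mean()) if not pollen.empty else np.nan,
        }
        if not seed.empty and not pollen.empty:
            row["gene_effective"] = effective_gene_dispersal(row["seed_mean"], row["pollen_mean"])
        else:
            row["gene_effective"] = np.nan
        rows.append(row)
    table = pd.DataFrame(rows)
    means = []
    for pop, sub in table.groupby("population", sort=True):
        means.append(
            {
                "population": pop,
                "patch": "means",
                "seed_max": np.nan,
                "seed_mean": float(sub["seed_mean"].mean()),
                "pollen_max": np.nan,
                "pollen_mean": float(sub["pollen_mean"].mean()),
                # population value = arithmetic mean of the patch values,
                # not the combination rule applied to the means
                "gene_effective": float(sub["gene_effective"].mean()),
            }
        )
    return pd.concat([table, pd.DataFrame(means)], ignore_index=True)


@dataclass
class DispersalCurveFit:
    a: float
    b: float
    c: float
    d: float
    r1: float
    k_literal: float       # 2c + 6 ln(r1), as conventionally printed
    k_curvature: float     # 2c + 6 d ln(r1), the second-derivative form
    roots: tuple[float, ...]  # metres, within the fitted distance range
    residual_norm: float


class DispersalCurve(BaseEstimator):
    """Least-squares cubic in ln(distance) fitted to a correlogram.

    ``fit(midpoints, r)`` needs >= 4 classes with finite r.  Fitted
    attributes: ``coef_`` (a, b, c, d), ``roots_`` (metres, restricted to
    the first..last midpoint), ``k_literal_``, ``k_curvature_``,
    ``r1_`` and ``residual_norm_``.
    """

    def fit(self, midpoints, r_values):
        m = np.asarray(midpoints, dtype=float)
        r = np.asarray(r_values, dtype=float)
        ok = np.isfinite(r) & np.isfinite(m) & (m > 0)
        m, r = m[ok], r[ok]
        if m.size < 4:
            raise InputError("cubic fit needs >= 4 classes with finite r")
        u = np.log(m)
        X = np.vander(u, 4, increasing=True)  # 1, u, u^2, u^3
        if np.linalg.matrix_rank(X) < 4:
            raise InputError("collinear design: distance classes too degenerate")
        coef, res, *_ = np.linalg.lstsq(X, r, rcond=None)
        a, b, c, d = (float(v) for v in coef)
        fitted = X @ coef
        self.coef_ = (a, b, c, d)
        self.r1_ = float(m[0])
        self.residual_norm_ = float(np.linalg.norm(r - fitted))
        self.k_literal_ = float(2 * c + 6 * np.log(self.r1_))
        self.k_curvature_ = float(2 * c + 6 * d * np.log(self.r1_))
        self.roots_ = self._real_roots(u.min(), u.max())
        return self

    def _real_roots(self, u_min: float, u_max: float) -> tuple[float, ...]:
        a, b, c, d = self.coef_
        poly = np.array([d, c, b, a])
        nz = np.flatnonzero(np.abs(poly) > 1e-14)
        if nz.size == 0:
            return ()
        roots = np.roots(poly[nz[0]:])
        real = roots[np.abs(roots.imag) < 1e-9].real
        inside = real[(real >= u_min - 1e-12) & (real <= u_max + 1e-12)]
        return tuple(float(np.exp(v)) for v in np.sort(inside))

    def predict(self, midpoints) -> np.ndarray:
        m = np.asarray(midpoints, dtype=float)
        u = np.log(m)
        a, b, c, d = self.coef_
        return a + b * u + c * u**2 + d * u**3


def fit_dispersal_curve(class_midpoints, r_values) -> DispersalCurveFit:
    """Functional wrapper over :class:`DispersalCurve`."""
    est = DispersalCurve().fit(class_midpoints, r_values)
    a, b, c, d = est.coef_
    return DispersalCurveFit(
        a=a, b=b, c=c, d=d,
        r1=est.r1_,
        k_literal=est.k_literal_,
        k_curvature=est.k_curvature_,
        roots=est.roots_,
        residual_norm=est.residual_norm_,
    )


@dataclass
class IndirectRange:
    """Effective gene-dispersal interval from the indirect (SGS) route."""

    min_m: float | None
    max_m: float | None
    collapsed: bool      # only one of {intercept, cubic root} existed
    random_variation: bool  # neither existed: spatially random patch


def indirect_summary(
    intercept: float | None, cubic_roots: tuple[float, ...] | None
) -> IndirectRange:
    """Bound the dispersal extent by the correlogram x-intercept and the
    first cubic-fit root; collapses to a single flagged value when only
    one exists, and labels the patch spatially random when neither does.
    """
    root = cubic_roots[0] if cubic_roots else None
    values = [v for v in (intercept, root) if v is not None]
    if not values:
        return IndirectRange(None, None, collapsed=False, random_variation=True)
    if len(values) == 1:
        return IndirectRange(values[0], values[0], collapsed=True, random_variation=False)
    return IndirectRange(min(values), max(values), collapsed=False, random_variation=False)
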