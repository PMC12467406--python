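"""Multilocus spatial autocorrelation (Smouse-Peakall) and its x-intercept.

For codominant biallelic data the squared genotypic distance between two
individuals is the dosage difference squared summed over loci (0 for
identical genotypes, 4 for opposite homozygotes per locus).  Pairs with
missing calls use their shared loci, rescaled to the full locus count.
The squared-distance matrix is double-centred (Gower) into a covariance
matrix C, and the autocorrelation for distance class h is

    r(h) = sum_{pairs (i,j) in h} 2 c_ij / sum_{pairs (i,j) in h} (c_ii + c_jj),

which is bounded in [-1, 1] whenever C is positive semi-definite (always
true for complete data; values are clipped otherwise).  Significance uses
a location-permutation envelope; per-class standard errors come from
bootstrapping pairs within the class.  The x-intercept — the distance at
which the correlogram first crosses zero, read as the extent of positive
genetic structure and hence the effective gene-dispersal neighbourhood —
is located by linear interpolation between class midpoints.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils import check_random_state

from .datatypes import MISSING, GenotypeMatrix, InputError
from .distance import DistanceClassSpec, pairwise_distance
from .kinship import _as_calls, _canonical_order

logger = logging.getLogger(__name__)


def genotypic_distance_squared(X) -> np.ndarray:
    """Pairwise squared genotypic distance (Smouse-Peakall, codominant).

    Missing-data pairs are rescaled by ``L / L_shared``; pairs sharing no
    genotyped locus are ``nan``.
    """
    calls = _as_calls(X)
    n, L = calls.shape
    acc = np.zeros((n, n))
    cnt = np.zeros((n, n))
    for l in range(L):
        g = calls[:, l].astype(float)
        m = g != MISSING
        diff = np.subtract.outer(g, g) ** 2
        mm = np.outer(m, m)
        acc += np.where(mm, diff, 0.0)
        cnt += mm
    with np.errstate(invalid="ignore", divide="ignore"):
        d2 = np.where(cnt > 0, acc * (L / np.maximum(cnt, 1)), np.nan)
    np.fill_diagonal(d2, 0.0)
    return d2


def _gower_center(d2: np.ndarray) -> np.ndarray:
    if np.isnan(d2).any():
        # rare with low missingness; fall back to the grand-mean imputation
        fill = np.nanmean(d2)
        d2 = np.where(np.isnan(d2), fill, d2)
    row = d2.mean(axis=1, keepdims=True)
    return -0.5 * (d2 - row - row.T + d2.mean())


@dataclass
class AutocorrResult:
    """Tabular view of a fitted :class:`SpatialAutocorrelation`."""

    per_class: pd.DataFrame  # class midpoint r lo hi se n_pairs signif
    x_intercept: float | None
    x_intercept_immediate: bool
    n_perm: int
    n_boot: int


def x_intercept(r_values, midpoints) -> tuple[float | None, bool]:
    """First zero crossing of the correlogram by linear interpolation.

    Returns ``(intercept_metres, immediate)``; ``immediate`` is True when
    the first class is already non-positive (intercept reported at the
    first midpoint), and the intercept is ``None`` when r never changes
    sign.
    """
    r = np.asarray(r_values, dtype=float)
    m = np.asarray(midpoints, dtype=float)
    ok = np.isfinite(r)
    r, m = r[ok], m[ok]
    if r.size < 2:
        raise InputError("need >= 2 classes with finite r")
    if r[0] <= 0:
        return float(m[0]), True
    for k in range(1, r.size):
        if r[k] <= 0:
            x0, x1, y0, y1 = m[k - 1], m[k], r[k - 1], r[k]
            if y1 == y0:
                return float(x1), False
            return float(x0 + (0.0 - y0) * (x1 - x0) / (y1 - y0)), False
    return None, False


class SpatialAutocorrelation(BaseEstimator):
    """Multilocus autocorrelogram with permutation envelope and bootstrap SEs.

    Parameters mirror :class:`finesgs.kinship.SGSAnalysis`; fitted
    attributes include ``r_``, ``envelope_``, ``se_``, ``pair_count_``,
    ``class_midpoints_``, ``x_intercept_`` and ``x_intercept_immediate_``.
    """

    def __init__(
        self,
        classes: DistanceClassSpec | None = None,
        n_permutations: int = 999,
        n_bootstraps: int = 999,
        random_state=None,
    ):
        self.classes = classes
        self.n_permutations = n_permutations
        self.n_bootstraps = n_bootstraps
        self.random_state = random_state

    def fit(self, X, coords=None, distances=None):
        calls = _as_calls(X)
        n = calls.shape[0]
        if distances is None:
            if coords is None:
                raise InputError("provide coords or distances")
            distances = pairwise_distance(coords)
        D = np.asarray(distances, dtype=float)

        C = _gower_center(genotypic_distance_squared(calls))
        iu, ju = np.triu_indices(n, k=1)
        num_p = 2.0 * C[iu, ju]
        den_p = C[iu, iu] + C[ju, ju]
        d_pairs = D[iu, ju]

        spec = self.classes or DistanceClassSpec()
        edges = spec.resolve_edges(d_pairs[d_pairs > 0])
        n_classes = len(edges) - 1
        cls = spec.assign(d_pairs, edges)

        if not np.any(cls >= 0):
            raise InputError("no pairs fall inside the distance classes")

        def class_r(labels):
            nums = np.bincount(labels[labels >= 0], weights=num_p[labels >= 0], minlength=n_classes)
            dens = np.bincount(labels[labels >= 0], weights=den_p[labels >= 0], minlength=n_classes)
            with np.errstate(invalid="ignore", divide="ignore"):
                r = np.where(dens > 0, nums / np.where(dens != 0, dens, 1.0), np.nan)
            return np.clip(r, -1.0, 1.0)

        r_obs = class_r(cls)
        count = np.bincount(cls[cls >= 0], minlength=n_classes)
        empty = count == 0
        if empty.any():
            logger.info("autocorr: %d empty distance classes", int(empty.sum()))
            r_obs[empty] = np.nan

        rs = check_random_state(self.random_state)
        canon = _canonical_order(X, n)
        rank = np.empty(n, dtype=int)
        rank[canon] = np.arange(n)

        # permutation envelope: shuffle spatial locations
        if self.n_permutations and self.n_permutations > 0:
            perm_r = np.empty((self.n_permutations, n_classes))
            for b in range(self.n_permutations):
                sigma = canon[rs.permutation(n)[rank]]
                dp = D[sigma[iu], sigma[ju]]
                perm_r[b] = class_r(spec.assign(dp, edges))
            lo = np.nanpercentile(perm_r, 2.5, axis=0)
            hi = np.nanpercentile(perm_r, 97.5, axis=0)
        else:
            lo = np.full(n_classes, np.nan)
            hi = np.full(n_classes, np.nan)

        # bootstrap SE: resample pairs within each class
        se = np.full(n_classes, np.nan)
        if self.n_bootstraps and self.n_bootstraps > 0:
            for c in range(n_classes):
                idx = np.flatnonzero(cls == c)
                if idx.size < 2:
                    continue
                draw = rs.randint(0, idx.size, size=(self.n_bootstraps, idx.size))
                nums = num_p[idx][draw].sum(axis=1)
                dens = den_p[idx][draw].sum(axis=1)
                ok = dens != 0
                if ok.sum() >= 2:
                    se[c] = float(np.std(np.clip(nums[ok] / dens[ok], -1, 1), ddof=1))

        self.covariance_ = C
        self.class_edges_ = edges
        self.class_midpoints_ = (edges[:-1] + edges[1:]) / 2.0
        self.r_ = r_obs
        self.envelope_ = np.column_stack([lo, hi])
        self.class_significant_ = (r_obs < lo) | (r_obs > hi)
        self.se_ = se
        self.pair_count_ = count
        finite = np.isfinite(r_obs)
        if finite.sum() >= 2:
            self.x_intercept_, self.x_intercept_immediate_ = x_intercept(
                r_obs[finite], self.class_midpoints_[finite]
            )
        else:
            self.x_intercept_, self.x_intercept_immediate_ = None, False
        return self

    def result_(self) -> AutocorrResult:
        per_class = pd.DataFrame(
            {
                "class_lower": self.class_edges_[:-1],
                "class_upper": self.class_edges_[1:],
                "midpoint": self.class_midpoints_,
                "r": self.r_,
                "lo": self.envelope_[:, 0],
                "hi": self.envelope_[:, 1],
                "se": self.se_,
                "signif": self.class_significant_,
                "n_pairs": self.pair_count_,
            }
        )
        return AutocorrResult(
            per_class=per_class,
            x_intercept=self.x_intercept_,
            x_intercept_immediate=self.x_intercept_immediate_,
            n_perm=self.n_permutations,
            n_boot=self.n_bootstraps,
        )
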