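"""Pairwise kinship, kinship-distance regression and the Sp statistic.

The kinship coefficient is the Loiselle et al. (1995) estimator: for a
biallelic locus l with reference-population alternate-allele frequency
``p_l`` and individual allele frequencies ``x_i = dosage/2``,

    F_ij,l = (x_i - p_l)(x_j - p_l) / (p_l q_l) + 1 / (n_l - 1),

where ``n_l`` is the number of gene copies sampled at the locus (twice
the genotyped individuals) and the second term is the small-sample bias
correction that re-centres unrelated pairs at zero.  Multilocus kinship averages the
per-locus values weighted by the locus polymorphism ``w_l = p_l q_l``
over the loci genotyped in both pair members.

Spatial genetic structure (SGS) is summarized by the regression slope
``bF`` of pairwise kinship on ln(pairwise distance), the mean kinship
``F1`` in the first distance class, and the intensity statistic

    Sp = -bF / (1 - F1).

Significance comes from permuting spatial locations among individuals
(the standard null of random spatial arrangement), and the slope's
standard error from jackknifing over loci.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils import check_random_state

from .datatypes import MISSING, GenotypeMatrix, InputError
from .distance import DistanceClassSpec, pairwise_distance

logger = logging.getLogger(__name__)


def _as_calls(X) -> np.ndarray:
    if isinstance(X, GenotypeMatrix):
        return X.calls
    arr = np.asarray(X)
    if arr.dtype.kind == "f":  # allow nan-coded missing
        out = np.where(np.isnan(arr), MISSING, arr).astype(np.int8)
        return out
    return arr.astype(np.int8)


def _locus_terms(g: np.ndarray):
    """Per-locus ingredients of the Loiselle estimator.

    Returns (valid, weight, centred allele-frequency vector with missing
    zeroed, genotyped mask, bias term) or None for unusable loci.
    """
    m = g != MISSING
    n_l = int(m.sum())
    if n_l < 2:
        return None
    p = float(g[m].sum()) / (2.0 * n_l)
    if p <= 0.0 or p >= 1.0:
        return None
    w = p * (1.0 - p)
    x = np.where(m, g / 2.0 - p, 0.0)
    # small-sample bias correction counts gene copies (2 per diploid);
    # it makes unrelated pairs average ~0 under the sample frequencies
    return w, x, m, 1.0 / (2 * n_l - 1)


def loiselle_kinship(X, return_weights: bool = False):
    """Multilocus Loiselle kinship matrix.

    Parameters
    ----------
    X : GenotypeMatrix or (n, L) dosage array
        ``-1`` (or nan) marks missing calls.
    return_weights : bool
        Also return the per-pair summed locus weights (used internally
        for the leave-one-locus-out jackknife).

    Returns
    -------
    F : (n, n) ndarray
        Symmetric kinship; pairs sharing no usable locus are ``nan``.
        The diagonal is computed but excluded from all SGS statistics.
    """
    calls = _as_calls(X)
    n, L = calls.shape
    if n < 2:
        raise InputError("kinship needs >= 2 individuals")
    S = np.zeros((n, n))
    W = np.zeros((n, n))
    used = 0
    for l in range(L):
        terms = _locus_terms(calls[:, l])
        if terms is None:
            continue
        w, x, m, bias = terms
        mm = np.outer(m, m)
        S += np.outer(x, x) + (w * bias) * mm
        W += w * mm
        used += 1
    if used == 0:
        raise InputError("all loci monomorphic or unusable")
    with np.errstate(invalid="ignore", divide="ignore"):
        F = np.where(W > 0, S / np.where(W > 0, W, 1.0), np.nan)
    if return_weights:
        return F, W
    return F


class LoiselleKinship(BaseEstimator):
    """Estimator wrapper around :func:`loiselle_kinship`.

    Fitted attributes
    -----------------
    kinship_ : (n, n) ndarray
    weight_sum_ : (n, n) ndarray of summed locus weights per pair
    """

    def fit(self, X, y=None):
        self.kinship_, self.weight_sum_ = loiselle_kinship(X, return_weights=True)
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).kinship_


def _canonical_order(X, n: int) -> np.ndarray:
    """Id-sorted individual order (identity when no ids are available)."""
    if isinstance(X, GenotypeMatrix):
        return np.argsort(np.asarray(X.samples, dtype=object))
    return np.arange(n)


def sp_statistic(b_f: float, f1: float) -> float:
    """SGS intensity Sp = -bF / (1 - F1); requires F1 < 1."""
    if not np.isfinite(f1) or f1 >= 1.0:
        raise InputError(f"F1 must be finite and < 1, got {f1}")
    return -b_f / (1.0 - f1)


def _regress_slope(lnd: np.ndarray, f: np.ndarray) -> float:
    x = lnd - lnd.mean()
    denom = float(x @ x)
    if denom == 0.0:
        return np.nan
    return float(x @ (f - f.mean()) / denom)


@dataclass
class SGSResult:
    """Tabular view of a fitted :class:`SGSAnalysis` (one stratum)."""

    b_f: float
    f1: float
    sp: float
    se_bf: float
    per_class: pd.DataFrame  # class_lower class_upper midpoint mean_fij lo hi signif n_pairs
    n_pairs_used: int
    n_zero_distance_pairs: int
    bf_envelope: tuple[float, float] = (np.nan, np.nan)
    bf_significant: bool | None = None


class SGSAnalysis(BaseEstimator):
    """Kinship-distance SGS profile with permutation envelopes.

    Parameters
    ----------
    classes : DistanceClassSpec or None
        Distance binning; default ten equal-pair-count classes.
    n_permutations : int
        Location permutations for the null envelope (0 disables).
    compute_se : bool
        Jackknife-over-loci standard error of the slope ``bF``.
    random_state : int, RandomState or None
        Seeds the permutation null; fixed seed gives identical envelopes
        regardless of input ordering.

    Fitted attributes (suffix ``_``) include ``b_f_``, ``f1_``, ``sp_``,
    ``se_bf_``, ``class_mean_``, ``envelope_``, ``class_significant_``,
    ``pair_count_``, ``class_edges_``, ``class_midpoints_``.
    """

    def __init__(
        self,
        classes: DistanceClassSpec | None = None,
        n_permutations: int = 999,
        compute_se: bool = True,
        random_state=None,
    ):
        self.classes = classes
        self.n_permutations = n_permutations
        self.compute_se = compute_se
        self.random_state = random_state

    # -----------------------------------------------------------------
    def fit(self, X, coords=None, distances=None):
        """Fit the SGS profile.

        Parameters
        ----------
        X : GenotypeMatrix or (n, L) dosage array
        coords : (n, 2) planar coordinates in metres (or pass
            ``distances`` directly).
        """
        calls = _as_calls(X)
        n = calls.shape[0]
        if distances is None:
            if coords is None:
                raise InputError("provide coords or distances")
            distances = pairwise_distance(coords)
        D = np.asarray(distances, dtype=float)
        if D.shape != (n, n):
            raise InputError("distance matrix does not match genotypes")

        F, W = loiselle_kinship(calls, return_weights=True)
        iu, ju = np.triu_indices(n, k=1)
        f_pairs = F[iu, ju]
        d_pairs = D[iu, ju]
        valid = np.isfinite(f_pairs)
        zero = valid & (d_pairs <= 0)
        self.n_zero_distance_pairs_ = int(zero.sum())
        if self.n_zero_distance_pairs_:
            logger.info(
                "SGS: excluded %d zero-distance pairs from the ln(d) regression",
                self.n_zero_distance_pairs_,
            )
        use = valid & (d_pairs > 0)
        if use.sum() < 2:
            raise InputError("not enough usable pairs for SGS")

        spec = self.classes or DistanceClassSpec()
        edges = spec.resolve_edges(d_pairs[use])
        n_classes = len(edges) - 1
        cls = spec.assign(d_pairs, edges)
        cls[~use] = -1

        # per-class observed means
        mean_f = np.full(n_classes, np.nan)
        count = np.zeros(n_classes, dtype=int)
        mean_d = np.full(n_classes, np.nan)
        for c in range(n_classes):
            sel = cls == c
            count[c] = int(sel.sum())
            if count[c]:
                mean_f[c] = float(f_pairs[sel].mean())
                mean_d[c] = float(d_pairs[sel].mean())
        if count[0] == 0:
            raise InputError(f"first distance class empty under spec {spec}")

        lnd = np.log(d_pairs[use])
        b_f = _regress_slope(lnd, f_pairs[use])
        f1 = float(mean_f[0])
        self.kinship_ = F
        self.class_edges_ = edges
        self.class_midpoints_ = (edges[:-1] + edges[1:]) / 2.0
        self.class_mean_distance_ = mean_d
        self.class_mean_ = mean_f
        self.pair_count_ = count
        self.b_f_ = b_f
        self.f1_ = f1
        self.sp_ = sp_statistic(b_f, f1)
        self.n_pairs_used_ = int(use.sum())

        # permutation null: shuffle locations among individuals.  The
        # permutation acts on a canonical (id-sorted) labelling so that a
        # fixed seed yields the same envelope whatever the input order.
        if self.n_permutations and self.n_permutations > 0:
            rs = check_random_state(self.random_state)
            canon = _canonical_order(X, n)
            rank = np.empty(n, dtype=int)
            rank[canon] = np.arange(n)
            perm_means = np.empty((self.n_permutations, n_classes))
            perm_slopes = np.empty(self.n_permutations)
            for b in range(self.n_permutations):
                sigma = canon[rs.permutation(n)[rank]]
                dp = D[sigma[iu], sigma[ju]]
                usep = valid & (dp > 0)
                clsp = spec.assign(dp, edges)
                clsp[~usep] = -1
                sums = np.bincount(clsp[clsp >= 0], weights=f_pairs[clsp >= 0], minlength=n_classes)
                cnts = np.bincount(clsp[clsp >= 0], minlength=n_classes)
                with np.errstate(invalid="ignore"):
                    perm_means[b] = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
                perm_slopes[b] = _regress_slope(np.log(dp[usep]), f_pairs[usep])
            lo = np.nanpercentile(perm_means, 2.5, axis=0)
            hi = np.nanpercentile(perm_means, 97.5, axis=0)
            self.envelope_ = np.column_stack([lo, hi])
            self.class_significant_ = (mean_f < lo) | (mean_f > hi)
            self.bf_envelope_ = (
                float(np.nanpercentile(perm_slopes, 2.5)),
                float(np.nanpercentile(perm_slopes, 97.5)),
            )
            self.bf_significant_ = bool(
                b_f < self.bf_envelope_[0] or b_f > self.bf_envelope_[1]
            )
        else:
            self.envelope_ = np.full((n_classes, 2), np.nan)
            self.class_significant_ = np.zeros(n_classes, dtype=bool)
            self.bf_envelope_ = (np.nan, np.nan)
            self.bf_significant_ = None

        # jackknife-over-loci SE of bF
        if self.compute_se:
            self.se_bf_ = self._jackknife_se(calls, F, W, iu, ju, use, lnd)
        else:
            self.se_bf_ = np.nan
        return self

    # -----------------------------------------------------------------
    def _jackknife_se(self, calls, F, W, iu, ju, use, lnd) -> float:
        S = F * W  # total weighted sums per pair (nan where W == 0)
        S_p = np.where(np.isfinite(S), S, 0.0)[iu, ju][use]
        W_p = W[iu, ju][use]
        slopes = []
        for l in range(calls.shape[1]):
            terms = _locus_terms(calls[:, l])
            if terms is None:
                continue
            w, x, m, bias = terms
            contrib = np.outer(x, x) + (w * bias) * np.outer(m, m)
            wmat = w * np.outer(m, m)
            c_p = contrib[iu, ju][use]
            w_l = wmat[iu, ju][use]
            W_rest = W_p - w_l
            ok = W_rest > 0
            if ok.sum() < 2:
                continue
            f_rest = (S_p[ok] - c_p[ok]) / W_rest[ok]
            slopes.append(_regress_slope(lnd[ok], f_rest))
        slopes = np.asarray(slopes, dtype=float)
        slopes = slopes[np.isfinite(slopes)]
        L = slopes.size
        if L < 2:
            return np.nan
        return float(np.sqrt((L - 1) / L * np.sum((slopes - slopes.mean()) ** 2)))

    # -----------------------------------------------------------------
    def result_(self) -> SGSResult:
        per_class = pd.DataFrame(
            {
                "class_lower": self.class_edges_[:-1],
                "class_upper": self.class_edges_[1:],
                "midpoint": self.class_midpoints_,
                "mean_distance": self.class_mean_distance_,
                "mean_fij": self.class_mean_,
                "lo": self.envelope_[:, 0],
                "hi": self.envelope_[:, 1],
                "signif": self.class_significant_,
                "n_pairs": self.pair_count_,
            }
        )
        return SGSResult(
            b_f=self.b_f_,
            f1=self.f1_,
            sp=self.sp_,
            se_bf=self.se_bf_,
            per_class=per_class,
            n_pairs_used=self.n_pairs_used_,
            n_zero_distance_pairs=self.n_zero_distance_pairs_,
            bf_envelope=self.bf_envelope_,
            bf_significant=self.bf_significant_,
        )


def sgs_by_stratum(
    gm: GenotypeMatrix,
    meta: pd.DataFrame,
    stratum: str,
    classes: DistanceClassSpec | None = None,
    n_permutations: int = 999,
    random_state=None,
    min_individuals: int = 10,
    coord_mode: str = "planar",
) -> dict[str, SGSResult]:
    """Independent SGS profile per stratum (population, age_class or patch).

    Allele frequencies are recomputed within each stratum.  Strata with
    fewer than ``min_individuals`` members are skipped with a warning.
    """
    if stratum not in meta.columns:
        raise InputError(f"stratum column {stratum!r} not in metadata")
    out: dict[str, SGSResult] = {}
    for name, sub in meta.groupby(stratum, sort=True):
        if len(sub) < min_individuals:
            logger.warning("sgs_by_stratum: stratum %s has %d < %d individuals; skipped",
                           name, len(sub), min_individuals)
            continue
        sub_gm = gm.select_samples(sub["id"].tolist())
        D = pairwise_distance(sub[["x", "y"]].to_numpy(), mode=coord_mode)
        try:
            est = SGSAnalysis(
                classes=classes, n_permutations=n_permutations, random_state=random_state
            ).fit(sub_gm, distances=D)
        except InputError as exc:
            logger.warning("sgs_by_stratum: stratum %s failed: %s", name, exc)
            continue
        out[str(name)] = est.result_()
    return out
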