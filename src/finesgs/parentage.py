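"""Categorical parentage by trio LOD scores with simulated confidence.

For an offspring o and candidate parent pair (p1, p2) the trio LOD sums,
over loci genotyped in all three individuals,

    LOD = sum_l ln[ P(g_o | g_p1, g_p2, eps) / P(g_o | allele freqs) ],

where the numerator mixes Mendelian transmission with a genotyping-error
kernel: the observed offspring genotype is the transmitted genotype with
probability (1 - eps)^2 (both alleles read correctly) and otherwise a
random Hardy-Weinberg genotype.  The denominator is the Hardy-Weinberg
genotype probability of an unrelated offspring.  A Mendelian-impossible
locus at eps = 0 contributes a large negative sentinel instead of -inf.

Assignment confidence follows the categorical-allocation recipe: simulate
offspring of known candidate pairs (honouring the proportion of parents
assumed sampled), assign each simulated offspring, and find the smallest
delta (LOD gap between best and runner-up pair) at which the fraction of
correct assignments among those exceeding it reaches the requested
confidence level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils import check_random_state

from .datatypes import MISSING, GenotypeMatrix, InputError
from .kinship import _as_calls

logger = logging.getLogger(__name__)

LOD_FLOOR = -1.0e6  # per-trio sentinel replacing -inf at eps = 0

# Mendelian transmission table M[gm, gf, go]
_MENDEL = np.zeros((3, 3, 3))
for _gm in range(3):
    for _gf in range(3):
        pm, pf = _gm / 2.0, _gf / 2.0
        _MENDEL[_gm, _gf, 0] = (1 - pm) * (1 - pf)
        _MENDEL[_gm, _gf, 1] = pm * (1 - pf) + (1 - pm) * pf
        _MENDEL[_gm, _gf, 2] = pm * pf


@dataclass
class ParentageConfig:
    """Parameters of the categorical-allocation simulation."""

    prop_candidates_sampled: float = 0.9
    genotyping_error: float = 0.01
    mismatch_tolerance: float = 0.01  # fraction of loci allowed to mismatch
    confidence_level: float = 0.80
    n_sim_offspring: int = 10_000
    seed: int | None = None

    def validate(self) -> list[str]:
        problems = []
        for name in (
            "prop_candidates_sampled",
            "genotyping_error",
            "mismatch_tolerance",
            "confidence_level",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                problems.append(f"{name} must be in [0, 1], got {v}")
        if self.n_sim_offspring < 1:
            problems.append("n_sim_offspring must be >= 1")
        return problems


def _hwe_probs(freqs: np.ndarray) -> np.ndarray:
    """(L, 3) Hardy-Weinberg genotype probabilities from alt frequencies."""
    p = np.asarray(freqs, dtype=float)
    return np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2], axis=1)


def _lnratio_table(freqs: np.ndarray, error: float) -> np.ndarray:
    """(L, 4, 4, 4) table of per-locus ln likelihood ratios.

    Index order is [locus, g_o, g_p1, g_p2]; index 3 on any axis means
    missing and contributes 0 (the locus is skipped).
    """
    hwe = _hwe_probs(freqs)  # (L, 3)
    L = hwe.shape[0]
    keep = (1.0 - error) ** 2
    # numerator: keep * M[g1, g2, go] + (1 - keep) * hwe[go]
    num = keep * _MENDEL.transpose(2, 0, 1)[None, :, :, :] + (1 - keep) * hwe[:, :, None, None]
    den = hwe[:, :, None, None]
    with np.errstate(divide="ignore"):
        ratio = np.log(num) - np.log(den)
    ratio = np.where(np.isneginf(ratio), LOD_FLOOR, ratio)
    table = np.zeros((L, 4, 4, 4))
    table[:, :3, :3, :3] = ratio
    return table


def trio_lod(offspring, parent1, parent2, allele_freqs, error: float = 0.01) -> float:
    """Trio LOD score over the loci genotyped in all three members."""
    o = _as_calls(np.atleast_2d(offspring))[0]
    g1 = _as_calls(np.atleast_2d(parent1))[0]
    g2 = _as_calls(np.atleast_2d(parent2))[0]
    if not (o.shape == g1.shape == g2.shape):
        raise InputError("trio genotype vectors must share the same loci")
    shared = (o != MISSING) & (g1 != MISSING) & (g2 != MISSING)
    if not shared.any():
        raise InputError("zero shared genotyped loci in trio")
    table = _lnratio_table(np.asarray(allele_freqs, dtype=float), error)
    oi = np.where(o == MISSING, 3, o)
    ai = np.where(g1 == MISSING, 3, g1)
    bi = np.where(g2 == MISSING, 3, g2)
    lod = float(table[np.arange(o.size), oi, ai, bi].sum())
    return max(lod, LOD_FLOOR)


def _pair_lods(table: np.ndarray, offspring_calls: np.ndarray, cand_calls: np.ndarray,
               pairs: np.ndarray) -> np.ndarray:
    """LOD of every offspring (rows) against every candidate pair (cols)."""
    L = cand_calls.shape[1]
    ai = np.where(cand_calls == MISSING, 3, cand_calls)
    g1 = ai[pairs[:, 0]]  # (P, L)
    g2 = ai[pairs[:, 1]]
    locus = np.arange(L)
    out = np.empty((offspring_calls.shape[0], pairs.shape[0]))
    for k, o in enumerate(offspring_calls):
        oi = np.where(o == MISSING, 3, o)
        out[k] = np.maximum(
            table[locus[None, :], oi[None, :], g1, g2].sum(axis=1), LOD_FLOOR
        )
    return out


def _mismatch_counts(offspring_calls: np.ndarray, cand_calls: np.ndarray,
                     pairs: np.ndarray) -> np.ndarray:
    """Mendelian-impossible locus count per offspring x candidate pair."""
    possible = _MENDEL.transpose(2, 0, 1) > 0  # [go, g1, g2]
    tab = np.ones((4, 4, 4), dtype=bool)
    tab[:3, :3, :3] = possible
    ai = np.where(cand_calls == MISSING, 3, cand_calls)
    g1 = ai[pairs[:, 0]]
    g2 = ai[pairs[:, 1]]
    out = np.empty((offspring_calls.shape[0], pairs.shape[0]), dtype=int)
    for k, o in enumerate(offspring_calls):
        oi = np.where(o == MISSING, 3, o)
        out[k] = (~tab[oi[None, :], g1, g2]).sum(axis=1)
    return out


def calibrate_delta(candidate_calls: np.ndarray, allele_freqs: np.ndarray,
                    config: ParentageConfig, random_state=None) -> float:
    """Critical delta achieving the configured assignment confidence.

    Simulates ``n_sim_offspring`` offspring of random candidate pairs;
    each true parent is treated as sampled with probability
    ``prop_candidates_sampled`` (an unsampled parent is replaced by a
    Hardy-Weinberg draw, so its offspring cannot be assigned correctly).
    Returns 0.0 when assignments are reliable at any delta, ``inf`` when
    the confidence level is unattainable.
    """
    cand = _as_calls(candidate_calls)
    n_cand = cand.shape[0]
    if n_cand < 2:
        raise InputError("calibration needs >= 2 candidates")
    if config.confidence_level <= 0:
        return 0.0
    rs = check_random_state(random_state if random_state is not None else config.seed)
    freqs = np.asarray(allele_freqs, dtype=float)
    table = _lnratio_table(freqs, config.genotyping_error)
    pairs = np.array(list(combinations_with_replacement(range(n_cand), 2)))

    n_sim = config.n_sim_offspring
    L = cand.shape[1]
    mothers = rs.randint(0, n_cand, n_sim)
    fathers = rs.randint(0, n_cand, n_sim)
    m_sampled = rs.random_sample(n_sim) < config.prop_candidates_sampled
    f_sampled = rs.random_sample(n_sim) < config.prop_candidates_sampled

    # unsampled true parents are outside the candidate set: HW genotypes;
    # missing candidate calls are likewise imputed from the frequencies
    hw_m = rs.binomial(2, np.broadcast_to(freqs, (n_sim, L)))
    hw_f = rs.binomial(2, np.broadcast_to(freqs, (n_sim, L)))
    gm = np.where(cand[mothers] == MISSING, hw_m, cand[mothers]).astype(float)
    gf = np.where(cand[fathers] == MISSING, hw_f, cand[fathers]).astype(float)
    gm = np.where(m_sampled[:, None], gm, hw_m)
    gf = np.where(f_sampled[:, None], gf, hw_f)

    off = rs.binomial(1, gm / 2.0) + rs.binomial(1, gf / 2.0)
    # observation error: whole genotype replaced by a HW draw w.p. 1-(1-eps)^2
    keep = (1.0 - config.genotyping_error) ** 2
    repl = rs.random_sample(off.shape) >= keep
    off = np.where(repl, rs.binomial(2, np.broadcast_to(freqs, off.shape)), off).astype(np.int8)

    lods = _pair_lods(table, off, cand, pairs)
    order = np.argsort(lods, axis=1)
    best = order[:, -1]
    delta = lods[np.arange(n_sim), best] - (
        lods[np.arange(n_sim), order[:, -2]] if pairs.shape[0] > 1 else 0.0
    )
    truth = np.sort(np.stack([mothers, fathers], axis=1), axis=1)
    assigned = pairs[best]
    correct = (assigned == truth).all(axis=1) & m_sampled & f_sampled

    # smallest threshold with >= confidence correct among deltas above it
    idx = np.argsort(-delta)
    frac = np.cumsum(correct[idx]) / np.arange(1, n_sim + 1)
    ok = frac >= config.confidence_level
    if not ok.any():
        return float("inf")
    last = np.flatnonzero(ok).max()
    if last == n_sim - 1:
        return 0.0
    return float(delta[idx][last])


@dataclass
class ParentageAssignment:
    offspring: str
    mother: str | None
    father: str | None
    trio_lod: float
    delta: float
    confident: bool
    mismatch_count: int
    tie: bool = False


class TrioParentage(BaseEstimator):
    """Categorical parentage allocator (fit on candidates, predict offspring).

    ``fit`` stores the candidate genotypes and allele frequencies and
    calibrates the critical delta by simulation; ``predict`` evaluates
    every unordered candidate pair (a single candidate can appear as both
    parents, i.e. selfing) for each offspring, picks the highest trio
    LOD, and flags the assignment confident when its delta reaches the
    calibrated threshold and the Mendelian mismatch fraction stays within
    tolerance.  Ties go to the lexicographically first candidate pair and
    are flagged.
    """

    def __init__(
        self,
        prop_candidates_sampled: float = 0.9,
        genotyping_error: float = 0.01,
        mismatch_tolerance: float = 0.01,
        confidence_level: float = 0.80,
        n_sim_offspring: int = 10_000,
        random_state=None,
    ):
        self.prop_candidates_sampled = prop_candidates_sampled
        self.genotyping_error = genotyping_error
        self.mismatch_tolerance = mismatch_tolerance
        self.confidence_level = confidence_level
        self.n_sim_offspring = n_sim_offspring
        self.random_state = random_state

    def _config(self) -> ParentageConfig:
        cfg = ParentageConfig(
            prop_candidates_sampled=self.prop_candidates_sampled,
            genotyping_error=self.genotyping_error,
            mismatch_tolerance=self.mismatch_tolerance,
            confidence_level=self.confidence_level,
            n_sim_offspring=self.n_sim_offspring,
        )
        problems = cfg.validate()
        if problems:
            raise InputError("; ".join(problems))
        return cfg

    def fit(self, X, y=None, candidate_ids=None, allele_freqs=None):
        """Store candidates, compute allele frequencies, calibrate delta."""
        cfg = self._config()
        if isinstance(X, GenotypeMatrix):
            self.candidate_ids_ = list(X.samples) if candidate_ids is None else list(candidate_ids)
        else:
            self.candidate_ids_ = (
                [str(i) for i in range(np.asarray(X).shape[0])]
                if candidate_ids is None
                else list(candidate_ids)
            )
        self.candidates_ = _as_calls(X)
        if allele_freqs is not None:
            self.allele_freqs_ = np.asarray(allele_freqs, dtype=float)
        else:
            obs = self.candidates_ != MISSING
            n = obs.sum(axis=0)
            alt = np.where(obs, self.candidates_, 0).sum(axis=0)
            self.allele_freqs_ = np.where(n > 0, alt / np.maximum(2 * n, 1), 0.5)
        self.allele_freqs_ = np.clip(self.allele_freqs_, 1e-6, 1 - 1e-6)
        if self.candidates_.shape[0] < 2:
            # only one possible (selfed) pair: nothing to discriminate
            logger.warning("parentage: single candidate; delta calibration skipped")
            self.critical_delta_ = 0.0
        else:
            self.critical_delta_ = calibrate_delta(
                self.candidates_, self.allele_freqs_, cfg, random_state=self.random_state
            )
        self.pairs_ = np.array(
            list(combinations_with_replacement(range(self.candidates_.shape[0]), 2))
        )
        self._table_ = _lnratio_table(self.allele_freqs_, self.genotyping_error)
        return self

    def predict(self, X, offspring_ids=None) -> list[ParentageAssignment]:
        if not hasattr(self, "critical_delta_"):
            raise InputError("fit before predict")
        if isinstance(X, GenotypeMatrix):
            ids = list(X.samples) if offspring_ids is None else list(offspring_ids)
        else:
            ids = (
                [f"o{i}" for i in range(np.asarray(X).shape[0])]
                if offspring_ids is None
                else list(offspring_ids)
            )
        off = _as_calls(X)
        lods = _pair_lods(self._table_, off, self.candidates_, self.pairs_)
        mism = _mismatch_counts(off, self.candidates_, self.pairs_)
        out: list[ParentageAssignment] = []
        n_loci = off.shape[1]
        for k, oid in enumerate(ids):
            row = lods[k]
            best_lod = row.max()
            winners = np.flatnonzero(row == best_lod)
            best = int(winners[0])  # pairs_ already in lexicographic order
            tie = winners.size > 1
            if tie:
                logger.info("parentage: LOD tie for offspring %s", oid)
            if row.size > 1:
                runner = np.partition(row, -2)[-2]
                delta = float(best_lod - runner) if not tie else 0.0
            else:
                delta = float("inf")
            i, j = self.pairs_[best]
            mcount = int(mism[k, best])
            shared = int(
                (
                    (off[k] != MISSING)
                    & (self.candidates_[i] != MISSING)
                    & (self.candidates_[j] != MISSING)
                ).sum()
            )
            frac = mcount / shared if shared else 1.0
            confident = bool(
                delta >= self.critical_delta_ and frac <= self.mismatch_tolerance
            )
            out.append(
                ParentageAssignment(
                    offspring=oid,
                    mother=self.candidate_ids_[i],
                    father=self.candidate_ids_[j],
                    trio_lod=float(best_lod),
                    delta=delta,
                    confident=confident,
                    mismatch_count=mcount,
                    tie=tie,
                )
            )
        return out


def assignments_frame(assignments: list[ParentageAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "offspring": a.offspring,
                "mother": a.mother,
                "father": a.father,
                "trio_lod": a.trio_lod,
                "delta": a.delta,
                "confident": a.confident,
                "mismatches": a.mismatch_count,
                "tie": a.tie,
            }
            for a in assignments
        ]
    )


def dispersal_events(
    assignments: list[ParentageAssignment] | pd.DataFrame, meta: pd.DataFrame
) -> pd.DataFrame:
    """Convert confident assignments into seed/pollen dispersal events.

    The parent nearer to the offspring is taken as the mother (seeds fall
    near the maternal tree; pollen travels): seed distance is
    offspring-mother, pollen distance mother-father (0 for selfed pairs).
    Events with missing coordinates are skipped.  The mother/father
    labelling is an assumption recorded in the output metadata, not an
    observation.
    """
    if isinstance(assignments, list):
        assignments = assignments_frame(assignments)
    pos = meta.set_index("id")
    rows = []
    for a in assignments.itertuples(index=False):
        if not a.confident or a.mother is None or a.father is None:
            continue
        try:
            o = pos.loc[a.offspring]
            p1 = pos.loc[a.mother]
            p2 = pos.loc[a.father]
        except KeyError:
            logger.warning("dispersal_events: missing coordinates for %s; skipped", a.offspring)
            continue
        d1 = float(np.hypot(o.x - p1.x, o.y - p1.y))
        d2 = float(np.hypot(o.x - p2.x, o.y - p2.y))
        mother, father = (p1, p2) if d1 <= d2 else (p2, p1)
        seed = min(d1, d2)
        pollen = 0.0 if a.mother == a.father else float(
            np.hypot(mother.x - father.x, mother.y - father.y)
        )
        rows.append(
            {"kind": "seed", "distance": seed, "patch": o.patch, "offspring": a.offspring}
        )
        rows.append(
            {"kind": "pollen", "distance": pollen, "patch": o.patch, "offspring": a.offspring}
        )
    return pd.DataFrame(rows, columns=["kind", "distance", "patch", "offspring"])
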