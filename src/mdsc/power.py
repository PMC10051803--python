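"""Split-selection Monte-Carlo power analysis for group comparisons.

The procedure builds two finite patient populations with a prescribed
GMFM-66 mean difference by *split selection*: the cohort is randomly
halved many times (790 + 790 from 1581, one patient dropped per candidate
when N is odd), and for each target difference d the candidate whose
realized mean difference is closest to d is kept.  Empirical power is then
estimated by repeatedly subsampling n patients per group without
replacement and testing for a group difference at level alpha — once on
the patients' true GMFM-66 values and once on their Medical Device Scores,
using the *identical* drawn patients for both score sources so the two
power columns are directly comparable.

The significance test defaults to Welch's two-sample t-test; Student's t
and Mann-Whitney are selectable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from itertools import combinations
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from mdsc._rng import substream
from mdsc.cohort import Cohort
from mdsc.errors import ConfigurationError
from mdsc.predict import PredictionResult

_CHUNK = 2000  # Monte-Carlo reps processed per vectorized block


@dataclass(frozen=True)
class TestSpec:
    """Which significance test the power estimate applies."""

    __test__ = False  # not a pytest collectable, despite the name

    test: str = "welch_t"
    alpha: float = 0.05
    two_sided: bool = True

    def validate(self) -> None:
        if self.test not in ("welch_t", "student_t", "mann_whitney"):
            raise ConfigurationError(f"unknown test {self.test!r}")
        if not (0.0 < self.alpha <= 0.5):
            raise ConfigurationError(f"alpha must be in (0, 0.5], got {self.alpha}")


@dataclass(frozen=True)
class SplitPair:
    """Two disjoint equal-size patient groups; group A has the higher mean."""

    group_a_ids: tuple
    group_b_ids: tuple
    target_d: float | None
    achieved_d: float
    source_seed: int
    candidate_index: int


def _scores_and_ids(population):
    """Accept a Cohort or a plain score vector (ids = indices)."""
    if isinstance(population, Cohort):
        return population.gmfm66, np.array(population.ids, dtype=object)
    scores = np.asarray(population, dtype=float)
    return scores, np.arange(len(scores))


def _oriented_pair(scores, ids, ia, ib, seed, index) -> SplitPair:
    ma, mb = scores[ia].mean(), scores[ib].mean()
    if mb > ma:
        ia, ib = ib, ia
        ma, mb = mb, ma
    return SplitPair(
        group_a_ids=tuple(ids[ia]),
        group_b_ids=tuple(ids[ib]),
        target_d=None,
        achieved_d=float(ma - mb),
        source_seed=seed,
        candidate_index=index,
    )


def random_splits(population, k: int, seed: int = 0) -> Iterator[SplitPair]:
    """Stream ``k`` uniformly random half/half partitions of the cohort.

    With an odd cohort size one uniformly chosen patient is left out of
    each candidate (1581 -> 790 + 790).  Deterministic given ``seed``.
    """
    if k < 1:
        raise ConfigurationError(f"k must be >= 1, got {k}")
    scores, ids = _scores_and_ids(population)
    n = len(scores)
    if n < 4:
        raise ConfigurationError(f"need at least 4 patients, got {n}")
    half = n // 2
    rng = np.random.default_rng(seed)
    for index in range(k):
        perm = rng.permutation(n)
        yield _oriented_pair(scores, ids, perm[:half], perm[half : 2 * half], seed, index)


def exhaustive_splits(population) -> Iterator[SplitPair]:
    """Every equal half/half partition of an even-size population.

    Complement pairs are emitted once (the element at index 0 is pinned to
    group one).  Intended as a brute-force oracle for small populations.
    """
    scores, ids = _scores_and_ids(population)
    n = len(scores)
    if n < 4 or n % 2:
        raise ConfigurationError("exhaustive enumeration needs an even size >= 4")
    half = n // 2
    rest = np.arange(1, n)
    for index, chosen in enumerate(combinations(rest, half - 1)):
        ia = np.concatenate(([0], np.array(chosen, dtype=int)))
        mask = np.ones(n, dtype=bool)
        mask[ia] = False
        yield _oriented_pair(scores, ids, ia, np.flatnonzero(mask), 0, index)


def select_splits_for_differences(
    candidates: Iterable[SplitPair], d_list
) -> dict[float, SplitPair]:
    """One pass over a candidate stream, keeping for each target d the
    candidate minimizing ``|achieved_d - d|`` (ties: earliest candidate)."""
    d_list = [float(d) for d in d_list]
    if not d_list:
        raise ConfigurationError("d_list must be non-empty")
    best: dict[float, SplitPair] = {}
    gaps = {d: math.inf for d in d_list}
    empty = True
    for cand in candidates:
        empty = False
        for d in d_list:
            gap = abs(cand.achieved_d - d)
            if gap < gaps[d]:
                gaps[d] = gap
                best[d] = replace(cand, target_d=d)
    if empty:
        raise ConfigurationError("candidate stream is empty")
    return best


def select_split_for_difference(
    candidates: Iterable[SplitPair], target_d: float
) -> SplitPair:
    """The candidate whose realized mean difference is closest to
    ``target_d``."""
    return select_splits_for_differences(candidates, [target_d])[float(target_d)]


def refine_split_to_difference(
    population, pair: SplitPair, target_d: float, tol: float = 1e-3
) -> SplitPair:
    """Exchange patients between the two halves until the realized mean
    difference matches ``target_d``.

    Pure candidate selection cannot reach large targets on a big cohort:
    the mean difference between complementary random halves of ~790 has a
    standard deviation near one GMFM-66 point, so differences of 5-10
    points never occur among any feasible number of random divisions.  To
    build group pairs that genuinely differ by the target — the premise of
    the sample-size grid — the best candidate is refined by a minimal
    sequence of A/B patient swaps: first greedy extreme-pair swaps while a
    full swap still undershoots, then one fine-tuning swap chosen (by a
    two-pointer scan over the sorted halves) to land the difference within
    ``tol`` of the target whenever the score distribution allows.

    Deterministic given the candidate.  Group sizes are preserved; the
    result keeps the candidate's provenance fields.
    """
    scores, ids = _scores_and_ids(population)
    lookup = {pid: s for pid, s in zip(ids, scores)}
    a = sorted(pair.group_a_ids, key=lookup.__getitem__)  # ascending
    b = sorted(pair.group_b_ids, key=lookup.__getitem__)
    h = len(a)
    target = float(target_d)

    def diff() -> float:
        return (sum(map(lookup.__getitem__, a)) - sum(map(lookup.__getitem__, b))) / h

    # phase 1: largest-gain swaps (A's weakest vs B's strongest) while a
    # full swap still leaves the difference below target
    i, j = 0, h - 1
    d_now = diff()
    while d_now < target and i < h and j >= 0:
        gain = 2.0 * (lookup[b[j]] - lookup[a[i]]) / h
        if gain <= 0 or d_now + gain > target:
            break
        a[i], b[j] = b[j], a[i]
        d_now += gain
        i += 1
        j -= 1
    # phase 2: one fine-tuning swap; need a pair with score gap closest to
    # the remaining shortfall
    short = target - d_now
    if abs(short) > tol:
        want = short * h / 2.0
        sa = sorted(a, key=lookup.__getitem__)
        sb = sorted(b, key=lookup.__getitem__)
        best = None
        jj = 0
        for x in sa:
            while jj < h - 1 and lookup[sb[jj]] - lookup[x] < want:
                jj += 1
            for cand_j in (jj - 1, jj):
                if 0 <= cand_j < h:
                    gap = lookup[sb[cand_j]] - lookup[x]
                    err = abs(gap - want)
                    if best is None or err < best[0]:
                        best = (err, x, sb[cand_j])
        if best is not None and best[0] < abs(want):
            _, x, y = best
            a[a.index(x)] = y
            b[b.index(y)] = x
            d_now = diff()
    if d_now < 0:
        a, b = b, a
        d_now = -d_now
    return replace(
        pair,
        group_a_ids=tuple(a),
        group_b_ids=tuple(b),
        target_d=target,
        achieved_d=float(d_now),
    )


# ---------------------------------------------------------------------------
# Empirical power.
# ---------------------------------------------------------------------------

def _pvalues(a: np.ndarray, b: np.ndarray, spec: TestSpec) -> np.ndarray:
    """Row-wise p-values for (reps, n) sample matrices."""
    alternative = "two-sided" if spec.two_sided else "greater"
    if spec.test == "welch_t":
        res = stats.ttest_ind(a, b, axis=1, equal_var=False, alternative=alternative)
    elif spec.test == "student_t":
        res = stats.ttest_ind(a, b, axis=1, equal_var=True, alternative=alternative)
    else:
        res = stats.mannwhitneyu(a, b, axis=1, alternative=alternative)
    return np.atleast_1d(res.pvalue)


def _subsample_indices(rng, pool_size: int, n: int, reps: int) -> np.ndarray:
    """(reps, n) index matrix, each row drawn without replacement."""
    return np.argsort(rng.random((reps, pool_size)), axis=1)[:, :n]


def _rejections_two_pools(scores_a, scores_b, n, reps, spec, rng):
    out = np.empty(reps, dtype=bool)
    done = 0
    while done < reps:
        chunk = min(_CHUNK, reps - done)
        ia = _subsample_indices(rng, len(scores_a), n, chunk)
        ib = _subsample_indices(rng, len(scores_b), n, chunk)
        out[done : done + chunk] = _pvalues(scores_a[ia], scores_b[ib], spec) < spec.alpha
        done += chunk
    return out


def _rejections_shared_pool(scores, n, reps, spec, rng):
    out = np.empty(reps, dtype=bool)
    done = 0
    while done < reps:
        chunk = min(_CHUNK, reps - done)
        idx = _subsample_indices(rng, len(scores), 2 * n, chunk)
        out[done : done + chunk] = (
            _pvalues(scores[idx[:, :n]], scores[idx[:, n:]], spec) < spec.alpha
        )
        done += chunk
    return out


def estimate_power(
    scores_a,
    scores_b,
    n: int,
    reps: int = 10000,
    testspec: TestSpec = TestSpec(),
    seed: int = 0,
) -> float:
    """Empirical power (%) of detecting a difference between two score
    pools at sample size ``n`` per group.

    Each repetition draws ``n`` values without replacement from each pool
    and applies the configured test; power is the rejection percentage.

    When both arguments are the *same* pool (the type-I calibration case)
    the two subsamples are drawn disjointly — ``2n`` values without
    replacement, split in half — so the null of exchangeable groups holds
    exactly and the rejection rate estimates the test's size.
    """
    testspec.validate()
    if reps < 1:
        raise ConfigurationError(f"reps must be >= 1, got {reps}")
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    shared = scores_a is scores_b or (a.shape == b.shape and np.array_equal(a, b))
    rng = substream(seed, 97)
    if shared:
        if 2 * n > len(a):
            raise ConfigurationError(
                f"n={n} too large: shared pool of {len(a)} must cover 2n draws"
            )
        rejections = _rejections_shared_pool(a, n, reps, testspec, rng)
    else:
        if n > min(len(a), len(b)):
            raise ConfigurationError(
                f"n={n} exceeds a group size ({len(a)}, {len(b)})"
            )
        rejections = _rejections_two_pools(a, b, n, reps, testspec, rng)
    return float(100.0 * rejections.mean())


def analytic_t_power(
    delta: float, sd_a: float, sd_b: float, n_a: int, n_b: int, alpha: float = 0.05
) -> float:
    """Closed-form two-sided Welch t-test power (%), via the noncentral t
    with Welch-Satterthwaite degrees of freedom.  Serves as the analytic
    oracle for the Monte-Carlo estimator on normal populations."""
    va, vb = sd_a**2 / n_a, sd_b**2 / n_b
    se = math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    nc = delta / se
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    power = 1 - stats.nct.cdf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc)
    return float(100.0 * power)


# ---------------------------------------------------------------------------
# The full power grid.
# ---------------------------------------------------------------------------

@dataclass
class PowerGrid:
    """Empirical power indexed by (n, target d, score source).

    ``frame`` columns: n, target_d, achieved_d, source ("gmfm" | "mds"),
    power_pct, reps, seed.
    """

    frame: pd.DataFrame
    reps: int
    seed: int
    testspec: TestSpec

    def cell(self, n: int, d: float, source: str) -> float:
        sel = self.frame[
            (self.frame["n"] == n)
            & (self.frame["target_d"] == float(d))
            & (self.frame["source"] == source)
        ]
        if len(sel) != 1:
            raise KeyError(f"no unique cell (n={n}, d={d}, source={source!r})")
        return float(sel["power_pct"].iloc[0])


def _mds_series(mds) -> pd.Series:
    if isinstance(mds, PredictionResult):
        return mds.mds_by_id()
    if isinstance(mds, Mapping):
        return pd.Series(mds, name="mds")
    if isinstance(mds, pd.Series):
        return mds
    raise ConfigurationError("mds must be a PredictionResult, Series, or mapping")


def power_table(
    cohort: Cohort,
    mds_result,
    d_list=(3, 4, 5, 6, 7, 8, 9, 10),
    n_list=(30, 40, 50, 75, 100, 150, 200, 250),
    k_splits: int = 10000,
    reps: int = 10000,
    testspec: TestSpec = TestSpec(),
    seed: int = 0,
    refine: bool = True,
) -> PowerGrid:
    """Full empirical power grid for both score sources.

    For each target difference d one split pair is selected from
    ``k_splits`` random candidates on the *true* GMFM-66 scores (the group
    difference is defined on the GMFM-66 scale) and, with ``refine`` on
    (the default), exchanged patient-by-patient until the realized
    difference matches the target (see
    :func:`refine_split_to_difference`).  For each (n, d) the power is
    computed twice over the same drawn patient subsamples — once with the
    patients' GMFM-66 values, once with their Medical Device Scores.
    """
    testspec.validate()
    d_list = [float(d) for d in d_list]
    n_list = [int(n) for n in n_list]
    if not d_list or not n_list:
        raise ConfigurationError("d_list and n_list must be non-empty")
    half = len(cohort) // 2
    too_big = [n for n in n_list if n > half]
    if too_big:
        raise ConfigurationError(
            f"sample sizes {too_big} exceed half the cohort ({half})"
        )
    gmfm = pd.Series(cohort.gmfm66, index=pd.Index(cohort.ids))
    mds = _mds_series(mds_result)
    missing = [pid for pid in cohort.ids if pid not in mds.index]
    if missing:
        raise ConfigurationError(
            f"mds does not cover every cohort patient ({len(missing)} missing, "
            f"e.g. {missing[:3]}); cross-fit the MDS first"
        )

    from mdsc._rng import derived_seed

    candidates = random_splits(cohort, k_splits, seed=derived_seed(seed, 50))
    selected = select_splits_for_differences(candidates, d_list)
    if refine:
        selected = {
            d: refine_split_to_difference(cohort, pair, d)
            for d, pair in selected.items()
        }

    rows = []
    for j, d in enumerate(d_list):
        pair = selected[d]
        ga_ids = list(pair.group_a_ids)
        gb_ids = list(pair.group_b_ids)
        gmfm_a = gmfm.loc[ga_ids].to_numpy()
        gmfm_b = gmfm.loc[gb_ids].to_numpy()
        mds_a = mds.loc[ga_ids].to_numpy(dtype=float)
        mds_b = mds.loc[gb_ids].to_numpy(dtype=float)
        for i, n in enumerate(n_list):
            rng = substream(seed, 51, j, i)
            hits_g = 0
            hits_m = 0
            done = 0
            while done < reps:
                chunk = min(_CHUNK, reps - done)
                ia = _subsample_indices(rng, len(gmfm_a), n, chunk)
                ib = _subsample_indices(rng, len(gmfm_b), n, chunk)
                # identical drawn patients for both score sources
                hits_g += int(
                    (_pvalues(gmfm_a[ia], gmfm_b[ib], testspec) < testspec.alpha).sum()
                )
                hits_m += int(
                    (_pvalues(mds_a[ia], mds_b[ib], testspec) < testspec.alpha).sum()
                )
                done += chunk
            for source, hits in (("gmfm", hits_g), ("mds", hits_m)):
                rows.append(
                    {
                        "n": n,
                        "target_d": d,
                        "achieved_d": pair.achieved_d,
                        "source": source,
                        "power_pct": 100.0 * hits / reps,
                        "reps": reps,
                        "seed": seed,
                    }
                )
    return PowerGrid(frame=pd.DataFrame(rows), reps=reps, seed=seed, testspec=testspec)


def smallest_n_for_power(
    grid: PowerGrid | pd.DataFrame, d: float, source: str, power_target: float = 80.0
):
    """Smallest configured group size reaching ``power_target`` percent for
    a given target difference and score source, or None if the grid never
    reaches it.  This is the sample-size lookup the grid exists for."""
    frame = grid.frame if isinstance(grid, PowerGrid) else grid
    sel = frame[
        (frame["target_d"] == float(d))
        & (frame["source"] == source)
        & (frame["power_pct"] >= power_target)
    ]
    if sel.empty:
        return None
    return int(sel["n"].min())
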