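"""Bait-normalized label-free interactome differential analysis.

LFQ intensities of co-purified proteins are first divided, per replicate,
by the bait protein's intensity in that replicate — cancelling pull-down
efficiency differences between runs — then log2-transformed and compared
between two arms (typically control vs knock-down) with a per-protein
Welch t-test.  Significance is controlled by a SAM-style permutation FDR:
the null t distribution comes from recomputing every statistic under
group-label permutations (all distinct splits when few, sampled
otherwise), and FDR(t*) is the median over permutations of the null
exceedance count divided by the observed exceedance count at |t| >= t*.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from ._util import rng_for

#: enumerate all distinct label splits when their number is at most this
ENUMERATION_BOUND = 200


class BaitError(ValueError):
    """Bait row absent or missing in some replicate."""


def bait_normalize(lfq: pd.DataFrame, bait_id: str) -> pd.DataFrame:
    """Divide every column by its bait intensity; bait row becomes 1.

    Raises :class:`BaitError` naming the replicate if the bait is absent
    from the matrix or missing (NaN/non-positive) in any column.
    """
    if bait_id not in lfq.index:
        raise BaitError(f"bait {bait_id!r} not present in the LFQ matrix")
    bait = lfq.loc[bait_id]
    bad = bait.index[~(bait > 0) | bait.isna()]
    if len(bad):
        raise BaitError(
            f"bait {bait_id!r} missing or non-positive in replicate(s): "
            f"{list(bad)}"
        )
    return lfq.div(bait, axis=1)


def _nan_moments(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise count, mean and ddof-1 variance ignoring NaNs, warning-free."""
    finite = np.isfinite(x)
    n = finite.sum(axis=1)
    filled = np.where(finite, x, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean = filled.sum(axis=1) / n
        var = (np.where(finite, (x - mean[:, None]) ** 2, 0.0)).sum(axis=1) / (n - 1)
    return n, mean, var


def _welch_t(a: np.ndarray, b: np.ndarray, s0: float = 0.0) -> np.ndarray:
    """Row-wise Welch t statistics tolerant of NaNs (needs >=2 per group).

    ``s0`` is the SAM-style variance-stabilizing constant added to the
    standard error: with only three replicates, occasional proteins with
    near-zero sample variance otherwise dominate the permutation null with
    arbitrarily large statistics.
    """
    na, ma, va = _nan_moments(a)
    nb, mb, vb = _nan_moments(b)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(va / na + vb / nb)
        t = (ma - mb) / (se + s0)
    t = np.where((na >= 2) & (nb >= 2) & (se + s0 > 0), t, np.nan)
    return t


def permutation_fdr_test(
    norm: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    fdr_cut: float = 0.01,
    n_perms: int | None = None,
    seed: int = 0,
    bait_id: str | None = None,
    s0: float = 0.1,
) -> pd.DataFrame:
    """Two-sample t-test with permutation-based FDR on log2 bait-normalized LFQ.

    Parameters
    ----------
    norm
        Bait-normalized intensity matrix (proteins x samples).
    group_a, group_b
        Column names of the two arms; the reported ``log2_ratio`` is
        mean(A) - mean(B) on the log2 scale (knock-down first to read as
        knock-down vs control).
    n_perms
        Number of sampled label permutations when the distinct splits
        exceed the enumeration bound; ignored otherwise.
    bait_id
        Excluded from testing when given (its ratio is 1 by construction).
    s0
        SAM-style fudge constant on the log2 scale added to every standard
        error (observed and permuted alike).

    Returns a table with ``log2_ratio``, ``t``, ``fdr``, ``significant``,
    ``tested``.  Proteins with fewer than two finite values per group are
    not tested.
    """
    cols = list(group_a) + list(group_b)
    x = np.log2(norm[cols].to_numpy(dtype=float))
    if bait_id is not None and bait_id in norm.index:
        x[norm.index.get_loc(bait_id), :] = np.nan
    na = len(group_a)
    ia = np.arange(na)
    ib = np.arange(na, len(cols))

    t_obs = _welch_t(x[:, ia], x[:, ib], s0=s0)
    _, mean_a, _ = _nan_moments(x[:, ia])
    _, mean_b, _ = _nan_moments(x[:, ib])
    log2_ratio = mean_a - mean_b
    tested = np.isfinite(t_obs)

    all_splits = list(combinations(range(len(cols)), na))
    if len(all_splits) <= ENUMERATION_BOUND:
        splits = all_splits
    else:
        rng = rng_for(seed, "permutation_fdr")
        picks = rng.choice(len(all_splits), size=n_perms or ENUMERATION_BOUND,
                           replace=False)
        splits = [all_splits[i] for i in picks]

    abs_obs = np.abs(t_obs[tested])
    order = np.sort(abs_obs)
    n_obs_ge = len(order) - np.searchsorted(order, abs_obs, side="left")

    exceed = np.empty((len(splits), tested.sum()))
    for s, split in enumerate(splits):
        pa = np.asarray(split)
        pb = np.asarray([i for i in range(len(cols)) if i not in split])
        t_perm = _welch_t(x[:, pa], x[:, pb], s0=s0)
        abs_perm = np.sort(np.abs(t_perm[np.isfinite(t_perm)]))
        exceed[s] = len(abs_perm) - np.searchsorted(abs_perm, abs_obs, side="left")

    with np.errstate(divide="ignore", invalid="ignore"):
        fdr_tested = np.median(exceed, axis=0) / n_obs_ge
    fdr_tested = np.minimum(fdr_tested, 1.0)

    fdr = np.full(len(norm), np.nan)
    fdr[tested] = fdr_tested
    out = pd.DataFrame(
        {
            "log2_ratio": log2_ratio,
            "t": t_obs,
            "fdr": fdr,
            "tested": tested,
            "significant": tested & (fdr <= fdr_cut),
            "n_permutations": len(splits),
        },
        index=norm.index,
    )
    out.index.name = "protein_id"
    return out


def dependence_summary(
    diff: pd.DataFrame, interactor_set=None
) -> dict:
    """Fraction of quantified interactors significantly reduced.

    ``interactor_set`` restricts the universe (e.g. previously known
    partners of the co-factor); by default all tested proteins count.
    Reduction means significant with a negative log2 ratio (knock-down vs
    control ordering).  The percentage is rounded half-up.
    """
    from ._util import percent

    sub = diff[diff["tested"]]
    if interactor_set is not None:
        sub = sub.loc[sub.index.intersection(pd.Index(interactor_set))]
    n_quant = len(sub)
    reduced = sub["significant"] & (sub["log2_ratio"] < 0)
    n_red = int(reduced.sum())
    return {
        "n_quantified": n_quant,
        "n_reduced": n_red,
        "fraction": n_red / n_quant if n_quant else float("nan"),
        "percent": percent(n_red, n_quant) if n_quant else None,
    }
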