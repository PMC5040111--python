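"""Dissimilarity-based community statistics.

Horn dissimilarity here is the abundance-based Morisita-Horn index,
bounded in [0, 1] and invariant to per-sample rescaling; permutational
MANOVA (pseudo-F on a distance matrix) and the Mantel test use label
permutations with exhaustive enumeration whenever the number of distinct
permutations is small. Alpha diversity uses natural logarithms.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Enumerate permutations exhaustively when their count is at most this.
MAX_EXHAUSTIVE = 10_000


def _as_matrix(m: pd.DataFrame | np.ndarray, min_samples: int = 2) -> pd.DataFrame:
    if isinstance(m, pd.DataFrame):
        frame = m
    else:
        arr = np.asarray(m, dtype=float)
        frame = pd.DataFrame(arr, index=[f"S{i}" for i in range(arr.shape[0])])
    if (frame.to_numpy() < 0).any():
        raise ValueError("abundance matrix has negative entries")
    if frame.shape[0] < min_samples:
        raise ValueError(f"need at least {min_samples} samples")
    return frame


def horn_dissimilarity_matrix(
    m: pd.DataFrame | np.ndarray, variant: str = "morisita"
) -> pd.DataFrame:
    """Pairwise Horn dissimilarity between samples (rows).

    ``variant="morisita"`` (default) is the abundance-based Morisita-Horn:

        d(x, y) = 1 - 2 sum(x_i y_i) /
                  [(sum(x_i^2)/X^2 + sum(y_i^2)/Y^2) * X * Y]

    with X = sum x, Y = sum y. ``variant="horn1966"`` is the ln-based Horn
    overlap on relative abundances p, q:

        d = 1 - [sum (p+q) ln(p+q) - sum p ln p - sum q ln q] / (2 ln 2).

    Both are in [0, 1], zero for proportional compositions, one for
    disjoint supports, and invariant to per-sample rescaling.
    """
    frame = _as_matrix(m)
    x = frame.to_numpy(dtype=float)
    totals = x.sum(axis=1)
    if (totals == 0).any():
        bad = [frame.index[i] for i in np.flatnonzero(totals == 0)]
        raise ValueError(f"all-zero sample(s): {bad}")
    if variant == "morisita":
        simpson = (x**2).sum(axis=1) / totals**2  # sum p_i^2 per sample
        cross = x @ x.T
        denom = (simpson[:, None] + simpson[None, :]) * np.outer(totals, totals)
        d = 1.0 - 2.0 * cross / denom
    elif variant == "horn1966":
        p = x / totals[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log(p), 0.0).sum(axis=1)
        n = p.shape[0]
        d = np.empty((n, n))
        for i in range(n):
            for j in range(i, n):
                s = p[i] + p[j]
                with np.errstate(divide="ignore", invalid="ignore"):
                    slogs = np.where(s > 0, s * np.log(s), 0.0).sum()
                overlap = (slogs - plogp[i] - plogp[j]) / (2.0 * np.log(2.0))
                d[i, j] = d[j, i] = 1.0 - overlap
    else:
        raise ValueError(f"unknown variant {variant!r}")
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 1.0)
    d = 0.5 * (d + d.T)
    return pd.DataFrame(d, index=frame.index, columns=frame.index)


def _check_distance(d: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    if not isinstance(d, pd.DataFrame):
        arr = np.asarray(d, dtype=float)
        d = pd.DataFrame(arr, index=[f"S{i}" for i in range(arr.shape[0])],
                         columns=[f"S{i}" for i in range(arr.shape[0])])
    arr = d.to_numpy(dtype=float)
    if arr.shape[0] != arr.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(arr, arr.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(arr), 0):
        raise ValueError("distance matrix must have a zero diagonal")
    return d


@dataclass
class AdonisResult:
    pseudo_F: float
    p_value: float
    n_permutations: int
    exhaustive: bool


def _pseudo_f(d2: np.ndarray, membership: np.ndarray) -> float:
    """PERMANOVA pseudo-F for a two-group partition from squared distances."""
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in (0, 1):
        idx = np.flatnonzero(membership == g)
        if len(idx) < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    df_between = 1
    df_within = n - 2
    return (ss_between / df_between) / (ss_within / df_within)


def adonis_pairwise(
    d: pd.DataFrame | np.ndarray,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
) -> AdonisResult:
    """Two-group permutational MANOVA on a distance matrix.

    ``groups`` maps each sample label (or position) to one of exactly two
    group labels. Label permutations are unrestricted; all distinct
    assignments are enumerated when there are at most
    :data:`MAX_EXHAUSTIVE` of them (p = #{F_perm >= F_obs} / total,
    identity included), otherwise ``n_perm`` Monte-Carlo draws are used
    with p = (count + 1) / (n_perm + 1).
    """
    d = _check_distance(d)
    if isinstance(groups, dict):
        labels = np.array([groups[s] for s in d.index])
    else:
        labels = np.asarray(list(groups))
        if len(labels) != d.shape[0]:
            raise ValueError("groups length does not match distance matrix")
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"need exactly two groups, got {list(uniq)}")
    membership = (labels == uniq[1]).astype(int)
    counts = np.bincount(membership, minlength=2)
    if counts.min() < 2:
        raise ValueError("each group needs at least 2 samples")

    d2 = d.to_numpy(dtype=float) ** 2
    n = d2.shape[0]
    f_obs = _pseudo_f(d2, membership)
    tol = 1e-12 * max(1.0, abs(f_obs))

    total = math.comb(n, int(counts[1]))
    if total <= MAX_EXHAUSTIVE:
        count = 0
        for ones in itertools.combinations(range(n), int(counts[1])):
            perm = np.zeros(n, dtype=int)
            perm[list(ones)] = 1
            if _pseudo_f(d2, perm) >= f_obs - tol:
                count += 1
        return AdonisResult(float(f_obs), count / total, total, True)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(membership)
        if _pseudo_f(d2, perm) >= f_obs - tol:
            count += 1
    return AdonisResult(float(f_obs), (count + 1) / (n_perm + 1), n_perm, False)


def mantel_test(
    d1: pd.DataFrame | np.ndarray,
    d2: pd.DataFrame | np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation of the lower-triangle entries; p is
    one-tailed (greater), from jointly permuting the row/column order of
    the second matrix — exhaustively over all n! relabelings when
    n! <= :data:`MAX_EXHAUSTIVE`.
    """
    d1 = _check_distance(d1)
    d2 = _check_distance(d2)
    if d1.shape != d2.shape:
        raise ValueError("distance matrices must have the same shape")
    if list(d1.index) != list(d2.index):
        d2 = d2.loc[d1.index, d1.index]
    n = d1.shape[0]
    if n < 3:
        raise ValueError("Mantel test needs at least 3 samples")
    a1 = d1.to_numpy(dtype=float)
    a2 = d2.to_numpy(dtype=float)
    il = np.tril_indices(n, k=-1)
    v1 = a1[il]
    if np.ptp(v1) == 0 or np.ptp(a2[il]) == 0:
        raise ValueError("constant distance matrix; correlation undefined")

    def _corr(order: np.ndarray) -> float:
        v2 = a2[np.ix_(order, order)][il]
        return float(np.corrcoef(v1, v2)[0, 1])

    identity = np.arange(n)
    r_obs = _corr(identity)
    tol = 1e-12

    if math.factorial(n) <= MAX_EXHAUSTIVE:
        count = 0
        total = 0
        for order in itertools.permutations(range(n)):
            total += 1
            if _corr(np.array(order)) >= r_obs - tol:
                count += 1
        return r_obs, count / total

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if _corr(rng.permutation(n)) >= r_obs - tol:
            count += 1
    return r_obs, (count + 1) / (n_perm + 1)


def alpha_diversity(m: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Per-sample richness, evenness, Shannon, Simpson, inverse Simpson.

    Shannon H = -sum p ln p; Simpson D = sum p^2; inverse Simpson = 1/D;
    evenness = H / ln(richness) (missing when richness = 1).
    """
    frame = _as_matrix(m, min_samples=1)
    x = frame.to_numpy(dtype=float)
    totals = x.sum(axis=1)
    if (totals == 0).any():
        bad = [frame.index[i] for i in np.flatnonzero(totals == 0)]
        raise ValueError(f"all-zero sample(s): {bad}")
    p = x / totals[:, None]
    richness = (x > 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    shannon = -plogp.sum(axis=1)
    simpson = (p**2).sum(axis=1)
    inv_simpson = 1.0 / simpson
    with np.errstate(divide="ignore", invalid="ignore"):
        evenness = np.where(richness > 1, shannon / np.log(richness), np.nan)
    return pd.DataFrame(
        {
            "richness": richness,
            "evenness": evenness,
            "shannon": shannon,
            "simpson": simpson,
            "inv_simpson": inv_simpson,
        },
        index=frame.index,
    )


def load_abundance_matrix(path, meta_columns: tuple[str, ...] = ()) -> tuple[
    pd.DataFrame, pd.DataFrame
]:
    """Read a samples x features TSV; returns (abundances, metadata)."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    meta = table[list(meta_columns)] if meta_columns else table.iloc[:, :0]
    data = table.drop(columns=list(meta_columns))
    return data.astype(float), meta


def write_distance_matrix(d: pd.DataFrame, path) -> None:
    d.to_csv(path, sep="\t")


def load_distance_matrix(path) -> pd.DataFrame:
    return _check_distance(pd.read_csv(path, sep="\t", index_col=0))
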