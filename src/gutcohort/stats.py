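"""Dissimilarity, ordination, hypothesis tests and temporal stability.

Community change is measured with the Bray-Curtis dissimilarity
d(i,j) = sum_k |x_ik - x_jk| / sum_k (x_ik + x_jk); group structure is
examined through principal-coordinate analysis (classical metric
scaling), within- vs between-group contrasts of the pairwise distances
(Wilcoxon rank-sum), and PERMANOVA, whose R^2 = SS_between / SS_total
attributes community variance to design factors and whose significance
comes from label permutation.  The longitudinal arm adds a sampling-
interval contrast (consecutive months vs gaps longer than six months)
and the per-feature stability classification (present at every one of an
individual's time points vs transient).

Caveat carried over from the study design: the Wilcoxon tests on
pairwise-distance lists ignore the non-independence of pairs that share
a sample; they are descriptive contrasts, not exact tests.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from scipy.spatial.distance import pdist, squareform

from .data_model import AbundanceTable, DistanceMatrix, Metadata

__all__ = [
    "bray_curtis",
    "pcoa",
    "PCoAResult",
    "group_contrast",
    "GroupContrast",
    "wilcoxon",
    "permanova",
    "PermanovaResult",
    "factor_sweep",
    "interval_classify",
    "stability",
    "StabilityResult",
]


def bray_curtis(table: AbundanceTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities between samples."""
    x = table.values
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    zero = x.sum(axis=1) <= 0
    if zero.any():
        bad = [table.sample_ids[i] for i in np.flatnonzero(zero)]
        raise ValueError(f"all-zero abundance sample(s): {bad}")
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(d, table.sample_ids)


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    proportion_explained: np.ndarray
    negative_eigen_fraction: float  # |sum of negative eigvals| / sum |eigvals|


def pcoa(d: DistanceMatrix, n_axes: int = 2) -> PCoAResult:
    """Classical scaling (principal coordinates) of a distance matrix.

    Double-centers -d^2/2, takes the eigendecomposition, and keeps the
    top ``n_axes`` positive eigenvalues; negative eigenvalues (possible
    for non-Euclidean dissimilarities such as Bray-Curtis) are dropped
    and their relative magnitude reported.  For a Euclidean-embeddable
    matrix the coordinates reproduce the distances exactly.
    """
    n = len(d)
    a = -0.5 * d.values**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ a @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = 1e-9 * max(abs(eigvals).max(), 1.0)
    pos = eigvals > tol
    neg_frac = float(abs(eigvals[eigvals < -tol]).sum() / max(abs(eigvals).sum(), tol))
    rank = int(pos.sum())
    if n_axes > rank:
        warnings.warn(f"requested {n_axes} axes but rank is {rank}; truncating")
        n_axes = rank
    lam = eigvals[pos][:n_axes]
    coords = eigvecs[:, pos][:, :n_axes] * np.sqrt(lam)
    total_pos = eigvals[pos].sum()
    frame = pd.DataFrame(
        coords, index=d.ids, columns=[f"PCo{i+1}" for i in range(n_axes)]
    )
    return PCoAResult(frame, eigvals[pos], lam / total_pos, neg_frac)


# ---------------------------------------------------------------------------
# rank-sum contrast


def wilcoxon(x, y, method: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration p when the pooled size is at most 12 with no ties,
    otherwise the normal approximation with midranks, tie correction and
    continuity correction (``method`` forces 'exact' or 'normal').
    Returns (U statistic of x, two-sided p).  If every value in both
    lists is identical the test is degenerate and p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(x.size * y.size / 2), 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    if method == "auto":
        method = "exact" if (x.size + y.size <= 12 and not has_ties) else "normal"
    scipy_method = {"exact": "exact", "normal": "asymptotic"}[method]
    res = sp_stats.mannwhitneyu(
        x, y, alternative="two-sided", method=scipy_method, use_continuity=True
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


@dataclass
class GroupContrast:
    label_within: str
    label_between: str
    within: np.ndarray
    between: np.ndarray
    statistic: float
    p_value: float


def group_contrast(
    d: DistanceMatrix, meta: Metadata, factor: str, scheme: str = "within_vs_between"
) -> GroupContrast:
    """Within-level vs between-level contrast of pairwise distances.

    Partitions the strict upper triangle of ``d`` by whether the two
    samples share the ``factor`` level, then runs the Wilcoxon rank-sum
    on the two lists.  Levels with fewer than 2 samples contribute no
    within pairs (warning); a single-level factor leaves the between list
    empty and is an error.
    """
    if scheme != "within_vs_between":
        raise ValueError(f"unknown scheme {scheme!r}")
    labels = meta.column(factor, d.ids)
    keep = labels.notna().to_numpy()
    if not keep.all():
        d = d.submatrix([s for s, k in zip(d.ids, keep) if k])
        labels = labels[keep]
    values = labels.to_numpy()
    counts = pd.Series(values).value_counts()
    small = counts[counts < 2]
    if len(small):
        warnings.warn(
            f"factor {factor!r}: level(s) {list(small.index)} have <2 samples "
            "and contribute no within pairs"
        )
    n = len(d)
    iu, ju = np.triu_indices(n, k=1)
    same = values[iu] == values[ju]
    within = d.values[iu[same], ju[same]]
    between = d.values[iu[~same], ju[~same]]
    if between.size == 0:
        raise ValueError(f"factor {factor!r} has a single level: no between pairs")
    if within.size == 0:
        raise ValueError(f"factor {factor!r}: no within pairs")
    stat, p = wilcoxon(within, between)
    return GroupContrast(
        f"within {factor}", f"between {factor}", within, between, stat, p
    )


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaResult:
    factor: str
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int
    n_samples: int
    seed: int | None = None


def _ss_within_all(d2: np.ndarray, label_codes: np.ndarray, n_levels: int) -> np.ndarray:
    """SS_within for each row of label codes (n_perm x n), vectorized."""
    n_perm, n = label_codes.shape
    out = np.empty(n_perm)
    for g in range(n_levels):
        mask = (label_codes == g).astype(float)  # n_perm x n
        ng = mask.sum(axis=1)
        quad = np.einsum("pi,ij,pj->p", mask, d2, mask)
        with np.errstate(invalid="ignore", divide="ignore"):
            out_g = np.where(ng > 0, quad / (2 * np.maximum(ng, 1)), 0.0)
        if g == 0:
            out = out_g
        else:
            out = out + out_g
    return out


def permanova(
    d: DistanceMatrix,
    meta: Metadata,
    factor: str,
    n_perm: int = 999,
    seed: int | None = 0,
) -> PermanovaResult:
    """One-factor PERMANOVA on a distance matrix.

    SS_total = sum_{i<j} d_ij^2 / n; SS_within sums the analogous
    quantity per level; R^2 = SS_between / SS_total; the pseudo-F uses
    (a-1, n-a) degrees of freedom, and p = (1 + #{F_perm >= F_obs}) /
    (1 + n_perm) under free label permutation with the given seed.
    """
    labels = meta.column(factor, d.ids)
    keep = labels.notna().to_numpy()
    ids = [s for s, k in zip(d.ids, keep) if k]
    if len(ids) < len(d.ids):
        d = d.submatrix(ids)
        labels = labels[keep]
    codes, levels = pd.factorize(labels.to_numpy())
    a = len(levels)
    n = len(d)
    if a < 2:
        raise ValueError(f"factor {factor!r} has a single level")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    d2 = d.values**2
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = _ss_within_all(d2, codes[np.newaxis, :], a)[0]
    ss_between = ss_total - ss_within
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    df_b, df_w = a - 1, n - a
    f_obs = _pseudo_f(ss_between, ss_within, df_b, df_w)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(codes) for _ in range(n_perm)])
    ss_w_perm = _ss_within_all(d2, perms, a)
    f_perm = _pseudo_f(ss_total - ss_w_perm, ss_w_perm, df_b, df_w)
    b = int((f_perm >= f_obs - 1e-12).sum())
    p = (1 + b) / (1 + n_perm)
    return PermanovaResult(factor, float(f_obs), float(r2), float(p), n_perm, n, seed)


def _pseudo_f(ss_between, ss_within, df_b: int, df_w: int):
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df_b) / (np.asarray(ss_within) / max(df_w, 1))
    return np.where(np.asarray(ss_within) <= 1e-300, np.inf, f) if np.ndim(f) else f


def factor_sweep(
    d: DistanceMatrix,
    meta: Metadata,
    factors: list[str],
    n_perm: int = 999,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Marginal PERMANOVA per factor, sorted by R^2 (descending).

    Samples missing a factor are dropped for that factor only;
    single-level factors are skipped with a warning.
    """
    rows = []
    for i, factor in enumerate(factors):
        sub_seed = None if seed is None else seed + i
        try:
            res = permanova(d, meta, factor, n_perm=n_perm, seed=sub_seed)
        except ValueError as exc:
            warnings.warn(f"factor {factor!r} skipped: {exc}")
            continue
        rows.append(
            (factor, res.r_squared, res.pseudo_f, res.p_value, res.n_samples)
        )
    out = pd.DataFrame(
        rows, columns=["factor", "r_squared", "pseudo_f", "p_value", "n_samples"]
    ).set_index("factor")
    return out.sort_values("r_squared", ascending=False)


# ---------------------------------------------------------------------------
# temporal rules


def interval_classify(month_i: int | None, month_j: int | None) -> str:
    """Sampling-interval class: consecutive months are 'short', gaps of
    more than 6 months are 'long', anything else 'other'."""
    if month_i is None or month_j is None or pd.isna(month_i) or pd.isna(month_j):
        raise ValueError("month index missing")
    delta = abs(int(month_i) - int(month_j))
    if delta == 1:
        return "short"
    if delta > 6:
        return "long"
    return "other"


def interval_contrast(d: DistanceMatrix, meta: Metadata) -> pd.DataFrame:
    """Within-participant pair distances labeled by interval class."""
    part = meta.column("participant_id", d.ids).to_numpy()
    months = meta.column("month_index", d.ids).to_numpy()
    rows = []
    n = len(d)
    for i, j in itertools.combinations(range(n), 2):
        if part[i] != part[j]:
            continue
        rows.append(
            (
                part[i],
                interval_classify(months[i], months[j]),
                float(d.values[i, j]),
            )
        )
    return pd.DataFrame(rows, columns=["participant_id", "interval", "distance"])


@dataclass
class StabilityResult:
    per_participant: pd.DataFrame  # rows (feature, participant) -> label
    cohort_stable: pd.Series  # feature -> bool
    vf_stable: pd.DataFrame  # rows (feature, participant) -> bool at >fraction

    def label(self, feature: str, participant: str) -> str:
        return self.per_participant.loc[(feature, participant), "label"]


def stability(
    presence: pd.DataFrame, meta: Metadata, vf_fraction: float = 0.6
) -> StabilityResult:
    """Classify features (taxa/ARGs/VFs) by within-individual persistence.

    ``presence`` is a feature x sample boolean frame over longitudinal
    samples.  A feature is *individual-stable* for a participant when it
    is present at every one of that participant's time points, otherwise
    *transient*; it is *cohort-stable* when present in every sample of
    every participant.  The virulence-factor stability flag is the
    strictly-greater rule: present in more than ``vf_fraction`` of a
    participant's samples.  Participants with a single sample are
    excluded with a warning.
    """
    part = meta.column("participant_id", list(presence.columns))
    counts = part.value_counts()
    single = counts[counts < 2]
    if len(single):
        warnings.warn(
            f"participant(s) {list(single.index)} have one sample; excluded"
        )
    keep = [s for s in presence.columns if counts[part[s]] >= 2]
    presence = presence[keep].astype(bool)
    part = part[keep]
    rows = []
    vf_rows = []
    participants = sorted(part.unique())
    for feature in presence.index:
        for pid in participants:
            cols = part.index[part == pid]
            vals = presence.loc[feature, cols]
            label = "individual_stable" if bool(vals.all()) else "transient"
            rows.append((feature, pid, label, float(vals.mean())))
            vf_rows.append((feature, pid, float(vals.mean()) > vf_fraction))
    per_part = pd.DataFrame(
        rows, columns=["feature", "participant", "label", "fraction_present"]
    ).set_index(["feature", "participant"])
    cohort = per_part.groupby(level="feature")["label"].agg(
        lambda s: bool((s == "individual_stable").all())
    )
    cohort.name = "cohort_stable"
    vf = pd.DataFrame(
        vf_rows, columns=["feature", "participant", "vf_stable"]
    ).set_index(["feature", "participant"])
    return StabilityResult(per_part, cohort, vf)
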