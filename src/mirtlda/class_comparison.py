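"""Univariate and multivariate class-comparison statistics.

Implements the statistics used to compare expression classes on
control-normalized CT data:

* pooled-variance two-sample t-test (nominal level 0.05 per assay);
* the random-variance moderated t-test, which shares variance
  information across assays through an inverse-gamma prior on the
  per-assay variance (precision ~ Gamma(a, scale=b)); marginally the
  scaled sample variance a*b*s2 follows F(n, 2a), the shrunken variance
  is (n*s2 + 2/b) / (n + 2a) and the null distribution is t with
  n + 2a degrees of freedom — valuable at the very small group sizes of
  qPCR cohort studies;
* Benjamini-Hochberg adjusted p-values;
* label-permutation machinery: per-assay permutation p-values (exact by
  enumeration when the number of distinct assignments is small), a
  global test counting assays significant at a stringent level, and a
  multivariate permutation selection that bounds the false-discovery
  proportion with stated confidence;
* a one-way F-test across more than two classes.

All statistics accept NaN-masked matrices (assays x samples) and are
vectorized across assays; permutations are vectorized across both assays
and permutations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb

import numpy as np
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .errors import FitError, ValidationError
from .normalization import (
    NormalizedMatrix,
    RelativeQuantification,
    compute_rq,
    fc_bin,
    group_fold_change,
)

__all__ = [
    "ComparisonResult",
    "RvmHyperparameters",
    "MultivariatePermutationResult",
    "two_sample_t",
    "fit_rvm",
    "rvm_t",
    "bh_fdr",
    "univariate_permutation_p",
    "global_permutation_test",
    "multivariate_permutation_select",
    "multiclass_f_test",
    "compare_classes",
    "pooled_t_stats",
]


@dataclass
class ComparisonResult:
    """Per-assay record of a class comparison (one report-table row)."""

    assay_id: str
    fc: float | None
    log2_fc: float | None
    fc_bin: str | None
    t_or_f: float
    p: float
    fdr_bh: float
    perm_p: float | None = None
    class_means: dict[str, float] = field(default_factory=dict)
    flagged: bool = False


@dataclass
class RvmHyperparameters:
    """Inverse-gamma prior on assay variances: precision ~ Gamma(a, scale=b)."""

    a: float
    b: float
    log_likelihood: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValidationError("RVM hyperparameters must be positive")


@dataclass
class MultivariatePermutationResult:
    selected_assays: list
    p_cutoff: float
    confidence_level: float
    fdr_bound: float
    n_permutations: int
    false_count_bound: float


# ---------------------------------------------------------------------------
# Vectorized group summaries
# ---------------------------------------------------------------------------


def _group_summary(X: np.ndarray, idx: np.ndarray):
    """Per-assay n, mean and sum of squared deviations over one column set,
    NaN-aware."""
    sub = X[:, idx]
    finite = np.isfinite(sub)
    n = finite.sum(axis=1)
    vals = np.where(finite, sub, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = vals.sum(axis=1) / n
        ss = (np.where(finite, (sub - mean[:, None]) ** 2, 0.0)).sum(axis=1)
    return n, mean, ss


def pooled_t_stats(X: np.ndarray, idx1, idx2):
    """Pooled two-sample t per assay row of ``X`` (NaN = missing).

    Returns ``(t, p, df, sp2, m1, m2, n1, n2)``.  Degenerate assays
    (pooled variance 0 or fewer than 2 values in a class) get t=0, p=1.
    """
    idx1 = np.asarray(idx1, dtype=int)
    idx2 = np.asarray(idx2, dtype=int)
    n1, m1, ss1 = _group_summary(X, idx1)
    n2, m2, ss2 = _group_summary(X, idx2)
    df = n1 + n2 - 2
    ok = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        sp2 = np.where(df > 0, (ss1 + ss2) / np.where(df > 0, df, 1), np.nan)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        t = (m1 - m2) / se
    degenerate = ~ok | ~np.isfinite(t)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1)))
    return t, p, df, sp2, m1, m2, n1, n2


def two_sample_t(x, y) -> tuple[float, float]:
    """Pooled-variance two-sided two-sample t-test on 1-D samples
    (NaN entries dropped)."""
    x = np.asarray(x, dtype=float)[None, :]
    y = np.asarray(y, dtype=float)[None, :]
    X = np.concatenate([x, y], axis=1)
    t, p, *_ = pooled_t_stats(
        X, np.arange(x.shape[1]), np.arange(x.shape[1], X.shape[1])
    )
    return float(t[0]), float(p[0])


# ---------------------------------------------------------------------------
# Random variance model
# ---------------------------------------------------------------------------


def _rvm_nll(theta, s2, n):
    # closed form of -sum log[ f_F(a*b*s2; n, 2a) * a*b ]: substituting
    # x = a*b*s2 into the F density leaves the data entering only through
    # u = n*b*s2/2
    a, b = np.exp(theta)
    u = n * b * s2 / 2.0
    ll = (
        (n / 2.0) * np.log(n * b / 2.0)
        + (n / 2.0 - 1.0) * np.log(s2)
        - (n / 2.0 + a) * np.log1p(u)
        - special.betaln(n / 2.0, a)
    )
    if not np.all(np.isfinite(ll)):
        return 1e12
    return -ll.sum()


def _rvm_nll_grad(theta, s2, n):
    # d(-logL)/d(log a), d(-logL)/d(log b); the n*b*s2/2 term is the only
    # place the data enter once x = a*b*s2 is substituted into the F density
    a, b = np.exp(theta)
    u = 1.0 + n * b * s2 / 2.0
    dla = a * np.sum(np.log(u) - special.digamma(n / 2.0 + a) + special.digamma(a))
    dlb = -np.sum(n / 2.0 - (n + 2.0 * a) * (n * b * s2 / 4.0) / u)
    return np.array([dla, dlb])


def fit_rvm(variances, dfs) -> RvmHyperparameters:
    """Maximum-likelihood fit of the variance prior.

    Under the model, a*b*s2_i ~ F(n_i, 2a) independently across assays.
    Zero variances carry no likelihood information under the continuous
    model and are excluded; at least 10 informative assays are required.
    Deterministic given inputs.
    """
    s2 = np.asarray(variances, dtype=float)
    n = np.asarray(dfs, dtype=float)
    keep = np.isfinite(s2) & (s2 > 0) & (n >= 1)
    s2, n = s2[keep], n[keep]
    if s2.size < 10:
        raise FitError(f"need >=10 positive variances, got {s2.size}")
    mean_s2 = float(np.mean(s2))
    x0 = np.log([2.0, 1.0 / max(mean_s2, 1e-12)])
    # bounded in log space: very large `a` is the total-shrinkage limit
    # (all variances equal) and is a legitimate boundary solution
    bounds = [(np.log(1e-6), np.log(1e7)), (np.log(1e-12), np.log(1e12))]
    res = optimize.minimize(
        _rvm_nll, x0, args=(s2, n), jac=_rvm_nll_grad, method="L-BFGS-B", bounds=bounds
    )
    # a solution pinned at the large-`a` bound (total shrinkage) is valid;
    # only retry when the optimizer returned something non-finite or worse
    # than the start
    acceptable = (
        np.all(np.isfinite(res.x))
        and np.isfinite(res.fun)
        and res.fun <= _rvm_nll(x0, s2, n) + 1e-9
    )
    if not acceptable:
        res = optimize.minimize(
            _rvm_nll,
            np.clip(x0, -20, 15),
            args=(s2, n),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000},
        )
    if not np.all(np.isfinite(res.x)) or not np.isfinite(res.fun):
        raise FitError(f"variance-prior fit did not converge: {res.message}")
    a, b = np.exp(res.x)
    return RvmHyperparameters(a=float(a), b=float(b), log_likelihood=float(-res.fun))


def rvm_shrunken_variance(sp2, df, hyper: RvmHyperparameters):
    """Posterior-mean style combination of the assay's pooled variance and
    the prior, with df + 2a degrees of freedom."""
    return (df * sp2 + 2.0 / hyper.b) / (df + 2.0 * hyper.a)


def rvm_t_stats(X: np.ndarray, idx1, idx2, hyper: RvmHyperparameters):
    """Vectorized random-variance t per assay row; returns (t, p, df_aug)."""
    t0, p0, df, sp2, m1, m2, n1, n2 = pooled_t_stats(X, idx1, idx2)
    ok = (n1 >= 2) & (n2 >= 2) & (df > 0) & np.isfinite(sp2)
    df_aug = df + 2.0 * hyper.a
    with np.errstate(invalid="ignore", divide="ignore"):
        s2_shrunk = rvm_shrunken_variance(np.where(ok, sp2, 0.0), df, hyper)
        se = np.sqrt(s2_shrunk * (1.0 / n1 + 1.0 / n2))
        t = (m1 - m2) / se
    degenerate = ~ok | ~np.isfinite(t)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, 2.0 * stats.t.sf(np.abs(t), df_aug))
    return t, p, df_aug


def rvm_t(x, y, hyper: RvmHyperparameters) -> tuple[float, float]:
    """Random-variance t-test on 1-D samples (NaN entries dropped)."""
    x = np.asarray(x, dtype=float)[None, :]
    y = np.asarray(y, dtype=float)[None, :]
    X = np.concatenate([x, y], axis=1)
    t, p, _ = rvm_t_stats(
        X, np.arange(x.shape[1]), np.arange(x.shape[1], X.shape[1]), hyper
    )
    return float(t[0]), float(p[0])


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Permutation machinery
# ---------------------------------------------------------------------------


def _two_class_indices(labels):
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) != 2:
        raise ValidationError(f"need exactly 2 classes, got {classes}")
    idx1 = np.flatnonzero(labels == classes[0])
    idx2 = np.flatnonzero(labels == classes[1])
    return classes, idx1, idx2


def _stat_fn(stat: str, hyper):
    if stat == "t":
        return lambda X, i1, i2: pooled_t_stats(X, i1, i2)[:2]
    if stat == "rvm":
        if hyper is None:
            raise ValidationError("stat='rvm' requires fitted hyperparameters")
        return lambda X, i1, i2: rvm_t_stats(X, i1, i2, hyper)[:2]
    raise ValidationError(f"unknown statistic {stat!r}")


def _enumerate_assignments(n, n1):
    for combo in itertools.combinations(range(n), n1):
        idx1 = np.array(combo, dtype=int)
        idx2 = np.setdiff1d(np.arange(n), idx1)
        yield idx1, idx2


def _random_assignments(n, n1, B, rng):
    for _ in range(B):
        perm = rng.permutation(n)
        yield perm[:n1], perm[n1:]


def univariate_permutation_p(
    values,
    labels,
    B: int = 1000,
    seed: int | None = None,
    stat: str = "t",
    hyper: RvmHyperparameters | None = None,
) -> np.ndarray:
    """Per-assay two-sided permutation p-value of the chosen statistic.

    Enumerates all C(n, n1) label assignments exhaustively when that
    count does not exceed ``B`` (then p = k/K exactly, the observed
    assignment included); otherwise Monte-Carlo with the add-one
    convention p = (1 + k) / (1 + B).
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    X = np.atleast_2d(np.asarray(values, dtype=float))
    _, idx1, idx2 = _two_class_indices(labels)
    fn = _stat_fn(stat, hyper)
    t_obs = np.abs(fn(X, idx1, idx2)[0])
    n, n1 = X.shape[1], idx1.size
    exhaustive = comb(n, n1) <= B
    assignments = (
        _enumerate_assignments(n, n1)
        if exhaustive
        else _random_assignments(n, n1, B, np.random.default_rng(seed))
    )
    count = np.zeros(X.shape[0])
    total = 0
    for i1, i2 in assignments:
        t_b = np.abs(fn(X, i1, i2)[0])
        count += t_b >= t_obs - 1e-12
        total += 1
    if exhaustive:
        return count / total
    return (1.0 + count) / (1.0 + total)


def global_permutation_test(
    matrix,
    labels,
    alpha: float = 0.001,
    B: int = 999,
    seed: int | None = None,
    stat: str = "t",
    hyper: RvmHyperparameters | None = None,
) -> float:
    """Global test of any class difference: permute labels, recompute all
    per-assay p-values and count those significant at ``alpha``; the
    global p is the proportion of permutations with at least as many
    significant assays as observed."""
    X = _as_matrix(matrix)
    _, idx1, idx2 = _two_class_indices(labels)
    fn = _stat_fn(stat, hyper)
    obs = int(np.sum(fn(X, idx1, idx2)[1] <= alpha))
    rng = np.random.default_rng(seed)
    n, n1 = X.shape[1], idx1.size
    hits = 0
    for i1, i2 in _random_assignments(n, n1, B, rng):
        hits += int(np.sum(fn(X, i1, i2)[1] <= alpha)) >= obs
    return hits / B


def multivariate_permutation_select(
    matrix,
    labels,
    confidence: float = 0.90,
    fdr_bound: float = 0.10,
    B: int = 1000,
    seed: int | None = None,
    stat: str = "rvm",
    hyper: RvmHyperparameters | None = None,
    assay_ids=None,
) -> MultivariatePermutationResult:
    """Select assays so that, with the stated confidence over the
    permutation distribution, the false-discovery proportion is below
    ``fdr_bound``.

    Candidate cutoffs are the ranked observed p-values p_(1) <= ... <=
    p_(G).  For each cutoff, label permutations estimate the distribution
    of the number of assays a null dataset would pass; the selection is
    the largest k whose ``confidence``-quantile of that count, divided by
    k, stays below the bound.  ``confidence=0`` degenerates to the
    expected-false-count rule.
    """
    if B < 100:
        raise ValidationError("need B >= 100 permutations for quantile estimation")
    X = _as_matrix(matrix)
    _, idx1, idx2 = _two_class_indices(labels)
    if stat == "rvm" and hyper is None:
        _, _, df, sp2, *_ = pooled_t_stats(X, idx1, idx2)
        hyper = fit_rvm(sp2, df)
    fn = _stat_fn(stat, hyper)
    p_obs = fn(X, idx1, idx2)[1]
    order = np.argsort(p_obs, kind="stable")
    p_sorted = p_obs[order]

    rng = np.random.default_rng(seed)
    n, n1 = X.shape[1], idx1.size
    perm_sorted = np.empty((B, p_obs.size))
    for b, (i1, i2) in enumerate(_random_assignments(n, n1, B, rng)):
        perm_sorted[b] = np.sort(fn(X, i1, i2)[1])

    # counts[b, k] = how many permuted p-values fall at or below p_(k+1)
    counts = np.stack(
        [np.searchsorted(perm_sorted[b], p_sorted + 1e-15, side="right") for b in range(B)]
    )
    if confidence <= 0:
        bound = counts.mean(axis=0)
    else:
        q_idx = min(B - 1, int(np.ceil(confidence * B)) - 1)
        bound = np.sort(counts, axis=0)[q_idx]
    ks = np.arange(1, p_obs.size + 1)
    admissible = np.flatnonzero(bound / ks <= fdr_bound)
    if admissible.size == 0:
        k_sel, cutoff, fbound = 0, 0.0, 0.0
    else:
        k_sel = int(admissible[-1]) + 1
        cutoff = float(p_sorted[k_sel - 1])
        fbound = float(bound[k_sel - 1])
    selected_idx = order[:k_sel]
    ids = (
        [assay_ids[i] for i in selected_idx]
        if assay_ids is not None
        else selected_idx.tolist()
    )
    return MultivariatePermutationResult(
        selected_assays=ids,
        p_cutoff=cutoff,
        confidence_level=confidence,
        fdr_bound=fdr_bound,
        n_permutations=B,
        false_count_bound=fbound,
    )


# ---------------------------------------------------------------------------
# Multi-class F-test
# ---------------------------------------------------------------------------


def multiclass_f_test(values, labels) -> tuple[np.ndarray, np.ndarray]:
    """One-way ANOVA F and p per assay row (NaN-aware).

    Classes with a single member contribute to the between-class term
    only (their within-class sum of squares is zero) — the standard
    decomposition handles this, at the cost of within degrees of freedom.
    """
    X = np.atleast_2d(np.asarray(values, dtype=float))
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) < 2:
        raise ValidationError("need at least 2 classes")
    parts = [_group_summary(X, np.flatnonzero(labels == c)) for c in classes]
    ns = np.stack([p[0] for p in parts])
    means = np.stack([p[1] for p in parts])
    ssw = np.stack([p[2] for p in parts]).sum(axis=0)
    N = ns.sum(axis=0)
    k_eff = (ns > 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        grand = np.nansum(np.where(ns > 0, ns * means, 0.0), axis=0) / N
        ssb = np.nansum(
            np.where(ns > 0, ns * (means - grand) ** 2, 0.0), axis=0
        )
        df_b = k_eff - 1
        df_w = N - k_eff
        F = (ssb / df_b) / (ssw / df_w)
    degenerate = ~np.isfinite(F) | (df_w <= 0) | (df_b <= 0)
    F = np.where(degenerate, 0.0, F)
    p = np.where(
        degenerate,
        1.0,
        stats.f.sf(F, np.maximum(df_b, 1), np.maximum(df_w, 1)),
    )
    if F.size == 1:
        return float(F[0]), float(p[0])
    return F, p


# ---------------------------------------------------------------------------
# End-to-end contrast driver
# ---------------------------------------------------------------------------


def _as_matrix(matrix) -> np.ndarray:
    if isinstance(matrix, NormalizedMatrix):
        return matrix.values_nan()
    return np.asarray(matrix, dtype=float)


def _groups_from_annotations(annotations):
    groups: dict[str, list[str]] = {}
    for a in annotations:
        groups.setdefault(a.group, []).append(a.sample_id)
    return groups


def compare_classes(
    norm: NormalizedMatrix,
    annotations,
    contrast,
    mode: str = "I",
    calibrator_id: str | None = None,
    alpha: float = 0.05,
    n_permutations: int = 0,
    seed: int | None = None,
    sample_subset: dict[str, list[str]] | None = None,
) -> list[ComparisonResult]:
    """Run one class comparison end to end and return per-assay records
    sorted by p-value.

    ``contrast`` is a pair of group labels for a two-class comparison or
    a ``{class label: [sample ids]}`` dict for a multi-class F-test.
    ``mode='I'`` is the relative-quantification route (plain t on log2 RQ,
    fold changes against a calibrator); ``mode='II'`` operates on the
    control-normalized CT values with the random-variance t and optional
    permutation p-values.  ``sample_subset`` restricts a pairwise
    contrast's groups (e.g. to a clinical-stage subset).
    """
    X_dct = norm.values_nan()
    log2_intensity = -X_dct  # log2 scale, higher = more expressed
    results: list[ComparisonResult] = []

    if isinstance(contrast, dict):  # multi-class F-test
        sample_pos = {s: i for i, s in enumerate(norm.sample_ids)}
        labels = np.empty(len(norm.sample_ids), dtype=object)
        used = np.zeros(len(norm.sample_ids), dtype=bool)
        for cls, ids in contrast.items():
            for s in ids:
                labels[sample_pos[s]] = cls
                used[sample_pos[s]] = True
        sub = log2_intensity[:, used]
        F, p = multiclass_f_test(sub, labels[used])
        fdr = bh_fdr(p)
        perm_p = None
        if n_permutations > 0:
            perm_p = _multiclass_permutation_p(sub, labels[used], n_permutations, seed)
        class_order = list(contrast)
        for i, assay in enumerate(norm.assay_ids):
            means = {
                cls: float(
                    2.0
                    ** np.nanmean(
                        log2_intensity[i, [sample_pos[s] for s in contrast[cls]]]
                    )
                )
                for cls in class_order
            }
            results.append(
                ComparisonResult(
                    assay_id=assay,
                    fc=None,
                    log2_fc=None,
                    fc_bin=None,
                    t_or_f=float(F[i]),
                    p=float(p[i]),
                    fdr_bh=float(fdr[i]),
                    perm_p=float(perm_p[i]) if perm_p is not None else None,
                    class_means=means,
                    flagged=p[i] == 1.0 and F[i] == 0.0,
                )
            )
        results.sort(key=lambda r: (r.p, r.assay_id))
        return results

    g1, g2 = contrast
    groups = _groups_from_annotations(annotations)
    if sample_subset is not None:
        groups = {
            g: [s for s in ids if s in set(sample_subset.get(g, ids))]
            for g, ids in groups.items()
        }
    for g in (g1, g2):
        if g not in groups or not groups[g]:
            raise ValidationError(f"contrast group {g!r} empty")
    sample_pos = {s: i for i, s in enumerate(norm.sample_ids)}
    idx1 = np.array([sample_pos[s] for s in groups[g1]])
    idx2 = np.array([sample_pos[s] for s in groups[g2]])

    if mode == "I":
        if calibrator_id is None:
            calibrators = [a.sample_id for a in annotations if a.is_calibrator]
            if len(calibrators) != 1:
                raise ValidationError("mode I needs a unique calibrator sample")
            calibrator_id = calibrators[0]
        rq = compute_rq(norm, calibrator_id)
        t, p, *_ = pooled_t_stats(log2_intensity, idx1, idx2)
        fcs = group_fold_change(rq, groups, g1, g2)
        hyper = None
    elif mode == "II":
        _, _, df, sp2, *_ = pooled_t_stats(log2_intensity, idx1, idx2)
        hyper = fit_rvm(sp2, df)
        t, p, _ = rvm_t_stats(log2_intensity, idx1, idx2, hyper)
        fcs = None
    else:
        raise ValidationError(f"unknown analysis mode {mode!r}")

    fdr = bh_fdr(p)
    perm_p = None
    if n_permutations > 0:
        perm_p = univariate_permutation_p(
            log2_intensity[:, np.concatenate([idx1, idx2])],
            np.array([g1] * idx1.size + [g2] * idx2.size, dtype=object),
            B=n_permutations,
            seed=seed,
            stat="rvm" if mode == "II" else "t",
            hyper=hyper,
        )
    with np.errstate(invalid="ignore"):
        gm1 = 2.0 ** np.nanmean(log2_intensity[:, idx1], axis=1)
        gm2 = 2.0 ** np.nanmean(log2_intensity[:, idx2], axis=1)
    for i, assay in enumerate(norm.assay_ids):
        if fcs is not None:
            rec = fcs[i]
            fc, lfc, fbin = (
                (rec.fc, rec.log2_fc, rec.fc_bin) if rec.evaluable else (None,) * 3
            )
        else:
            ratio = gm1[i] / gm2[i]
            fc = float(ratio) if np.isfinite(ratio) else None
            lfc = float(np.log2(ratio)) if fc else None
            fbin = fc_bin(fc) if fc else None
        results.append(
            ComparisonResult(
                assay_id=assay,
                fc=fc,
                log2_fc=lfc,
                fc_bin=fbin,
                t_or_f=float(t[i]),
                p=float(p[i]),
                fdr_bh=float(fdr[i]),
                perm_p=float(perm_p[i]) if perm_p is not None else None,
                class_means={g1: float(gm1[i]), g2: float(gm2[i])},
                flagged=(p[i] == 1.0 and t[i] == 0.0),
            )
        )
    results.sort(key=lambda r: (r.p, r.assay_id))
    return results


def _multiclass_permutation_p(X, labels, B, seed):
    rng = np.random.default_rng(seed)
    _, p_obs = _f_as_arrays(X, labels)
    count = np.zeros(X.shape[0])
    lab = np.asarray(labels).copy()
    for _ in range(B):
        rng.shuffle(lab)
        _, p_b = _f_as_arrays(X, lab)
        count += p_b <= p_obs + 1e-15
    return (1.0 + count) / (1.0 + B)


def _f_as_arrays(X, labels):
    out = multiclass_f_test(X, labels)
    F, p = out
    return np.atleast_1d(F), np.atleast_1d(p)
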