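"""Donor-level statistics and multivariate summaries of dependence profiles.

Covers the analyses typically run downstream of the dependence metrics:
paired t tests between conditions within donors, Dunnett-style many-to-one
comparisons against an unstimulated control (family-wise error controlled by
a seeded Monte-Carlo approximation of the joint max-|t| null over the
equicorrelated statistics of the paired design), Sidak-corrected pairwise
contrasts, and PCA of per-sample dependence profiles with ranked loadings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import StatsError

GLUCOSE_METRIC = "glucose_dependence"
MITO_METRIC = "mitochondrial_dependence"


@dataclass(frozen=True)
class PairedTestResult:
    statistic: float
    pvalue: float
    n: int
    df: int


def paired_difference_test(x, y) -> PairedTestResult:
    """Two-sided paired t test on within-donor differences.

    Pairs with a missing value on either side are dropped; fewer than three
    complete pairs is an error.  All-zero differences give t = 0, p = 1.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise StatsError(f"paired test needs equal lengths, got {x.size} and {y.size}")
    keep = np.isfinite(x) & np.isfinite(y)
    d = x[keep] - y[keep]
    n = int(d.size)
    if n < 3:
        raise StatsError(f"paired test needs >= 3 complete pairs, got {n}")
    if np.all(d == 0):
        return PairedTestResult(statistic=0.0, pvalue=1.0, n=n, df=n - 1)
    res = sps.ttest_rel(x[keep], y[keep])
    pvalue = float(res.pvalue)
    if not np.isfinite(pvalue):  # zero-variance nonzero differences
        pvalue = 0.0
    return PairedTestResult(
        statistic=float(res.statistic), pvalue=pvalue, n=n, df=n - 1
    )


def _paired_t_stats(values: np.ndarray) -> np.ndarray:
    """Paired t statistics of columns 1.. vs column 0, vectorized over sims.

    ``values`` has shape (n_sims, n_donors, n_groups); returns
    (n_sims, n_groups - 1).
    """
    diffs = values[:, :, 1:] - values[:, :, :1]
    n = diffs.shape[1]
    mean = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    return np.where(np.isfinite(t), t, 0.0)


def compare_to_control(
    data: pd.DataFrame,
    control: str = "Medium",
    value: str = "value",
    group: str = "group",
    donor: str = "donor",
    n_mc: int = 20000,
    seed: int = 0,
) -> pd.DataFrame:
    """Many-to-one comparisons of each group against a shared control.

    Repeated-measures design: every donor contributes one value per group, and
    each non-control group is compared to the control by a paired t test on
    within-donor differences.  Because all comparisons share the control
    donor values, the test statistics are equicorrelated; the family-wise
    adjustment is Dunnett-style, estimating ``P(max_j |T_j| >= |t_j|)`` under
    the joint null by seeded Monte-Carlo over that correlated statistic.
    A family of size one reduces exactly to the raw paired t.

    Returns a data frame with one row per non-control group: statistic,
    raw p, adjusted p (always >= raw), and n donors.
    """
    for col in (value, group, donor):
        if col not in data.columns:
            raise StatsError(f"column {col!r} missing from data")
    wide = data.pivot_table(index=donor, columns=group, values=value, aggfunc="mean")
    if control not in wide.columns:
        raise StatsError(f"control group {control!r} not present")
    missing = wide.isna()
    if missing.to_numpy().any():
        named = [
            f"(donor={wide.index[d]}, group={wide.columns[g]})"
            for d, g in zip(*np.nonzero(missing.to_numpy()))
        ]
        raise StatsError("unbalanced design; missing cells: " + ", ".join(named))
    groups = [c for c in wide.columns if c != control]
    n_donors = wide.shape[0]
    if n_donors < 3:
        raise StatsError(f"need >= 3 donors, got {n_donors}")

    observed = _paired_t_stats(
        wide[[control] + groups].to_numpy()[None, :, :]
    )[0]
    raw = 2.0 * sps.t.sf(np.abs(observed), df=n_donors - 1)

    if len(groups) == 1:
        adjusted = raw.copy()
    else:
        rng = np.random.default_rng(seed)
        null = rng.standard_normal(size=(n_mc, n_donors, len(groups) + 1))
        max_abs = np.abs(_paired_t_stats(null)).max(axis=1)
        # add-one Monte-Carlo p; monotone vs raw by construction of max
        adjusted = np.array(
            [
                (1.0 + np.count_nonzero(max_abs >= abs(t))) / (n_mc + 1.0)
                for t in observed
            ]
        )
        adjusted = np.maximum(adjusted, raw)
    return pd.DataFrame(
        {
            "group": groups,
            "statistic": observed,
            "raw_p": raw,
            "adjusted_p": np.clip(adjusted, 0.0, 1.0),
            "n_donors": n_donors,
            "method": "dunnett_mc",
        }
    )


def sidak_adjust(p: float | np.ndarray, k: int) -> float | np.ndarray:
    """Sidak family-wise correction: ``1 - (1 - p)^k`` for a family of size k."""
    if k < 1:
        raise StatsError(f"family size must be >= 1, got {k}")
    return 1.0 - (1.0 - np.asarray(p, dtype=np.float64)) ** k


def pairwise_condition_tests(
    data: pd.DataFrame,
    contrasts: list[tuple[tuple[str, str], tuple[str, str]]],
    factor_a: str,
    factor_b: str,
    value: str = "value",
    donor: str = "donor",
) -> pd.DataFrame:
    """Paired contrasts between cells of a two-factor layout, Sidak-adjusted.

    Each contrast names two (factor_a level, factor_b level) cells; the cells
    are compared by a paired t test across donors and the whole family of
    contrasts is corrected with the Sidak closed form ``1 - (1 - p)^k``.
    Every referenced cell must be complete for all donors.
    """
    if not contrasts:
        raise StatsError("no contrasts given")
    wide = data.pivot_table(
        index=donor, columns=[factor_a, factor_b], values=value, aggfunc="mean"
    )
    needed = {cell for pair in contrasts for cell in pair}
    missing = [cell for cell in needed if cell not in wide.columns]
    if missing:
        raise StatsError(f"missing cells in two-factor layout: {sorted(missing)}")
    sub = wide[list(needed)]
    if sub.isna().to_numpy().any():
        raise StatsError("two-factor layout incomplete across donors")
    k = len(contrasts)
    rows = []
    for cell_1, cell_2 in contrasts:
        res = paired_difference_test(wide[cell_1], wide[cell_2])
        rows.append(
            {
                "contrast": f"{cell_1} vs {cell_2}",
                "statistic": res.statistic,
                "raw_p": res.pvalue,
                "adjusted_p": float(sidak_adjust(res.pvalue, k)),
                "n_donors": res.n,
                "method": f"sidak_k{k}",
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PCAResult:
    """PCA of a samples x features profile matrix.

    ``scores`` are samples x components, ``loadings`` features x components
    with orthonormal columns, ``explained_variance_fraction`` non-increasing.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_fraction: np.ndarray
    dropped_samples: list = field(default_factory=list)
    dropped_features: list = field(default_factory=list)


def build_profile_matrix(
    profiles: pd.DataFrame,
    sample: str = "sample_id",
    population: str = "population",
    metrics: tuple[str, ...] = (GLUCOSE_METRIC, MITO_METRIC),
) -> pd.DataFrame:
    """Pivot tidy profiles into samples x ``population:metric`` features.

    Only the two dependence metrics enter by default: the capacities are
    their affine complements and would duplicate every axis of variance.
    """
    for col in (sample, population, *metrics):
        if col not in profiles.columns:
            raise StatsError(f"column {col!r} missing from profiles")
    blocks = []
    for metric in metrics:
        wide = profiles.pivot_table(
            index=sample, columns=population, values=metric, aggfunc="mean"
        )
        wide.columns = [f"{pop}:{metric}" for pop in wide.columns]
        blocks.append(wide)
    matrix = pd.concat(blocks, axis=1)
    return matrix[sorted(matrix.columns)]


def pca_profiles(
    matrix: pd.DataFrame, n_components: int | None = None, scale: bool = True
) -> PCAResult:
    """PCA of the profile matrix (complete-case rows, centered, unit-variance).

    Zero-variance features are dropped with a note; the sign of each component
    is fixed so its largest-|loading| feature loads positively.
    """
    complete = matrix.dropna(axis=0)
    dropped_samples = [s for s in matrix.index if s not in complete.index]
    if complete.shape[0] < 2:
        raise StatsError(f"PCA needs >= 2 complete samples, got {complete.shape[0]}")
    variances = complete.var(axis=0, ddof=1)
    dropped_features = [c for c in complete.columns if variances[c] == 0]
    kept = complete.drop(columns=dropped_features)
    if kept.shape[1] < 2:
        raise StatsError(
            f"PCA needs >= 2 features with nonzero variance, got {kept.shape[1]}"
        )
    x = kept.to_numpy(dtype=np.float64)
    x = x - x.mean(axis=0)
    if scale:
        x = x / x.std(axis=0, ddof=1)
    max_components = min(x.shape[0] - 1, x.shape[1])
    k = max_components if n_components is None else min(n_components, max_components)

    u, s, vt = np.linalg.svd(x, full_matrices=False)
    total = float((s**2).sum())
    # component sign: largest-|loading| feature loads positively; ties by
    # feature order (ascending names if the matrix is name-sorted)
    for j in range(len(s)):
        lead = int(np.argmax(np.abs(vt[j])))
        if vt[j, lead] < 0:
            vt[j] = -vt[j]
            u[:, j] = -u[:, j]
    scores = u[:, :k] * s[:k]
    comp_names = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=kept.index, columns=comp_names),
        loadings=pd.DataFrame(vt[:k].T, index=kept.columns, columns=comp_names),
        explained_variance_fraction=(s[:k] ** 2) / total,
        dropped_samples=dropped_samples,
        dropped_features=dropped_features,
    )


def top_loadings(result: PCAResult, component: str | int = "PC1", k: int = 10
                 ) -> pd.DataFrame:
    """The k features with the largest |loading| on one component.

    Ties are broken by feature name ascending.  The metric class column says
    whether the feature is a glucose- or mitochondrial-dependence measure.
    """
    name = f"PC{component}" if isinstance(component, int) else component
    if name not in result.loadings.columns:
        raise StatsError(
            f"component {name!r} not in result (have {list(result.loadings.columns)})"
        )
    frame = pd.DataFrame(
        {
            "feature": result.loadings.index,
            "loading": result.loadings[name].to_numpy(),
        }
    )
    frame["abs_loading"] = frame["loading"].abs()
    frame["metric_class"] = [
        f.rsplit(":", 1)[1] if ":" in f else "" for f in frame["feature"]
    ]
    frame = frame.sort_values(
        ["abs_loading", "feature"], ascending=[False, True], kind="mergesort"
    ).head(min(k, frame.shape[0]))
    return frame.drop(columns="abs_loading").reset_index(drop=True)
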