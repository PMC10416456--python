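"""Per-peak m6A dynamics: differential calls, origin, change classes, clusters.

A peak is differential between two stages when its normalized-level fold
change exceeds ``fc_threshold`` (symmetric, max/min) AND a Pearson chi-square
test on the raw 2x2 [[ip1, in1], [ip2, in2]] table gives p below ``alpha``.
The three consecutive transitions of the 4-stage course define the
change-count classes (0..3); the origin of a peak is the earliest stage
where its level exceeds the modified threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .io_formats import STAGES, StageCounts

FC_THRESHOLD = 1.2
ALPHA = 0.05


def transitions(stages: tuple[str, ...] = STAGES) -> list[tuple[str, str]]:
    """The consecutive stage pairs, e.g. (D0,D2), (D2,D5), (D5,D15)."""
    return list(zip(stages[:-1], stages[1:]))


def symmetric_fold_change(a, b):
    """max(a,b)/min(a,b) elementwise; direction-free fold change."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    with np.errstate(divide="ignore"):
        return np.maximum(a, b) / np.minimum(a, b)


def _chi2_2x2(ip1, in1, ip2, in2):
    """Vectorized Pearson chi-square (1 df, no continuity correction)."""
    a, b, c, d = (np.asarray(x, dtype=float) for x in (ip1, in1, ip2, in2))
    n = a + b + c + d
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    stat = np.where(n > 0, stat, np.nan)
    return stat, stats.chi2.sf(stat, df=1)


def differential_peak(
    ip1,
    in1,
    ip2,
    in2,
    fc_threshold: float = FC_THRESHOLD,
    alpha: float = ALPHA,
    libsizes: tuple[float, float, float, float] | None = None,
) -> pd.DataFrame:
    """Differential m6A call between two stages (vectorized over peaks).

    ``libsizes`` is (ip_lib1, input_lib1, ip_lib2, input_lib2) for the
    normalized levels entering the fold change; if omitted the libraries are
    assumed equal.  The chi-square table's odds are only comparable across
    stages when the IP/input library balance is the same, so the input
    column is rescaled by each stage's balance relative to their geometric
    mean before testing; with equal balances (in particular, equal library
    sizes) this reduces exactly to the plain Pearson chi-square on the raw
    counts.  When any expected cell of the table is below 1 the peak is
    flagged ``low_count`` and p comes from Fisher's exact test.
    """
    ip1 = np.atleast_1d(np.asarray(ip1, dtype=float))
    in1 = np.atleast_1d(np.asarray(in1, dtype=float))
    ip2 = np.atleast_1d(np.asarray(ip2, dtype=float))
    in2 = np.atleast_1d(np.asarray(in2, dtype=float))
    if libsizes is None:
        libsizes = (1.0, 1.0, 1.0, 1.0)
    l_ip1, l_in1, l_ip2, l_in2 = libsizes
    r1 = (ip1 / l_ip1) / (in1 / l_in1)
    r2 = (ip2 / l_ip2) / (in2 / l_in2)
    fc = symmetric_fold_change(r1, r2)

    b1 = l_ip1 / l_in1
    b2 = l_ip2 / l_in2
    b_mid = np.sqrt(b1 * b2)
    in1_adj = in1 * (b1 / b_mid)
    in2_adj = in2 * (b2 / b_mid)
    stat, p = _chi2_2x2(ip1, in1_adj, ip2, in2_adj)

    n = ip1 + in1_adj + ip2 + in2_adj
    with np.errstate(divide="ignore", invalid="ignore"):
        expected_min = (
            np.minimum(ip1 + in1_adj, ip2 + in2_adj)
            * np.minimum(ip1 + ip2, in1_adj + in2_adj)
            / n
        )
    low = (expected_min < 1.0) | ~np.isfinite(stat)
    if low.any():
        p = p.copy()
        for i in np.flatnonzero(low):
            table = np.round(
                [[ip1[i], in1_adj[i]], [ip2[i], in2_adj[i]]]
            ).astype(int)
            p[i] = stats.fisher_exact(table).pvalue
    return pd.DataFrame(
        {
            "fold_change": fc,
            "chi2": stat,
            "p": p,
            "low_count": low,
            "is_differential": (fc > fc_threshold) & (p < alpha),
        }
    )


def transition_differentials(
    counts: StageCounts,
    fc_threshold: float = FC_THRESHOLD,
    alpha: float = ALPHA,
) -> dict[str, pd.DataFrame]:
    """Differential calls for each consecutive stage transition.

    Returns a dict keyed ``"D0->D2"`` etc.; each frame carries a BH-adjusted
    p column (``p_bh``) for reference, but classification uses raw p.
    """
    out = {}
    for s1, s2 in transitions(counts.stages):
        df = differential_peak(
            counts.ip[s1],
            counts.input[s1],
            counts.ip[s2],
            counts.input[s2],
            fc_threshold=fc_threshold,
            alpha=alpha,
            libsizes=(
                counts.ip_libsize[s1],
                counts.input_libsize[s1],
                counts.ip_libsize[s2],
                counts.input_libsize[s2],
            ),
        )
        df.index = counts.peak_ids
        df["p_bh"] = multipletests(df.p.fillna(1.0), method="fdr_bh")[1]
        out[f"{s1}->{s2}"] = df
    return out


def differential_flags(
    diffs: dict[str, pd.DataFrame], fc_only: bool = False, fc_threshold: float = FC_THRESHOLD
) -> pd.DataFrame:
    """Boolean peak x transition matrix of differential calls.

    With ``fc_only`` the chi-square gate is ignored and only the fold-change
    criterion is applied (useful on noiseless levels, where any change is
    trivially significant at infinite depth).
    """
    cols = {}
    for name, df in diffs.items():
        cols[name] = (df.fold_change > fc_threshold) if fc_only else df.is_differential
    return pd.DataFrame(cols)


def level_change_flags(
    levels: pd.DataFrame, fc_threshold: float = FC_THRESHOLD
) -> pd.DataFrame:
    """Fold-change-only change calls computed directly from a level matrix."""
    cols = {}
    for s1, s2 in transitions(tuple(levels.columns)):
        fc = symmetric_fold_change(levels[s1], levels[s2])
        cols[f"{s1}->{s2}"] = pd.Series(fc > fc_threshold, index=levels.index)
    return pd.DataFrame(cols)


def call_modified(
    peak_level: pd.DataFrame, threshold: float = 1.5
) -> pd.DataFrame:
    """Per-stage modified flag: level strictly greater than ``threshold``."""
    return peak_level.gt(threshold)


def peak_origin(modified: pd.DataFrame) -> pd.Series:
    """Earliest stage at which each peak is modified; 'never' if none."""
    stages = list(modified.columns)
    arr = modified.to_numpy(dtype=bool)
    first = np.where(arr.any(axis=1), arr.argmax(axis=1), -1)
    labels = np.array(stages + ["never"], dtype=object)
    out = pd.Series(labels[first], index=modified.index, name="origin")
    return out


def change_classes(diff_flags: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Number of differential transitions per peak plus class fractions."""
    count = diff_flags.sum(axis=1).astype(int)
    count.name = "change_count"
    frac = count.value_counts(normalize=True).reindex(range(4), fill_value=0.0)
    frac.index.name = "change_count"
    frac.name = "fraction"
    return count, frac


def dynamic_genes(
    gene_level: pd.DataFrame, fc_threshold: float = FC_THRESHOLD
) -> pd.Series:
    """Genes whose pooled m6A level changes by more than the fold threshold
    in at least one consecutive transition."""
    flags = level_change_flags(gene_level, fc_threshold=fc_threshold)
    out = flags.any(axis=1)
    out.name = "dynamic"
    return out


def cluster_profiles(
    peak_level: pd.DataFrame, k: int = 8, seed: int = 0, n_init: int = 10
) -> tuple[pd.Series, np.ndarray, pd.Series]:
    """K-means on row-z-scored level profiles.

    Constant rows (zero variance, no z-score) are flagged and assigned to the
    centroid nearest the zero profile.  Returns (labels, centroids, flags).
    """
    if len(peak_level) < k:
        raise ValueError(f"need at least k={k} peaks, got {len(peak_level)}")
    x = peak_level.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    constant = sd[:, 0] == 0
    z = np.zeros_like(x)
    ok = ~constant
    z[ok] = (x[ok] - mu[ok]) / sd[ok]
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    labels = np.empty(len(x), dtype=int)
    labels[ok] = km.fit_predict(z[ok])
    if constant.any():
        labels[constant] = km.predict(z[constant])
    return (
        pd.Series(labels, index=peak_level.index, name="cluster"),
        km.cluster_centers_,
        pd.Series(constant, index=peak_level.index, name="constant_profile"),
    )


def dispersion_scores(expression: pd.DataFrame, log2_transform: bool = True) -> pd.Series:
    """Expression dispersion score: sample SD (ddof=1) across the stages.

    Computed on log2(x+1) of the normalized expression by default, so the
    score is invariant to a common rescaling only up to the +1 offset;
    a fully common scale should be applied upstream.
    """
    x = expression.astype(float)
    if log2_transform:
        x = np.log2(x + 1.0)
    out = x.std(axis=1, ddof=1)
    out.name = "dispersion_score"
    return out


def overlap_test(set_a, set_b, universe) -> tuple[int, float]:
    """One-tailed hypergeometric overlap test: P(X >= |A & B|).

    X ~ Hypergeometric(|U|, |A|, |B|); both sets must be subsets of the
    universe.
    """
    u = set(universe)
    if not u:
        raise ValueError("empty universe")
    a = set(set_a)
    b = set(set_b)
    if not a <= u or not b <= u:
        raise ValueError("sets must be subsets of the universe")
    k = len(a & b)
    p = float(stats.hypergeom.sf(k - 1, len(u), len(a), len(b)))
    return k, p


@dataclass
class PeakDynamics:
    """Bundle of per-peak dynamics results."""

    differentials: dict[str, pd.DataFrame]
    change_count: pd.Series
    class_fractions: pd.Series
    modified: pd.DataFrame
    origin: pd.Series
    clusters: pd.Series


def analyze_peaks(
    counts: StageCounts,
    peak_level: pd.DataFrame,
    fc_threshold: float = FC_THRESHOLD,
    alpha: float = ALPHA,
    mod_threshold: float = 1.5,
    k: int = 8,
    seed: int = 0,
) -> PeakDynamics:
    """Full per-peak dynamics analysis on filtered counts and levels."""
    diffs = transition_differentials(counts, fc_threshold=fc_threshold, alpha=alpha)
    flags = differential_flags(diffs)
    count, frac = change_classes(flags)
    modified = call_modified(peak_level, threshold=mod_threshold)
    origin = peak_origin(modified)
    clusters, _, _ = cluster_profiles(peak_level, k=k, seed=seed)
    return PeakDynamics(diffs, count, frac, modified, origin, clusters)
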