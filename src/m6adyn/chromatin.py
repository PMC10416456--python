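"""Chromatin-accessibility x m6A integration.

Gene-level accessibility (pre-aggregated ATAC signal) is compared against
m6A levels via rank-sum tests, a five-category co-dynamics classification,
PCC-binned change profiles, and stage overlaps.  Categories:

1. no change in either signal
2. accessibility changes only
3. m6A changes only
4. both change with contrasting trends (discordant)
5. both change with similar trends (concordant)

"Change" reuses the m6A fold-change rule (any consecutive transition with
symmetric fold change above the threshold); concordance is the sign of the
Pearson correlation between the two 3-point change-ratio vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dynamics import FC_THRESHOLD, level_change_flags, symmetric_fold_change, transitions
from .regulators import pcc

CATEGORY_NAMES = {
    1: "no_change",
    2: "access_only",
    3: "m6a_only",
    4: "discordant",
    5: "concordant",
}

#: m6A-level group bounds: low < 1.5 <= medium <= 4 < high
M6A_GROUP_BOUNDS = (1.5, 4.0)


def rank_sum_test(x, y) -> float:
    """Two-sided Mann-Whitney (Wilcoxon rank-sum) p-value.

    Exact null distribution when both groups are small (min n <= 20) and
    tie-free; otherwise the tie-corrected normal approximation without
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("rank-sum test needs non-empty groups")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(x), len(y)) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=False
    )
    return float(res.pvalue)


def compare_target_accessibility(
    targets,
    accessibility: pd.DataFrame,
    seed: int = 0,
    min_targets: int = 3,
) -> pd.DataFrame | None:
    """Per-stage accessibility of target genes vs all genes vs a random set.

    The random control is a uniform sample (without replacement) of the same
    size, fixed by ``seed``.  Returns None (with a warning) if fewer than
    ``min_targets`` targets are present in the matrix.
    """
    targets = pd.Index(targets).intersection(accessibility.index)
    if len(targets) < min_targets:
        warnings.warn(
            f"only {len(targets)} targets with accessibility; comparison skipped"
        )
        return None
    rng = np.random.default_rng(seed)
    rand = pd.Index(
        rng.choice(accessibility.index.to_numpy(), size=len(targets), replace=False)
    )
    rows = {}
    for s in accessibility.columns:
        t = accessibility.loc[targets, s]
        a = accessibility[s]
        r = accessibility.loc[rand, s]
        rows[s] = {
            "median_targets": t.median(),
            "median_random": r.median(),
            "median_all": a.median(),
            "p_vs_all": rank_sum_test(t, a),
            "p_vs_random": rank_sum_test(t, r),
            "n_targets": len(t),
        }
    out = pd.DataFrame(rows).T
    out.index.name = "stage"
    return out


def accessibility_groups(
    accessibility: pd.Series, low_frac: float = 0.10, high_frac: float = 0.10
) -> pd.Series:
    """Rank genes by accessibility into low10 / mid / high10 groups.

    Group sizes are floor(frac*n); ties broken by gene id for determinism.
    """
    order = accessibility.reset_index()
    order.columns = ["gene_id", "v"]
    order = order.sort_values(["v", "gene_id"], ascending=[True, True])
    n = len(order)
    n_low = int(np.floor(low_frac * n))
    n_high = int(np.floor(high_frac * n))
    group = pd.Series("mid", index=accessibility.index, name="access_group", dtype=object)
    group[order.gene_id.head(n_low)] = "low10"
    group[order.gene_id.tail(n_high)] = "high10"
    return group


def m6a_by_accessibility_group(
    accessibility: pd.DataFrame,
    gene_level: pd.DataFrame,
    low_frac: float = 0.10,
    high_frac: float = 0.10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Median m6A per accessibility group per stage, plus pairwise rank-sum p."""
    common = accessibility.index.intersection(gene_level.index)
    med_rows, p_rows = {}, {}
    for s in gene_level.columns:
        grp = accessibility_groups(accessibility.loc[common, s], low_frac, high_frac)
        vals = gene_level.loc[common, s]
        med_rows[s] = {g: vals[grp == g].median() for g in ("low10", "mid", "high10")}
        p_rows[s] = {
            f"{a}_vs_{b}": rank_sum_test(vals[grp == a], vals[grp == b])
            for a, b in (("low10", "mid"), ("mid", "high10"), ("low10", "high10"))
        }
    medians = pd.DataFrame(med_rows).T.rename_axis("stage")
    pvals = pd.DataFrame(p_rows).T.rename_axis("stage")
    return medians, pvals


def accessibility_of_modified_vs_unmodified(
    modified: pd.DataFrame, accessibility: pd.DataFrame
) -> pd.DataFrame:
    """Per-stage accessibility comparison of m6A-modified vs unmodified genes."""
    common = modified.index.intersection(accessibility.index)
    rows = {}
    for s in modified.columns:
        flags = modified.loc[common, s].astype(bool)
        a = accessibility.loc[common, s]
        if flags.all() or (~flags).all():
            raise ValueError(f"one group is empty at stage {s}")
        rows[s] = {
            "median_modified": a[flags].median(),
            "median_unmodified": a[~flags].median(),
            "n_modified": int(flags.sum()),
            "n_unmodified": int((~flags).sum()),
            "p": rank_sum_test(a[flags], a[~flags]),
        }
    out = pd.DataFrame(rows).T
    out.index.name = "stage"
    return out


# ---------------------------------------------------------------------------
# co-dynamics categories
# ---------------------------------------------------------------------------


def _change_ratios(levels: pd.DataFrame) -> pd.DataFrame:
    """value(s+1)/value(s) over the consecutive transitions."""
    cols = {}
    for s1, s2 in transitions(tuple(levels.columns)):
        cols[f"{s1}->{s2}"] = levels[s2] / levels[s1]
    return pd.DataFrame(cols)


@dataclass
class CoDynamicsLabels:
    """Whole-trajectory and per-transition co-dynamics categories."""

    category: pd.Series
    per_transition: pd.DataFrame
    degenerate: pd.Series
    m6a_ratios: pd.DataFrame
    access_ratios: pd.DataFrame


def co_dynamics_categories(
    gene_level: pd.DataFrame,
    accessibility: pd.DataFrame,
    fc_threshold: float = FC_THRESHOLD,
) -> CoDynamicsLabels:
    """Assign each gene a co-dynamics category (1..5).

    Whole-trajectory: m6A (accessibility) "changed" iff any consecutive
    symmetric fold change exceeds the threshold; when both change, the sign
    of the PCC between the two change-ratio vectors separates concordant (5)
    from discordant (4); a zero/undefined PCC falls to 4 with a degenerate
    flag.  Per-transition labels use the same rule transition-wise, with
    concordance decided by the two ratios being on the same side of 1.
    """
    common = gene_level.index.intersection(accessibility.index)
    m = gene_level.loc[common]
    a = accessibility.loc[common, m.columns]
    m_changed_t = level_change_flags(m, fc_threshold)
    a_changed_t = level_change_flags(a, fc_threshold)
    m_ratios = _change_ratios(m)
    a_ratios = _change_ratios(a)

    m_changed = m_changed_t.any(axis=1)
    a_changed = a_changed_t.any(axis=1)
    cat = pd.Series(1, index=common, name="category", dtype=int)
    cat[a_changed & ~m_changed] = 2
    cat[m_changed & ~a_changed] = 3
    both = m_changed & a_changed
    degenerate = pd.Series(False, index=common, name="degenerate")
    for g in common[both]:
        r = pcc(m_ratios.loc[g], a_ratios.loc[g])
        if np.isnan(r) or r == 0:
            cat[g] = 4
            degenerate[g] = True
        else:
            cat[g] = 5 if r > 0 else 4

    per = pd.DataFrame(1, index=common, columns=m_ratios.columns, dtype=int)
    for t in m_ratios.columns:
        mc = m_changed_t[t]
        ac = a_changed_t[t]
        per.loc[ac & ~mc, t] = 2
        per.loc[mc & ~ac, t] = 3
        b = mc & ac
        same = (m_ratios[t] - 1) * (a_ratios[t] - 1) > 0
        per.loc[b & same, t] = 5
        per.loc[b & ~same, t] = 4
    return CoDynamicsLabels(cat, per, degenerate, m_ratios, a_ratios)


def pcc_bins(
    gene_level: pd.DataFrame,
    accessibility: pd.DataFrame,
    n_bins: int = 18,
    drop_frac: float = 0.05,
) -> tuple[pd.DataFrame, pd.Series]:
    """Mean |log2 m6A fold change| per transition across PCC-ranked bins.

    Genes are ranked by the PCC of their m6A and accessibility trajectories;
    the top and bottom floor(drop_frac*n) are dropped and the remainder is
    split into ``n_bins`` groups whose sizes differ by at most one.
    """
    common = gene_level.index.intersection(accessibility.index)
    m = gene_level.loc[common]
    a = accessibility.loc[common, m.columns]
    r = pd.Series(
        [pcc(m.loc[g], a.loc[g]) for g in common], index=common, name="pcc"
    ).dropna()
    order = r.reset_index()
    order.columns = ["gene_id", "r"]
    order = order.sort_values(["r", "gene_id"], ascending=[True, True])
    n = len(order)
    n_drop = int(np.floor(drop_frac * n))
    kept = order.gene_id.iloc[n_drop : n - n_drop].to_numpy()
    if len(kept) < n_bins:
        raise ValueError("too few genes with defined PCC for the requested bins")
    chunks = np.array_split(kept, n_bins)
    ratios = _change_ratios(m)
    abs_lfc = np.abs(np.log2(ratios))
    rows = {
        i: abs_lfc.loc[chunk].mean() for i, chunk in enumerate(chunks)
    }
    binned = pd.DataFrame(rows).T
    binned.index.name = "pcc_bin"
    sizes = pd.Series([len(c) for c in chunks], name="n_genes").rename_axis("pcc_bin")
    binned["n_genes"] = sizes
    return binned, r


def category_overlap(per_transition: pd.DataFrame) -> pd.DataFrame:
    """Cross-window overlap structure of each category.

    For every category, the per-window counts, all pairwise intersection
    sizes, the triple intersection, and the number of genes consistent in
    all windows (same as the full intersection for a fixed category).
    """
    windows = list(per_transition.columns)
    rows = {}
    for c in sorted(CATEGORY_NAMES):
        sets = {w: set(per_transition.index[per_transition[w] == c]) for w in windows}
        row = {f"n_{w}": len(sets[w]) for w in windows}
        for i in range(len(windows)):
            for j in range(i + 1, len(windows)):
                wi, wj = windows[i], windows[j]
                row[f"n_{wi}&{wj}"] = len(sets[wi] & sets[wj])
        inter = set.intersection(*sets.values()) if sets else set()
        row["n_all"] = len(inter)
        rows[c] = row
    out = pd.DataFrame(rows).T
    out.index.name = "category"
    return out


def consistent_genes(per_transition: pd.DataFrame, category: int) -> pd.Index:
    """Genes assigned the same category in every window."""
    return per_transition.index[(per_transition == category).all(axis=1)]


def ecdf_compare(groups: dict[str, pd.Series]) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Empirical CDFs per group plus pairwise two-sided rank-sum p-values."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    curves = {}
    for name, vals in groups.items():
        v = np.sort(np.asarray(vals, dtype=float))
        curves[name] = pd.DataFrame(
            {"value": v, "ecdf": np.arange(1, len(v) + 1) / len(v)}
        )
    names = list(groups)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            rows.append(
                {"group_a": a, "group_b": b, "p": rank_sum_test(groups[a], groups[b])}
            )
    return curves, pd.DataFrame(rows)


def m6a_level_groups(
    gene_level: pd.Series, bounds: tuple[float, float] = M6A_GROUP_BOUNDS
) -> pd.Series:
    """Split genes into low / medium / high m6A groups at the given bounds."""
    lo, hi = bounds
    grp = pd.Series("medium", index=gene_level.index, name="m6a_group", dtype=object)
    grp[gene_level < lo] = "low"
    grp[gene_level > hi] = "high"
    return grp


def tf_binding_by_m6a_group(
    binding: pd.DataFrame,
    gene_level: pd.DataFrame,
    bounds: tuple[float, float] = M6A_GROUP_BOUNDS,
) -> pd.DataFrame:
    """TF binding distribution per m6A-level group, with pairwise rank-sum p.

    Binding columns are named ``TF_stage`` (e.g. ``POU5F1_D0``); the m6A
    grouping uses the matching stage.  Empty pairs are skipped with a
    warning.
    """
    rows = []
    common = binding.index.intersection(gene_level.index)
    for col in binding.columns:
        tf, _, stage = col.rpartition("_")
        if stage not in gene_level.columns:
            raise ValueError(f"binding column {col!r} does not end in a stage name")
        grp = m6a_level_groups(gene_level.loc[common, stage], bounds)
        vals = binding.loc[common, col]
        medians = {g: vals[grp == g].median() for g in ("low", "medium", "high")}
        for a, b in (("low", "medium"), ("medium", "high"), ("low", "high")):
            va, vb = vals[grp == a], vals[grp == b]
            if len(va) == 0 or len(vb) == 0:
                warnings.warn(f"empty m6A group for {col}: {a} vs {b} skipped")
                p = np.nan
            else:
                p = rank_sum_test(va, vb)
            rows.append(
                {
                    "tf": tf,
                    "stage": stage,
                    "pair": f"{a}_vs_{b}",
                    "median_a": medians[a],
                    "median_b": medians[b],
                    "p": p,
                }
            )
    return pd.DataFrame(rows)
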