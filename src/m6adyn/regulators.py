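"""Writer/eraser/reader correlation analysis and target-gene discovery.

Gene-wise Pearson correlations over the four stage points relate each
regulator's expression to transcriptome-wide m6A levels and expression.
The top and bottom 5% of the ranked coefficients form the positively and
negatively correlated classes; |r| < 0.1 among the remainder is "not
correlated".  A writer's candidate targets are genes whose expression is in
the negative class while their m6A level is in the positive class (m6A
silences the transcript the writer methylates); for an eraser the signs are
reversed.  With only four points per correlation no per-gene p-value is
reported; significance is assessed only on the class overlap, with a
one-tailed hypergeometric test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import overlap_test, transitions
from .io_formats import STAGES

DEFAULT_WRITERS = ("METTL3", "METTL14", "RBM15")
DEFAULT_ERASERS = ("FTO", "ALKBH5")
DEFAULT_READERS = ("YTHDF1", "YTHDF2", "YTHDF3", "YTHDC1", "YTHDC2", "IGF2BP2")

EXTREME_FRAC = 0.05
NOT_COR_BAND = 0.1


@dataclass
class RegulatorSet:
    """Regulator expression trajectories with their roles.

    ``df`` is indexed by regulator name with a ``role`` column
    (writer/eraser/reader) and one expression column per stage.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if "role" not in self.df.columns:
            raise ValueError("RegulatorSet requires a 'role' column")
        bad = set(self.df.role) - {"writer", "eraser", "reader"}
        if bad:
            raise ValueError(f"unknown regulator roles: {sorted(bad)}")

    @classmethod
    def from_expression(
        cls,
        expression: pd.DataFrame,
        writers=DEFAULT_WRITERS,
        erasers=DEFAULT_ERASERS,
        readers=DEFAULT_READERS,
    ) -> "RegulatorSet":
        """Pull regulator rows present in an expression matrix."""
        rows = []
        for names, role in ((writers, "writer"), (erasers, "eraser"), (readers, "reader")):
            for n in names:
                if n in expression.index:
                    rows.append((n, role))
        if not rows:
            raise ValueError("no regulator genes found in the expression matrix")
        idx = [n for n, _ in rows]
        df = expression.loc[idx].copy()
        df.insert(0, "role", [r for _, r in rows])
        return cls(df)

    def expression(self, name: str) -> pd.Series:
        return self.df.loc[name].drop("role").astype(float)

    def role(self, name: str) -> str:
        return str(self.df.loc[name, "role"])

    def names(self, role: str | None = None) -> list[str]:
        if role is None:
            return list(self.df.index)
        return list(self.df.index[self.df.role == role])


def pcc(x, y) -> float:
    """Pearson correlation of two equal-length vectors; NaN if degenerate."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.std() == 0 or len(x) < 2:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def pcc_profile(matrix: pd.DataFrame, v: pd.Series) -> pd.Series:
    """Row-wise Pearson correlation of a gene x stage matrix with a vector."""
    x = matrix.to_numpy(dtype=float)
    y = v.reindex(matrix.columns).to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ yc) / (sx * sy)
    r[(sx == 0) | (sy == 0)] = np.nan
    return pd.Series(r, index=matrix.index, name="pcc")


def classify_correlations(
    r: pd.Series,
    extreme_frac: float = EXTREME_FRAC,
    not_cor_band: float = NOT_COR_BAND,
) -> pd.DataFrame:
    """Label genes pos_cor / neg_cor / not_cor / unclassified from ranked r.

    Exactly floor(extreme_frac * n_defined) genes land in each extreme class
    (ties broken by gene id for determinism); |r| < not_cor_band among the
    remainder is not_cor; everything else, and undefined r, is unclassified.
    """
    defined = r.dropna()
    n = len(defined)
    k = int(np.floor(extreme_frac * n))
    order = defined.reset_index()
    order.columns = ["gene_id", "r"]
    order = order.sort_values(["r", "gene_id"], ascending=[False, True])
    pos = set(order.gene_id.head(k))
    neg = set(order.gene_id.tail(k)[::-1]) - pos
    label = pd.Series("unclassified", index=r.index, name="label", dtype=object)
    label[r.index.isin(pos)] = "pos_cor"
    label[r.index.isin(neg)] = "neg_cor"
    mid = label.eq("unclassified") & r.notna() & (r.abs() < not_cor_band)
    label[mid] = "not_cor"
    return pd.DataFrame({"r": r, "label": label})


@dataclass
class TargetResult:
    """Candidate target genes of one regulator with the overlap test."""

    regulator: str
    role: str
    targets: pd.Index
    overlap: int
    p: float
    m6a_classes: pd.DataFrame
    expr_classes: pd.DataFrame


def identify_targets(
    regulator: str,
    role: str,
    m6a_r: pd.Series,
    expr_r: pd.Series,
    extreme_frac: float = EXTREME_FRAC,
    not_cor_band: float = NOT_COR_BAND,
) -> TargetResult:
    """Intersect the extreme correlation classes into a target set.

    Writer: (expression neg_cor) & (m6A pos_cor).  Eraser: reversed.
    The hypergeometric universe is the genes with defined r for both signals.
    """
    if role not in ("writer", "eraser"):
        raise ValueError(f"targets are defined for writers/erasers, not {role!r}")
    universe = m6a_r.dropna().index.intersection(expr_r.dropna().index)
    m6a_cls = classify_correlations(m6a_r.loc[universe], extreme_frac, not_cor_band)
    expr_cls = classify_correlations(expr_r.loc[universe], extreme_frac, not_cor_band)
    if role == "writer":
        m6a_set = m6a_cls.index[m6a_cls.label == "pos_cor"]
        expr_set = expr_cls.index[expr_cls.label == "neg_cor"]
    else:
        m6a_set = m6a_cls.index[m6a_cls.label == "neg_cor"]
        expr_set = expr_cls.index[expr_cls.label == "pos_cor"]
    targets = m6a_set.intersection(expr_set).sort_values()
    overlap, p = overlap_test(m6a_set, expr_set, universe)
    return TargetResult(regulator, role, targets, overlap, p, m6a_cls, expr_cls)


def reader_association(
    target_expression: pd.DataFrame, regulators: RegulatorSet
) -> tuple[pd.DataFrame, pd.Series]:
    """Correlate each target gene's expression with every reader's expression.

    Returns the gene x reader PCC matrix and the top reader per gene.
    """
    readers = regulators.names("reader")
    if not readers:
        raise ValueError("no readers in the regulator set")
    cols = {
        rd: pcc_profile(target_expression, regulators.expression(rd)) for rd in readers
    }
    mat = pd.DataFrame(cols)
    top = mat.idxmax(axis=1)
    top.name = "top_reader"
    return mat, top


def regulator_m6a_vs_expression(
    gene_m6a: pd.Series, gene_expression: pd.Series
) -> pd.DataFrame:
    """Stage-over-stage relative change of a regulator's own m6A level and
    expression: value(s+1)/value(s) for the three transitions."""
    stages = tuple(gene_expression.index)
    rows = {}
    for s1, s2 in transitions(stages):
        rows[f"{s1}->{s2}"] = {
            "expression_ratio": float(gene_expression[s2]) / float(gene_expression[s1]),
            "m6a_ratio": float(gene_m6a[s2]) / float(gene_m6a[s1]),
        }
    out = pd.DataFrame(rows).T
    out.index.name = "transition"
    return out


def correlate_regulators(
    gene_level: pd.DataFrame,
    expression: pd.DataFrame,
    regulators: RegulatorSet,
    names: list[str] | None = None,
    stages: tuple[str, ...] = STAGES,
) -> dict[str, dict[str, pd.Series]]:
    """Per-regulator PCC of its expression vs gene m6A levels and expression.

    The regulator's own gene is excluded from both rankings.
    """
    out = {}
    for name in names or regulators.names():
        z = regulators.expression(name).loc[list(stages)]
        m6a_r = pcc_profile(gene_level.loc[:, list(stages)], z)
        expr_r = pcc_profile(expression.loc[:, list(stages)], z)
        m6a_r = m6a_r.drop(name, errors="ignore")
        expr_r = expr_r.drop(name, errors="ignore")
        out[name] = {"m6a": m6a_r, "expression": expr_r}
    return out
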