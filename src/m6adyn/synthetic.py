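"""Synthetic 4-stage MeRIP-seq study with planted ground truth.

The generator emits everything the pipeline consumes — peak catalog (BED),
gene annotation (GTF), paired IP/input count matrices with library sizes,
normalized expression, gene-level accessibility, TF binding scores and peak
sequences — together with truth tables for every planted structure:

* per-peak methylation trajectories mu(p, s) realizing planted change
  classes (0-3 differential transitions at the 1.2 fold threshold) and
  origin stages (first crossing of the 1.5 modified threshold);
* writer/eraser target genes whose m6A and expression trajectories have an
  exact sample Pearson correlation of +-r_plant with the regulator's
  expression over the four stages;
* five co-dynamics categories coupling (or decoupling) accessibility
  changes to m6A changes.

Identifiability over four time points is delicate: the Pearson correlation
of two random 4-point trajectories is uniform on [-1, 1], so planted
couplings would drown in null extremes.  The generator therefore (a) uses
regulator expression trajectories chosen so that their correlation with any
single-transition change shape is at most 0.5, and (b) samples non-target
("uncoupled") trajectory directions under a hard bound on their correlation
with every regulator (``uncoupled_max``).  Real data offers no such
guarantee; see the methods note.

All peaks of a gene share the gene's methylation trajectory, so the pooled
gene-level ratio equals the planted trajectory exactly and peak- and
gene-level truth are mutually consistent.  Truth labels are always computed
from the noiseless trajectories with the pipeline's own rules, so planted
labels agree exactly with what the pipeline would report at infinite depth.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import chromatin, dynamics
from .io_formats import (
    STAGES,
    GeneAnnotation,
    PeakTable,
    StageCounts,
    write_gene_annotation,
    write_peaks,
)
from .regulators import RegulatorSet

# Fixed regulator expression directions (unit, mean-zero over the 4 stages).
# Chosen numerically so that |corr| <= 0.5 against each single-transition
# change shape and pairwise |corr| <= 0.46 between regulators; this keeps
# null change trajectories out of the extreme correlation classes while the
# three target sets stay mutually separable.
REGULATOR_DIRECTIONS = {
    "METTL14": np.array([-0.4217, 0.0254, 0.8077, -0.4113]),
    "RBM15": np.array([-0.3964, 0.8105, 0.0169, -0.4309]),
    "ALKBH5": np.array([0.4124, -0.5848, 0.5726, -0.4002]),
}

TARGETED_WRITERS = ("METTL14", "RBM15")
TARGETED_ERASERS = ("ALKBH5",)

OTHER_REGULATORS = {
    "METTL3": "writer",
    "FTO": "eraser",
    "YTHDF1": "reader",
    "YTHDF2": "reader",
    "YTHDF3": "reader",
    "YTHDC1": "reader",
    "YTHDC2": "reader",
    "IGF2BP2": "reader",
}


def _unit_centered(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    v = v - v.mean()
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("degenerate direction")
    return v / n


_Z = np.vstack([_unit_centered(v) for v in REGULATOR_DIRECTIONS.values()])


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the simulated 4-stage differentiation course.

    Fractions describe peaks/genes carrying m6A peaks: ``frac_unchanged``
    plus the three change-class fractions must sum to one, and the first two
    co-dynamics category fractions (no-change, accessibility-only) must sum
    to ``frac_unchanged`` since those categories imply an unchanged m6A
    trajectory.  ``depth_mean`` is the expected input count per peak;
    ``dispersion`` is the negative-binomial size (None = Poisson).
    """

    n_genes: int = 2000
    n_peaks: int = 3000
    stages: tuple[str, ...] = STAGES
    frac_genes_with_peaks: float = 0.70
    frac_unmodified: float = 0.05
    frac_unchanged: float = 0.14
    frac_change_once: float = 0.47
    frac_change_twice: float = 0.30
    frac_change_thrice: float = 0.09
    frac_origin_d0: float = 0.855
    n_targets: int = 60
    r_plant: float = 0.9
    depth_mean: float = 1000.0
    dispersion: float | None = None
    category_fracs: tuple[float, float, float, float, float] = (
        0.06,
        0.08,
        0.46,
        0.20,
        0.20,
    )
    uncoupled_max: float = 0.55
    unchanged_fc_max: float = 1.03
    changed_fc_range: tuple[float, float] = (1.35, 1.9)
    mod_threshold: float = 1.5
    fc_threshold: float = 1.2
    access_noise_sd: float = 0.02
    access_m6a_coupling: float = 0.3
    access_target_boost: float = 1.8
    access_modified_boost: float = 1.5
    frac_intergenic: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        fr = dict(
            frac_genes_with_peaks=self.frac_genes_with_peaks,
            frac_unmodified=self.frac_unmodified,
            frac_unchanged=self.frac_unchanged,
            frac_change_once=self.frac_change_once,
            frac_change_twice=self.frac_change_twice,
            frac_change_thrice=self.frac_change_thrice,
            frac_origin_d0=self.frac_origin_d0,
            frac_intergenic=self.frac_intergenic,
        )
        for k, v in fr.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{k}={v} outside [0, 1]")
        ch = self.frac_change_once + self.frac_change_twice + self.frac_change_thrice
        if abs(ch - (1.0 - self.frac_unchanged)) > 1e-9:
            raise ValueError(
                "change-class fractions must sum to 1 - frac_unchanged "
                f"({ch:.4f} vs {1 - self.frac_unchanged:.4f})"
            )
        if abs(sum(self.category_fracs) - 1.0) > 1e-9:
            raise ValueError("category fractions must sum to 1")
        if abs(self.category_fracs[0] + self.category_fracs[1] - self.frac_unchanged) > 1e-9:
            raise ValueError(
                "categories 1+2 imply an unchanged m6A trajectory; their "
                "fractions must sum to frac_unchanged"
            )
        if self.frac_origin_d0 > 1.0 - self.frac_unmodified + 1e-12:
            raise ValueError(
                "frac_origin_d0 exceeds the fraction of modified peaks "
                f"({self.frac_origin_d0} > {1 - self.frac_unmodified})"
            )
        if not 0.0 <= self.r_plant <= 1.0:
            raise ValueError("r_plant must lie in [0, 1] (0 = uncoupled)")
        if self.n_targets > self.n_genes / 10:
            raise ValueError("n_targets must not exceed n_genes / 10")
        if len(self.stages) != 4:
            raise ValueError("the design has exactly four stages")
        n_peak_genes = round(self.frac_genes_with_peaks * self.n_genes)
        n_reg = len(TARGETED_WRITERS) + len(TARGETED_ERASERS) + len(OTHER_REGULATORS)
        n_intergenic = round(self.frac_intergenic * self.n_peaks)
        if self.n_peaks - n_intergenic - n_reg < n_peak_genes:
            raise ValueError("n_peaks too small for the requested peak-bearing genes")
        if 3 * self.n_targets > n_peak_genes:
            raise ValueError("not enough peak-bearing genes for the planted targets")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.dispersion is not None and self.dispersion <= 0:
            raise ValueError("dispersion (NB size) must be positive or None")


@dataclass
class Truth:
    """Planted ground truth, with labels derived from the noiseless field."""

    peak_mu: pd.DataFrame
    gene_mu: pd.DataFrame
    peak_labels: pd.DataFrame
    gene_labels: pd.DataFrame
    access_clean: pd.DataFrame
    input_mean: pd.DataFrame
    target_map: dict[str, list[str]]


@dataclass
class SimStudy:
    """Complete simulated study: inputs for the pipeline plus the truth."""

    config: SimConfig
    peaks: PeakTable
    annotation: GeneAnnotation
    counts: StageCounts
    expression: pd.DataFrame
    accessibility: pd.DataFrame
    tf_binding: pd.DataFrame
    sequences: dict[str, str]
    regulators: RegulatorSet
    truth: Truth

    def write(self, out_dir: str | os.PathLike) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        def tsv(name: str, df: pd.DataFrame) -> None:
            p = out / f"{name}.tsv"
            df.to_csv(p, sep="\t", float_format="%.10g")
            paths[name] = p

        paths["peaks"] = out / "peaks.bed"
        write_peaks(self.peaks, paths["peaks"])
        paths["annotation"] = out / "annotation.gtf"
        write_gene_annotation(self.annotation, paths["annotation"])
        tsv("ip_counts", self.counts.ip)
        tsv("input_counts", self.counts.input)
        libs = pd.DataFrame(
            {"ip": self.counts.ip_libsize, "input": self.counts.input_libsize}
        ).T
        libs.index.name = "assay"
        tsv("libsizes", libs)
        tsv("expression", self.expression)
        tsv("accessibility", self.accessibility)
        tsv("tf_binding", self.tf_binding)
        paths["sequences"] = out / "peak_sequences.fasta"
        with open(paths["sequences"], "w") as fh:
            for pid, seq in self.sequences.items():
                fh.write(f">{pid}\n{seq}\n")
        tsv("truth_peak_mu", self.truth.peak_mu)
        tsv("truth_gene_mu", self.truth.gene_mu)
        tsv("truth_peaks", self.truth.peak_labels)
        tsv("truth_genes", self.truth.gene_labels)
        tsv("truth_accessibility", self.truth.access_clean)
        return paths


# ---------------------------------------------------------------------------
# trajectory machinery
# ---------------------------------------------------------------------------


def _corr_with_regulators(x: np.ndarray) -> np.ndarray:
    xc = x - x.mean()
    n = np.linalg.norm(xc)
    if n == 0:
        return np.zeros(len(_Z))
    return _Z @ xc / n


def _draw_factors(
    rng: np.random.Generator,
    changed: set[int],
    cfg: SimConfig,
    fixed_up: int | None = None,
    f_cross_min: float | None = None,
    pre_exact: set[int] = frozenset(),
) -> np.ndarray:
    f = np.ones(3)
    for t in range(3):
        if t in changed:
            lo, hi = cfg.changed_fc_range
            if t == fixed_up and f_cross_min is not None:
                lo = min(max(lo, f_cross_min), hi - 1e-6)
            mag = rng.uniform(lo, hi)
            up = True if t == fixed_up else bool(rng.random() < 0.5)
            f[t] = mag if up else 1.0 / mag
        elif t in pre_exact:
            f[t] = 1.0
        else:
            mag = rng.uniform(1.0, cfg.unchanged_fc_max)
            f[t] = mag if rng.random() < 0.5 else 1.0 / mag
    return f


def _bounded_shape(rng, cfg, draw, max_tries: int = 200) -> np.ndarray:
    """Redraw a trajectory until its |PCC| with every regulator direction is
    within the uncoupled bound; keep the best attempt as a fallback."""
    best_c, best_x = np.inf, None
    for _ in range(max_tries):
        f = draw()
        x = np.concatenate([[1.0], np.cumprod(f)])
        c = float(np.max(np.abs(_corr_with_regulators(x))))
        if c <= cfg.uncoupled_max:
            return x
        if c < best_c:
            best_c, best_x = c, x
    return best_x


def _uncoupled_direction(rng: np.random.Generator, cfg: SimConfig) -> np.ndarray:
    """Unit mean-zero 4-vector with bounded |PCC| against every regulator."""
    for _ in range(500):
        v = _unit_centered(rng.normal(size=4))
        if np.max(np.abs(_Z @ v)) <= cfg.uncoupled_max:
            return v
    return v  # pragma: no cover - acceptance probability is ~0.2


def coupled_direction(
    rng: np.random.Generator, z: np.ndarray, r: float, sign: int
) -> np.ndarray:
    """Unit mean-zero direction with exact sample PCC = sign*r against z."""
    z = _unit_centered(z)
    for _ in range(100):
        w = rng.normal(size=4)
        w = w - w.mean()
        w = w - (w @ z) * z
        n = np.linalg.norm(w)
        if n > 1e-8:
            break
    w = w / n
    return sign * r * z + np.sqrt(1.0 - r * r) * w


def _scaled_trajectory(
    rng: np.random.Generator,
    cfg: SimConfig,
    changed: set[int],
    origin_idx: int | None,
) -> np.ndarray:
    """Noiseless 4-point level trajectory realizing change set and origin.

    origin_idx None = never modified; 0 = modified at the first stage; 1..3 =
    first crossing of the modified threshold at that stage.  Safety margins
    (levels at least ~8% away from the 1.5 threshold at the defining stages,
    fold changes at least 1.35 or at most the unchanged jitter) keep the
    planted labels recoverable under sequencing noise.
    """
    if origin_idx is not None and origin_idx > 0:
        tc = origin_idx - 1
        scale = rng.uniform(1.10, 1.35)
        pre = set(range(tc))
        x = _bounded_shape(
            rng,
            cfg,
            lambda: _draw_factors(
                rng, changed, cfg, fixed_up=tc, f_cross_min=1.62 / scale, pre_exact=pre
            ),
        )
        return scale * x
    x = _bounded_shape(rng, cfg, lambda: _draw_factors(rng, changed, cfg))
    if origin_idx == 0:
        return rng.uniform(1.7, 3.5) * x
    return (1.35 * rng.uniform(0.6, 0.95) / x.max()) * x


def _draw_change_set(
    rng: np.random.Generator, k: int, origin_idx: int | None
) -> tuple[set[int], int | None]:
    """Transitions carrying a change, honoring the origin constraint.

    A late origin requires the crossing transition to be an up-change and
    every earlier transition unchanged; if the drawn origin is infeasible
    for the class the origin falls back to the first stage.
    """
    if origin_idx is not None and origin_idx > 0:
        tc = origin_idx - 1
        if k == 0 or k - 1 > 2 - tc:
            origin_idx = 0
        else:
            later = [t for t in range(tc + 1, 3)]
            extra = rng.choice(later, size=k - 1, replace=False) if k > 1 else []
            return {tc, *map(int, extra)}, origin_idx
    return set(map(int, rng.choice(3, size=k, replace=False))), origin_idx


# ---------------------------------------------------------------------------
# the study
# ---------------------------------------------------------------------------


def _gene_layout(gene_ids: list[str], rng) -> pd.DataFrame:
    """Toy genome: 50 genes per chromosome, fixed-size non-overlapping genes
    with 600 nt 5'UTR, 3600 nt CDS and 1800 nt 3'UTR."""
    rows = {}
    for i, gid in enumerate(gene_ids):
        chrom = f"chr{i // 50 + 1}"
        offset = (i % 50) * 8000 + 1000
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            cds_start, cds_end = offset + 600, offset + 4200
        else:
            cds_start, cds_end = offset + 1800, offset + 5400
        rows[gid] = dict(
            chrom=chrom,
            strand=strand,
            tx_start=offset,
            tx_end=offset + 6000,
            cds_start=cds_start,
            cds_end=cds_end,
        )
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "gene_id"
    return df


def _place_peak(rng, gene: pd.Series) -> tuple[int, int]:
    """Peak coordinates within a gene; midpoints favor the stop-proximal
    window to reproduce the canonical metagene enrichment."""
    stop = gene.cds_end if gene.strand == "+" else gene.cds_start
    u = rng.random()
    if u < 0.35:
        mid = stop + rng.integers(-50, 51)
    elif u < 0.65:
        mid = rng.integers(gene.cds_start + 60, gene.cds_end - 60)
    elif u < 0.90:  # 3'UTR
        if gene.strand == "+":
            mid = rng.integers(gene.cds_end + 60, gene.tx_end - 60)
        else:
            mid = rng.integers(gene.tx_start + 60, gene.cds_start - 60)
    else:  # 5'UTR
        if gene.strand == "+":
            mid = rng.integers(gene.tx_start + 60, gene.cds_start - 60)
        else:
            mid = rng.integers(gene.cds_end + 60, gene.tx_end - 60)
    w = int(rng.integers(100, 251))
    start = int(max(gene.tx_start, mid - w // 2))
    end = int(min(gene.tx_end, start + w))
    return start, end


def _counts(rng, mean: np.ndarray, dispersion: float | None) -> np.ndarray:
    if dispersion is None:
        return rng.poisson(mean)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def plant_regulator_targets(
    config: SimConfig, rng: np.random.Generator, peak_genes: list[str]
) -> tuple[dict[str, list[str]], dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Choose disjoint target sets and their coupled trajectory directions.

    For a writer target, the gene's m6A direction has sample PCC exactly
    +r_plant with the regulator's expression shape and the expression
    direction exactly -r_plant; an eraser's targets have the signs flipped.
    Returns (target gene ids per regulator, m6A direction per target gene,
    expression direction per target gene).
    """
    regs = list(TARGETED_WRITERS) + list(TARGETED_ERASERS)
    perm = rng.permutation(peak_genes)
    target_map: dict[str, list[str]] = {}
    m6a_dirs: dict[str, np.ndarray] = {}
    expr_dirs: dict[str, np.ndarray] = {}
    for i, reg in enumerate(regs):
        chosen = sorted(perm[i * config.n_targets : (i + 1) * config.n_targets])
        target_map[reg] = [str(g) for g in chosen]
        z = _unit_centered(REGULATOR_DIRECTIONS[reg])
        m_sign, e_sign = (1, -1) if reg in TARGETED_WRITERS else (-1, 1)
        for g in target_map[reg]:
            if config.r_plant == 0.0:
                # fully uncoupled: bounded against every regulator, like nulls
                m6a_dirs[g] = _uncoupled_direction(rng, config)
                expr_dirs[g] = _uncoupled_direction(rng, config)
            else:
                m6a_dirs[g] = coupled_direction(rng, z, config.r_plant, m_sign)
                expr_dirs[g] = coupled_direction(rng, z, config.r_plant, e_sign)
    return target_map, m6a_dirs, expr_dirs


def _target_levels(rng, cfg: SimConfig, y: np.ndarray) -> np.ndarray:
    """Level trajectory base*(1 + c*y) with fold changes nudged off the
    differential boundary; the affine form preserves the planted PCC."""
    base = rng.uniform(2.2, 3.2)
    for c in np.linspace(0.45, 0.20, 26):
        m = base * (1.0 + c * y)
        if m.min() <= 0.3:
            continue
        fc = dynamics.symmetric_fold_change(m[1:], m[:-1])
        if np.all((fc <= 1.10) | (fc >= 1.30)):
            return m
    return base * (1.0 + 0.3 * y)


def plant_accessibility(
    config: SimConfig,
    rng: np.random.Generator,
    gene_mu: pd.DataFrame,
    gene_category: pd.Series,
    boosted: pd.Series,
) -> pd.DataFrame:
    """Noiseless gene-level accessibility realizing the planted categories.

    Categories 4/5 tie the accessibility change ratios to the m6A change
    ratios (reciprocal for discordant, equal for concordant); category 2
    draws its own change pattern; categories 1/3 stay within the unchanged
    jitter.  ``boosted`` scales baseline accessibility (target-gene and
    modified-gene boosts); baseline is also mildly anti-coupled to the mean
    m6A level (access_m6a_coupling).
    """
    rows = {}
    for g in gene_category.index:
        cat = gene_category[g]
        base = 2.0 ** rng.normal(3.0, 0.8)
        base *= float(boosted.get(g, 1.0))
        if g in gene_mu.index:
            factor = (gene_mu.loc[g].mean() / 2.0) ** (-config.access_m6a_coupling)
            base *= float(np.clip(factor, 0.5, 2.0))
        if cat in (2,):
            k = 1 + int(rng.choice(3, p=[0.55, 0.30, 0.15]))
            changed = set(map(int, rng.choice(3, size=k, replace=False)))
            f = _draw_factors(rng, changed, config)
        elif cat in (4, 5) and g in gene_mu.index:
            mu = gene_mu.loc[g].to_numpy()
            ratios = mu[1:] / mu[:-1]
            f = ratios if cat == 5 else 1.0 / ratios
        else:  # categories 1 and 3: unchanged accessibility
            f = _draw_factors(rng, set(), config)
        x = np.concatenate([[1.0], np.cumprod(f)])
        rows[g] = base * x
    out = pd.DataFrame.from_dict(rows, orient="index", columns=list(config.stages))
    out.index.name = "gene_id"
    return out


def simulate_study(config: SimConfig) -> SimStudy:
    """Generate the full study deterministically from the config seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    stages = list(cfg.stages)

    gene_ids = [f"g{i:04d}" for i in range(1, cfg.n_genes + 1)]
    special = (
        list(TARGETED_WRITERS) + list(TARGETED_ERASERS) + list(OTHER_REGULATORS)
    )
    all_genes = gene_ids + special
    n_peak_genes = round(cfg.frac_genes_with_peaks * cfg.n_genes)
    peak_genes = sorted(
        str(g) for g in rng.choice(gene_ids, size=n_peak_genes, replace=False)
    )

    target_map, m6a_dirs, expr_dirs = plant_regulator_targets(cfg, rng, peak_genes)
    target_of: dict[str, str] = {
        g: reg for reg, genes in target_map.items() for g in genes
    }

    # ---- per-gene m6A trajectories, categories and labels -----------------
    cat_choices = np.arange(1, 6)
    class_given_changed = np.array(
        [cfg.frac_change_once, cfg.frac_change_twice, cfg.frac_change_thrice]
    )
    if class_given_changed.sum() > 0:
        class_given_changed = class_given_changed / class_given_changed.sum()
    else:
        class_given_changed = np.array([1.0, 0.0, 0.0])  # unused when all unchanged
    p_d0 = cfg.frac_origin_d0 / (1.0 - cfg.frac_unmodified) if cfg.frac_unmodified < 1 else 0.0
    late_split = np.array([0.5, 0.3, 0.2])

    gene_mu_rows: dict[str, np.ndarray] = {}
    planted_cat: dict[str, int] = {}
    for g in peak_genes:
        if g in target_of:
            planted_cat[g] = 0  # emergent, not planted
            gene_mu_rows[g] = _target_levels(rng, cfg, m6a_dirs[g])
            continue
        cat = int(rng.choice(cat_choices, p=np.asarray(cfg.category_fracs)))
        planted_cat[g] = cat
        k = 0 if cat in (1, 2) else 1 + int(rng.choice(3, p=class_given_changed))
        if rng.random() < cfg.frac_unmodified:
            origin_idx = None
        elif rng.random() < p_d0:
            origin_idx = 0
        else:
            origin_idx = 1 + int(rng.choice(3, p=late_split))
        changed, origin_idx = _draw_change_set(rng, k, origin_idx)
        gene_mu_rows[g] = _scaled_trajectory(rng, cfg, changed, origin_idx)

    # regulator genes carry weakly varying m6A on their own transcripts
    for reg in special:
        v = _uncoupled_direction(rng, cfg)
        gene_mu_rows[reg] = rng.uniform(1.8, 2.6) * (1.0 + 0.05 * v)
        planted_cat[reg] = 0

    gene_mu = pd.DataFrame.from_dict(gene_mu_rows, orient="index", columns=stages)
    gene_mu.index.name = "gene_id"

    # ---- expression -------------------------------------------------------
    expr_rows: dict[str, np.ndarray] = {}
    for g in gene_ids:
        base = 2.0 ** rng.normal(5.0, 1.2)
        if g in target_of:
            v = expr_dirs[g]
            amp = rng.uniform(0.25, 0.45)
        else:
            v = _uncoupled_direction(rng, cfg)
            amp = rng.uniform(0.08, 0.45)
        expr_rows[g] = base * (1.0 + amp * v)
    for reg in special:
        z = REGULATOR_DIRECTIONS.get(reg)
        base = 2.0 ** rng.normal(6.0, 0.5)
        if z is not None:
            expr_rows[reg] = base * (1.0 + 0.5 * _unit_centered(z))
        else:
            v = _uncoupled_direction(rng, cfg)
            expr_rows[reg] = base * (1.0 + rng.uniform(0.05, 0.12) * v)
    # one reader tracks the first writer target, exercising reader association
    first_target = target_map[TARGETED_WRITERS[0]][0] if cfg.n_targets else None
    if first_target is not None:
        expr_rows["YTHDF2"] = 5.0 + 0.8 * expr_rows[first_target]
    expression = pd.DataFrame.from_dict(expr_rows, orient="index", columns=stages)
    expression = expression.loc[all_genes]
    expression.index.name = "gene_id"

    # ---- genome, peaks ----------------------------------------------------
    ann_df = _gene_layout(all_genes, rng)
    n_chrom = int(np.ceil(len(all_genes) / 50))
    annotation = GeneAnnotation(ann_df)

    n_intergenic = round(cfg.frac_intergenic * cfg.n_peaks)
    n_gene_peaks = cfg.n_peaks - n_intergenic - len(special)
    extra = n_gene_peaks - len(peak_genes)
    extra_counts = (
        rng.multinomial(extra, np.full(len(peak_genes), 1.0 / len(peak_genes)))
        if extra > 0
        else np.zeros(len(peak_genes), dtype=int)
    )
    peak_rows = []
    peak_gene_of: list[str | None] = []
    for g, bonus in zip(peak_genes, extra_counts):
        for _ in range(1 + int(bonus)):
            s, e = _place_peak(rng, ann_df.loc[g])
            peak_rows.append((ann_df.loc[g, "chrom"], s, e, ann_df.loc[g, "strand"]))
            peak_gene_of.append(g)
    for reg in special:
        s, e = _place_peak(rng, ann_df.loc[reg])
        peak_rows.append((ann_df.loc[reg, "chrom"], s, e, ann_df.loc[reg, "strand"]))
        peak_gene_of.append(reg)
    for i in range(n_intergenic):
        start = 1000 + i * 1200
        peak_rows.append((f"chr{n_chrom + 1}", start, start + 200, "."))
        peak_gene_of.append(None)
    peak_ids = [f"p{i + 1:05d}" for i in range(len(peak_rows))]
    peaks_df = pd.DataFrame(
        peak_rows, columns=["chrom", "start", "end", "strand"], index=peak_ids
    )
    peaks_df.index.name = "peak_id"
    from .io_formats import assign_peaks_to_genes

    peaks = PeakTable(assign_peaks_to_genes(peaks_df, annotation))

    # ---- per-peak mu and counts ------------------------------------------
    mu = np.empty((len(peak_ids), 4))
    for i, g in enumerate(peak_gene_of):
        if g is None:
            v = _uncoupled_direction(rng, cfg)
            x = 1.0 + 0.05 * v
            mu[i] = (1.35 * rng.uniform(0.6, 0.95) / x.max()) * x
        else:
            mu[i] = gene_mu.loc[g].to_numpy()
    peak_mu = pd.DataFrame(mu, index=pd.Index(peak_ids, name="peak_id"), columns=stages)

    med = float(np.median(expression.to_numpy()))
    weight = np.clip(np.sqrt(expression / med), 0.5, 3.0)
    w = np.ones((len(peak_ids), 4))
    for i, g in enumerate(peak_gene_of):
        if g is not None:
            w[i] = weight.loc[g].to_numpy()
    sf_ip = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=4))
    sf_in = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=4))
    input_mean = cfg.depth_mean * w * sf_in
    ip_mean = cfg.depth_mean * w * mu * sf_ip
    counts = StageCounts(
        ip=pd.DataFrame(
            _counts(rng, ip_mean, cfg.dispersion), index=peak_mu.index, columns=stages
        ),
        input=pd.DataFrame(
            _counts(rng, input_mean, cfg.dispersion), index=peak_mu.index, columns=stages
        ),
        ip_libsize=pd.Series(
            np.round(3 * cfg.depth_mean * cfg.n_peaks * sf_ip).astype(int),
            index=stages,
        ),
        input_libsize=pd.Series(
            np.round(3 * cfg.depth_mean * cfg.n_peaks * sf_in).astype(int),
            index=stages,
        ),
        stages=cfg.stages,
    )

    # ---- accessibility ----------------------------------------------------
    modified_genes = gene_mu.index[(gene_mu > cfg.mod_threshold).any(axis=1)]
    boost = pd.Series(1.0, index=pd.Index(all_genes))
    boost[boost.index.isin(target_of)] *= cfg.access_target_boost
    boost[boost.index.isin(modified_genes)] *= cfg.access_modified_boost
    cat_series = pd.Series(
        {g: planted_cat.get(g, 0) for g in all_genes}, name="planted_category"
    )
    # genes without peaks / targets: free accessibility patterns (0 = free)
    free = cat_series.index[cat_series == 0]
    free_cat = pd.Series(
        rng.choice([1, 2], p=[0.5, 0.5], size=len(free)), index=free
    )
    cat_for_access = cat_series.copy()
    cat_for_access[free] = free_cat
    access_clean = plant_accessibility(cfg, rng, gene_mu, cat_for_access, boost)
    noise = np.exp(rng.normal(0.0, cfg.access_noise_sd, size=access_clean.shape))
    accessibility = access_clean * noise

    # ---- TF binding -------------------------------------------------------
    group_idx = {}
    for s in ("D0", "D15"):
        lv = gene_mu[s]
        group_idx[s] = pd.Series(
            np.where(lv < 1.5, 0, np.where(lv > 4.0, 2, 1)), index=gene_mu.index
        )
    tf_rows = {}
    for g in gene_mu.index:
        base = 2.0 ** rng.normal(2.0, 0.5, size=6)
        tf_rows[g] = dict(
            POU5F1_D0=base[0] * (1 + 0.6 * group_idx["D0"][g]),
            POU5F1_D15=base[1],
            TBX5_D0=base[2],
            TBX5_D15=base[3] * (1 + 0.6 * group_idx["D15"][g]),
            NANOG_D0=base[4],
            NANOG_D15=base[5],
        )
    tf_binding = pd.DataFrame.from_dict(tf_rows, orient="index")
    tf_binding.index.name = "gene_id"

    # ---- sequences --------------------------------------------------------
    bases = np.array(list("ACGT"))
    sequences = {}
    ever_modified = (peak_mu > cfg.mod_threshold).any(axis=1)
    for pid, row in peaks.df.iterrows():
        length = int(row.end - row.start)
        seq = rng.choice(bases, size=length)
        lam = 2.0 if ever_modified[pid] else 0.3
        for _ in range(rng.poisson(lam)):
            pos = int(rng.integers(0, max(1, length - 5)))
            seq[pos : pos + 5] = list("GGACT")
        sequences[pid] = "".join(seq)

    # ---- truth labels from the noiseless field ----------------------------
    peak_flags = dynamics.level_change_flags(peak_mu, cfg.fc_threshold)
    peak_count, _ = dynamics.change_classes(peak_flags)
    peak_modified = dynamics.call_modified(peak_mu, cfg.mod_threshold)
    peak_origin = dynamics.peak_origin(peak_modified)
    peak_labels = pd.DataFrame(
        {
            "gene_id": pd.array(
                [g if g is not None else pd.NA for g in peak_gene_of], dtype="string"
            ),
            "change_count": peak_count,
            "origin": peak_origin,
        }
    )
    gene_flags = dynamics.level_change_flags(gene_mu, cfg.fc_threshold)
    gene_count, _ = dynamics.change_classes(gene_flags)
    gene_origin = dynamics.peak_origin(dynamics.call_modified(gene_mu, cfg.mod_threshold))
    truth_cat = chromatin.co_dynamics_categories(
        gene_mu, access_clean, cfg.fc_threshold
    ).category
    gene_labels = pd.DataFrame(
        {
            "change_count": gene_count,
            "origin": gene_origin,
            "category": truth_cat,
            "planted_category": cat_series.reindex(gene_mu.index),
        }
    )
    for reg in target_map:
        gene_labels[f"target_{reg}"] = gene_labels.index.isin(target_map[reg])
    gene_labels.index.name = "gene_id"

    truth = Truth(
        peak_mu=peak_mu,
        gene_mu=gene_mu,
        peak_labels=peak_labels,
        gene_labels=gene_labels,
        access_clean=access_clean,
        input_mean=pd.DataFrame(input_mean, index=peak_mu.index, columns=stages),
        target_map=target_map,
    )
    regset = RegulatorSet.from_expression(expression)
    return SimStudy(
        config=cfg,
        peaks=peaks,
        annotation=annotation,
        counts=counts,
        expression=expression,
        accessibility=accessibility,
        tf_binding=tf_binding,
        sequences=sequences,
        regulators=regset,
        truth=truth,
    )
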