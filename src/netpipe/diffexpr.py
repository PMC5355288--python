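"""Small-cohort differential expression with empirical-Bayes moderated t.

The model: for gene g with residual variance s_g^2 on d degrees of freedom,
the gene variances are assumed exchangeable under a scaled inverse-chi-square
prior with df d0 and scale s0^2. The posterior variance

    s~_g^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d)

shrinks noisy gene-wise variances toward the prior, and the moderated t
statistic logFC / (s~_g * sqrt(v)) is referred to a t distribution on
d0 + d degrees of freedom. (d0, s0^2) are estimated by method of moments on
log s_g^2 via trigamma inversion. With d0 = 0 the statistic reduces to the
ordinary two-sample t; as d0 -> infinity all genes share the prior variance.

Group comparisons are fit by ordinary least squares of log2 expression on a
case/control indicator plus optional blocking covariates (batch, family),
so "case minus control" log2 fold change is the group coefficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .interactome import GeneList, normalize_symbol

log = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "DETable",
    "quantile_normalize",
    "collapse_probes",
    "fit_de",
    "benjamini_hochberg",
    "split_by_direction",
    "restricted_test",
    "overlap_genes",
]

#: d0 values above this are treated as "effectively infinite" shrinkage.
D0_CAP = 1e6


@dataclass
class ExpressionMatrix:
    """Log2 expression values (genes x samples) plus per-sample design.

    ``design`` is indexed by sample ID and must carry a ``group`` column with
    values ``case``/``control``; ``family_id`` and ``batch`` are optional
    blocking covariates.
    """

    values: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene IDs: {dupes[:5]}")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample IDs in expression matrix")
        missing = set(self.values.columns) - set(self.design.index)
        if missing:
            raise ValueError(f"samples missing from design table: {sorted(missing)[:5]}")
        self.design = self.design.loc[list(self.values.columns)]
        if "group" not in self.design.columns:
            raise ValueError("design table must have a 'group' column")
        bad = set(self.design["group"]) - {"case", "control"}
        if bad:
            raise ValueError(f"group labels must be case/control, got {sorted(bad)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class DETable:
    """Per-gene differential-expression results.

    ``table`` is indexed by gene with columns logFC, t, p, adj_p, direction;
    ``d0``/``s0_sq`` are the fitted prior df and prior variance of the
    variance-shrinkage model. ``missing_genes`` records requested genes that
    were not on the platform (restricted testing only).
    """

    table: pd.DataFrame
    d0: float
    s0_sq: float
    missing_genes: list[str] = field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample (column) onto the common mean quantile distribution.

    After the transform each column's sorted values equal the across-column
    mean of sorted values; within-column ranks are preserved. Idempotent.
    """
    vals = m.values.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        rows, cols = np.nonzero(~np.isfinite(vals))
        cells = [
            f"({m.values.index[r]}, {m.values.columns[c]})"
            for r, c in list(zip(rows, cols))[:10]
        ]
        raise ValueError(f"non-finite expression values at {', '.join(cells)}")
    if vals.shape[1] < 2:
        raise ValueError("quantile normalization needs at least two samples")
    order = np.argsort(vals, axis=0, kind="stable")
    ref = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        out[order[:, j], j] = ref
    return ExpressionMatrix(
        values=pd.DataFrame(out, index=m.values.index, columns=m.values.columns),
        design=m.design,
    )


def collapse_probes(m: ExpressionMatrix, probe_to_gene: dict[str, str]) -> ExpressionMatrix:
    """Average probe rows targeting the same gene into one row per gene.

    Probes absent from the mapping are dropped; their count is logged.
    """
    if not probe_to_gene:
        raise ValueError("probe-to-gene mapping is empty")
    mapping = {str(p): normalize_symbol(g) for p, g in probe_to_gene.items()}
    mapped = [p for p in m.values.index if p in mapping]
    n_dropped = len(m.values) - len(mapped)
    if n_dropped:
        log.info("dropping %d unmapped probes", n_dropped)
    sub = m.values.loc[mapped]
    genes = pd.Index([mapping[p] for p in mapped], name="gene")
    collapsed = sub.groupby(genes).mean()
    return ExpressionMatrix(values=collapsed, design=m.design)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise ValueError("trigamma inverse needs a positive argument")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(100):
        tri = special.polygamma(1, y)
        step = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += step
        if abs(step) < 1e-10 * y:
            break
    return float(y)


def _estimate_prior(s2: np.ndarray, d: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) from log residual variances.

    Marginally s_g^2 / s0^2 ~ F(d, d0), so z = log s^2 has
    E[z] = log s0^2 + psi(d/2) - log(d/2) - (psi(d0/2) - log(d0/2)) and
    Var[z] = psi'(d/2) + psi'(d0/2); solving the second moment for d0 uses
    trigamma inversion. Non-positive excess variance means "no evidence of
    variance heterogeneity": d0 is capped at D0_CAP (effectively infinite).
    """
    s2 = np.maximum(s2, 1e-300)
    z = np.log(s2)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    e_mean = float(np.mean(e))
    excess = float(np.var(e, ddof=1)) - float(special.polygamma(1, d / 2.0))
    if excess <= 1e-10:
        return D0_CAP, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(excess)
    d0 = min(d0, D0_CAP)
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def _design_matrix(design: pd.DataFrame, covariates: tuple[str, ...]) -> tuple[np.ndarray, list[str]]:
    n = len(design)
    cols = [np.ones(n), (design["group"].to_numpy() == "case").astype(float)]
    names = ["intercept", "group"]
    for cov in covariates:
        if cov not in design.columns:
            raise ValueError(f"covariate {cov!r} not in design table")
        levels = design[cov].astype(str)
        counts = levels.value_counts()
        # singleton levels (e.g. non-twin individuals each in their own
        # "family") carry no blocking information and, pooled, would span a
        # whole group; they share the reference level instead
        blocked = levels.where(levels.map(counts) > 1, other="__ref__")
        dummies = pd.get_dummies(blocked, drop_first="__ref__" not in set(blocked))
        dummies = dummies.drop(columns=["__ref__"], errors="ignore")
        for level in dummies.columns:
            cols.append(dummies[level].to_numpy(dtype=float))
            names.append(f"{cov}[{level}]")
    return np.column_stack(cols), names


def fit_de(
    m: ExpressionMatrix,
    covariates: tuple[str, ...] = (),
    fdr_q: float = 0.05,
    d0: float | None = None,
    s0_sq: float | None = None,
) -> DETable:
    """Fit gene-wise case-vs-control contrasts with variance shrinkage.

    Per gene: OLS of expression on the group indicator plus covariate dummy
    columns; empirical-Bayes shrinkage of the residual variance; moderated t
    and BH-adjusted p-values. ``d0``/``s0_sq`` may be pinned (e.g. d0=0 for
    the ordinary t, d0=inf for fully pooled variance) instead of estimated.

    Raises when a group has fewer than 2 samples or when the group indicator
    is collinear with the covariates.
    """
    counts = m.design["group"].value_counts()
    for grp in ("case", "control"):
        if counts.get(grp, 0) < 2:
            raise ValueError(f"group {grp!r} has {counts.get(grp, 0)} samples; need >= 2")
    X, names = _design_matrix(m.design, tuple(covariates))
    n, p = X.shape
    rank_full = np.linalg.matrix_rank(X)
    if rank_full < p:
        X_nogroup = np.delete(X, 1, axis=1)
        if np.linalg.matrix_rank(X_nogroup) == rank_full:
            raise ValueError(
                "group is collinear with covariates "
                f"({', '.join(names[2:])}); the contrast is not estimable"
            )
        raise ValueError("design matrix is rank deficient")
    d = n - p
    if d < 1:
        raise ValueError(f"residual df {d} < 1: too many covariates for {n} samples")

    xtx_inv = np.linalg.inv(X.T @ X)
    hat = xtx_inv @ X.T                      # p x n
    v_group = float(xtx_inv[1, 1])           # unscaled variance of the contrast
    Y = m.values.to_numpy(dtype=float)       # genes x n
    beta = Y @ hat.T                         # genes x p
    resid = Y - beta @ X.T
    s2 = np.einsum("ij,ij->i", resid, resid) / d
    logfc = beta[:, 1]

    if d0 is None:
        d0_hat, s0_hat = _estimate_prior(s2, d)
    else:
        d0_hat = float(d0)
        s0_hat = float(s0_sq) if s0_sq is not None else float(np.median(s2))
    if np.isinf(d0_hat):
        d0_hat = D0_CAP
        s2_post = np.full_like(s2, s0_hat)  # exact infinite-shrinkage limit
        df_total = D0_CAP
    elif d0_hat == 0.0:
        s2_post = s2
        df_total = float(d)
    else:
        s2_post = (d0_hat * s0_hat + d * s2) / (d0_hat + d)
        df_total = min(d0_hat + d, D0_CAP)
    with np.errstate(divide="ignore"):
        t_mod = logfc / np.sqrt(s2_post * v_group)
    pvals = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    table = pd.DataFrame(
        {
            "logFC": logfc,
            "t": t_mod,
            "p": pvals,
            "adj_p": benjamini_hochberg(pvals),
            "direction": np.where(logfc > 0, "up", "down"),
        },
        index=m.values.index,
    )
    return DETable(table=table, d0=d0_hat, s0_sq=s0_hat)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up FDR adjustment: adj_p(i) = min_{j: p_j >= p_i} n*p_(j)/j, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def split_by_direction(t: DETable, fdr_q: float = 0.05) -> tuple[GeneList, GeneList]:
    """Significant genes (adj_p <= fdr_q) split into up- and down-regulated lists."""
    tab = t.table
    sig = tab["adj_p"] <= fdr_q
    up = GeneList(list(tab.index[sig & (tab["logFC"] > 0)]), label="up")
    down = GeneList(list(tab.index[sig & (tab["logFC"] < 0)]), label="down")
    return up, down


def restricted_test(t_full: DETable, subset: GeneList, fdr_q: float = 0.05) -> DETable:
    """Re-adjust raw p-values over a pre-specified candidate subset only.

    Raw p-values are untouched; only the multiplicity correction changes —
    restricting the family to, say, hub genes. Requested genes missing from
    the fitted table (not on the platform / failed QC) are recorded in
    ``missing_genes``; an empty intersection raises.
    """
    tested = set(t_full.table.index)
    keep = [g for g in subset if g in tested]
    missing = [g for g in subset if g not in tested]
    if not keep:
        raise ValueError("no subset gene was tested in the full table")
    if missing:
        log.info("%d subset genes not measured: %s", len(missing), ", ".join(missing))
    sub = t_full.table.loc[keep].copy()
    sub["adj_p"] = benjamini_hochberg(sub["p"].to_numpy())
    return DETable(table=sub, d0=t_full.d0, s0_sq=t_full.s0_sq, missing_genes=missing)


def overlap_genes(a: GeneList, b: GeneList) -> tuple[int, GeneList]:
    """Intersection of two gene lists after symbol normalization."""
    common = [s for s in a if s in b.as_set]
    shared = GeneList(common, label=f"{a.label}&{b.label}")
    return len(shared), shared
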