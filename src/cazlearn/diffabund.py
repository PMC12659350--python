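"""Gene-catalog differential abundance and CAZyme prioritization.

The disease analysis takes a gene x sample count matrix with per-sample
metadata (a disease indicator plus clinical covariates) through a fixed
pipeline:

1. prevalence filter — drop genes nonzero in fewer than 10% of samples;
2. zero imputation — replace each gene's zeros by half its minimum nonzero
   value, so the subsequent log transform is defined;
3. log2 fold change — log2 of the disease-group mean over the control-group
   mean, per gene, on imputed counts;
4. per-gene linear model — each gene's imputed counts are log2-transformed
   and z-scored within the gene, then regressed (OLS) on the disease
   indicator and covariates; the reported p-value is the two-sided t-test
   on the disease coefficient;
5. Benjamini–Hochberg step-up correction, significance declared at q <= 0.25;
6. volcano labeling by disjunctions of (logFC, p) clauses — presets for the
   Crohn's disease (CD) and IgG4-related disease rule sets are included;
7. prioritization of CAZyme-predicted genes by the mean of the gene's logFC
   percentile (among all genes in the result set) and the classifier's
   family probability.

The pipeline order is enforced: the count matrix carries its processing
stage and each step refuses inputs that skipped a prerequisite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

FDR_THRESHOLD = 0.25


class DiffAbundanceError(ValueError):
    """Raised on invalid differential-abundance inputs or pipeline misuse."""


@dataclass
class CountMatrix:
    """Gene x sample counts plus sample metadata.

    ``metadata`` is indexed by sample id and must contain the disease
    indicator column; ``stage`` tracks pipeline progress
    (raw -> filtered -> imputed).
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    disease_col: str = "disease"
    stage: str = "raw"

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise DiffAbundanceError("counts must be non-negative")
        if set(self.counts.columns) != set(self.metadata.index):
            raise DiffAbundanceError("sample ids in counts and metadata differ")
        if self.disease_col not in self.metadata.columns:
            raise DiffAbundanceError(
                f"metadata lacks disease column {self.disease_col!r}"
            )
        # align metadata rows to count columns
        self.metadata = self.metadata.loc[list(self.counts.columns)]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def disease_samples(self) -> list[str]:
        return list(self.metadata.index[self.metadata[self.disease_col].astype(bool)])

    def control_samples(self) -> list[str]:
        return list(self.metadata.index[~self.metadata[self.disease_col].astype(bool)])


def prevalence_filter(m: CountMatrix, min_prev: float = 0.10) -> CountMatrix:
    """Remove genes with prevalence (fraction of nonzero samples) below
    ``min_prev``; the boundary (exactly 10%) is retained."""
    if not 0 < min_prev <= 1:
        raise DiffAbundanceError("min_prev must lie in (0, 1]")
    prev = (m.counts > 0).mean(axis=1)
    kept = m.counts.loc[prev >= min_prev]
    logger.info(
        "prevalence filter: kept %d of %d genes (min_prev=%.3g)",
        kept.shape[0], m.n_genes, min_prev,
    )
    return replace(m, counts=kept, stage="filtered")


def zero_impute(m: CountMatrix) -> CountMatrix:
    """Replace each gene's zeros by (its minimum nonzero value) / 2."""
    if m.stage not in ("filtered",):
        raise DiffAbundanceError(
            f"zero_impute expects a prevalence-filtered matrix, got stage {m.stage!r}"
        )
    values = m.counts.to_numpy(dtype=float, copy=True)
    if values.shape[0]:
        masked = np.where(values > 0, values, np.inf)
        min_nonzero = masked.min(axis=1)
        dead = ~np.isfinite(min_nonzero)
        if dead.any():
            offenders = list(m.counts.index[dead][:5])
            raise DiffAbundanceError(
                f"all-zero gene(s) reached imputation (pipeline-order violation): {offenders}"
            )
        zero_mask = values == 0
        values[zero_mask] = np.broadcast_to((min_nonzero / 2.0)[:, None], values.shape)[zero_mask]
    imputed = pd.DataFrame(values, index=m.counts.index, columns=m.counts.columns)
    return replace(m, counts=imputed, stage="imputed")


def log_fold_change(
    m: CountMatrix,
    disease_samples: Sequence[str] | None = None,
    control_samples: Sequence[str] | None = None,
) -> pd.Series:
    """Per-gene log2(mean over disease / mean over control) on imputed counts."""
    if m.stage != "imputed":
        raise DiffAbundanceError(
            f"log_fold_change expects an imputed matrix, got stage {m.stage!r}"
        )
    disease_samples = list(disease_samples or m.disease_samples())
    control_samples = list(control_samples or m.control_samples())
    if not disease_samples or not control_samples:
        raise DiffAbundanceError("both groups must be non-empty")
    mean_d = m.counts[disease_samples].mean(axis=1)
    mean_c = m.counts[control_samples].mean(axis=1)
    assert (mean_c > 0).all(), "control means must be positive after imputation"
    return np.log2(mean_d / mean_c).rename("logFC")


def _check_design(X: pd.DataFrame) -> None:
    if X.isna().any().any():
        bad = list(X.columns[X.isna().any()])
        raise DiffAbundanceError(f"missing values in design columns: {bad}")
    if X.shape[0] <= X.shape[1]:
        raise DiffAbundanceError(
            f"fewer samples ({X.shape[0]}) than model parameters ({X.shape[1]}) + 1"
        )
    rank = np.linalg.matrix_rank(X.to_numpy(dtype=float))
    if rank < X.shape[1]:
        # name the columns involved: those whose removal restores full rank
        culprits = [
            c for c in X.columns
            if c != "const"
            and np.linalg.matrix_rank(X.drop(columns=[c]).to_numpy(dtype=float))
            == X.shape[1] - 1
        ]
        raise DiffAbundanceError(f"collinear design matrix; involved columns: {culprits}")


def fit_gene_models(
    m: CountMatrix, covariates: Sequence[str] = ()
) -> pd.DataFrame:
    """Per-gene OLS of log2 + z-scored counts on disease plus covariates.

    Each gene's imputed counts are log2-transformed and z-scored within the
    gene (sample standard deviation, n-1 denominator); the gene's response is
    regressed on an intercept, the disease indicator and the named covariate
    columns jointly.  Returns a frame indexed by gene with the disease
    coefficient ``estimate`` and its two-sided t-test ``p``.  Genes with zero
    variance after transformation are dropped (logged), not reported as NaN.
    """
    if m.stage != "imputed":
        raise DiffAbundanceError(
            f"fit_gene_models expects an imputed matrix, got stage {m.stage!r}"
        )
    for cov in covariates:
        if cov not in m.metadata.columns:
            raise DiffAbundanceError(f"metadata lacks covariate column {cov!r}")

    X = pd.DataFrame(index=m.metadata.index)
    X["const"] = 1.0
    X[m.disease_col] = m.metadata[m.disease_col].astype(float)
    for cov in covariates:
        X[cov] = pd.to_numeric(m.metadata[cov], errors="raise").astype(float)
    _check_design(X)
    Xmat = X.to_numpy(dtype=float)

    values = np.log2(m.counts.to_numpy(dtype=float))
    sd = values.std(axis=1, ddof=1)
    keep = sd > 0
    if (~keep).any():
        logger.info("dropping %d zero-variance gene(s) before model fits", int((~keep).sum()))
    genes = m.counts.index[keep]
    z = (values[keep] - values[keep].mean(axis=1, keepdims=True)) / sd[keep][:, None]

    disease_idx = list(X.columns).index(m.disease_col)
    estimates = np.empty(len(genes))
    pvals = np.empty(len(genes))
    for i in range(len(genes)):
        fit = sm.OLS(z[i], Xmat).fit()
        estimates[i] = fit.params[disease_idx]
        pvals[i] = fit.pvalues[disease_idx]
    return pd.DataFrame({"estimate": estimates, "p": pvals}, index=genes)


def bh_adjust(pvals: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values with monotone enforcement."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise DiffAbundanceError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    # enforce monotonicity from the largest p downwards
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# Volcano label rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LabelClause:
    """A conjunction of bounds on logFC and p; ``None`` leaves a side open."""

    logfc_gt: float | None = None
    logfc_lt: float | None = None
    p_lt: float | None = None

    def matches(self, logfc: float, p: float) -> bool:
        if self.logfc_gt is not None and not logfc > self.logfc_gt:
            return False
        if self.logfc_lt is not None and not logfc < self.logfc_lt:
            return False
        if self.p_lt is not None and not p < self.p_lt:
            return False
        return True


@dataclass(frozen=True)
class LabelRuleSet:
    """A gene is labeled iff any clause in the disjunction holds."""

    clauses: tuple[LabelClause, ...]

    def matches(self, logfc: float, p: float) -> bool:
        return any(c.matches(logfc, p) for c in self.clauses)


CD_RULES = LabelRuleSet(
    clauses=(
        LabelClause(logfc_gt=0.0),
        LabelClause(logfc_lt=0.0, p_lt=1e-8),
        LabelClause(logfc_lt=-4.5, p_lt=1e-3),
    )
)

IGG4_RULES = LabelRuleSet(
    clauses=(
        LabelClause(logfc_gt=2.0, p_lt=1e-5),
        LabelClause(logfc_lt=-2.0, p_lt=10 ** -3.5),
        LabelClause(logfc_gt=3.0, p_lt=10 ** -2.5),
        LabelClause(logfc_lt=-3.5, p_lt=1e-2),
    )
)

RULE_PRESETS: Mapping[str, LabelRuleSet] = {"cd": CD_RULES, "igg4": IGG4_RULES}


def volcano_labels(results: pd.DataFrame, ruleset: LabelRuleSet) -> pd.Series:
    """Boolean label per gene from a (logFC, p) rule disjunction."""
    for col in ("logFC", "p"):
        if col not in results.columns:
            raise DiffAbundanceError(f"results frame lacks column {col!r}")
    return pd.Series(
        [ruleset.matches(row.logFC, row.p) for row in results.itertuples()],
        index=results.index,
        name="volcano_label",
    )


# ---------------------------------------------------------------------------
# Prioritization
# ---------------------------------------------------------------------------

def percentile_rank(values: pd.Series) -> pd.Series:
    """(rank - 1) / (n - 1) in [0, 1], average ranks for ties."""
    n = len(values)
    if n == 1:
        return pd.Series([1.0], index=values.index)
    ranks = values.rank(method="average")
    return (ranks - 1.0) / (n - 1.0)


def prioritize(
    results: pd.DataFrame, family_probability: Mapping[str, float]
) -> pd.Series:
    """Mean of logFC percentile and CAZyme family probability, sorted
    descending.

    The percentile is computed among *all* genes in the result set; only
    genes with a family probability (i.e. CAZyme-predicted) receive a
    priority — others are excluded and logged.
    """
    if "logFC" not in results.columns:
        raise DiffAbundanceError("results frame lacks column 'logFC'")
    pct = percentile_rank(results["logFC"])
    covered = [g for g in results.index if g in family_probability]
    skipped = len(results) - len(covered)
    if skipped:
        logger.info("prioritize: %d gene(s) without a CAZyme prediction excluded", skipped)
    prio = pd.Series(
        [(pct[g] + float(family_probability[g])) / 2.0 for g in covered],
        index=covered,
        name="priority",
    )
    return prio.sort_values(ascending=False)


# ---------------------------------------------------------------------------
# Full analysis
# ---------------------------------------------------------------------------

def run_differential_abundance(
    m: CountMatrix,
    covariates: Sequence[str] = (),
    min_prev: float = 0.10,
    ruleset: LabelRuleSet = CD_RULES,
    fdr: float = FDR_THRESHOLD,
    family_probability: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Filter -> impute -> logFC -> per-gene OLS -> BH -> labels -> priority."""
    filtered = prevalence_filter(m, min_prev=min_prev)
    imputed = zero_impute(filtered)
    logfc = log_fold_change(imputed)
    fits = fit_gene_models(imputed, covariates=covariates)
    out = fits.join(logfc, how="left")
    out["q"] = bh_adjust(out["p"])
    out["significant"] = out["q"] <= fdr
    out["volcano_label"] = volcano_labels(out, ruleset)
    if family_probability is not None:
        prio = prioritize(out, family_probability)
        out["priority"] = prio.reindex(out.index)
    return out[
        ["logFC", "estimate", "p", "q", "significant", "volcano_label"]
        + (["priority"] if family_probability is not None else [])
    ]
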