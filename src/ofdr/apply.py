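"""Ordered-category differential expression front-end.

Takes a genes x samples expression matrix with an ordered sample annotation
(time points or dose levels), forms one hypothesis set per gene from either
successive-difference or baseline contrasts, computes per-contrast two-sample
t-tests, runs a set-testing procedure, and reports per-gene calls
(induced / suppressed / mixed) together with a dose-sensitivity tabulation —
how many contrasts each significant gene is significant in.

Expression values are assumed already normalized and on a scale where a
two-sample t-test per contrast is sensible (e.g. log intensities); no
preprocessing is performed here.  Direction +1 means higher expression at the
later / dosed category ("induced").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import DecisionReport, PValueSetCollection, run_procedure

__all__ = [
    "ExpressionDataset",
    "ContrastDesign",
    "GeneReport",
    "read_expression",
    "compute_contrast_pvalues",
    "analyze",
]


@dataclass
class ExpressionDataset:
    """Expression matrix plus an ordered categorical sample annotation."""

    values: pd.DataFrame          # genes x samples
    sample_category: pd.Series    # ordered categorical, indexed by sample

    def __post_init__(self):
        if not self.values.index.is_unique:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene id(s): {dupes[:5]}")
        unknown = [s for s in self.sample_category.index if s not in self.values.columns]
        if unknown:
            raise ValueError(f"annotation references unknown sample(s): {unknown[:5]}")
        missing = [s for s in self.values.columns if s not in self.sample_category.index]
        if missing:
            raise ValueError(f"sample(s) missing from the annotation: {missing[:5]}")
        if not isinstance(self.sample_category.dtype, pd.CategoricalDtype):
            self.sample_category = self.sample_category.astype("category")
        if not self.sample_category.cat.ordered:
            self.sample_category = self.sample_category.cat.as_ordered()
        if self.sample_category.isna().any():
            raise ValueError("every sample needs a category label")
        if len(self.categories) < 2:
            raise ValueError("need at least two ordered categories")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def categories(self) -> list:
        return list(self.sample_category.cat.categories)

    def samples_in(self, category) -> list:
        mask = self.sample_category == category
        return list(self.sample_category.index[mask])


@dataclass
class ContrastDesign:
    """Which per-gene comparisons make up the hypothesis set.

    ``successive`` compares each category with the previous one (j+1 vs j);
    ``baseline`` compares each non-first category with the first.  Both yield
    q = n_categories - 1 contrasts, ordered, stored as (earlier, later) pairs.
    """

    mode: str
    contrasts: list[tuple]

    @classmethod
    def from_categories(cls, categories: list, mode: str = "baseline") -> "ContrastDesign":
        if mode == "successive":
            pairs = [(a, b) for a, b in zip(categories[:-1], categories[1:])]
        elif mode == "baseline":
            pairs = [(categories[0], b) for b in categories[1:]]
        else:
            raise ValueError(f"mode must be 'successive' or 'baseline', got {mode!r}")
        return cls(mode=mode, contrasts=pairs)

    @property
    def q(self) -> int:
        return len(self.contrasts)


def read_expression(matrix_path, annotation_path) -> ExpressionDataset:
    """Read a TSV expression matrix and a sample annotation TSV.

    The matrix has gene ids in the first column and one column per sample.
    The annotation needs columns ``sample_id``, ``category`` and
    ``category_order`` (a sortable key defining the category ordering).
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    ann = pd.read_csv(annotation_path, sep="\t")
    required = {"sample_id", "category", "category_order"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"annotation is missing column(s): {sorted(missing)}")
    ordered = ann.sort_values("category_order")
    categories = list(dict.fromkeys(ordered["category"]))
    cat = pd.Series(
        pd.Categorical(ann["category"], categories=categories, ordered=True).astype(object),
        index=ann["sample_id"].tolist(),
    ).astype(pd.CategoricalDtype(categories, ordered=True))
    return ExpressionDataset(values=values, sample_category=cat)


def _ttest(a: np.ndarray, b: np.ndarray, equal_var: bool) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sided t-test p-values and mean-difference signs (b - a)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(b, a, axis=1, equal_var=equal_var, nan_policy="omit")
        diff = np.nanmean(b, axis=1) - np.nanmean(a, axis=1)
    p = np.asarray(res.pvalue, dtype=float)
    sign = np.sign(diff).astype(int)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        # zero variance on both sides: equal means are uninformative (p = 1),
        # separated means are an unambiguous difference (p -> 0)
        p = p.copy()
        separated = degenerate & (diff != 0)
        p[degenerate] = 1.0
        p[separated] = 0.0
        sign[degenerate & ~separated] = 0
        if np.any(degenerate & ~separated):
            warnings.warn(
                f"{int(np.sum(degenerate & ~separated))} contrast(s) with zero variance "
                "and equal means; reported p = 1 with no direction",
                UserWarning,
                stacklevel=3,
            )
    return p, sign


def compute_contrast_pvalues(
    dataset: ExpressionDataset, design: ContrastDesign, test: str = "welch_t"
) -> PValueSetCollection:
    """Per-gene, per-contrast two-sample t-test p-values and signs.

    ``welch_t`` (default) does not assume equal group variances; ``pooled_t``
    is the classical equal-variance test.  The sign is that of the mean
    difference, later/dosed category minus earlier/baseline.  A contrast with
    fewer than two non-missing replicates on either side is uninformative and
    reported as p = 1, sign 0, with a warning.
    """
    if test not in ("welch_t", "pooled_t"):
        raise ValueError(f"test must be 'welch_t' or 'pooled_t', got {test!r}")
    equal_var = test == "pooled_t"
    n_genes = len(dataset.gene_ids)
    P = np.empty((n_genes, design.q))
    S = np.empty((n_genes, design.q), dtype=int)
    for j, (cat_a, cat_b) in enumerate(design.contrasts):
        a = dataset.values[dataset.samples_in(cat_a)].to_numpy(dtype=float)
        b = dataset.values[dataset.samples_in(cat_b)].to_numpy(dtype=float)
        if a.shape[1] < 2 or b.shape[1] < 2:
            raise ValueError(
                f"contrast {cat_a!r} vs {cat_b!r} needs >= 2 replicates per category"
            )
        p, sign = _ttest(a, b, equal_var)
        thin = (np.sum(~np.isnan(a), axis=1) < 2) | (np.sum(~np.isnan(b), axis=1) < 2)
        if thin.any():
            warnings.warn(
                f"{int(thin.sum())} gene(s) have < 2 non-missing replicates for contrast "
                f"{cat_a!r} vs {cat_b!r}; their p-values are set to 1",
                UserWarning,
                stacklevel=2,
            )
            p[thin] = 1.0
            sign[thin] = 0
        P[:, j] = p
        S[:, j] = sign
    return PValueSetCollection(P, S, list(dataset.gene_ids))


def _call(direction_row: np.ndarray) -> str:
    nonzero = direction_row[direction_row != 0]
    if nonzero.size == 0:
        return "none"
    if np.all(nonzero == 1):
        return "induced"
    if np.all(nonzero == -1):
        return "suppressed"
    return "mixed"


@dataclass
class GeneReport:
    """Gene-level results of an ordered-category analysis."""

    decisions: DecisionReport
    design: ContrastDesign
    gene_table: pd.DataFrame        # gene_id, screening_p, rejected, call, n_significant
    contrast_table: pd.DataFrame    # long: gene_id, contrast, rejected, direction
    sensitivity_table: pd.DataFrame  # rejected-gene counts by number of significant contrasts

    @property
    def n_rejected_genes(self) -> int:
        return int(self.gene_table["rejected"].sum())

    def summary(self) -> str:
        calls = self.gene_table.loc[self.gene_table["rejected"], "call"].value_counts()
        lines = [
            self.decisions.summary(),
            f"  design: {self.design.mode} ({self.design.q} contrasts per gene)",
            f"  genes called induced:   {int(calls.get('induced', 0))}",
            f"  genes called suppressed: {int(calls.get('suppressed', 0))}",
            f"  genes called mixed:     {int(calls.get('mixed', 0))}",
            "  significant-contrast distribution (1..q): "
            + ", ".join(
                f"{int(k)}: {int(v)}"
                for k, v in zip(
                    self.sensitivity_table["n_contrasts"], self.sensitivity_table["n_genes"]
                )
            ),
        ]
        return "\n".join(lines)


def analyze(
    dataset: ExpressionDataset,
    design: ContrastDesign | str = "baseline",
    method: str = "hochberg",
    alpha: float = 0.05,
    test: str = "welch_t",
) -> GeneReport:
    """Full ordered-category analysis: tests, procedure, calls, tabulation."""
    if isinstance(design, str):
        design = ContrastDesign.from_categories(dataset.categories, design)
    collection = compute_contrast_pvalues(dataset, design, test)
    decisions = run_procedure(collection, alpha, method)

    directions = np.vstack(decisions.direction)
    rejected = np.vstack(decisions.individual_rejected)
    n_sig = rejected.sum(axis=1)
    gene_table = pd.DataFrame(
        {
            "gene_id": list(dataset.gene_ids),
            "screening_p": decisions.screening.p0,
            "rejected": decisions.screening.rejected,
            "call": [
                _call(directions[i]) if decisions.screening.rejected[i] else "none"
                for i in range(len(dataset.gene_ids))
            ],
            "n_significant": n_sig,
        }
    )
    contrast_names = [f"{a}_vs_{b}" for a, b in design.contrasts]
    contrast_table = decisions.hypothesis_table().rename(columns={"set_id": "gene_id"})
    contrast_table["contrast"] = np.tile(contrast_names, len(dataset.gene_ids))
    contrast_table = contrast_table[["gene_id", "contrast", "rejected", "direction"]]

    counts = [
        int(np.sum(n_sig[decisions.screening.rejected] == k))
        for k in range(1, design.q + 1)
    ]
    sensitivity_table = pd.DataFrame(
        {"n_contrasts": np.arange(1, design.q + 1), "n_genes": counts}
    )
    return GeneReport(
        decisions=decisions,
        design=design,
        gene_table=gene_table,
        contrast_table=contrast_table,
        sensitivity_table=sensitivity_table,
    )
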