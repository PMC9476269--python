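"""Subtype-specific gene selection and signature-matrix construction.

The signature matrix is the deconvolution design: one column of median
linear expression per renal-cell-carcinoma subtype (clear cell ccRCC,
papillary pRCC, chromophobe chRCC), restricted to genes that are
specifically up-regulated in exactly one subtype relative to both others.

Gene selection combines a fold-change filter (subtype median at least
``min_fold`` times the median of *each* other subtype, with a small
pseudocount) with a one-sided rank-sum test against each other subtype,
Holm-corrected within the per-gene pair of contrasts.  Genes are ranked by
the smaller of their two pairwise fold changes (descending; ties broken
lexicographically by gene id), and the top-k per subtype enter the matrix.

Signature size k is chosen on an independent tuning cohort: matrices of
increasing k are used to deconvolve the tuning samples and the largest k
whose proportion assignments still change substantially relative to the
previous matrix is kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import holm_adjust
from .expression import LINEAR, ExpressionMatrix, ExpressionError

log = logging.getLogger(__name__)

SUBTYPES = ("ccRCC", "pRCC", "chRCC")
FOLD_PSEUDOCOUNT = 1e-6


class SignatureError(ValueError):
    """Invalid signature construction request or content."""


@dataclass
class SignatureMatrix:
    """Genes × subtypes matrix of median linear reference expression.

    ``data`` has one row per signature gene and the three subtype columns in
    :data:`SUBTYPES` order.  ``per_subtype_genes`` records which genes were
    selected for which subtype; the three sets are disjoint and their union
    equals the row set.  ``k`` is the per-subtype gene count for freshly
    built matrices, or ``None`` after alignment has dropped genes.
    """

    data: pd.DataFrame
    per_subtype_genes: dict[str, list[str]]
    k: int | None = None

    def __post_init__(self) -> None:
        if list(self.data.columns) != list(SUBTYPES):
            raise SignatureError(f"signature columns must be {SUBTYPES}, got {list(self.data.columns)}")
        if self.data.index.has_duplicates:
            raise SignatureError("duplicate gene ids in signature")
        if self.data.size and float(self.data.to_numpy().min()) < 0:
            raise SignatureError("signature medians must be non-negative (linear scale)")
        sets = [set(self.per_subtype_genes.get(s, ())) for s in SUBTYPES]
        for i in range(3):
            for j in range(i + 1, 3):
                common = sets[i] & sets[j]
                if common:
                    raise SignatureError(f"per-subtype gene sets overlap: {sorted(common)[:5]}")
        union = sets[0] | sets[1] | sets[2]
        if union != set(self.data.index):
            raise SignatureError("per-subtype gene sets do not partition the signature rows")
        if self.k is not None and len(self.data) != 3 * self.k:
            raise SignatureError(f"expected {3 * self.k} rows for k={self.k}, got {len(self.data)}")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_genes(self) -> int:
        return len(self.data)

    def column(self, subtype: str) -> np.ndarray:
        return self.data[subtype].to_numpy(dtype=float)

    def subset(self, genes: list[str]) -> "SignatureMatrix":
        """Restrict to a gene subset (keeps signature row order)."""
        keep = [g for g in self.genes if g in set(genes)]
        per = {s: [g for g in gl if g in set(keep)] for s, gl in self.per_subtype_genes.items()}
        return SignatureMatrix(self.data.loc[keep], per, k=None)

    def to_tsv(self, path) -> None:
        out = pd.DataFrame(
            {
                "gene_id": self.genes,
                "subtype": [self._subtype_of(g) for g in self.genes],
                "median_ccRCC": self.data["ccRCC"].to_numpy(),
                "median_pRCC": self.data["pRCC"].to_numpy(),
                "median_chRCC": self.data["chRCC"].to_numpy(),
            }
        )
        out.to_csv(path, sep="\t", index=False)

    def _subtype_of(self, gene: str) -> str:
        for s in SUBTYPES:
            if gene in set(self.per_subtype_genes.get(s, ())):
                return s
        raise SignatureError(f"gene {gene!r} not assigned to a subtype")

    @classmethod
    def from_tsv(cls, path) -> "SignatureMatrix":
        df = pd.read_csv(path, sep="\t", comment="#")
        required = {"gene_id", "subtype", "median_ccRCC", "median_pRCC", "median_chRCC"}
        if not required.issubset(df.columns):
            raise SignatureError(f"signature file missing columns {sorted(required - set(df.columns))}")
        data = pd.DataFrame(
            {
                "ccRCC": pd.to_numeric(df["median_ccRCC"], errors="raise").to_numpy(),
                "pRCC": pd.to_numeric(df["median_pRCC"], errors="raise").to_numpy(),
                "chRCC": pd.to_numeric(df["median_chRCC"], errors="raise").to_numpy(),
            },
            index=pd.Index(df["gene_id"].astype(str), name="gene_id"),
        )
        per: dict[str, list[str]] = {s: [] for s in SUBTYPES}
        for gene, sub in zip(df["gene_id"].astype(str), df["subtype"].astype(str)):
            if sub not in SUBTYPES:
                raise SignatureError(f"unknown subtype {sub!r} for gene {gene!r}")
            per[sub].append(gene)
        k = len(per[SUBTYPES[0]])
        same_k = all(len(per[s]) == k for s in SUBTYPES)
        return cls(data, per, k=k if same_k else None)


def _check_labels(m: ExpressionMatrix, labels: pd.Series, min_per_subtype: int = 3) -> pd.Series:
    labels = pd.Series(labels)
    labels = labels.reindex(m.samples)
    if labels.isna().any():
        missing = labels.index[labels.isna()].tolist()
        raise SignatureError(f"missing subtype labels for samples: {missing[:10]}")
    bad = set(labels.unique()) - set(SUBTYPES)
    if bad:
        raise SignatureError(f"unknown subtype labels: {sorted(bad)}")
    counts = labels.value_counts()
    for s in SUBTYPES:
        if counts.get(s, 0) < min_per_subtype:
            raise SignatureError(
                f"subtype {s} has {counts.get(s, 0)} samples; at least {min_per_subtype} required"
            )
    return labels


def select_subtype_specific_genes(
    train: ExpressionMatrix,
    labels: pd.Series,
    min_fold: float = 2.0,
    alpha: float = 0.05,
) -> dict[str, list[str]]:
    """Rank genes specifically up-regulated in exactly one subtype.

    A gene is specific to subtype s iff its median expression in s is at
    least ``min_fold`` times the median in *each* of the other two subtypes
    (pseudocount 1e−6 in the denominator) and a one-sided Wilcoxon rank-sum
    test of s versus each other subtype is significant at ``alpha`` after
    Holm correction over the gene's two contrasts.  Ranking key is the
    minimum of the two pairwise fold changes, descending; ties break
    lexicographically by gene id.  Empty lists are legal results.
    """
    if train.scale != LINEAR:
        raise ExpressionError("gene selection requires linear-scale training data")
    labels = _check_labels(train, labels)
    values = train.values
    genes = np.asarray(train.genes)
    groups = {s: values[:, (labels == s).to_numpy()] for s in SUBTYPES}
    medians = {s: np.median(groups[s], axis=1) for s in SUBTYPES}

    result: dict[str, list[str]] = {}
    for s in SUBTYPES:
        others = [o for o in SUBTYPES if o != s]
        folds = np.stack(
            [medians[s] / (medians[o] + FOLD_PSEUDOCOUNT) for o in others], axis=1
        )
        min_fold_change = folds.min(axis=1)
        candidate = min_fold_change >= min_fold
        selected_idx: list[int] = []
        if candidate.any():
            idx = np.flatnonzero(candidate)
            pvals = np.empty((idx.size, 2))
            for j, o in enumerate(others):
                res = stats.mannwhitneyu(
                    groups[s][idx], groups[o][idx], alternative="greater", axis=1
                )
                pvals[:, j] = res.pvalue
            for row, gi in enumerate(idx):
                adj = holm_adjust(pvals[row])
                if np.all(adj < alpha):
                    selected_idx.append(gi)
        order = sorted(
            selected_idx, key=lambda gi: (-min_fold_change[gi], str(genes[gi]))
        )
        result[s] = [str(genes[gi]) for gi in order]
        log.info("subtype %s: %d specific genes", s, len(result[s]))
    return result


def build_signature_matrix(
    train: ExpressionMatrix,
    labels: pd.Series,
    selected: dict[str, list[str]],
    k: int,
) -> SignatureMatrix:
    """Build the median-expression signature from the top-k genes per subtype."""
    if train.scale != LINEAR:
        raise ExpressionError("signature construction requires linear-scale training data")
    labels = _check_labels(train, labels)
    for s in SUBTYPES:
        if len(selected.get(s, ())) < k:
            raise SignatureError(
                f"subtype {s} has only {len(selected.get(s, ()))} ranked genes; k={k} requested"
            )
    per = {s: list(selected[s][:k]) for s in SUBTYPES}
    rows = [g for s in SUBTYPES for g in per[s]]
    sub = train.data.loc[rows]
    cols = {
        s: np.median(sub.loc[:, (labels == s).to_numpy()].to_numpy(), axis=1)
        for s in SUBTYPES
    }
    data = pd.DataFrame(cols, index=pd.Index(rows, name="gene_id"))[list(SUBTYPES)]
    return SignatureMatrix(data, per, k=k)


@dataclass
class SignatureSelectionResult:
    """Chosen signature plus the per-k mean L1 proportion-shift trace."""

    signature: SignatureMatrix
    trace: pd.DataFrame  # columns: k, delta (NaN for the first k)
    chosen_k: int
    candidates: dict[int, SignatureMatrix] = field(repr=False, default_factory=dict)


def iterative_signature_selection(
    train: ExpressionMatrix,
    labels: pd.Series,
    tuning: ExpressionMatrix,
    start_k: int = 2,
    step: int = 2,
    max_k: int = 100,
    change_tol: float = 0.01,
    min_fold: float = 2.0,
    alpha: float = 0.05,
) -> SignatureSelectionResult:
    """Grow the signature until deconvolution of a tuning cohort stabilizes.

    For k = start_k, start_k+step, … ≤ max_k a candidate matrix M_k is built
    and used to deconvolve the tuning cohort; Δ_k is the mean per-sample L1
    distance between the proportion vectors under M_k and under the previous
    matrix.  The largest k with Δ_k ≥ ``change_tol`` is selected (start_k if
    no step produces a substantial change).
    """
    from .deconvolution import deconvolve_cohort

    if start_k < 2:
        raise SignatureError("start_k must be ≥ 2")
    if max_k < start_k:
        raise SignatureError(f"max_k={max_k} below start_k={start_k}")
    selected = select_subtype_specific_genes(train, labels, min_fold=min_fold, alpha=alpha)
    available = min(len(selected[s]) for s in SUBTYPES)
    if available < start_k:
        raise SignatureError(
            f"only {available} selectable genes per subtype; start_k={start_k} not reachable"
        )
    grid = [k for k in range(start_k, max_k + 1, step) if k <= available]

    candidates: dict[int, SignatureMatrix] = {}
    prev_props: pd.DataFrame | None = None
    rows = []
    chosen_k = grid[0]
    for k in grid:
        sig_k = build_signature_matrix(train, labels, selected, k)
        candidates[k] = sig_k
        table = deconvolve_cohort(tuning, sig_k)
        props = table[["prop_cc", "prop_p", "prop_h"]]
        delta = np.nan
        if prev_props is not None:
            both = props.notna().all(axis=1) & prev_props.notna().all(axis=1)
            if not both.any():
                raise SignatureError("no tuning sample deconvolvable under consecutive matrices")
            delta = float(
                np.abs(props[both].to_numpy() - prev_props[both].to_numpy()).sum(axis=1).mean()
            )
            if delta >= change_tol:
                chosen_k = k
        rows.append({"k": k, "delta": delta})
        prev_props = props
    trace = pd.DataFrame(rows)
    log.info("iterative selection chose k=%d (grid %s)", chosen_k, grid)
    return SignatureSelectionResult(
        signature=candidates[chosen_k], trace=trace, chosen_k=chosen_k, candidates=candidates
    )
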