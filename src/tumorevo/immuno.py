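"""Immune repertoire, neoantigen, and expression-signature comparisons.

Covers the immunogenomic layer of the pipeline: Horn's modified Morisita
overlap index between clonotype repertoires (abundance-weighted, computed
on relative abundances, so it is invariant to sequencing depth), pre- vs
posttreatment contrasts of pairwise overlap, neoantigen burden and
intersample overlap counts, MHC binding-rank classification, mean-expression
signature scoring, differential-expression threshold filtering, and the
preranked gene score -log10(p) * log2(fold change) used to order genes for
enrichment analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import GroupContrastResult, students_t_test

__all__ = [
    "GeneSignature",
    "OverlapContrast",
    "EmptyRepertoireError",
    "MissingSignatureError",
    "morisita_horn",
    "repertoire_matrix",
    "overlap_matrix",
    "compare_overlap_groups",
    "neoantigen_burden",
    "neoantigen_overlap_counts",
    "classify_binder",
    "signature_score",
    "apply_de_filters",
    "prerank_gene_score",
]


class EmptyRepertoireError(ValueError):
    """A repertoire with zero total count has no defined overlap index."""


class MissingSignatureError(KeyError):
    """None of a signature's genes appear in the expression matrix."""


@dataclass(frozen=True)
class GeneSignature:
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"signature {self.name!r} has no genes")


def morisita_horn(x, y) -> float:
    """Horn's modified Morisita overlap index on relative abundances.

    With p_i = x_i / sum(x) and q_i = y_i / sum(y):

        MH = 2 sum(p_i q_i) / (sum(p_i^2) + sum(q_i^2))

    Both vectors index the same clonotype universe. The index lies in
    [0, 1]: 1 for identical relative abundances, 0 for disjoint supports,
    and it is invariant to scaling either count vector.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("count vectors must be 1-D and of equal length")
    if (xa < 0).any() or (ya < 0).any():
        raise ValueError("counts must be nonnegative")
    sx, sy = xa.sum(), ya.sum()
    if sx == 0 or sy == 0:
        raise EmptyRepertoireError("overlap undefined for an empty repertoire")
    p, q = xa / sx, ya / sy
    denom = (p**2).sum() + (q**2).sum()
    return float(min(max(2.0 * (p * q).sum() / denom, 0.0), 1.0))


def repertoire_matrix(reps: pd.DataFrame) -> pd.DataFrame:
    """Pivot a tidy clonotype table (sample_id, clonotype, count) to a
    sample-by-clonotype count matrix over the union clonotype universe."""
    if (reps["count"] <= 0).any():
        raise ValueError("clonotype counts must be positive integers")
    if reps.duplicated(["sample_id", "clonotype"]).any():
        raise ValueError("clonotype keys must be unique within a sample")
    return (
        reps.pivot(index="sample_id", columns="clonotype", values="count")
        .fillna(0.0)
        .sort_index()
    )


def overlap_matrix(reps: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Morisita-Horn matrix over all samples of a tidy clonotype
    table; diagonal 1."""
    mat = repertoire_matrix(reps)
    if len(mat) < 2:
        raise ValueError("need at least 2 samples")
    samples = list(mat.index)
    out = pd.DataFrame(np.eye(len(samples)), index=samples, columns=samples)
    for i, a in enumerate(samples):
        for b in samples[i + 1 :]:
            v = morisita_horn(mat.loc[a].to_numpy(), mat.loc[b].to_numpy())
            out.loc[a, b] = out.loc[b, a] = v
    return out


@dataclass
class OverlapContrast:
    """Pre/post contrast of pairwise overlap values.

    ``pair_values`` maps 'pre-pre' / 'pre-post' / 'post-post' to the
    off-diagonal index values in each pair class; ``insufficient`` flags
    classes with fewer than 2 pairs. ``test`` contrasts post-post against
    pre-post (None when either class is insufficient).
    """

    pair_values: dict[str, np.ndarray]
    group_means: dict[str, float]
    insufficient: dict[str, bool]
    test: GroupContrastResult | None


def compare_overlap_groups(m, phases) -> OverlapContrast:
    """Partition off-diagonal overlap values by phase pair and contrast
    post-post versus pre-post with a two-sided Student's t test.

    ``m`` is a square overlap matrix (DataFrame or ndarray); ``phases``
    gives each sample's phase in {pre, post}, aligned with the matrix.
    """
    if isinstance(m, pd.DataFrame):
        labels = [str(phases[s]) for s in m.index]
        vals = m.to_numpy(float)
    else:
        vals = np.asarray(m, dtype=float)
        labels = [str(p) for p in phases]
    n = vals.shape[0]
    if vals.shape != (n, n) or len(labels) != n:
        raise ValueError("matrix and phases are misaligned")
    bad = set(labels) - {"pre", "post"}
    if bad:
        raise ValueError(f"unknown phase labels: {sorted(bad)}")
    groups: dict[str, list[float]] = {"pre-pre": [], "pre-post": [], "post-post": []}
    for i in range(n):
        for j in range(i + 1, n):
            key = "-".join(sorted((labels[i], labels[j]), reverse=True))
            groups[key].append(vals[i, j])
    pair_values = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    insufficient = {k: len(v) < 2 for k, v in pair_values.items()}
    group_means = {
        k: (float(v.mean()) if len(v) else float("nan")) for k, v in pair_values.items()
    }
    test = None
    if not insufficient["post-post"] and not insufficient["pre-post"]:
        test = students_t_test(pair_values["post-post"], pair_values["pre-post"])
    return OverlapContrast(
        pair_values=pair_values,
        group_means=group_means,
        insufficient=insufficient,
        test=test,
    )


# ---------------------------------------------------------------------------
# neoantigens
# ---------------------------------------------------------------------------

def neoantigen_burden(t: pd.DataFrame, rank_cutoff: float = 2.0) -> pd.Series:
    """Distinct predicted peptides with binding rank <= ``rank_cutoff`` per
    sample. ``t`` has columns sample_id, peptide, binding_rank."""
    if (t["binding_rank"] < 0).any():
        raise ValueError("binding ranks must be nonnegative")
    keep = t.loc[t["binding_rank"] <= rank_cutoff]
    counts = keep.groupby("sample_id")["peptide"].nunique()
    return counts.reindex(sorted(t["sample_id"].unique()), fill_value=0).astype(int)


def neoantigen_overlap_counts(
    t: pd.DataFrame, rank_cutoff: float | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise intersection sizes of per-sample peptide sets, plus the
    log10(count + 1) display transform. Self-pairs give the set size.
    Optionally restrict to binders at ``rank_cutoff`` first."""
    if rank_cutoff is not None:
        t = t.loc[t["binding_rank"] <= rank_cutoff]
    samples = sorted(t["sample_id"].unique())
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    sets = {s: set(t.loc[t["sample_id"] == s, "peptide"]) for s in samples}
    counts = pd.DataFrame(0, index=samples, columns=samples, dtype=int)
    for i, a in enumerate(samples):
        for b in samples[i:]:
            c = len(sets[a] & sets[b])
            counts.loc[a, b] = counts.loc[b, a] = c
    return counts, np.log10(counts + 1.0)


def classify_binder(
    binding_rank: float, strong: float = 0.5, weak: float = 2.0
) -> str:
    """MHC binding class from a percentile rank: <= ``strong`` percentile
    is a strong binder, <= ``weak`` (inclusive) a weak binder, otherwise a
    non-binder."""
    if not strong < weak:
        raise ValueError("strong threshold must be below weak threshold")
    if binding_rank < 0:
        raise ValueError("binding rank must be nonnegative")
    if binding_rank <= strong:
        return "strong"
    if binding_rank <= weak:
        return "weak"
    return "non-binder"


# ---------------------------------------------------------------------------
# expression signatures and DE thresholds
# ---------------------------------------------------------------------------

def signature_score(
    expr: pd.DataFrame, sig: GeneSignature, log_transform: bool = False
) -> tuple[pd.Series, int]:
    """Per-sample signature score: unweighted mean expression over the
    signature genes present in the matrix. Returns (scores, n_genes_used).
    With ``log_transform`` the mean is taken on log2(x + 1) values."""
    present = sorted(sig.genes & set(expr.index))
    if not present:
        raise MissingSignatureError(
            f"no gene of signature {sig.name!r} is in the expression matrix"
        )
    sub = expr.loc[present]
    if log_transform:
        sub = np.log2(sub + 1.0)
    scores = sub.mean(axis=0)
    scores.name = sig.name
    return scores, len(present)


def apply_de_filters(
    stats: pd.DataFrame,
    fc_min: float = 1.5,
    padj_max: float = 0.05,
    basemean_min: float = 10.0,
) -> tuple[set[str], set[str]]:
    """Differential-expression threshold filter with strict inequalities.

    up   = fold_change > fc_min     and p_adj < padj_max and base_mean > basemean_min
    down = fold_change < 1 / fc_min and p_adj < padj_max and base_mean > basemean_min

    ``stats`` has columns gene, fold_change, p_adj, base_mean.
    """
    if ((stats["p_adj"] < 0) | (stats["p_adj"] > 1)).any():
        raise ValueError("adjusted p-values must lie in [0, 1]")
    if (stats["base_mean"] < 0).any():
        raise ValueError("base means must be nonnegative")
    common = (stats["p_adj"] < padj_max) & (stats["base_mean"] > basemean_min)
    up = set(stats.loc[common & (stats["fold_change"] > fc_min), "gene"])
    down = set(stats.loc[common & (stats["fold_change"] < 1.0 / fc_min), "gene"])
    return up, down


def prerank_gene_score(
    p_value: float, fold_change: float, p_floor: float = 1e-300
) -> float:
    """Preranked gene score -log10(p) * log2(fold change).

    Monotone decreasing in p at fixed fold change > 1; the sign follows
    the direction of change. p-values at or below zero are floored at
    ``p_floor`` with a warning.
    """
    if fold_change <= 0:
        raise ValueError("fold change must be positive")
    if p_value > 1:
        raise ValueError("p-value must be <= 1")
    if p_value <= 0:
        warnings.warn(
            f"p-value {p_value!r} floored at {p_floor}", RuntimeWarning, stacklevel=2
        )
        p_value = p_floor
    return float(-np.log10(p_value) * np.log2(fold_change))
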