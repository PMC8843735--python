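"""Clonal reconstruction and sample phylogenies from cellular prevalences.

Pipeline implemented here, in running order:

1. ``pyclone_input_filter`` — the clustering input filter: depth > 20 in
   all samples, MAF > 0.15 in any sample, and a valid copy-number call at
   the locus in every sample.
2. ``vaf_to_cp`` — the purity/copy-number correction turning a variant
   allele fraction into a cellular prevalence (CP), the fraction of tumor
   cells carrying the mutation:

       CP = VAF * (rho * C_T + (1 - rho) * 2) / (rho * m)

   with tumor purity rho, total tumor copy number C_T at the locus, and
   mutation multiplicity m (default 1: the mutation sits on one copy).
3. ``cluster_variants`` — a multi-sample binomial-mixture EM that groups
   variants into clones sharing a CP vector across samples, with BIC model
   selection over a range of clone counts. This plays the role of a
   variational clonal-inference tool (PyClone-style) with the same
   input/output contract: read counts + purity + copy number in, clone
   assignments and a clone-by-sample CP matrix out.
4. ``cp_to_distribution`` / ``jensen_shannon_divergence`` /
   ``pairwise_distances`` — each sample's clone-prevalence column is
   normalized to a probability distribution and samples are compared by
   the Jensen-Shannon divergence in bits (base-2 logs, so the divergence
   is bounded by 1).
5. ``neighbor_joining`` — canonical Saitou-Nei neighbor joining on the JSD
   matrix, with deterministic tie-breaking and negative branch lengths
   clamped to zero (raw values kept in diagnostics).
6. ``classify_seeding`` / ``founding_clone`` — per-sample monoclonal vs
   polyclonal seeding calls and founding-clone identification from the CP
   matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from skbio import TreeNode

from .filtering import CohortVariantTable, copy_number_matrix

__all__ = [
    "ClonePrevalenceMatrix",
    "DistanceMatrix",
    "PhyloTree",
    "ClusterModel",
    "DegenerateSampleError",
    "ConvergenceError",
    "pyclone_input_filter",
    "vaf_to_cp",
    "expected_vaf",
    "cluster_variants",
    "cp_to_distribution",
    "jensen_shannon_divergence",
    "pairwise_distances",
    "neighbor_joining",
    "classify_seeding",
    "founding_clone",
    "newick_string",
]


class DegenerateSampleError(ValueError):
    """A sample's clone-prevalence column is all zero (no clone present)."""


class ConvergenceError(RuntimeError):
    """EM failed to produce a finite fit for any clone count."""


@dataclass
class ClonePrevalenceMatrix:
    """Clone-by-sample cellular prevalence matrix.

    ``cp`` is a DataFrame with clone ids as index and sample ids as
    columns, entries in [0, 1]. ``n_mutations`` counts the mutations
    assigned to each clone.
    """

    cp: pd.DataFrame
    n_mutations: pd.Series

    def __post_init__(self) -> None:
        vals = self.cp.to_numpy(float)
        if ((vals < -1e-12) | (vals > 1 + 1e-12)).any():
            raise ValueError("cellular prevalences must lie in [0, 1]")
        self.cp = self.cp.clip(0.0, 1.0)
        self.n_mutations = self.n_mutations.reindex(self.cp.index)
        if self.n_mutations.isna().any() or (self.n_mutations < 1).any():
            raise ValueError("every clone needs n_mutations >= 1")

    @property
    def clone_ids(self) -> list[str]:
        return list(self.cp.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.cp.columns)


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative sample-by-sample distance matrix."""

    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        d = np.asarray(self.values, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] != len(self.sample_ids):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if (np.diag(d) != 0).any():
            raise ValueError("distance matrix diagonal must be zero")
        if (d < 0).any():
            raise ValueError("distances must be nonnegative")
        self.values = d

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class PhyloTree:
    """Unrooted weighted tree over samples (leaves), skbio-backed.

    The unrooted tree is stored with a trifurcating root node, the usual
    convention for neighbor-joining output. ``diagnostics`` records raw
    (pre-clamp) negative branch lengths keyed by child node.
    """

    root: TreeNode
    diagnostics: dict = field(default_factory=dict)

    @property
    def leaf_names(self) -> list[str]:
        return sorted(t.name for t in self.root.tips())

    @property
    def newick(self) -> str:
        return newick_string(self)

    def tip_distances(self) -> pd.DataFrame:
        dm = self.root.tip_tip_distances()
        return pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))


@dataclass
class ClusterModel:
    """Fitted clone mixture: assignments, CP estimates and fit scores."""

    K: int
    assignment: pd.Series  # variant_id -> clone id
    cp_hat: ClonePrevalenceMatrix
    weights: pd.Series
    loglik: float
    bic: float
    bic_by_k: dict[int, float]
    n_iter: int
    converged: bool


# ---------------------------------------------------------------------------
# input filter and the VAF <-> CP transform
# ---------------------------------------------------------------------------

def pyclone_input_filter(
    table: CohortVariantTable,
    cn: pd.DataFrame,
    min_depth: int = 20,
    min_maf: float = 0.15,
) -> set[str]:
    """Variants eligible for clonal clustering.

    Keeps a variant iff (a) depth strictly greater than ``min_depth`` in
    *all* samples (a sample without an observation fails), (b) MAF strictly
    greater than ``min_maf`` in *any* sample, and (c) a copy-number segment
    covers the locus in *every* sample.
    """
    obs = table.observations
    n_samples = len(table.sample_ids)
    depth_ok = (
        obs.loc[obs["depth"] > min_depth]
        .groupby("variant_id")["sample_id"]
        .nunique()
    )
    cand = set(depth_ok.index[depth_ok == n_samples])
    if not cand:
        return set()
    maf_ok = obs.groupby("variant_id")["maf"].max()
    cand &= set(maf_ok.index[maf_ok > min_maf])
    if not cand:
        return set()
    loci = (
        obs.loc[obs["variant_id"].isin(cand), ["variant_id", "chrom", "pos"]]
        .drop_duplicates("variant_id")
        .set_index("variant_id")
    )
    cn_mat = copy_number_matrix(cn, loci, table.sample_ids)
    covered = cn_mat.notna().all(axis=1)
    return set(covered.index[covered])


def vaf_to_cp(
    vaf: float, purity: float, cn_total: float, multiplicity: float = 1.0
) -> float:
    """Cellular prevalence from a variant allele fraction.

    CP = vaf * (purity * cn_total + (1 - purity) * 2) / (purity *
    multiplicity), clamped to [0, 1]. Normal cells are assumed diploid at
    the locus.
    """
    if not 0 < purity <= 1:
        raise ValueError(f"purity must lie in (0, 1], got {purity}")
    if cn_total < 1:
        raise ValueError("total copy number must be >= 1")
    if not 1 <= multiplicity <= cn_total:
        raise ValueError("multiplicity must lie in [1, cn_total]")
    cp = vaf * (purity * cn_total + (1 - purity) * 2.0) / (purity * multiplicity)
    return float(min(max(cp, 0.0), 1.0))


def expected_vaf(
    cp, purity, cn_total, multiplicity: float = 1.0
):
    """Inverse of :func:`vaf_to_cp`: expected VAF of a mutation at cellular
    prevalence ``cp``. Accepts scalars or broadcastable arrays."""
    cp = np.asarray(cp, dtype=float)
    purity = np.asarray(purity, dtype=float)
    cn_total = np.asarray(cn_total, dtype=float)
    return cp * purity * multiplicity / (purity * cn_total + (1 - purity) * 2.0)


# ---------------------------------------------------------------------------
# binomial-mixture clustering in CP space
# ---------------------------------------------------------------------------

def _cluster_matrices(
    table: CohortVariantTable,
    filtered: Sequence[str],
    cn: pd.DataFrame | None,
    multiplicity: float,
):
    """Pivot the long table into variant-by-sample count matrices plus the
    per-(variant, sample) VAF coefficient a = rho*m / (rho*C_T + 2(1-rho)),
    so that E[VAF] = CP * a."""
    variants = sorted(filtered)
    samples = list(table.sample_ids)
    obs = table.observations
    sub = obs.loc[obs["variant_id"].isin(variants)]
    alt = (
        sub.pivot(index="variant_id", columns="sample_id", values="alt_count")
        .reindex(index=variants, columns=samples)
        .fillna(0)
        .to_numpy(float)
    )
    depth = (
        sub.pivot(index="variant_id", columns="sample_id", values="depth")
        .reindex(index=variants, columns=samples)
        .fillna(0)
        .to_numpy(float)
    )
    purity = table.samples.loc[samples, "purity"].to_numpy(float)
    if cn is not None:
        loci = (
            sub[["variant_id", "chrom", "pos"]]
            .drop_duplicates("variant_id")
            .set_index("variant_id")
        )
        cn_mat = (
            copy_number_matrix(cn, loci, samples)
            .reindex(index=variants)
            .to_numpy(float)
        )
        cn_mat = np.where(np.isnan(cn_mat), 2.0, cn_mat)
    else:
        cn_mat = np.full(alt.shape, 2.0)
    coeff = purity[None, :] * multiplicity / (
        purity[None, :] * cn_mat + 2.0 * (1 - purity[None, :])
    )
    return variants, samples, alt, depth, coeff


_EVAF_EPS = 1e-7


def _loglik_matrix(alt, depth, coeff, C):
    """Per-variant, per-clone binomial log-likelihood (without the constant
    binomial coefficient). C is (K, S)."""
    n, s = alt.shape
    k = C.shape[0]
    out = np.empty((n, k))
    for j in range(k):
        evaf = np.clip(C[j][None, :] * coeff, _EVAF_EPS, 1 - _EVAF_EPS)
        out[:, j] = (alt * np.log(evaf) + (depth - alt) * np.log1p(-evaf)).sum(axis=1)
    return out


def _mstep_cp(r_k, alt, depth, coeff):
    """MLE of one clone's CP per sample given responsibilities r_k (N,).

    When the coefficient a is constant within a sample the weighted moment
    estimator CP = sum(r*alt) / sum(r*depth*a) is the exact MLE; otherwise
    the unique root of the score function is found by bisection.
    """
    w = r_k[:, None]
    num = (w * alt).sum(axis=0)
    den = (w * depth * coeff).sum(axis=0)
    cp = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    const = np.ptp(coeff, axis=0) < 1e-12
    if const.all():
        return np.clip(cp, 0.0, 1.0)
    # bisection for samples with locus-varying coefficients
    s_idx = np.where(~const)[0]
    a = coeff[:, s_idx]
    al = alt[:, s_idx]
    dp = depth[:, s_idx]
    lo = np.full(len(s_idx), 1e-9)
    hi = np.full(len(s_idx), 1.0)
    num_s = (w * al).sum(axis=0)
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        evaf = np.clip(mid[None, :] * a, _EVAF_EPS, 1 - _EVAF_EPS)
        g = num_s / mid - (w * (dp - al) * (a / (1 - evaf))).sum(axis=0)
        up = g > 0
        lo = np.where(up, mid, lo)
        hi = np.where(up, hi, mid)
    cp[s_idx] = 0.5 * (lo + hi)
    return np.clip(cp, 0.0, 1.0)


def _empirical_cp(alt, depth, coeff):
    with np.errstate(invalid="ignore", divide="ignore"):
        emp = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0) / np.maximum(
            coeff, 1e-12
        )
    return np.clip(emp, 0.0, 1.0)


def _fit_em(alt, depth, coeff, K, rng, max_iter, tol, init_C=None):
    n = alt.shape[0]
    emp = _empirical_cp(alt, depth, coeff)
    if init_C is not None:
        C = np.clip(init_C.copy(), 0.005, 0.995)
    else:
        # initialize clone CP vectors from the empirical CP of random variants
        idx = rng.choice(n, size=K, replace=K > n)
        C = np.clip(
            emp[idx] + rng.normal(0, 0.02, size=(K, emp.shape[1])), 0.005, 0.995
        )
    pi = np.full(K, 1.0 / K)
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ll_ik = _loglik_matrix(alt, depth, coeff, C) + np.log(pi)[None, :]
        norm = logsumexp(ll_ik, axis=1)
        loglik = float(norm.sum())
        r = np.exp(ll_ik - norm[:, None])
        if abs(loglik - prev) < tol * max(1.0, abs(loglik)):
            converged = True
            break
        prev = loglik
        pi = np.clip(r.mean(axis=0), 1e-10, None)
        pi /= pi.sum()
        for j in range(K):
            C[j] = _mstep_cp(r[:, j], alt, depth, coeff)
    return C, pi, loglik, r, it, converged


def cluster_variants(
    table: CohortVariantTable,
    filtered: Iterable[str],
    cn: pd.DataFrame | None = None,
    k_range: Sequence[int] = range(1, 9),
    n_restarts: int = 5,
    seed: int = 0,
    multiplicity: float = 1.0,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> ClusterModel:
    """Cluster variants into clones by a multi-sample binomial mixture.

    Each clone k carries a cellular-prevalence vector over samples; a
    variant's likelihood under clone k is the product over samples of
    Binomial(alt | depth, expected VAF), with the expected VAF obtained by
    inverting the purity/copy-number correction. EM is run ``n_restarts``
    times per candidate clone count and the count is selected by minimum
    BIC. Deterministic for a fixed seed.

    Clones in the returned model are relabeled clone_0, clone_1, ... in
    decreasing order of mean CP across samples, so the most prevalent
    (truncal) clone is clone_0.
    """
    filtered = sorted(set(filtered))
    if not filtered:
        raise ValueError("no variants passed the clustering input filter")
    variants, samples, alt, depth, coeff = _cluster_matrices(
        table, filtered, cn, multiplicity
    )
    # binomial coefficient: constant across K, include once for a true loglik
    const = float(
        (gammaln(depth + 1) - gammaln(alt + 1) - gammaln(depth - alt + 1)).sum()
    )
    n = len(variants)
    s = len(samples)
    root_seq = np.random.SeedSequence(seed)
    best = None
    bic_by_k: dict[int, float] = {}
    for K, k_seq in zip(k_range, root_seq.spawn(len(list(k_range)))):
        if K < 1 or K > n:
            continue
        k_best = None
        children = k_seq.spawn(n_restarts + 1)
        # first restart warm-starts EM from k-means centroids on the
        # empirical CP matrix; the rest use random variant rows
        inits: list[np.ndarray | None] = [None] * n_restarts
        if K > 1:
            from sklearn.cluster import KMeans

            emp = _empirical_cp(alt, depth, coeff)
            km = KMeans(
                n_clusters=K,
                n_init=3,
                random_state=int(children[-1].generate_state(1)[0] % (2**31)),
            ).fit(emp)
            inits = [km.cluster_centers_] + inits
        for child, init_C in zip(children, inits):
            rng = np.random.default_rng(child)
            C, pi, ll, r, it, conv = _fit_em(
                alt, depth, coeff, K, rng, max_iter, tol, init_C=init_C
            )
            if not np.isfinite(ll):
                continue
            if k_best is None or ll > k_best[2]:
                k_best = (C, pi, ll, r, it, conv)
        if k_best is None:
            continue
        C, pi, ll, r, it, conv = k_best
        ll_full = ll + const
        n_params = K * s + (K - 1)
        bic = -2.0 * ll_full + n_params * np.log(n)
        bic_by_k[K] = float(bic)
        if best is None or bic < best[0]:
            best = (bic, K, C, pi, ll_full, r, it, conv)
    if best is None:
        raise ConvergenceError("no clone count produced a finite EM fit")
    bic, K, C, pi, loglik, r, n_iter, converged = best
    hard = r.argmax(axis=1)
    # relabel clones by decreasing mean CP; drop empty clusters
    used = sorted(set(hard), key=lambda j: (-C[j].mean(), j))
    relabel = {old: f"clone_{rank}" for rank, old in enumerate(used)}
    assignment = pd.Series(
        [relabel[j] for j in hard], index=pd.Index(variants, name="variant_id"),
        name="clone",
    )
    clone_ids = [relabel[j] for j in used]
    cp_df = pd.DataFrame(C[used], index=clone_ids, columns=samples)
    n_mut = assignment.value_counts().reindex(clone_ids)
    weights = pd.Series(pi[used] / pi[used].sum(), index=clone_ids)
    return ClusterModel(
        K=len(used),
        assignment=assignment,
        cp_hat=ClonePrevalenceMatrix(cp=cp_df, n_mutations=n_mut),
        weights=weights,
        loglik=float(loglik),
        bic=float(bic),
        bic_by_k=bic_by_k,
        n_iter=n_iter,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Jensen-Shannon distances between samples
# ---------------------------------------------------------------------------

def cp_to_distribution(cp_column) -> np.ndarray:
    """Normalize a per-clone prevalence column to a probability vector."""
    col = np.asarray(cp_column, dtype=float)
    if (col < 0).any():
        raise ValueError("prevalences must be nonnegative")
    total = col.sum()
    if total <= 0:
        raise DegenerateSampleError("all-zero prevalence column: no clone present")
    return col / total


def _entropy_bits(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def jensen_shannon_divergence(p, q) -> float:
    """Jensen-Shannon divergence in bits: JSD = H(m) - (H(p) + H(q)) / 2
    with m = (p + q)/2 and base-2 entropies, so the result lies in [0, 1].
    Symmetric; zero iff p == q."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 1:
        raise ValueError("p and q must be 1-D vectors of equal length")
    for name, v in (("p", p), ("q", q)):
        if (v < 0).any():
            raise ValueError(f"{name} has negative entries")
        if abs(v.sum() - 1.0) > 1e-8:
            raise ValueError(f"{name} must sum to 1 (got {v.sum()!r})")
    m = 0.5 * (p + q)
    jsd = _entropy_bits(m) - 0.5 * (_entropy_bits(p) + _entropy_bits(q))
    return float(min(max(jsd, 0.0), 1.0))


def pairwise_distances(cpm: ClonePrevalenceMatrix) -> DistanceMatrix:
    """Sample-by-sample JSD matrix over normalized clone-prevalence columns."""
    samples = cpm.sample_ids
    dists = {s: cp_to_distribution(cpm.cp[s].to_numpy()) for s in samples}
    n = len(samples)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = jensen_shannon_divergence(
                dists[samples[i]], dists[samples[j]]
            )
    return DistanceMatrix(values=d, sample_ids=list(samples))


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(d: DistanceMatrix) -> PhyloTree:
    """Canonical Saitou-Nei neighbor joining.

    Q(i,j) = (n-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k); the minimizing
    pair is joined (ties broken at the lowest (row, col) index pair),
    branch lengths follow the standard formulas, and the reduced matrix
    uses d(u,k) = (d(i,k) + d(j,k) - d(i,j)) / 2. Negative branch lengths
    are clamped to zero after the raw values are recorded in diagnostics.
    Returns an unrooted tree (trifurcating root).
    """
    n0 = len(d.sample_ids)
    if n0 < 3:
        raise ValueError("neighbor joining needs at least 3 samples")
    D = d.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=s) for s in d.sample_ids]
    raw_negative: dict[str, float] = {}

    def _attach(parent: TreeNode, child: TreeNode, length: float, tag: str) -> None:
        if length < 0:
            raw_negative[tag] = float(length)
            length = 0.0
        child.length = float(length)
        parent.append(child)

    join_count = 0
    while len(nodes) > 3:
        n = len(nodes)
        rowsum = D.sum(axis=1)
        Q = (n - 2) * D - rowsum[:, None] - rowsum[None, :]
        np.fill_diagonal(Q, np.inf)
        # argmin in row-major order -> lowest (row, col) on exact ties
        i, j = np.unravel_index(int(np.argmin(Q)), Q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (rowsum[i] - rowsum[j]) / (2.0 * (n - 2))
        lj = D[i, j] - li
        parent = TreeNode()
        tag_i = nodes[i].name or f"internal_{join_count}_a"
        tag_j = nodes[j].name or f"internal_{join_count}_b"
        _attach(parent, nodes[i], li, tag_i)
        _attach(parent, nodes[j], lj, tag_j)
        join_count += 1
        dn = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        m = len(keep)
        newD = np.zeros((m + 1, m + 1))
        newD[:m, :m] = D[np.ix_(keep, keep)]
        newD[:m, m] = newD[m, :m] = dn[keep]
        D = newD
        nodes = [nodes[k] for k in keep] + [parent]

    # final trifurcation
    (a, b, c) = (0, 1, 2)
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    root = TreeNode()
    for k, lk in zip((a, b, c), (la, lb, lc)):
        _attach(root, nodes[k], lk, nodes[k].name or f"final_{k}")
    diagnostics = {"raw_negative_branch_lengths": raw_negative}
    return PhyloTree(root=root, diagnostics=diagnostics)


_NEEDS_QUOTE = set(" \t()[]:;,'")


def _format_label(name: str) -> str:
    if name and not (_NEEDS_QUOTE & set(name)):
        return name
    return "'" + name.replace("'", "''") + "'"


def _newick_node(node: TreeNode, sig: int) -> str:
    if node.is_tip():
        s = _format_label(node.name or "")
    else:
        s = "(" + ",".join(_newick_node(c, sig) for c in node.children) + ")"
        if node.name:
            s += _format_label(node.name)
    if node.length is not None:
        s += f":{node.length:.{sig}g}"
    return s


def newick_string(tree: PhyloTree, sig_digits: int = 6) -> str:
    """Newick serialization with branch lengths at ``sig_digits``
    significant digits; labels containing spaces or Newick metacharacters
    are single-quoted."""
    return _newick_node(tree.root, sig_digits) + ";\n"


# ---------------------------------------------------------------------------
# seeding patterns and founding clones
# ---------------------------------------------------------------------------

def classify_seeding(cp_column, presence_threshold: float = 0.1) -> str:
    """'monoclonal' iff exactly one clone has prevalence at or above the
    presence threshold; otherwise 'polyclonal'."""
    col = np.asarray(cp_column, dtype=float)
    if col.sum() <= 0:
        raise DegenerateSampleError("all-zero prevalence column")
    n_present = int((col >= presence_threshold).sum())
    return "monoclonal" if n_present == 1 else "polyclonal"


def founding_clone(
    cpm: ClonePrevalenceMatrix, presence_threshold: float = 0.1
) -> tuple[dict[str, str | None], str | None]:
    """Per-sample founding clone and the cohort-level founder.

    The per-sample founder is the clone of maximal CP among clones at or
    above the presence threshold (ties go to the clone listed first, i.e.
    the lowest clone id); samples with no clone above the threshold get
    None. The cohort founder is the clone that is per-sample founder most
    often (ties again to the lowest clone id).
    """
    clone_order = {c: i for i, c in enumerate(cpm.clone_ids)}
    per_sample: dict[str, str | None] = {}
    for s in cpm.sample_ids:
        col = cpm.cp[s]
        present = col[col >= presence_threshold]
        if present.empty:
            per_sample[s] = None
            continue
        best = sorted(present.items(), key=lambda kv: (-kv[1], clone_order[kv[0]]))
        per_sample[s] = best[0][0]
    counts: dict[str, int] = {}
    for f in per_sample.values():
        if f is not None:
            counts[f] = counts.get(f, 0) + 1
    if not counts:
        return per_sample, None
    cohort = sorted(counts.items(), key=lambda kv: (-kv[1], clone_order[kv[0]]))[0][0]
    return per_sample, cohort
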