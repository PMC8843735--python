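"""Synthetic multi-region tumor cohorts with known ground truth.

Emulates the data shape of a rapid-autopsy style cohort: a handful of
pretreatment samples and a larger set of posttreatment metastases from one
patient, whole-exome read counts at ~200x depth, a clone tree with
per-sample cellular prevalences, per-sample purity, immune-repertoire
clonotype tables with controlled inter-sample overlap, and per-sample
neoantigen sets tied to the clones present in each sample.

Every generator is deterministic given its seed (byte-identical outputs),
and every downstream stage of the pipeline has a recoverable answer stored
in :class:`GroundTruth`.

Construction rules:

* The clone tree is a random rooted tree; the root clone is truncal (its
  mutations are carried by every tumor cell, prevalence 1 in every
  sample).
* Each sample activates an ancestor-closed subset of clones (a clone can
  only be present where its parent is), so the tree sum condition —
  children's prevalences sum to at most the parent's — holds by
  construction. Active non-root clones are guaranteed a prevalence margin
  above the seeding presence threshold, so seeding labels are unambiguous.
* Read counts are generated by inverting the VAF->CP purity/copy-number
  correction: expected VAF = CP * purity * multiplicity / (purity * C_T +
  2 (1 - purity)), depth ~ Poisson around ``depth_mean`` (floored at 20),
  alt ~ Binomial(depth, expected VAF). Mutation multiplicity is fixed at 1.
* Three simulated callers each miss a true variant independently; calls at
  MAF below 5% are missed much more often, which is what the
  reinterrogation rescue is designed to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .filtering import CohortVariantTable, IMPACT_LEVELS
from .phylogeny import ClonePrevalenceMatrix, expected_vaf

__all__ = [
    "CloneTree",
    "SimulationConfig",
    "GroundTruth",
    "SyntheticCohort",
    "SEEDING_PRESENCE_THRESHOLD",
    "MIN_ACTIVE_CP",
    "simulate_clone_tree",
    "simulate_cp_matrix",
    "simulate_copy_number",
    "simulate_variant_reads",
    "simulate_rna_evidence",
    "simulate_repertoires",
    "simulate_neoantigens",
    "simulate_expression",
    "simulate_cohort",
]

#: presence threshold the seeding truth labels are defined against
SEEDING_PRESENCE_THRESHOLD = 0.1
#: guaranteed minimum prevalence of an active clone (margin over threshold)
MIN_ACTIVE_CP = 0.12
#: prevalence a clone reaches in its "home" sample. A clone only enters a
#: clone tree because clustering detected it somewhere, and the clustering
#: input filter needs MAF > 0.15 in some sample: at the lowest simulated
#: purity (0.6) a prevalence of 0.5 puts the expected VAF right at that
#: detection boundary.
DETECTABLE_CP = 0.5

_CALLERS = ("strelka2", "cadabra", "mutect2")
_CHROMS = tuple(f"chr{i}" for i in range(1, 6))


@dataclass
class CloneTree:
    """Rooted clone tree with disjoint mutation sets per clone."""

    clone_ids: tuple[str, ...]
    parent_of: dict[str, str | None]
    mutations_of: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        roots = [c for c in self.clone_ids if self.parent_of.get(c) is None]
        if len(roots) != 1:
            raise ValueError(f"clone tree must have exactly one root, got {roots}")
        seen: set[str] = set()
        for c in self.clone_ids:
            muts = self.mutations_of.get(c, ())
            if len(muts) < 1:
                raise ValueError(f"clone {c} has no mutations")
            overlap = seen & set(muts)
            if overlap:
                raise ValueError(f"mutation sets overlap: {sorted(overlap)[:3]} ...")
            seen |= set(muts)
        # acyclicity: walking up from every clone must reach the root
        for c in self.clone_ids:
            hops, cur = 0, c
            while self.parent_of[cur] is not None:
                cur = self.parent_of[cur]
                hops += 1
                if hops > len(self.clone_ids):
                    raise ValueError("cycle detected in clone tree")

    @property
    def root(self) -> str:
        return next(c for c in self.clone_ids if self.parent_of[c] is None)

    def children_of(self, clone: str) -> list[str]:
        return [c for c in self.clone_ids if self.parent_of[c] == clone]

    def clone_of_mutation(self) -> dict[str, str]:
        return {m: c for c in self.clone_ids for m in self.mutations_of[c]}


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort shape and noise levels for the synthetic generator.

    Defaults mirror the motivating study design: 4 pretreatment and 13
    posttreatment tumor samples from one patient, exome depth around 200x,
    purity drawn from [0.6, 0.9], shared subclones carrying under 150
    mutations each.
    """

    n_samples_pre: int = 4
    n_samples_post: int = 13
    n_clones: int = 8
    mutations_per_clone: int = 50
    depth_mean: float = 200.0
    purity_range: tuple[float, float] = (0.6, 0.9)
    #: max clones with nonzero prevalence per sample: int (same for all),
    #: a per-sample sequence, or None to draw 1..min(4, n_clones) per sample
    seeding_mix: int | Sequence[int] | None = None
    repertoire_overlap: float = 0.5
    n_clonotypes: int = 500
    caller_dropout: float = 0.1
    low_maf_dropout: float = 0.7
    binder_fraction: float = 0.3
    neoantigen_fraction: float = 0.3
    #: how strongly pre vs post samples prefer disjoint clone pools (0..1)
    phase_divergence: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples_pre < 0 or self.n_samples_post < 1:
            raise ValueError("need nonnegative pre and >= 1 post samples")
        if self.n_clones < 1:
            raise ValueError("need at least 1 clone")
        if self.mutations_per_clone < 1:
            raise ValueError("need >= 1 mutation per clone")
        lo, hi = self.purity_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("purity_range must satisfy 0 < lo <= hi <= 1")
        if not 0 <= self.repertoire_overlap <= 1:
            raise ValueError("repertoire_overlap must lie in [0, 1]")
        if not 0 <= self.binder_fraction <= 1:
            raise ValueError("binder_fraction must lie in [0, 1]")

    @property
    def sample_ids(self) -> list[str]:
        return [f"pre_{i}" for i in range(self.n_samples_pre)] + [
            f"post_{i}" for i in range(self.n_samples_post)
        ]

    @property
    def phases(self) -> dict[str, str]:
        return {s: ("pre" if s.startswith("pre_") else "post") for s in self.sample_ids}


@dataclass
class GroundTruth:
    tree: CloneTree
    cp_true: ClonePrevalenceMatrix
    assignment_true: dict[str, str]
    purity_true: pd.Series
    seeding_true: dict[str, str]


@dataclass
class SyntheticCohort:
    """Everything one simulated patient produces, inputs plus truth."""

    config: SimulationConfig
    truth: GroundTruth
    variants: CohortVariantTable
    copy_number: pd.DataFrame
    rna: pd.DataFrame
    repertoires: dict[str, pd.DataFrame]  # chain -> tidy clonotype table
    neoantigens: pd.DataFrame
    expression: pd.DataFrame
    de_genes_true: list[str]
    signatures: dict[str, list[str]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# clone tree
# ---------------------------------------------------------------------------

def simulate_clone_tree(
    n_clones: int, mutations_per_clone: int, seed: int
) -> CloneTree:
    """Random rooted clone tree; clone i's parent is uniform over clones
    0..i-1, so clone_0 is the truncal root. Mutation ids are disjoint
    blocks of ``mutations_per_clone`` per clone."""
    if n_clones < 2:
        raise ValueError("need at least 2 clones")
    if mutations_per_clone < 1:
        raise ValueError("need at least 1 mutation per clone")
    rng = np.random.default_rng(seed)
    ids = tuple(f"clone_{i}" for i in range(n_clones))
    parent: dict[str, str | None] = {ids[0]: None}
    for i in range(1, n_clones):
        parent[ids[i]] = ids[int(rng.integers(0, i))]
    mutations = {
        ids[i]: tuple(
            _locus_key(i * mutations_per_clone + j) for j in range(mutations_per_clone)
        )
        for i in range(n_clones)
    }
    return CloneTree(clone_ids=ids, parent_of=parent, mutations_of=mutations)


# ---------------------------------------------------------------------------
# cellular prevalences and seeding truth
# ---------------------------------------------------------------------------

def _active_counts(config: SimulationConfig, rng: np.random.Generator) -> list[int]:
    n = len(config.sample_ids)
    mix = config.seeding_mix
    cap = min(4, config.n_clones)
    if mix is None:
        return [int(rng.integers(1, cap + 1)) for _ in range(n)]
    if isinstance(mix, (int, np.integer)):
        mix = [int(mix)] * n
    mix = [int(m) for m in mix]
    if len(mix) != n:
        raise ValueError("seeding_mix sequence length must equal sample count")
    if any(m < 1 or m > config.n_clones for m in mix):
        raise ValueError("seeding_mix entries must lie in [1, n_clones]")
    return mix


def _phase_pools(tree: CloneTree) -> dict[str, set[str]]:
    """Split non-root clones into two pools by the root-child subtree they
    descend from (alternating assignment of root children)."""
    pools: dict[str, set[str]] = {"pre": set(), "post": set()}
    for k, child in enumerate(tree.children_of(tree.root)):
        pool = "pre" if k % 2 == 0 else "post"
        stack = [child]
        while stack:
            c = stack.pop()
            pools[pool].add(c)
            stack.extend(tree.children_of(c))
    return pools


def _draw_active_set(
    tree: CloneTree,
    size: int,
    preferred: set[str],
    divergence: float,
    rng: np.random.Generator,
) -> list[str]:
    active = [tree.root]
    while len(active) < size:
        cands = [
            c
            for c in tree.clone_ids
            if c not in active and tree.parent_of[c] in active
        ]
        if not cands:
            break
        w = np.array(
            [1.0 if c in preferred else max(1.0 - divergence, 1e-3) for c in cands]
        )
        active.append(str(rng.choice(cands, p=w / w.sum())))
    return active


def _assign_column(
    tree: CloneTree,
    active: list[str],
    rng: np.random.Generator,
    boost: str | None = None,
    boost_cp: float = DETECTABLE_CP,
) -> dict[str, float]:
    """One sample's CP values over active clones: root at 1.0, then a
    Dirichlet stick-break at each node over (active children, retained
    residual). Retries until every active clone clears MIN_ACTIVE_CP and
    the boosted clone (if any) clears ``boost_cp``; a deterministic split
    is the fallback. The Dirichlet concentration favors the boosted
    clone's lineage so the rejection loop terminates quickly."""
    active_set = set(active)
    boost_path: set[str] = set()
    if boost is not None:
        cur: str | None = boost
        while cur is not None:
            boost_path.add(cur)
            cur = tree.parent_of[cur]

    def attempt(deterministic: bool) -> dict[str, float]:
        cp = {c: 0.0 for c in tree.clone_ids}
        cp[tree.root] = 1.0
        queue = [tree.root]
        while queue:
            node = queue.pop(0)
            ch = [c for c in tree.children_of(node) if c in active_set]
            if not ch:
                continue
            k = len(ch)
            if deterministic:
                if any(c in boost_path for c in ch):
                    shares = [
                        0.78 if c in boost_path else 0.17 / max(k - 1, 1) for c in ch
                    ]
                else:
                    shares = [0.75 / k] * k
            else:
                alpha = np.ones(k + 1)
                for idx, c in enumerate(ch):
                    if c in boost_path:
                        alpha[idx] = 8.0
                shares = rng.dirichlet(alpha)[:k]
            for c, w in zip(ch, shares):
                cp[c] = cp[node] * float(w)
            queue.extend(ch)
        return cp

    for _ in range(300):
        cp = attempt(deterministic=False)
        if all(cp[c] >= MIN_ACTIVE_CP for c in active_set) and (
            boost is None or cp[boost] >= boost_cp
        ):
            return cp
    return attempt(deterministic=True)


def simulate_cp_matrix(
    tree: CloneTree,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[ClonePrevalenceMatrix, dict[str, str]]:
    """Per-sample clone prevalences plus seeding truth labels.

    A sample is labeled monoclonal iff exactly one clone is active (only
    the truncal root); active clones are guaranteed a prevalence of at
    least :data:`MIN_ACTIVE_CP`, above the seeding presence threshold, and
    inactive clones have prevalence exactly 0, so the label is recoverable
    by thresholding at :data:`SEEDING_PRESENCE_THRESHOLD`.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    counts = _active_counts(config, rng)
    pools = _phase_pools(tree)
    phases = config.phases
    actives: dict[str, list[str]] = {}
    for sample, size in zip(config.sample_ids, counts):
        preferred = pools[phases[sample]] or set(tree.clone_ids)
        actives[sample] = _draw_active_set(
            tree, size, preferred, config.phase_divergence, rng
        )
    # a clone tree only contains clones observed somewhere in the patient:
    # place every globally-missing clone into one sample whose active set
    # already contains its parent (processed root-down so parents come first)
    order = [tree.root]
    while len(order) < len(tree.clone_ids):
        order.extend(
            c for p in list(order) for c in tree.children_of(p) if c not in order
        )
    for clone in order:
        if any(clone in a for a in actives.values()):
            continue
        hosts = [s for s, a in actives.items() if tree.parent_of[clone] in a]
        actives[str(rng.choice(sorted(hosts)))].append(clone)
    # give each non-root clone a "home" sample where it reaches a
    # detectable prevalence (one boost target per sample): clones enter a
    # tree only because clustering detected them somewhere. Boosting a
    # clone implies every ancestor in that sample also clears the bar, so
    # a sample whose boost target is an ancestor can be upgraded to the
    # descendant; failing everything else, the clone (plus any missing
    # ancestors) is activated in a boost-free sample.
    def _ancestors(clone: str) -> set[str]:
        out: set[str] = set()
        cur = tree.parent_of[clone]
        while cur is not None:
            out.add(cur)
            cur = tree.parent_of[cur]
        return out

    boosted: dict[str, str] = {}
    for clone in order:
        if clone == tree.root:
            continue
        hosts = sorted(s for s, a in actives.items() if clone in a)
        free = [s for s in hosts if s not in boosted]
        if free:
            boosted[str(rng.choice(free))] = clone
            continue
        anc = _ancestors(clone)
        upgradable = [s for s in hosts if boosted[s] in anc]
        if upgradable:
            boosted[str(rng.choice(upgradable))] = clone
            continue
        spare = sorted(s for s in actives if s not in boosted)
        if spare:
            s = str(rng.choice(spare))
            for c in order:
                if (c == clone or c in anc) and c not in actives[s]:
                    actives[s].append(c)
            boosted[s] = clone
    cols: dict[str, dict[str, float]] = {}
    seeding_true: dict[str, str] = {}
    for sample in config.sample_ids:
        col = _assign_column(tree, actives[sample], rng, boost=boosted.get(sample))
        cols[sample] = col
        n_present = sum(v >= SEEDING_PRESENCE_THRESHOLD for v in col.values())
        seeding_true[sample] = "monoclonal" if n_present == 1 else "polyclonal"
    cp = pd.DataFrame(cols).reindex(list(tree.clone_ids))[config.sample_ids]
    n_mut = pd.Series(
        {c: len(tree.mutations_of[c]) for c in tree.clone_ids}, name="n_mutations"
    )
    return ClonePrevalenceMatrix(cp=cp, n_mutations=n_mut), seeding_true


# ---------------------------------------------------------------------------
# loci, copy number, and read counts
# ---------------------------------------------------------------------------

_BASES = ("A", "C", "G", "T")


def _locus_fields(i: int) -> tuple[str, int, str, str]:
    """Deterministic locus layout: variants along 5 chromosomes at 1-based
    positions spaced 1 kb apart."""
    chrom = _CHROMS[i % len(_CHROMS)]
    pos = 1000 * (i // len(_CHROMS) + 1) + 1
    return chrom, pos, _BASES[i % 4], _BASES[(i + 1) % 4]


def _locus_key(i: int) -> str:
    chrom, pos, ref, alt = _locus_fields(i)
    return f"{chrom}:{pos}:{ref}:{alt}"


def _locus_index(variant_id: str) -> int:
    chrom, pos, *_ = variant_id.split(":")
    return (int(pos) // 1000 - 1) * len(_CHROMS) + _CHROMS.index(chrom)


def _variant_loci(tree: CloneTree) -> pd.DataFrame:
    """Locus table for every mutation; variant ids are coordinate keys
    (chrom:pos:ref:alt), stable across MAF serialization round trips."""
    records = []
    muts = sorted(m for c in tree.clone_ids for m in tree.mutations_of[c])
    for m in muts:
        i = _locus_index(m)
        chrom, pos, ref, alt = _locus_fields(i)
        records.append(
            {
                "variant_id": m,
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "gene": f"GENE{i // 3:04d}",
            }
        )
    return pd.DataFrame(records).set_index("variant_id")


def simulate_copy_number(
    sample_ids: Sequence[str],
    gain_fraction: float = 0.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """SEG-style table: one whole-chromosome segment per (sample, chrom),
    total copy number 2 except a ``gain_fraction`` of segments at 3."""
    if rng is None:
        rng = np.random.default_rng(0)
    rows = []
    for s in sample_ids:
        for chrom in _CHROMS:
            gained = rng.random() < gain_fraction
            cn = 3 if gained else 2
            rows.append(
                {
                    "sample_id": s,
                    "chrom": chrom,
                    "start": 1,
                    "end": 500_000_000,
                    "cn_total": cn,
                    "cn_major": cn - 1,
                    "cn_minor": 1,
                }
            )
    return pd.DataFrame(rows)


def simulate_variant_reads(
    cp: ClonePrevalenceMatrix,
    tree: CloneTree,
    purity: Mapping[str, float] | pd.Series,
    cn: pd.DataFrame,
    depth_mean: float = 200.0,
    seed: int = 0,
    caller_dropout: float = 0.1,
    low_maf_dropout: float = 0.7,
    phases: Mapping[str, str] | None = None,
) -> CohortVariantTable:
    """Read counts and caller flags for every (sample, variant) pair.

    Expected VAF comes from inverting the VAF->CP correction at
    multiplicity 1; depth is Poisson around ``depth_mean`` floored at 20;
    alt counts are binomial. Each of the three simulated callers misses a
    true variant independently with probability ``caller_dropout``
    (``low_maf_dropout`` when the observed MAF falls below 5%), which
    produces the partially-PASS rows the reinterrogation rescue recovers.
    Rows with zero alt reads carry no PASS flags.
    """
    rng = np.random.default_rng(seed)
    purity = pd.Series(purity)
    loci = _variant_loci(tree)
    clone_of = tree.clone_of_mutation()
    samples = cp.sample_ids
    variants = list(loci.index)
    impacts = rng.choice(
        IMPACT_LEVELS, size=len(variants), p=(0.15, 0.35, 0.30, 0.20)
    )
    impact_of = dict(zip(variants, impacts))

    from .filtering import copy_number_matrix

    cn_mat = copy_number_matrix(cn, loci, samples)
    rows = []
    for v in variants:
        clone = clone_of[v]
        for s in samples:
            rho = float(purity[s])
            cnt = float(cn_mat.loc[v, s]) if not np.isnan(cn_mat.loc[v, s]) else 2.0
            cp_vs = float(cp.cp.loc[clone, s])
            evaf = float(expected_vaf(cp_vs, rho, cnt))
            depth = max(20, int(rng.poisson(depth_mean)))
            alt = int(rng.binomial(depth, evaf)) if evaf > 0 else 0
            maf = alt / depth
            if alt > 0:
                p_miss = caller_dropout if maf >= 0.05 else low_maf_dropout
                flags = rng.random(len(_CALLERS)) >= p_miss
            else:
                flags = np.zeros(len(_CALLERS), dtype=bool)
            rows.append(
                {
                    "sample_id": s,
                    "variant_id": v,
                    "chrom": loci.loc[v, "chrom"],
                    "pos": int(loci.loc[v, "pos"]),
                    "ref": loci.loc[v, "ref"],
                    "alt": loci.loc[v, "alt"],
                    "gene": loci.loc[v, "gene"],
                    "impact": impact_of[v],
                    "alt_count": alt,
                    "ref_count": depth - alt,
                    **{f"pass_{c}": bool(f) for c, f in zip(_CALLERS, flags)},
                }
            )
    obs = pd.DataFrame(rows)
    if phases is None:
        phases = {s: "post" for s in samples}
    samples_df = pd.DataFrame(
        {"phase": [phases[s] for s in samples], "purity": [purity[s] for s in samples]},
        index=pd.Index(samples, name="sample_id"),
    )
    return CohortVariantTable(observations=obs, samples=samples_df, callers=_CALLERS)


def simulate_rna_evidence(
    table: CohortVariantTable,
    seed: int = 0,
    expressed_gene_fraction: float = 0.6,
    mean_reads: float = 8.0,
) -> pd.DataFrame:
    """RNA variant-support table: a fraction of genes is expressed; for
    variants in expressed genes, supporting reads scale with the DNA MAF."""
    rng = np.random.default_rng(seed)
    genes = sorted(table.observations["gene"].unique())
    expressed_genes = {
        g for g in genes if rng.random() < expressed_gene_fraction
    }
    obs = table.observations
    rows = []
    for _, r in obs.iterrows():
        if r["gene"] in expressed_genes and r["alt_count"] > 0:
            lam = mean_reads * 2.0 * r["maf"]
            count = int(rng.poisson(lam))
        else:
            count = 0
        rows.append(
            {
                "sample_id": r["sample_id"],
                "variant_id": r["variant_id"],
                "supporting_read_count": count,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# repertoires, neoantigens, expression
# ---------------------------------------------------------------------------

def simulate_repertoires(
    config: SimulationConfig,
    chain: str = "IGH",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Tidy clonotype table (sample_id, chain, clonotype, count).

    Each sample carries ``round(overlap * n_clonotypes)`` clonotypes from a
    pool shared by all samples plus private clonotypes; counts are
    heavy-tailed (rounded lognormal). Expected pairwise Morisita-Horn
    overlap increases monotonically with ``repertoire_overlap``; at 0 the
    supports are disjoint and the index is exactly 0.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_shared = int(round(config.repertoire_overlap * config.n_clonotypes))
    n_private = config.n_clonotypes - n_shared
    rows = []
    for s in config.sample_ids:
        keys = [f"{chain}_shared_{i}" for i in range(n_shared)] + [
            f"{chain}_{s}_priv_{i}" for i in range(n_private)
        ]
        counts = np.maximum(1, np.round(rng.lognormal(2.0, 1.0, size=len(keys)))).astype(int)
        for k, c in zip(keys, counts):
            rows.append(
                {"sample_id": s, "chain": chain, "clonotype": k, "count": int(c)}
            )
    return pd.DataFrame(rows)


def simulate_neoantigens(
    truth: GroundTruth,
    binder_fraction: float = 0.3,
    seed: int = 0,
    neoantigen_fraction: float = 0.3,
) -> pd.DataFrame:
    """Per-sample predicted neoantigen table (sample_id, peptide, gene,
    binding_rank).

    A fixed fraction of mutations yields a candidate peptide; the peptide
    set of a sample is determined by the clones present there (prevalence
    > 0), so samples with identical clone sets get identical peptide sets.
    Binding percentile ranks are drawn per peptide (an HLA-binding
    property, not a sample property): ``binder_fraction`` of peptides fall
    below the conventional weak-binder rank of 2.0.
    """
    if not 0 <= binder_fraction <= 1:
        raise ValueError("binder_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    tree = truth.tree
    loci = _variant_loci(tree)
    clone_of = tree.clone_of_mutation()
    peptides: dict[str, tuple[str, str, float]] = {}
    for v in sorted(clone_of):
        if rng.random() < neoantigen_fraction:
            if rng.random() < binder_fraction:
                rank = float(rng.uniform(0.05, 2.0))
            else:
                rank = float(rng.uniform(2.0, 50.0))
            peptides[v] = (f"PEP_{v}", str(loci.loc[v, "gene"]), rank)
    rows = []
    for s in truth.cp_true.sample_ids:
        present = {
            c for c in tree.clone_ids if truth.cp_true.cp.loc[c, s] > 0
        }
        for v, (pep, gene, rank) in peptides.items():
            if clone_of[v] in present:
                rows.append(
                    {
                        "sample_id": s,
                        "peptide": pep,
                        "gene": gene,
                        "binding_rank": rank,
                    }
                )
    return pd.DataFrame(rows, columns=["sample_id", "peptide", "gene", "binding_rank"])


def simulate_expression(
    sample_ids: Sequence[str],
    phases: Mapping[str, str],
    n_genes: int = 300,
    n_de: int = 40,
    log2_effect: float = 1.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Gene-by-sample expression matrix with a known set of genes shifted
    between pre and post samples (half up, half down in post)."""
    rng = np.random.default_rng(seed)
    genes = [f"GENE{i:04d}" for i in range(n_genes)]
    base = rng.lognormal(3.0, 1.0, size=n_genes)
    de_genes = list(rng.choice(genes, size=min(n_de, n_genes), replace=False))
    direction = {g: (1 if i % 2 == 0 else -1) for i, g in enumerate(de_genes)}
    mat = np.empty((n_genes, len(sample_ids)))
    for j, s in enumerate(sample_ids):
        fold = np.ones(n_genes)
        if phases[s] == "post":
            for g, d in direction.items():
                fold[genes.index(g)] = 2.0 ** (d * log2_effect)
        noise = rng.lognormal(0.0, 0.25, size=n_genes)
        mat[:, j] = base * fold * noise
    expr = pd.DataFrame(mat, index=pd.Index(genes, name="gene"), columns=list(sample_ids))
    return expr, sorted(de_genes)


_DEFAULT_SIGNATURES = {
    "T_CELL": [f"GENE{i:04d}" for i in range(0, 12)],
    "B_CELL": [f"GENE{i:04d}" for i in range(12, 24)],
    "MAST_CELL": [f"GENE{i:04d}" for i in range(24, 32)],
    "MAPK": [f"GENE{i:04d}" for i in range(32, 44)],
}


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Full synthetic patient: clone tree, prevalences, reads, RNA support,
    repertoires (IGH and TRB), neoantigens, and expression. Deterministic
    for a fixed ``config.seed``."""
    seq = np.random.SeedSequence(config.seed)
    s_tree, s_cp, s_pur, s_reads, s_rna, s_igh, s_trb, s_neo, s_expr, s_cn = (
        int(c.generate_state(1)[0] % (2**31)) for c in seq.spawn(10)
    )
    if config.n_clones == 1:
        # degenerate single-clone patient: trivial truncal tree
        tree = CloneTree(
            clone_ids=("clone_0",),
            parent_of={"clone_0": None},
            mutations_of={
                "clone_0": tuple(
                    _locus_key(j) for j in range(config.mutations_per_clone)
                )
            },
        )
    else:
        tree = simulate_clone_tree(config.n_clones, config.mutations_per_clone, s_tree)
    cp_true, seeding_true = simulate_cp_matrix(
        tree, config, np.random.default_rng(s_cp)
    )
    rng_p = np.random.default_rng(s_pur)
    purity = pd.Series(
        rng_p.uniform(*config.purity_range, size=len(config.sample_ids)),
        index=config.sample_ids,
        name="purity",
    )
    cn = simulate_copy_number(config.sample_ids, rng=np.random.default_rng(s_cn))
    variants = simulate_variant_reads(
        cp_true,
        tree,
        purity,
        cn,
        depth_mean=config.depth_mean,
        seed=s_reads,
        caller_dropout=config.caller_dropout,
        low_maf_dropout=config.low_maf_dropout,
        phases=config.phases,
    )
    truth = GroundTruth(
        tree=tree,
        cp_true=cp_true,
        assignment_true=tree.clone_of_mutation(),
        purity_true=purity,
        seeding_true=seeding_true,
    )
    rna = simulate_rna_evidence(variants, seed=s_rna)
    reps = {
        "IGH": simulate_repertoires(config, "IGH", np.random.default_rng(s_igh)),
        "TRB": simulate_repertoires(config, "TRB", np.random.default_rng(s_trb)),
    }
    neo = simulate_neoantigens(
        truth,
        binder_fraction=config.binder_fraction,
        seed=s_neo,
        neoantigen_fraction=config.neoantigen_fraction,
    )
    expr, de_true = simulate_expression(
        config.sample_ids, config.phases, seed=s_expr
    )
    return SyntheticCohort(
        config=config,
        truth=truth,
        variants=variants,
        copy_number=cn,
        rna=rna,
        repertoires=reps,
        neoantigens=neo,
        expression=expr,
        de_genes_true=de_true,
        signatures={k: list(v) for k, v in _DEFAULT_SIGNATURES.items()},
    )
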