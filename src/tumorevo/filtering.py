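"""Somatic-variant post-processing for a multi-region tumor cohort.

The cohort is a long table of per-sample variant observations coming from
three independent somatic callers. This module implements the filtering
layer applied downstream of calling:

* merge of per-caller call sets into one table with per-caller PASS flags
  and a strict ``pass_all`` flag (PASS in every caller, optional quality
  threshold);
* impact/MAF counting (high/moderate impact, MAF strictly above 5%);
* cross-sample *reinterrogation*: variants that are high quality in at
  least one tumor are rescued in every other tumor where any supporting
  alt reads exist, regardless of caller flags — recovering calls missed at
  low allele frequency;
* non-private (shared by >= 2 tumors) and recurrent (shared by >= 3 tumors,
  MAF > 5%, expressed in RNA) selection;
* MAF-versus-purity correlation for a single variant, optionally restricted
  to copy-neutral samples (total copy number 2 at the locus).

MAF here is the *mutant allele frequency* alt/(alt+ref); the tabular MAF
(Mutation Annotation Format) dialect lives in :mod:`tumorevo.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import CorrelationResult, InsufficientDataError, pearson_correlation

__all__ = [
    "IMPACT_LEVELS",
    "CODING_IMPACTS",
    "CohortVariantTable",
    "CallerConflictError",
    "UndefinedValueError",
    "compute_maf",
    "merge_caller_calls",
    "count_impactful_variants",
    "high_quality_subset",
    "high_quality_union",
    "reinterrogate",
    "nonprivate_filter",
    "flag_expressed",
    "recurrent_impact_selection",
    "maf_purity_correlation",
    "copy_number_at",
    "copy_number_matrix",
]

IMPACT_LEVELS = ("HIGH", "MODERATE", "LOW", "MODIFIER")
#: impacts that change the coding sequence
CODING_IMPACTS = ("HIGH", "MODERATE")

PHASES = ("pre", "post")


class CallerConflictError(ValueError):
    """Two callers disagree on read counts for the same (sample, variant)."""


class UndefinedValueError(ValueError):
    """A derived quantity is undefined (e.g. MAF at zero depth)."""


def compute_maf(alt_count: int, ref_count: int) -> float:
    """Mutant allele frequency alt / (alt + ref).

    Raises :class:`UndefinedValueError` at zero depth.
    """
    if alt_count < 0 or ref_count < 0:
        raise ValueError("read counts must be nonnegative")
    depth = alt_count + ref_count
    if depth == 0:
        raise UndefinedValueError("MAF undefined at zero depth")
    return alt_count / depth


def _vector_maf(alt: np.ndarray, ref: np.ndarray) -> np.ndarray:
    depth = alt + ref
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(depth > 0, alt / np.where(depth > 0, depth, 1), np.nan)
    return maf


@dataclass
class CohortVariantTable:
    """Long table of per-sample variant observations plus sample metadata.

    ``observations`` columns (one row per (sample_id, variant_id)):
    sample_id, variant_id, chrom, pos, ref, alt, gene, impact, alt_count,
    ref_count, one boolean ``pass_<caller>`` column per caller, pass_all,
    rescued. Derived columns depth, maf, pass_any are (re)computed on
    construction. ``samples`` is indexed by sample_id with columns
    ``phase`` in {pre, post} and ``purity`` in (0, 1].
    """

    observations: pd.DataFrame
    samples: pd.DataFrame
    callers: tuple[str, ...] = ("strelka2", "cadabra", "mutect2")

    def __post_init__(self) -> None:
        obs = self.observations.copy()
        required = {"sample_id", "variant_id", "alt_count", "ref_count"}
        missing = required - set(obs.columns)
        if missing:
            raise ValueError(f"observations missing columns: {sorted(missing)}")
        if obs.duplicated(["sample_id", "variant_id"]).any():
            raise ValueError("(sample_id, variant_id) pairs must be unique")
        if (obs["alt_count"] < 0).any() or (obs["ref_count"] < 0).any():
            raise ValueError("read counts must be nonnegative")
        for c in self.pass_columns:
            if c not in obs.columns:
                raise ValueError(f"missing caller flag column {c!r}")
            obs[c] = obs[c].astype(bool)
        if "pass_all" not in obs.columns:
            obs["pass_all"] = obs[list(self.pass_columns)].all(axis=1)
        if "rescued" not in obs.columns:
            obs["rescued"] = False
        obs["rescued"] = obs["rescued"].astype(bool)
        obs["depth"] = obs["alt_count"] + obs["ref_count"]
        obs["maf"] = _vector_maf(
            obs["alt_count"].to_numpy(float), obs["ref_count"].to_numpy(float)
        )
        obs["pass_any"] = obs[list(self.pass_columns)].any(axis=1)
        self.observations = obs.reset_index(drop=True)

        smp = self.samples
        if "phase" not in smp.columns or "purity" not in smp.columns:
            raise ValueError("samples table needs 'phase' and 'purity' columns")
        bad_phase = ~smp["phase"].isin(PHASES)
        if bad_phase.any():
            raise ValueError(f"unknown phase labels: {sorted(smp.loc[bad_phase, 'phase'])}")
        if ((smp["purity"] <= 0) | (smp["purity"] > 1)).any():
            raise ValueError("purity must lie in (0, 1]")
        unknown = set(obs["sample_id"]) - set(smp.index)
        if unknown:
            raise ValueError(f"observations reference unknown samples: {sorted(unknown)}")

    @property
    def pass_columns(self) -> tuple[str, ...]:
        return tuple(f"pass_{c}" for c in self.callers)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples.index)

    @property
    def variant_ids(self) -> list[str]:
        return sorted(self.observations["variant_id"].unique())

    def observed_mask(self) -> pd.Series:
        """Rows that count as observed: called by any caller or rescued."""
        return self.observations["pass_any"] | self.observations["rescued"]

    def with_observations(self, obs: pd.DataFrame) -> "CohortVariantTable":
        return replace(self, observations=obs)


def merge_caller_calls(
    per_caller: Mapping[str, pd.DataFrame],
    samples: pd.DataFrame,
    quality_threshold: float = 0.0,
) -> CohortVariantTable:
    """Merge per-caller variant tables into one cohort table.

    Each input table has one row per (sample_id, variant_id) the caller
    reported, with columns sample_id, variant_id, alt_count, ref_count, an
    optional boolean ``pass`` column (default True) and optional annotation
    columns (chrom, pos, ref, alt, gene, impact, qual). The union of calls
    is retained; per-caller PASS flags are recorded and ``pass_all`` is True
    iff the variant is PASS in *every* caller and (when a ``qual`` column is
    present) its quality score exceeds ``quality_threshold``.

    Read counts for the same key must agree across callers (they come from
    the same alignments); a disagreement raises :class:`CallerConflictError`.
    """
    callers = tuple(per_caller)
    if not callers:
        raise ValueError("need at least one caller table")
    key = ["sample_id", "variant_id"]
    anno_cols = ["chrom", "pos", "ref", "alt", "gene", "impact", "qual"]
    frames = []
    for name, df in per_caller.items():
        df = df.copy()
        if df.empty and "sample_id" not in df.columns:
            df = pd.DataFrame(columns=key + ["alt_count", "ref_count"])
        df[f"pass_{name}"] = df["pass"].astype(bool) if "pass" in df.columns else True
        frames.append(df.drop(columns=["pass"], errors="ignore"))

    merged: pd.DataFrame | None = None
    for df in frames:
        if merged is None:
            merged = df
            continue
        overlap_anno = [c for c in anno_cols if c in merged.columns and c in df.columns]
        right = df.drop(columns=overlap_anno, errors="ignore")
        merged = merged.merge(
            right, on=key, how="outer", suffixes=("", "_other")
        )
        for cnt in ("alt_count", "ref_count"):
            other = f"{cnt}_other"
            if other in merged.columns:
                both = merged[cnt].notna() & merged[other].notna()
                if (merged.loc[both, cnt] != merged.loc[both, other]).any():
                    bad = merged.loc[
                        both & (merged[cnt] != merged[other]), key
                    ].iloc[0]
                    raise CallerConflictError(
                        f"conflicting {cnt} for {tuple(bad)} across callers"
                    )
                merged[cnt] = merged[cnt].fillna(merged[other])
                merged = merged.drop(columns=[other])
        # annotation columns only present on the right side
        for c in anno_cols:
            if c in df.columns and c not in merged.columns:
                merged = merged.merge(df[key + [c]], on=key, how="left")
    assert merged is not None
    for name in callers:
        col = f"pass_{name}"
        if col in merged:
            merged[col] = merged[col].astype("boolean").fillna(False).astype(bool)
        else:
            merged[col] = False
    merged["alt_count"] = merged["alt_count"].fillna(0).astype(int)
    merged["ref_count"] = merged["ref_count"].fillna(0).astype(int)
    pass_cols = [f"pass_{c}" for c in callers]
    merged["pass_all"] = merged[pass_cols].all(axis=1)
    if "qual" in merged.columns and quality_threshold > 0:
        merged["pass_all"] &= merged["qual"].fillna(-np.inf) > quality_threshold
    return CohortVariantTable(observations=merged, samples=samples, callers=callers)


def count_impactful_variants(
    table: CohortVariantTable,
    min_maf: float = 0.05,
    include_rescued: bool = False,
) -> pd.Series:
    """Per-sample count of coding (HIGH/MODERATE impact) variants with
    MAF strictly greater than ``min_maf``.

    By default counts initial calls only (any caller PASS); set
    ``include_rescued`` to also count reinterrogation rescues.
    """
    obs = table.observations
    called = obs["pass_any"] | (obs["rescued"] if include_rescued else False)
    keep = (
        called
        & obs["impact"].isin(CODING_IMPACTS)
        & (obs["maf"] > min_maf)
    )
    counts = obs.loc[keep].groupby("sample_id")["variant_id"].nunique()
    return counts.reindex(table.sample_ids, fill_value=0).astype(int)


def high_quality_subset(
    table: CohortVariantTable, min_maf: float = 0.05
) -> dict[str, set[str]]:
    """Per-sample sets of high-quality variants: PASS in all callers
    (``pass_all``) and MAF strictly greater than ``min_maf``."""
    obs = table.observations
    keep = obs["pass_all"] & (obs["maf"] > min_maf)
    out: dict[str, set[str]] = {s: set() for s in table.sample_ids}
    for s, grp in obs.loc[keep].groupby("sample_id"):
        out[str(s)] = set(grp["variant_id"])
    return out


def high_quality_union(table: CohortVariantTable, min_maf: float = 0.05) -> set[str]:
    """Union over samples of :func:`high_quality_subset`."""
    return set().union(*high_quality_subset(table, min_maf).values())


def reinterrogate(
    table: CohortVariantTable,
    hq_union: Iterable[str],
    min_alt_reads: int = 1,
) -> CohortVariantTable:
    """Rescue high-quality variants in every sample with supporting reads.

    For every (sample, variant) whose variant belongs to ``hq_union`` and
    whose alt read count is at least ``min_alt_reads``, the observation is
    marked ``rescued`` regardless of caller flags or MAF. No observation is
    ever removed.
    """
    hq = set(hq_union)
    obs = table.observations.copy()
    hit = obs["variant_id"].isin(hq) & (obs["alt_count"] >= min_alt_reads)
    obs["rescued"] = obs["rescued"] | hit
    return table.with_observations(obs)


def nonprivate_filter(table: CohortVariantTable, min_samples: int = 2) -> set[str]:
    """Variants observed (called or rescued) in at least ``min_samples``
    tumors — the non-private mutation set."""
    obs = table.observations.loc[table.observed_mask()]
    n_by_variant = obs.groupby("variant_id")["sample_id"].nunique()
    return set(n_by_variant.index[n_by_variant >= min_samples])


def flag_expressed(
    variants: Iterable[str],
    rna: pd.DataFrame,
    min_reads: int = 1,
) -> set[str]:
    """Subset of ``variants`` with RNA support of at least ``min_reads``
    supporting reads in *any* tumor RNA sample.

    ``rna`` has columns sample_id, variant_id, supporting_read_count.
    """
    variants = set(variants)
    if rna.empty:
        return set()
    if (rna["supporting_read_count"] < 0).any():
        raise ValueError("RNA supporting read counts must be nonnegative")
    supported = rna.loc[rna["supporting_read_count"] >= min_reads, "variant_id"]
    return variants & set(supported)


def recurrent_impact_selection(
    table: CohortVariantTable,
    expressed: Iterable[str],
    min_samples: int = 3,
    min_maf: float = 0.05,
    impacts: Sequence[str] | None = None,
) -> set[str]:
    """Recurrent expressed variants: observed in >= ``min_samples`` tumors,
    MAF strictly greater than ``min_maf`` in at least one observed sample,
    and expressed in RNA. Optionally restricted to given impact classes
    (e.g. ``CODING_IMPACTS`` for nonsynonymous-only selection).

    The three criteria intersect; applying them in any order gives the same
    set.
    """
    expressed = set(expressed)
    obs = table.observations.loc[table.observed_mask()]
    if impacts is not None:
        obs = obs.loc[obs["impact"].isin(tuple(impacts))]
    grp = obs.groupby("variant_id")
    n_samples = grp["sample_id"].nunique()
    max_maf = grp["maf"].max()
    ok = (n_samples >= min_samples) & (max_maf > min_maf)
    return set(n_samples.index[ok]) & expressed


# ---------------------------------------------------------------------------
# copy-number helpers (SEG-style segment table)
# ---------------------------------------------------------------------------

def copy_number_at(
    cn: pd.DataFrame, sample_id: str, chrom: str, pos: int
) -> int | None:
    """Total copy number of the segment covering (chrom, pos) for a sample,
    or None when no segment covers the locus. Coordinates are 1-based
    inclusive."""
    seg = cn[
        (cn["sample_id"] == sample_id)
        & (cn["chrom"] == chrom)
        & (cn["start"] <= pos)
        & (cn["end"] >= pos)
    ]
    if seg.empty:
        return None
    return int(seg.iloc[0]["cn_total"])


def copy_number_matrix(
    cn: pd.DataFrame, loci: pd.DataFrame, sample_ids: Sequence[str]
) -> pd.DataFrame:
    """Copy number per (variant, sample); NaN where no segment covers the
    locus. ``loci`` is indexed by variant_id with columns chrom, pos."""
    out = pd.DataFrame(np.nan, index=loci.index, columns=list(sample_ids))
    for s in sample_ids:
        sub = cn[cn["sample_id"] == s]
        for chrom, seg in sub.groupby("chrom"):
            seg = seg.sort_values("start")
            in_chrom = loci.index[loci["chrom"] == chrom]
            if len(in_chrom) == 0:
                continue
            pos = loci.loc[in_chrom, "pos"].to_numpy()
            idx = np.searchsorted(seg["start"].to_numpy(), pos, side="right") - 1
            valid = idx >= 0
            covered = np.zeros(len(pos), dtype=bool)
            vals = np.full(len(pos), np.nan)
            ends = seg["end"].to_numpy()
            cns = seg["cn_total"].to_numpy(float)
            covered[valid] = pos[valid] <= ends[idx[valid]]
            sel = valid & covered
            vals[sel] = cns[idx[sel]]
            out.loc[in_chrom, s] = vals
    return out


def maf_purity_correlation(
    table: CohortVariantTable,
    variant_id: str,
    cn: pd.DataFrame | None = None,
    copy_neutral_only: bool = False,
) -> CorrelationResult:
    """Pearson correlation between a variant's per-sample MAF and tumor
    purity, optionally restricted to copy-neutral samples (total CN 2 at
    the locus)."""
    obs = table.observations
    rows = obs.loc[(obs["variant_id"] == variant_id) & (obs["depth"] > 0)]
    if copy_neutral_only:
        if cn is None:
            raise ValueError("copy_neutral_only requires a copy-number table")
        keep = []
        for _, r in rows.iterrows():
            total = copy_number_at(cn, r["sample_id"], r["chrom"], int(r["pos"]))
            keep.append(total == 2)
        rows = rows.loc[np.asarray(keep, dtype=bool)]
    if len(rows) < 3:
        raise InsufficientDataError(
            f"variant {variant_id!r}: need >= 3 samples with coverage, got {len(rows)}"
        )
    purity = table.samples.loc[rows["sample_id"], "purity"].to_numpy(float)
    return pearson_correlation(rows["maf"].to_numpy(float), purity)
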