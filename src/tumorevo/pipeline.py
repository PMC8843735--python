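"""End-to-end orchestration: configuration, stage reports, and the demo run.

``run_demo`` simulates one synthetic patient, writes all input tables, and
then runs the full analysis chain — caller-merge filters, reinterrogation
rescue, clonal clustering, Jensen-Shannon/neighbor-joining phylogeny,
seeding classification, repertoire overlap, neoantigen statistics,
signature scoring and DE thresholds — emitting one :class:`StageReport`
per stage and a machine-readable summary. Fixed seed implies
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import filtering, immuno, io as tio, phylogeny, stats, synthetic

log = logging.getLogger("tumorevo")

__all__ = ["PipelineConfig", "StageReport", "ConfigError", "run_demo"]


class ConfigError(ValueError):
    """Unknown or invalid configuration keys."""


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters in one serializable, human-editable object."""

    simulation: synthetic.SimulationConfig = field(
        default_factory=synthetic.SimulationConfig
    )
    min_maf: float = 0.05                 # strict MAF floor for counting/HQ calls
    min_shared_samples: int = 2           # nonprivate threshold
    recurrent_min_samples: int = 3        # recurrent-selection threshold
    min_rna_reads: int = 1                # "expressed" evidence floor
    rescue: bool = True                   # apply reinterrogation
    quality_threshold: float = 0.0        # pass_all quality score gate (0 = off)
    cluster_min_depth: int = 20
    cluster_min_maf: float = 0.15
    k_min: int = 1
    k_max: int = 8
    n_restarts: int = 3
    presence_threshold: float = 0.1       # seeding/founder presence cutoff
    rank_cutoff: float = 2.0              # weak-binder percentile rank
    fc_min: float = 1.5
    padj_max: float = 0.05
    basemean_min: float = 10.0
    seed: int = 42

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["simulation"]["purity_range"] = list(d["simulation"]["purity_range"])
        if isinstance(d["simulation"]["seeding_mix"], tuple):
            d["simulation"]["seeding_mix"] = list(d["simulation"]["seeding_mix"])
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        sim = d.pop("simulation", {})
        if isinstance(sim, dict):
            sim_known = {f.name for f in dataclasses.fields(synthetic.SimulationConfig)}
            sim_unknown = set(sim) - sim_known
            if sim_unknown:
                raise ConfigError(f"unknown simulation keys: {sorted(sim_unknown)}")
            if "purity_range" in sim:
                sim["purity_range"] = tuple(sim["purity_range"])
            if isinstance(sim.get("seeding_mix"), list):
                sim["seeding_mix"] = tuple(sim["seeding_mix"])
            sim = synthetic.SimulationConfig(**sim)
        return cls(simulation=sim, **d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(data)


@dataclass
class StageReport:
    stage: str
    input_digest: str
    parameters: dict[str, Any]
    summaries: dict[str, Any]
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def _digest(*parts: str) -> str:
    h = hashlib.sha256()
    for p in parts:
        h.update(p.encode())
    return h.hexdigest()[:16]


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    raise TypeError(f"not JSON-serializable: {type(o)}")


def _write_json(obj, path) -> None:
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n"
    )


def _write_inputs(cohort: synthetic.SyntheticCohort, indir: Path) -> None:
    indir.mkdir(parents=True, exist_ok=True)
    tio.write_maf_table(cohort.variants, indir / "variants.maf.tsv")
    tio.write_samples_table(cohort.variants.samples, indir / "samples.tsv")
    tio.write_seg(cohort.copy_number, indir / "copy_number.seg.tsv")
    cohort.rna.to_csv(indir / "rna_support.tsv", sep="\t", index=False)
    for chain, df in cohort.repertoires.items():
        df.to_csv(indir / f"repertoire_{chain.lower()}.tsv", sep="\t", index=False)
    cohort.neoantigens.to_csv(indir / "neoantigens.tsv", sep="\t", index=False)
    tio.write_matrix(cohort.expression, indir / "expression.tsv", index_label="gene")
    tio.write_gmt(cohort.signatures, indir / "signatures.gmt")
    truth = cohort.truth
    _write_json(
        {
            "parent_of": truth.tree.parent_of,
            "n_mutations": {
                c: len(truth.tree.mutations_of[c]) for c in truth.tree.clone_ids
            },
            "cp_true": {
                s: truth.cp_true.cp[s].round(6).to_dict()
                for s in truth.cp_true.sample_ids
            },
            "purity_true": truth.purity_true.round(6).to_dict(),
            "seeding_true": truth.seeding_true,
        },
        indir / "ground_truth.json",
    )


def _de_stats(
    expr: pd.DataFrame, phases: dict[str, str]
) -> pd.DataFrame:
    """Per-gene post-vs-pre contrast: Student's t on log2(x+1), raw-scale
    fold change post/pre, BH-adjusted p, base mean."""
    pre = [s for s in expr.columns if phases[s] == "pre"]
    post = [s for s in expr.columns if phases[s] == "post"]
    logx = np.log2(expr + 1.0)
    rows = []
    for g in expr.index:
        x, y = logx.loc[g, post].to_numpy(), logx.loc[g, pre].to_numpy()
        try:
            res = stats.students_t_test(x, y)
            p = res.p_value
        except (stats.DegenerateDataError, stats.InsufficientDataError):
            p = 1.0
        fc = (expr.loc[g, post].mean() + 1e-9) / (expr.loc[g, pre].mean() + 1e-9)
        rows.append(
            {
                "gene": g,
                "fold_change": float(fc),
                "p_value": float(p),
                "base_mean": float(expr.loc[g].mean()),
            }
        )
    df = pd.DataFrame(rows)
    df["p_adj"] = stats.bh_fdr(df["p_value"].to_numpy())
    return df


def run_demo(config: PipelineConfig, outdir) -> list[StageReport]:
    """Simulate, analyze, and report. Returns the per-stage reports; all
    tables, the Newick tree, and ``summary.json`` are written under
    ``outdir``. Any stage failure aborts with the stage name attached."""
    outdir = Path(outdir)
    indir = outdir / "inputs"
    resdir = outdir / "results"
    resdir.mkdir(parents=True, exist_ok=True)
    reports: list[StageReport] = []
    summary: dict[str, Any] = {}
    stage = "simulate"
    try:
        # --- simulate -----------------------------------------------------
        log.info("[simulate] seed=%d", config.simulation.seed)
        cohort = synthetic.simulate_cohort(config.simulation)
        _write_inputs(cohort, indir)
        digest = _digest(*(p.read_text() for p in sorted(indir.glob("*"))))
        reports.append(
            StageReport(
                stage="simulate",
                input_digest=digest,
                parameters=config.to_dict()["simulation"],
                summaries={
                    "n_samples": len(cohort.variants.sample_ids),
                    "n_variants": len(cohort.variants.variant_ids),
                    "n_clones_true": len(cohort.truth.tree.clone_ids),
                },
            )
        )

        # --- filter -------------------------------------------------------
        stage = "filter"
        log.info("[filter] min_maf=%.3f", config.min_maf)
        table = cohort.variants
        counts = filtering.count_impactful_variants(table, config.min_maf)
        counts.rename("n_impactful").to_csv(resdir / "impactful_counts.tsv", sep="\t")
        hq = filtering.high_quality_union(table, config.min_maf)
        rescued_table = (
            filtering.reinterrogate(table, hq) if config.rescue else table
        )
        nonprivate = filtering.nonprivate_filter(
            rescued_table, config.min_shared_samples
        )
        expressed = filtering.flag_expressed(
            nonprivate, cohort.rna, config.min_rna_reads
        )
        recurrent = filtering.recurrent_impact_selection(
            rescued_table, expressed, config.recurrent_min_samples, config.min_maf
        )
        _write_json(
            {
                "high_quality_union": sorted(hq),
                "nonprivate": sorted(nonprivate),
                "expressed": sorted(expressed),
                "recurrent": sorted(recurrent),
            },
            resdir / "filter_sets.json",
        )
        reports.append(
            StageReport(
                stage="filter",
                input_digest=digest,
                parameters={
                    "min_maf": config.min_maf,
                    "min_shared_samples": config.min_shared_samples,
                    "recurrent_min_samples": config.recurrent_min_samples,
                    "min_rna_reads": config.min_rna_reads,
                    "rescue": config.rescue,
                },
                summaries={
                    "impactful_per_sample": counts.to_dict(),
                    "n_high_quality": len(hq),
                    "n_nonprivate": len(nonprivate),
                    "n_expressed": len(expressed),
                    "n_recurrent": len(recurrent),
                },
            )
        )
        summary["n_recurrent_variants"] = len(recurrent)

        # --- cluster ------------------------------------------------------
        stage = "cluster"
        eligible = phylogeny.pyclone_input_filter(
            rescued_table,
            cohort.copy_number,
            config.cluster_min_depth,
            config.cluster_min_maf,
        )
        k_range = range(config.k_min, config.k_max + 1)
        log.info("[cluster] %d eligible variants, K in %s", len(eligible), list(k_range))
        model = phylogeny.cluster_variants(
            rescued_table,
            eligible,
            cn=cohort.copy_number,
            k_range=k_range,
            n_restarts=config.n_restarts,
            seed=config.seed,
        )
        tio.write_cp_matrix(model.cp_hat, resdir / "cp_matrix.tsv")
        model.assignment.to_csv(resdir / "clone_assignment.tsv", sep="\t")
        reports.append(
            StageReport(
                stage="cluster",
                input_digest=digest,
                parameters={
                    "k_range": [config.k_min, config.k_max],
                    "n_restarts": config.n_restarts,
                    "seed": config.seed,
                },
                summaries={
                    "selected_K": model.K,
                    "bic_by_k": {str(k): v for k, v in model.bic_by_k.items()},
                    "n_clustered_variants": int(model.assignment.size),
                },
            )
        )
        summary["selected_K"] = model.K

        # --- tree ---------------------------------------------------------
        stage = "tree"
        dmat = phylogeny.pairwise_distances(model.cp_hat)
        tree = phylogeny.neighbor_joining(dmat)
        tio.write_distance_matrix(dmat, resdir / "distances.tsv")
        tio.write_newick(tree, resdir / "tree.nwk")
        reports.append(
            StageReport(
                stage="tree",
                input_digest=digest,
                parameters={"distance": "jensen_shannon_bits", "method": "neighbor_joining"},
                summaries={
                    "n_leaves": len(tree.leaf_names),
                    "n_clamped_branches": len(
                        tree.diagnostics["raw_negative_branch_lengths"]
                    ),
                },
            )
        )

        # --- seeding ------------------------------------------------------
        stage = "seeding"
        seeding = {
            s: phylogeny.classify_seeding(
                model.cp_hat.cp[s].to_numpy(), config.presence_threshold
            )
            for s in model.cp_hat.sample_ids
        }
        founders, cohort_founder = phylogeny.founding_clone(
            model.cp_hat, config.presence_threshold
        )
        pd.DataFrame(
            {
                "seeding": pd.Series(seeding),
                "founding_clone": pd.Series(founders, dtype=object),
            }
        ).rename_axis("sample_id").to_csv(resdir / "seeding.tsv", sep="\t")
        reports.append(
            StageReport(
                stage="seeding",
                input_digest=digest,
                parameters={"presence_threshold": config.presence_threshold},
                summaries={
                    "seeding": seeding,
                    "cohort_founding_clone": cohort_founder,
                    "n_monoclonal": sum(v == "monoclonal" for v in seeding.values()),
                },
            )
        )
        summary["seeding"] = seeding
        summary["cohort_founding_clone"] = cohort_founder

        # --- overlap ------------------------------------------------------
        stage = "overlap"
        phases = dict(cohort.variants.samples["phase"])
        overlap_summ = {}
        for chain, reps in cohort.repertoires.items():
            m = immuno.overlap_matrix(reps)
            tio.write_matrix(
                m.round(6), resdir / f"overlap_{chain.lower()}.tsv",
                index_label="sample_id",
            )
            contrast = immuno.compare_overlap_groups(m, phases)
            overlap_summ[chain] = {
                "group_means": {
                    k: (None if np.isnan(v) else round(v, 6))
                    for k, v in contrast.group_means.items()
                },
                "insufficient": contrast.insufficient,
                "post_post_vs_pre_post_p": (
                    None if contrast.test is None else contrast.test.p_value
                ),
            }
        reports.append(
            StageReport(
                stage="overlap",
                input_digest=digest,
                parameters={"index": "morisita_horn"},
                summaries=overlap_summ,
            )
        )
        summary["repertoire_overlap"] = overlap_summ

        # --- neoantigen -----------------------------------------------------
        stage = "neoantigen"
        burden = immuno.neoantigen_burden(cohort.neoantigens, config.rank_cutoff)
        burden.rename("n_binders").to_csv(resdir / "neoantigen_burden.tsv", sep="\t")
        counts_mat, log10_mat = immuno.neoantigen_overlap_counts(cohort.neoantigens)
        tio.write_matrix(
            log10_mat.round(6), resdir / "neoantigen_overlap_log10.tsv",
            index_label="sample_id",
        )
        pre_b = burden[[s for s in burden.index if phases[s] == "pre"]]
        post_b = burden[[s for s in burden.index if phases[s] == "post"]]
        try:
            btest = stats.students_t_test(pre_b, post_b)
            burden_p = btest.p_value
        except (stats.DegenerateDataError, stats.InsufficientDataError):
            burden_p = None
        reports.append(
            StageReport(
                stage="neoantigen",
                input_digest=digest,
                parameters={"rank_cutoff": config.rank_cutoff},
                summaries={
                    "burden": burden.to_dict(),
                    "pre_vs_post_p": burden_p,
                },
            )
        )
        summary["neoantigen_burden_pre_vs_post_p"] = burden_p

        # --- signatures -----------------------------------------------------
        stage = "signatures"
        sig_scores = {}
        for name, genes in cohort.signatures.items():
            sig = immuno.GeneSignature(name=name, genes=frozenset(genes))
            scores, n_used = immuno.signature_score(cohort.expression, sig)
            sig_scores[name] = scores
        sig_df = pd.DataFrame(sig_scores).T
        tio.write_matrix(sig_df.round(6), resdir / "signature_scores.tsv",
                         index_label="signature")
        de = _de_stats(cohort.expression, phases)
        de.round(6).to_csv(resdir / "de_stats.tsv", sep="\t", index=False)
        up, down = immuno.apply_de_filters(
            de, config.fc_min, config.padj_max, config.basemean_min
        )
        de_nonzero = de.loc[(de["p_value"] > 0) & (de["fold_change"] > 0)]
        prerank = {
            g: immuno.prerank_gene_score(p, fc)
            for g, p, fc in zip(
                de_nonzero["gene"], de_nonzero["p_value"], de_nonzero["fold_change"]
            )
        }
        pd.Series(prerank, name="score").sort_values(ascending=False).round(6).to_csv(
            resdir / "prerank_scores.tsv", sep="\t", index_label="gene"
        )
        reports.append(
            StageReport(
                stage="signatures",
                input_digest=digest,
                parameters={
                    "fc_min": config.fc_min,
                    "padj_max": config.padj_max,
                    "basemean_min": config.basemean_min,
                },
                summaries={
                    "n_up": len(up),
                    "n_down": len(down),
                    "signatures": sorted(sig_scores),
                },
            )
        )
        summary["n_de_up"] = len(up)
        summary["n_de_down"] = len(down)

        # --- stats summary --------------------------------------------------
        stage = "report"
        _write_json(summary, resdir / "summary.json")
        _write_json([r.to_dict() for r in reports], resdir / "stage_reports.json")
    except Exception as err:
        _write_json(
            [r.to_dict() for r in reports], resdir / "stage_reports.partial.json"
        )
        raise RuntimeError(f"demo failed at stage {stage!r}: {err}") from err
    return reports
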