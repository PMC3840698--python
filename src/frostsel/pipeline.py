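"""End-to-end pipeline: simulate -> prep -> trees -> rates -> selection ->
resample -> report.

Every stage reads its inputs from, and writes its outputs to, a run
directory, so any downstream stage can be re-run from on-disk artifacts and
reproduce its outputs byte-identically.  The run manifest records the counts
at every filtering step (genes simulated, ortholog sets passing the
composition rule, congruent trees, long-branch actions, outlier rows,
selection tests and skips) together with the seed and thresholds.

Layout of a run directory::

    data/genes/*.fasta  data/labels.tsv  data/truth.tsv  data/config.txt
    prep/ortholog_sets.tsv
    trees/*.nwk  trees/qc_log.tsv  trees/stats.tsv
    rates/rates.tsv  rates/rates_raw.tsv
    selection/results_<branch>.tsv
    resample/medians.tsv  resample/differences.tsv  resample/enrichment.tsv
    manifest.json
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import CodonAlignment
from .branchsite import ForegroundMissingError, fit_branch_site, fit_codon_scale
from .dnds import lineage_rates
from .nucphylo import check_topology, fit_gene_tree, long_branch_qc
from .seqprep import (
    CdsRecord,
    build_ortholog_sets,
    composition_filter,
    filter_cds,
    label_lti,
)
from .simulate import SimulationConfig, generate_dataset
from .stats import (
    fdr_adjust,
    filter_outliers,
    rate_difference,
    resample_pvalue,
    selection_enrichment,
)
from .topology import BARLEY, LOLIUM, RICE, SpeciesTopology

log = logging.getLogger("frostsel.pipeline")

SPECIES_SEP = "__"


@dataclass
class RunConfig:
    """Thresholds and paths for one pipeline run.  Defaults are the study's
    analysis constants: long-branch factor 3, outlier bounds dS > 2 /
    dN > 0.5, significance level 0.05 after FDR, posterior cutoff 0.9,
    omega2 starting values {0.5, 1, 1.5, 2}, 50 000 resamples."""

    out_dir: Path
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    foreground_branches: tuple[str, ...] = ("BP_ancestral", "CP_stem")
    long_branch_factor: float = 3.0
    ds_outlier: float = 2.0
    dn_outlier: float = 0.5
    alpha: float = 0.05
    posterior_cutoff: float = 0.9
    omega2_starts: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0)
    n_resamples: int = 50_000
    qc_max_iterations: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        for name in ("long_branch_factor", "ds_outlier", "dn_outlier",
                     "alpha", "posterior_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _stage_dir(cfg: RunConfig, name: str) -> Path:
    d = cfg.out_dir / name
    d.mkdir(parents=True, exist_ok=True)
    return d


def write_stage_tsv(df: pd.DataFrame, path: Path, cfg: RunConfig,
                    stage: str, units: str) -> None:
    """Stage outputs are self-describing: a comment line names the
    producing stage, the units and the run seed."""
    with open(path, "w") as fh:
        fh.write(f"# stage={stage} units={units} seed={cfg.seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_stage_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def stage_simulate(cfg: RunConfig, topology: SpeciesTopology) -> Path:
    data_dir = cfg.out_dir / "data"
    generate_dataset(topology, cfg.simulation, out_dir=data_dir)
    return data_dir


def _load_gene_alignments(data_dir: Path) -> dict[str, CodonAlignment]:
    gene_dir = data_dir / "genes"
    if not gene_dir.is_dir() or not any(gene_dir.glob("*.fasta")):
        raise FileNotFoundError(
            f"stage 'prep': no gene FASTA files under {gene_dir}"
        )
    return {
        p.stem: CodonAlignment.read_fasta(p)
        for p in sorted(gene_dir.glob("*.fasta"))
    }


def stage_prep(cfg: RunConfig) -> pd.DataFrame:
    """Pool sequences per species, apply CDS hygiene filtering, build RBH
    ortholog sets, apply the composition filter and the LTI label rule."""
    data_dir = cfg.out_dir / "data"
    genes = _load_gene_alignments(data_dir)
    labels = pd.read_csv(data_dir / "labels.tsv", sep="\t")
    lti_genes = set(labels.loc[labels["is_lti"], "gene_id"])

    records: dict[str, list[CdsRecord]] = {}
    n_raw = n_kept = 0
    for gene_id, aln in genes.items():
        for sp, seq in aln.sequences().items():
            rec = CdsRecord(id=f"{sp}{SPECIES_SEP}{gene_id}", species=sp,
                            sequence=seq)
            records.setdefault(sp, []).append(rec)
            n_raw += 1
    for sp in list(records):
        records[sp] = filter_cds(records[sp])
        n_kept += len(records[sp])
    log.info("prep: %d/%d CDS records pass hygiene filter", n_kept, n_raw)

    sets = build_ortholog_sets(records)
    # species-level LTI evidence: barley and L. perenne members of LTI genes
    lti_table = {
        (sp, f"{sp}{SPECIES_SEP}{g}") for g in lti_genes for sp in (BARLEY, LOLIUM)
    }
    rows = []
    for oset in sets:
        oset.is_lti = label_lti(oset, lti_table)
        passed = composition_filter(oset)
        for sp, gid in sorted(oset.members.items()):
            rows.append({
                "anchor_id": oset.anchor_id, "species": sp, "gene_id": gid,
                "is_lti": oset.is_lti, "passed_composition": passed,
            })
    table = pd.DataFrame(rows)
    write_stage_tsv(table, _stage_dir(cfg, "prep") / "ortholog_sets.tsv",
                    cfg, stage="prep", units="none")
    return table


def _set_alignment(
    genes: dict[str, CodonAlignment], members: pd.DataFrame
) -> tuple[str, CodonAlignment]:
    """Rebuild the codon alignment of one ortholog set, pulling each member
    sequence from its own source gene (an RBH mismatch may point a species
    at another gene's sequence; members whose length differs from the
    anchor's are dropped here and logged)."""
    gene_id = members["anchor_id"].iloc[0].split(SPECIES_SEP, 1)[1]
    anchor_len = genes[gene_id].n_codons
    taxa, rows = [], []
    for _, row in members.sort_values("species").iterrows():
        sp, gid = row["species"], row["gene_id"]
        src = gid.split(SPECIES_SEP, 1)[1]
        source = genes.get(src)
        if source is None or sp not in source.taxa:
            continue
        if source.n_codons != anchor_len:
            log.info("trees: %s member %s length mismatch, dropped",
                     gene_id, gid)
            continue
        taxa.append(sp)
        rows.append(source.row(sp))
    return gene_id, CodonAlignment(taxa, np.stack(rows))


def stage_trees(
    cfg: RunConfig, topology: SpeciesTopology
) -> tuple[dict[str, object], pd.DataFrame]:
    """Estimate gene trees with topology-congruence and long-branch QC.

    Dropping a long external branch sends the reduced set back through the
    whole loop (refit, re-check composition and congruence), up to
    ``qc_max_iterations`` rounds, mirroring the iterative filtering design.
    """
    genes = _load_gene_alignments(cfg.out_dir / "data")
    sets = read_stage_tsv(cfg.out_dir / "prep" / "ortholog_sets.tsv")
    tree_dir = _stage_dir(cfg, "trees")
    qc_rows, stat_rows = [], []
    kept: dict[str, object] = {}
    for anchor_id, members in sets[sets["passed_composition"]].groupby(
        "anchor_id", sort=True
    ):
        gene_id, aln = _set_alignment(genes, members)
        status = "max_qc_iterations"
        gt = None
        for it in range(cfg.qc_max_iterations):
            status = "kept"
            if not composition_filter(frozenset(aln.taxa)):
                status = "failed_composition"
                break
            gt = fit_gene_tree(aln)
            if not check_topology(gt, topology):
                status = "incongruent_topology"
                break
            qc = long_branch_qc(gt, factor=cfg.long_branch_factor)
            qc_rows.append({
                "gene_id": gene_id, "iteration": it, "action": qc.action,
                "taxon": qc.taxon or "", "ratio": round(qc.ratio, 6),
            })
            if qc.action == "keep":
                break
            if qc.action == "discard_tree":
                status = "long_internal_branch"
                break
            aln = aln.subset([t for t in aln.taxa if t != qc.taxon])
        else:
            status = "max_qc_iterations"
        if status == "kept" and gt is not None:
            kept[gene_id] = (aln, gt)
            with open(tree_dir / f"{gene_id}.nwk", "w") as fh:
                fh.write(gt.newick() + "\n")
        stat_rows.append({
            "gene_id": gene_id, "status": status,
            "n_taxa": aln.n_taxa,
            "log_likelihood": (round(gt.log_likelihood, 4) if gt else np.nan),
        })
        log.info("trees: %s -> %s", gene_id, status)
    qc_df = pd.DataFrame(
        qc_rows, columns=["gene_id", "iteration", "action", "taxon", "ratio"]
    )
    write_stage_tsv(qc_df, tree_dir / "qc_log.tsv", cfg, stage="trees",
                    units="branch_length_ratio")
    stats_df = pd.DataFrame(stat_rows)
    write_stage_tsv(stats_df, tree_dir / "stats.tsv", cfg, stage="trees",
                    units="log_likelihood_nats")
    return kept, stats_df


def stage_rates(cfg: RunConfig, kept: dict) -> pd.DataFrame:
    """Per-gene per-species GTR distances and dN/dS to the outgroups,
    followed by the outlier rule (dS > 2 or dN > 0.5 removed)."""
    labels = pd.read_csv(cfg.out_dir / "data" / "labels.tsv", sep="\t")
    lti = dict(zip(labels["gene_id"], labels["is_lti"]))
    frames = []
    for gene_id, (aln, gt) in sorted(kept.items()):
        df = lineage_rates(gene_id, aln, gt)
        df["is_lti"] = lti.get(gene_id, False)
        frames.append(df)
    raw = (
        pd.concat(frames, ignore_index=True) if frames
        else pd.DataFrame(columns=["gene_id", "species", "gtr_distance",
                                   "dS", "dN", "omega", "saturated", "is_lti"])
    )
    rate_dir = _stage_dir(cfg, "rates")
    write_stage_tsv(raw, rate_dir / "rates_raw.tsv", cfg, stage="rates",
                    units="substitutions_per_site")
    rates = filter_outliers(raw, ds_max=cfg.ds_outlier, dn_max=cfg.dn_outlier)
    write_stage_tsv(rates, rate_dir / "rates.tsv", cfg, stage="rates",
                    units="substitutions_per_site")
    return rates


def stage_selection(cfg: RunConfig, kept: dict) -> dict[str, pd.DataFrame]:
    """Branch-site LRTs on each foreground branch, FDR-adjusted per branch
    over all tested genes.  The preliminary codon-scale fit is shared
    between foreground branches of the same gene."""
    sel_dir = _stage_dir(cfg, "selection")
    rows_by_branch: dict[str, list] = {b: [] for b in cfg.foreground_branches}
    for gene_id, (aln, gt) in sorted(kept.items()):
        prelim = fit_codon_scale(aln, gt.tree)
        for branch in cfg.foreground_branches:
            try:
                r = fit_branch_site(aln, gt.tree, branch, gene_id=gene_id,
                                    omega2_starts=cfg.omega2_starts,
                                    prelim=prelim,
                                    posterior_cutoff=cfg.posterior_cutoff)
            except ForegroundMissingError as exc:
                log.info("selection: %s on %s skipped (%s)", gene_id, branch,
                         exc)
                continue
            rows_by_branch[branch].append({
                "gene_id": gene_id, "lnl_null": round(r.lnl_null, 6),
                "lnl_alt": round(r.lnl_alt, 6), "lr": round(r.lr, 6),
                "p_value": r.p_value, "omega2": round(r.omega2, 6),
                "sites": ";".join(map(str, r.neb_sites)),
            })
    out: dict[str, pd.DataFrame] = {}
    for branch in cfg.foreground_branches:
        df = pd.DataFrame(rows_by_branch[branch],
                          columns=["gene_id", "lnl_null", "lnl_alt",
                                   "lr", "p_value", "omega2", "sites"])
        if not df.empty:
            df["p_fdr"] = fdr_adjust(df["p_value"].values)
        else:
            df["p_fdr"] = []
        write_stage_tsv(df, sel_dir / f"results_{branch}.tsv", cfg,
                        stage="selection",
                        units="log_likelihood_nats;sites_1based_codons")
        out[branch] = df
    return out


def stage_resample(
    cfg: RunConfig,
    rates: pd.DataFrame,
    selection: dict[str, pd.DataFrame],
) -> dict:
    """LTI-versus-all comparisons: rate-difference resampling (median
    statistic), likelihood-ratio resampling (third quartile), and the
    significant-proportion enrichment test, one per foreground branch."""
    res_dir = _stage_dir(cfg, "resample")
    lti_ids = sorted(rates.loc[rates["is_lti"], "gene_id"].unique())
    ss = np.random.SeedSequence([cfg.seed, 2718])
    rng = np.random.default_rng(ss)

    median_rows, diff_rows = [], []
    for metric in ("gtr_distance", "dS", "dN"):
        for sp in sorted(rates["species"].unique()):
            sub = rates[rates["species"] == sp]
            median_rows.append({
                "species": sp, "metric": metric,
                "median_all": sub[metric].median(),
                "median_lti": sub.loc[sub["is_lti"], metric].median(),
            })
        for group in ("brachypodium", "core_pooideae"):
            diffs = rate_difference(rates, group, metric)
            lti_here = [g for g in lti_ids if g in diffs.index]
            if not lti_here:
                continue
            rr = resample_pvalue(diffs, lti_here, statistic="median",
                                 n_resamples=cfg.n_resamples, seed=rng,
                                 keep_draws=False)
            diff_rows.append({
                "comparison": f"{group}_vs_{RICE}", "metric": metric,
                "observed_lti_median": rr.observed,
                "resampled_mean": rr.null_mean, "p_value": rr.pvalue,
            })
    medians = pd.DataFrame(median_rows)
    write_stage_tsv(medians, res_dir / "medians.tsv", cfg,
                    stage="resample", units="substitutions_per_site")
    diffs_df = pd.DataFrame(diff_rows)
    write_stage_tsv(diffs_df, res_dir / "differences.tsv", cfg,
                    stage="resample",
                    units=f"substitutions_per_site;n_resamples={cfg.n_resamples}")

    labels = pd.read_csv(cfg.out_dir / "data" / "labels.tsv", sep="\t")
    lti_all = sorted(labels.loc[labels["is_lti"], "gene_id"])
    enrich_rows = []
    enrichments = {}
    for branch, df in selection.items():
        if df.empty:
            continue
        pvals = pd.Series(df["p_value"].values, index=df["gene_id"])
        lti_branch = [g for g in lti_all if g in pvals.index]
        if not lti_branch:
            continue
        enr = selection_enrichment(
            pvals, lti_branch, foreground=branch, alpha=cfg.alpha,
            n_resamples=cfg.n_resamples, seed=rng,
        )
        lrs = pd.Series(df["lr"].values, index=df["gene_id"])
        q3 = resample_pvalue(lrs, lti_branch, statistic="third_quartile",
                             n_resamples=cfg.n_resamples, seed=rng,
                             keep_draws=False)
        enrichments[branch] = (enr, q3)
        enrich_rows.append({
            "foreground": branch,
            "n_tested": enr.n_total, "n_lti": enr.n_lti,
            "n_significant_all": enr.n_significant_total,
            "n_significant_lti": enr.n_significant_lti,
            "proportion_all": enr.proportion_all,
            "proportion_lti": enr.proportion_lti,
            "p_proportion": enr.resampling.pvalue,
            "p_lr_third_quartile": q3.pvalue,
        })
    enrich_df = pd.DataFrame(enrich_rows)
    write_stage_tsv(enrich_df, res_dir / "enrichment.tsv", cfg,
                    stage="resample",
                    units=f"proportions;alpha={cfg.alpha};n_resamples={cfg.n_resamples}")
    return {"medians": medians, "differences": diffs_df,
            "enrichment": enrich_df, "objects": enrichments}


@dataclass
class PipelineResult:
    manifest: dict
    rates: pd.DataFrame
    selection: dict[str, pd.DataFrame]
    resample: dict


def run_pipeline(
    cfg: RunConfig, topology: SpeciesTopology | None = None
) -> PipelineResult:
    """Run all stages in order; artifacts land under ``cfg.out_dir`` and the
    manifest (counts at every filter stage, seed, thresholds) is written to
    ``manifest.json``."""
    topology = topology or SpeciesTopology()
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(cfg.out_dir / "run.log")
    log.addHandler(fh)
    try:
        stage_simulate(cfg, topology)
        sets = stage_prep(cfg)
        kept, tree_stats = stage_trees(cfg, topology)
        rates = stage_rates(cfg, kept)
        selection = stage_selection(cfg, kept)
        resample = stage_resample(cfg, rates, selection)
    finally:
        log.removeHandler(fh)
        fh.close()

    anchors = sets.groupby("anchor_id").first()
    status_counts = tree_stats["status"].value_counts().to_dict()
    qc = read_stage_tsv(cfg.out_dir / "trees" / "qc_log.tsv")
    raw_rates = read_stage_tsv(cfg.out_dir / "rates" / "rates_raw.tsv")
    manifest = {
        "seed": cfg.seed,
        "n_genes_simulated": cfg.simulation.n_genes,
        "n_ortholog_sets": int(len(anchors)),
        "n_pass_composition": int(anchors["passed_composition"].sum()),
        "n_lti_sets": int(anchors["is_lti"].sum()),
        "tree_status_counts": {k: int(v) for k, v in status_counts.items()},
        "n_trees_kept": int(status_counts.get("kept", 0)),
        "qc_actions": {
            k: int(v) for k, v in qc["action"].value_counts().items()
        },
        "n_rate_rows_raw": int(len(raw_rates)),
        "n_rate_rows_kept": int(len(rates)),
        "selection": {
            branch: {
                "n_tested": int(len(df)),
                "n_significant": int((df["p_fdr"] < cfg.alpha).sum())
                if not df.empty else 0,
            }
            for branch, df in selection.items()
        },
        "thresholds": {
            "long_branch_factor": cfg.long_branch_factor,
            "ds_outlier": cfg.ds_outlier, "dn_outlier": cfg.dn_outlier,
            "alpha": cfg.alpha, "posterior_cutoff": cfg.posterior_cutoff,
            "omega2_starts": list(cfg.omega2_starts),
            "n_resamples": cfg.n_resamples,
        },
    }
    with open(cfg.out_dir / "manifest.json", "w") as fh2:
        json.dump(manifest, fh2, indent=2, sort_keys=True)
    return PipelineResult(manifest=manifest, rates=rates,
                          selection=selection, resample=resample)
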