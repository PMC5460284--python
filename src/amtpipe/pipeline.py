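"""End-to-end orchestration: simulate -> quantify -> AMT -> align -> test.

Every stage is a pure function of its declared inputs; under a fixed
config the whole artifact directory is reproduced byte-identically.
The run log records parameters, seeds and the per-stage feature counts.
"""

from __future__ import annotations

import os
import sys
from typing import Mapping, TextIO

import numpy as np
import pandas as pd

from . import alignment, amtdb, destats, integrate, io, simulate, umc
from .config import PipelineConfig
from .errors import AmtPipeError

UMC_TSV_COLUMNS = [
    "umc_id", "run_id", "umc_mass_da", "net", "umc_intensity", "n_ions",
    "peptide_seq", "id_score", "protein_ids", "id_conflict",
]


def quantify_runs(
    runs: Mapping[str, pd.DataFrame],
    mass_tol_ppm: float = 10.0,
    max_scan_gap: int = 5,
    calibrate: bool = True,
) -> pd.DataFrame:
    """Group each run's ions into UMCs with IDs and cross-run aligned NETs.

    First pass computes raw min-max NETs per run; the per-peptide median
    raw NET over identified UMCs then serves as the elution reference and
    each run is refit against it (linear map), which absorbs run-to-run
    gradient differences.
    """
    first = {}
    for run_id, features in runs.items():
        first[run_id] = umc.quantify_run(features, mass_tol_ppm=mass_tol_ppm,
                                         max_scan_gap=max_scan_gap)
    if calibrate:
        identified = pd.concat(
            [u[u["peptide_seq"].notna()][["peptide_seq", "net"]] for u in first.values()],
            ignore_index=True,
        )
        if not identified.empty:
            reference = identified.groupby("peptide_seq")["net"].median().to_dict()
            for run_id, features in runs.items():
                try:
                    first[run_id] = umc.quantify_run(
                        features, mass_tol_ppm=mass_tol_ppm,
                        max_scan_gap=max_scan_gap, calibration=reference,
                    )
                except AmtPipeError:
                    pass  # too few anchors in this run: keep raw NETs
    combined = pd.concat(first.values(), ignore_index=True)
    return combined


def umcs_for_tsv(umcs: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in UMC_TSV_COLUMNS if c in umcs.columns]
    extra = [c for c in umcs.columns if c in ("source", "duplicate", "true_peptide")]
    return umcs[cols + extra]


class _Log:
    def __init__(self, path: str | None, stream: TextIO = sys.stderr):
        self.path = path
        self.stream = stream
        self.lines: list[str] = []

    def __call__(self, key: str, value) -> None:
        line = f"{key} = {value}"
        self.lines.append(line)
        print(f"[amtpipe] {line}", file=self.stream)

    def flush(self) -> None:
        if self.path:
            with open(self.path, "w") as fh:
                fh.write("\n".join(self.lines) + "\n")


def run_pipeline(config: PipelineConfig, outdir: str, stream: TextIO = sys.stderr) -> dict:
    """Run the full synthetic-study workflow and write every artifact.

    Returns the count ledger (also written to ``run_log.txt``).  Stage
    failures propagate with the failing stage named; artifacts written
    before the failure are retained.
    """
    config.validate()
    os.makedirs(outdir, exist_ok=True)
    log = _Log(os.path.join(outdir, "run_log.txt"), stream)
    counts: dict[str, object] = {}

    def record(key, value):
        counts[key] = value
        log(key, value)

    log("config.seed", config.seed)
    for key in ("n_proteins", "de_fraction", "effect_size", "n_permutations"):
        log(f"config.{key}", getattr(config, key))

    stage = "simulate"
    try:
        sim_cfg = config.simulation()
        universe, truth, runs, expression, annotation = simulate.simulate_all(sim_cfg)
        sim_dir = os.path.join(outdir, "sim")
        simulate.write_dataset(sim_dir, sim_cfg, universe, truth, runs, expression, annotation)
        design = simulate.make_design(sim_cfg)
        expr_design = simulate.expression_design(sim_cfg)
        record("count.peptides_universe", len(universe))
        record("count.runs", len(runs))
        record("count.expressed_genes", int(expression.shape[0]))
        record("count.features_total", int(sum(len(df) for df in runs.values())))

        stage = "quantify"
        umcs = quantify_runs(runs, mass_tol_ppm=config.umc_mass_tol_ppm,
                             max_scan_gap=config.umc_max_scan_gap)
        io.write_tsv(umcs_for_tsv(umcs), os.path.join(outdir, "umcs.tsv"))
        record("count.umcs", int(len(umcs)))
        record("count.identified_umcs", int(umcs["peptide_seq"].notna().sum()))

        stage = "build-amt"
        params = config.match_params()
        db = amtdb.build_amt_db(umcs[umcs["peptide_seq"].notna()], params)
        io.write_tsv(db, os.path.join(outdir, "amt_db.tsv"))
        record("count.amt_entries", int(len(db)))

        stage = "assign"
        assigned, report = amtdb.assign_all(umcs, db, params)
        io.write_tsv(umcs_for_tsv(assigned), os.path.join(outdir, "assigned_umcs.tsv"))
        io.write_tsv(report, os.path.join(outdir, "match_report.tsv"))
        record("count.amt_assigned_umcs", int((assigned["source"] == amtdb.ASSIGN_AMT).sum()))

        stage = "align"
        table = alignment.build_alignment_table(assigned, design)
        missing_before = table.n_missing()
        table = alignment.rescue_missing(
            table, assigned,
            mass_tol_ppm=config.rescue_mass_tol_ppm,
            tech_net_tol=config.rescue_tech_net_tol,
            bio_net_tol=config.rescue_bio_net_tol,
        )
        io.write_matrix(table.intensities, os.path.join(outdir, "alignment_intensity.tsv"),
                        index_label="peptide_seq")
        io.write_matrix(table.provenance, os.path.join(outdir, "alignment_provenance.tsv"),
                        index_label="peptide_seq")
        io.write_tsv(table.peptides.reset_index(), os.path.join(outdir, "alignment_peptides.tsv"))
        record("count.aligned_peptides", int(table.shape[0]))
        record("count.missing_cells_before_rescue", missing_before)
        record("count.missing_cells_after_rescue", table.n_missing())
        detected_proteins = sorted({
            p for prots in table.peptides["protein_ids"] for p in prots
        })
        record("count.detected_proteins", len(detected_proteins))

        stage = "normalize"
        table = alignment.quantile_normalize(alignment.log2_transform(table))
        io.write_matrix(table.intensities, os.path.join(outdir, "alignment_normalized_log2.tsv"),
                        index_label="peptide_seq")
        sim_rows = []
        run_ids = list(table.intensities.columns)
        for i, a in enumerate(run_ids):
            for b in run_ids[i + 1:]:
                jac, cor = alignment.dataset_similarity(table, a, b)
                sim_rows.append((a, b, jac, "" if cor is None else cor))
        io.write_tsv(pd.DataFrame(sim_rows, columns=["run_a", "run_b", "jaccard", "pearson"]),
                     os.path.join(outdir, "dataset_similarity.tsv"))

        stage = "de-test-genes"
        gene_design = destats.GroupDesign.from_frame(
            expr_design, simulate.GROUP_CONTROL, simulate.GROUP_CASE, sample_col="sample")
        gene_de = destats.de_test(np.log2(expression), gene_design,
                                  n_permutations=config.n_permutations, seed=config.seed)
        gene_results, fc_cutoff = destats.select_degs(
            gene_de, p_cut=config.p_cut, percentile=config.deg_fc_percentile)
        io.write_matrix(gene_results, os.path.join(outdir, "de_genes.tsv"),
                        index_label="gene_id")
        degs = gene_results[gene_results["is_de"]]
        record("stat.deg_fc_cutoff", round(fc_cutoff, 6))
        record("count.degs", int(len(degs)))
        record("count.degs_up", int((degs["direction"] == "up").sum()))
        record("count.degs_down", int((degs["direction"] == "down").sum()))
        io.write_id_list(degs.index[degs["direction"] == "up"],
                         os.path.join(outdir, "degs_up.txt"))
        io.write_id_list(degs.index[degs["direction"] == "down"],
                         os.path.join(outdir, "degs_down.txt"))

        stage = "de-test-peptides"
        run_design = destats.GroupDesign.from_frame(
            design, simulate.GROUP_CONTROL, simulate.GROUP_CASE)
        pep_de = destats.de_test(table.intensities, run_design,
                                 n_permutations=config.n_permutations,
                                 seed=config.seed + 1)
        pep_results = destats.select_depeptides(pep_de.results, p_cut=config.p_cut,
                                                fc_cut=config.depeptide_fc_cut)
        io.write_matrix(pep_results, os.path.join(outdir, "de_peptides.tsv"),
                        index_label="peptide_seq")
        depeptides = pep_results[pep_results["is_de"]]
        record("count.depeptides", int(len(depeptides)))
        record("count.depeptides_up", int((depeptides["direction"] == "up").sum()))
        record("count.depeptides_down", int((depeptides["direction"] == "down").sum()))

        stage = "dep-call"
        pep_meta = universe.peptides[["peptide_seq", "protein_ids", "proteotypic"]]
        deps, conflicts = destats.select_deps(pep_results, pep_meta,
                                              min_unique=config.dep_min_unique)
        io.write_tsv(deps, os.path.join(outdir, "deps.tsv"))
        io.write_tsv(conflicts, os.path.join(outdir, "dep_conflicts.tsv"))
        record("count.deps", int(len(deps)))
        record("count.deps_up", int((deps["direction"] == "up").sum()))
        record("count.deps_down", int((deps["direction"] == "down").sum()))
        record("count.dep_conflicts", int(len(conflicts)))

        stage = "integrate"
        mapping = truth.proteins[["gene_id", "protein_id"]]
        gene_of = dict(zip(mapping["protein_id"], mapping["gene_id"]))
        deg_set = set(degs.index)
        dep_genes = {gene_of[p] for p in deps["protein_id"] if p in gene_of}
        detected_genes = {gene_of[p] for p in detected_proteins if p in gene_of}
        expressed = set(expression.index)
        ov_detect = integrate.overlap_analysis(
            {"expressed_genes": expressed, "detected_proteins": detected_genes})
        ov_de = integrate.overlap_analysis({"DEGs": deg_set, "DEPs": dep_genes})
        ov_rows = []
        for name, ov in (("detection", ov_detect), ("differential", ov_de)):
            for key, count in sorted(ov["regions"].items(), key=lambda kv: sorted(kv[0])):
                ov_rows.append((name, "&".join(sorted(key)), count))
        io.write_tsv(pd.DataFrame(ov_rows, columns=["analysis", "region", "count"]),
                     os.path.join(outdir, "overlaps.tsv"))
        record("count.deg_dep_shared", int(ov_de["regions"].get(frozenset({"DEGs", "DEPs"}), 0)))

        prot_abund = integrate.protein_abundance(table.intensities, pep_meta, design)
        per_gene, summary = integrate.mrna_protein_correlation(
            expression, prot_abund, mapping)
        io.write_tsv(per_gene, os.path.join(outdir, "mrna_protein_correlation.tsv"))
        record("stat.mean_spearman_rho", round(summary["mean_rho"], 6))
        record("count.correlation_pairs", summary["n_pairs"])
        record("count.correlation_undefined", summary["n_undefined"])

        stage = "enrich"
        for direction, ids in (("up", degs.index[degs["direction"] == "up"]),
                               ("down", degs.index[degs["direction"] == "down"])):
            if len(ids) == 0:
                continue
            enr = integrate.enrich_terms(set(ids), expressed, annotation,
                                         alpha=config.p_cut)
            io.write_tsv(enr, os.path.join(outdir, f"enrichment_degs_{direction}.tsv"))
            record(f"count.enriched_terms_degs_{direction}",
                   int(enr["significant"].sum()) if len(enr) else 0)
    except AmtPipeError:
        log("error.stage", stage)
        log.flush()
        raise
    log.flush()
    return counts
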