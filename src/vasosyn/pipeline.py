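"""End-to-end orchestration of the transcriptome and phenotype analyses.

`run_transcriptome` strings together the full paired-design analysis:
FPM normalization -> control-variability threshold -> per-condition paired
effects with the built-in log-ratio test (BH-corrected, filling both FDR
columns when external DESeq2/edgeR-style tables are absent) -> triple DEG
filter -> synergy decomposition and classification -> scatter slopes ->
CI-based set reconciliation.  All result tables are plain TSV; run metadata
is JSON.  Identical inputs and seed give byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import effects, io, synergy, threshold
from .effects import STRESSOR_CONDITIONS
from .phenotypes import contractility_assay, filter_cells, gate_cell_cycle, ocr_params

logger = logging.getLogger(__name__)


@dataclass
class TranscriptomeResult:
    """Bundle of all transcriptome-stage outputs."""

    fpm: pd.DataFrame
    cv_stats: threshold.CVStats
    effect_tables: dict  # condition -> per-gene effect frame
    deg_tables: dict  # condition -> audited DEG frame
    synergy_table: pd.DataFrame
    slopes: list
    reconciliation: pd.DataFrame
    reconciliation_summary: dict
    n_paired_sets: int

    def deg_set(self, condition: str) -> set:
        t = self.deg_tables[condition]
        return set(t.index[t["is_deg"]])


def run_transcriptome(
    counts: io.CountMatrix,
    sheet: io.SampleSheet,
    external_fdr: dict | None = None,
    level: float = 0.99,
    fdr_cut: float = 0.05,
    fpm_cut: float = 3.0,
    min_mean_fpm: float = 1.0,
    pseudocount: float = 0.0,
    outdir: str | Path | None = None,
) -> TranscriptomeResult:
    """Run the full paired transcriptome analysis.

    ``external_fdr`` optionally maps condition -> gene-indexed frame with
    columns ``fdr_method1``/``fdr_method2`` from external DE tools; when
    absent, both columns are filled by the built-in paired log-ratio t-test
    with Benjamini-Hochberg correction.
    """
    fpm = io.compute_fpm(counts)
    sets = io.build_paired_sets(sheet)
    control_samples = [ps.sample("CTRL") for ps in sets]
    cv_table = threshold.gene_cv(fpm, control_samples, min_mean_fpm=min_mean_fpm)
    cv_stats = threshold.fc_threshold(cv_table)
    logger.info(
        "derived |log2FC| threshold %.3f from mean control CV %.3f over %d genes",
        cv_stats.threshold_log2fc, cv_stats.mean_cv, len(cv_table),
    )

    group_means = io.group_mean_fpm(fpm, sheet, grouping="condition")

    effect_tables: dict = {}
    deg_tables: dict = {}
    for cond in STRESSOR_CONDITIONS:
        eff = effects.paired_effect_table(fpm, sets, cond, level=level, pseudocount=pseudocount)
        effect_tables[cond] = eff
        stats = pd.DataFrame({"log2fc": eff["log2fc"]})
        if external_fdr and cond in external_fdr:
            ext = external_fdr[cond].reindex(eff.index)
            stats["fdr_method1"] = ext["fdr_method1"]
            stats["fdr_method2"] = ext["fdr_method2"]
        else:
            stats["fdr_method1"] = eff["fdr"]
            stats["fdr_method2"] = eff["fdr"]
        for grp in ("CTRL", cond):
            stats[f"mean_fpm_{grp}"] = group_means[grp]
        deg_tables[cond] = threshold.filter_deg(
            stats, cv_stats, fdr_cut=fdr_cut, fpm_cut=fpm_cut
        )

    syn = synergy.build_synergy_table(
        effect_tables["MET"]["log2fc"],
        effect_tables["HUM"]["log2fc"],
        effect_tables["ALL"]["log2fc"],
    )
    deg_flags = pd.DataFrame(
        {c: deg_tables[c]["is_deg"] for c in STRESSOR_CONDITIONS}
    )
    syn = synergy.classify_table(syn, cv_stats.threshold_log2fc, deg_flags)

    all_deg = list(syn.index[deg_flags["ALL"]])
    slopes = []
    if len(all_deg) >= 2:
        for y_cond, col in (("MET", "log2fc_met"), ("HUM", "log2fc_hum")):
            try:
                slopes.append(
                    synergy.scatter_slope(
                        syn.loc[all_deg, "log2fc_all"],
                        syn.loc[all_deg, col],
                        gene_set_label="ALL_DEG",
                        x_condition="ALL",
                        y_condition=y_cond,
                    )
                )
            except ValueError as exc:
                logger.warning("slope ALL vs %s not computed: %s", y_cond, exc)
    else:
        logger.warning("fewer than 2 combined-condition DEG; no scatter slopes")

    recon = synergy.reconcile_sets(
        {"MET": set(syn.index[deg_flags["MET"]]),
         "ALL": set(syn.index[deg_flags["ALL"]])},
        {"MET": effect_tables["MET"], "ALL": effect_tables["ALL"]},
        conditions=("MET", "ALL"),
    )
    recon_summary = synergy.reconciliation_summary(recon) if not recon.empty else {}

    result = TranscriptomeResult(
        fpm=fpm,
        cv_stats=cv_stats,
        effect_tables=effect_tables,
        deg_tables=deg_tables,
        synergy_table=syn,
        slopes=slopes,
        reconciliation=recon,
        reconciliation_summary=recon_summary,
        n_paired_sets=len(sets),
    )
    if outdir is not None:
        write_transcriptome_outputs(result, outdir)
    return result


def write_transcriptome_outputs(result: TranscriptomeResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    float_fmt = "%.6g"
    for cond, eff in result.effect_tables.items():
        eff.to_csv(outdir / f"effects_{cond}.tsv", sep="\t", float_format=float_fmt)
    for cond, deg in result.deg_tables.items():
        deg.to_csv(outdir / f"deg_{cond}.tsv", sep="\t", float_format=float_fmt)
    result.synergy_table.to_csv(outdir / "synergy.tsv", sep="\t", float_format=float_fmt)
    synergy.export_mesh(result.synergy_table).to_csv(
        outdir / "synergy_mesh.tsv", sep="\t", index=False, float_format=float_fmt
    )
    if not result.reconciliation.empty:
        result.reconciliation.to_csv(outdir / "reconciliation.tsv", sep="\t")
    meta = {
        "threshold_log2fc": result.cv_stats.threshold_log2fc,
        "mean_cv": result.cv_stats.mean_cv,
        "n_paired_sets": result.n_paired_sets,
        "n_deg": {c: int(result.deg_tables[c]["is_deg"].sum()) for c in result.deg_tables},
        "slopes": [
            {
                "x": s.x_condition,
                "y": s.y_condition,
                "slope": s.slope,
                "n_genes": s.n_genes,
                "gene_set": s.gene_set_label,
            }
            for s in result.slopes
        ],
        "reconciliation": result.reconciliation_summary,
    }
    io.write_run_metadata(outdir / "run_metadata.json", meta)


@dataclass
class PhenotypeResult:
    """Per-assay metric tables from the phenotype stage."""

    tables: dict = field(default_factory=dict)


def run_phenotype(
    ocr_traces: dict | None = None,
    contractility: dict | None = None,
    dapi: dict | None = None,
    level: float = 0.95,
    outdir: str | Path | None = None,
) -> PhenotypeResult:
    """Compute per-assay metric tables from phenotype input tables.

    ``ocr_traces`` maps sample label -> phase-annotated OCR trace;
    ``contractility`` maps sample label -> (before, after) cell-object
    tables (unfiltered); ``dapi`` maps sample label -> DAPI-integral array.
    Functional paired effects across samples are left to `effects`
    (level 0.95 by convention for assays).
    """
    result = PhenotypeResult()
    if ocr_traces:
        rows = []
        for label, trace in sorted(ocr_traces.items()):
            p = ocr_params(trace)
            rows.append(
                {
                    "sample": label,
                    "nmoc": p.nmoc,
                    "br": p.br,
                    "pl": p.pl,
                    "atp_ocr": p.atp_ocr,
                    "max_ocr": p.max_ocr,
                    "coupling_methods": p.coupling_methods,
                    "coupling_results": p.coupling_results,
                    "utilization": p.utilization,
                    "flags": ";".join(p.flags),
                }
            )
        result.tables["ocr"] = pd.DataFrame(rows)
    if contractility:
        rows = []
        for label, (before, after) in sorted(contractility.items()):
            fb, fa = filter_cells(before), filter_cells(after)
            if fb.empty or fa.empty:
                raise ValueError(f"{label}: no cells pass the object filter")
            mb, ma, idx = contractility_assay(fb, fa)
            rows.append(
                {
                    "sample": label,
                    "median_circ_before": mb,
                    "median_circ_after": ma,
                    "contraction_index": idx,
                    "n_cells_before": len(fb),
                    "n_cells_after": len(fa),
                }
            )
        result.tables["contractility"] = pd.DataFrame(rows)
    if dapi:
        rows = []
        for label, integrals in sorted(dapi.items()):
            g = gate_cell_cycle(integrals)
            rows.append(
                {
                    "sample": label,
                    "g1_mode": g.g1_mode,
                    "frac_g1": g.fractions[0],
                    "frac_s": g.fractions[1],
                    "frac_g2": g.fractions[2],
                    "n_gated": g.n_gated,
                    "n_excluded": g.n_excluded,
                }
            )
        result.tables["cell_cycle"] = pd.DataFrame(rows)
    if not result.tables:
        raise ValueError("no phenotype inputs provided")
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, tab in result.tables.items():
            tab.to_csv(outdir / f"phenotype_{name}.tsv", sep="\t", index=False,
                       float_format="%.6g")
    return result


def load_run_config(path: str | Path) -> dict:
    """Read a YAML/JSON run configuration file."""
    import yaml

    with open(path) as fh:
        if str(path).endswith(".json"):
            return json.load(fh)
        return yaml.safe_load(fh)
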