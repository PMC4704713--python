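"""End-to-end orchestration: catalog -> rates -> context -> covariates -> QC.

A single config (YAML-friendly dict) names the inputs and surfaces every
analysis threshold (read support 4 / 0.75, 50-nt clustering, 10-kb G/C
windows, 1% and 0.25-log-FPKM bins, 16-test Bonferroni family) as a key
with the study default.  Results are written as TSV/JSON plus a run
manifest (input digests, config digest, seed) so identical runs are
byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import catalog as cat
from . import context as ctx
from . import covariates as cov
from . import enrichment as enr
from . import rates as rt
from .genome import (
    base_composition,
    gc_windows,
    load_annotation,
    load_reference,
    trinucleotide_census,
)

log = logging.getLogger(__name__)

DEFAULT_FILTERS = {"min_depth": 4, "min_alt_fraction": 0.75, "cluster_nt": 50}
DEFAULT_ANALYSIS = {
    "gc_window_bp": 10_000,
    "gc_groups": 2,
    "replication_groups": 3,
    "expression_groups": 2,
    "bonferroni_family": 16,
    "rate_denominator": "full",  # 'full' reference length or 'masked'
}


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_full_analysis(config: dict, outdir) -> dict:
    """Run the whole pipeline from files named in ``config``; write a report
    bundle under ``outdir`` and return the in-memory results."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = config["inputs"]
    filters = {**DEFAULT_FILTERS, **config.get("filters", {})}
    analysis = {**DEFAULT_ANALYSIS, **config.get("analysis", {})}
    design_cfg = config.get("design", {})
    seed = int(config.get("seed", 2015))

    genome = load_reference(inputs["fasta"], inputs.get("exclusions"))

    ancestor_path = Path(inputs["ancestor_vcf"])
    vcf_dir = Path(inputs["vcf_dir"])
    line_paths = sorted(
        p for p in vcf_dir.glob("*.vcf") if p.resolve() != ancestor_path.resolve()
    )
    if not line_paths:
        raise FileNotFoundError(f"no line VCFs found in {vcf_dir}")

    ancestor_raw = cat.read_variants(
        ancestor_path, "ancestor", filters["min_depth"],
        filters["min_alt_fraction"], genome,
    )
    raw_by_line, new_by_line = {}, {}
    for p in line_paths:
        line_id = p.stem
        raw = cat.read_variants(p, line_id, filters["min_depth"],
                                filters["min_alt_fraction"], genome)
        raw_by_line[line_id] = raw
        new_by_line[line_id] = cat.subtract_ancestor(raw, ancestor_raw)

    contamination, retained = cat.detect_cross_contamination(new_by_line, seed)
    for report in contamination:
        if report["dropped"]:
            log.info("contamination: dropped %s (pair %s/%s, %d shared; seed %d)",
                     report["dropped"], report["line_a"], report["line_b"],
                     report["n_shared"], seed)
    retained_ids = sorted(retained)

    events = []
    for line_id in retained_ids:
        evs = cat.cluster_and_classify(new_by_line[line_id], filters["cluster_nt"])
        events.extend(cat.annotate_context(e, genome) for e in evs)

    # --- rates and spectrum --------------------------------------------------
    L = (genome.total_length_bp if analysis["rate_denominator"] == "full"
         else genome.analyzed_length_bp)
    design = rt.ExperimentDesign(
        n_lines=len(retained_ids),
        generations=float(design_cfg.get("generations", 1952.0)),
        analyzed_length_bp=float(L),
    )
    summary = cat.catalog_summary(events)
    per_line = summary.drop(index="total").reindex(retained_ids).fillna(0)
    rate_estimates = {}
    for cls in cat.EVENT_CLASSES:
        counts = per_line[cls].to_numpy()
        rate_estimates[cls] = rt.class_rate(
            int(counts.sum()), design, counts, event_class=cls
        )
    indel_counts = (per_line["insertion"] + per_line["deletion"]).to_numpy()
    rate_estimates["indel"] = rt.class_rate(
        int(indel_counts.sum()), design, indel_counts, event_class="indel"
    )

    composition = base_composition(genome)
    spectrum = rt.conditional_spectrum(events, composition, design)
    snm_counts = per_line["SNM"].to_numpy(int)
    pois_fit, nb_fit, fit_cmp = (
        rt.fit_count_distribution(snm_counts)
        if len(snm_counts) >= 5
        else (None, None, {"note": "too few lines"})
    )

    # --- context -------------------------------------------------------------
    census = trinucleotide_census(genome)
    ctx_table = ctx.context_relative_rates(events, census, design,
                                           line_ids=retained_ids)
    ctx_sig = {
        base: ctx.context_significance(ctx_table, base)
        for base in ("AT", "GC")
    }
    cpg_counts = ctx.cpg_direction_counts(events)
    cpg_summary = None
    if sum(cpg_counts.values()) > 0 and spectrum.total_count > 0:
        gc_src = {
            "C>A": spectrum.counts["GC>TA_tv"],
            "C>T": spectrum.counts["GC>AT_ts"],
            "C>G": spectrum.counts["GC>CG_tv"],
        }
        if sum(gc_src.values()) > 0:
            expected = {k: v / sum(gc_src.values()) for k, v in gc_src.items()}
            cpg_summary = ctx.cpg_spectrum_test(cpg_counts, expected)

    # --- covariates ----------------------------------------------------------
    windows = gc_windows(genome, analysis["gc_window_bp"])
    covariate_tables = {
        "gc": cov.bin_by_gc(windows, events, analysis["gc_groups"])
    }
    if inputs.get("oris"):
        ori_table = pd.read_csv(inputs["oris"], sep="\t")
        covariate_tables["replication_time"] = cov.bin_by_replication_time(
            genome, events, ori_table, analysis["replication_groups"]
        )
    if inputs.get("expression"):
        expr = pd.read_csv(inputs["expression"], sep="\t")
        covariate_tables["expression"] = cov.bin_by_expression(
            genome, events, expr, analysis["expression_groups"]
        )

    # --- enrichment and QC ---------------------------------------------------
    enrichment_results = {}
    chromosome_tests = {}
    if inputs.get("annotation"):
        fmap = load_annotation(inputs["annotation"], genome)
        for cls in ("SNM", "insertion", "deletion"):
            cls_events = [e for e in events if e.event_class == cls]
            if cls_events:
                enrichment_results[cls] = enr.feature_enrichment(cls_events, fmap)
    if len(genome.names) >= 2:
        for cls in ("SNM", "insertion"):
            cls_events = [e for e in events if e.event_class == cls]
            if cls_events:
                chromosome_tests[cls] = enr.chromosome_distribution_test(
                    cls_events, genome.chromosome_lengths
                )

    marker_matrix = build_marker_matrix(ancestor_raw, raw_by_line, retained_ids)
    fn_rates = enr.false_negative_rate(marker_matrix) if marker_matrix else {}

    popgen = {}
    pi = design_cfg.get("pi")
    snm_rate = rate_estimates["SNM"].rate
    if pi and snm_rate > 0:
        popgen["ne"] = rt.effective_population_size(pi, snm_rate)

    results = {
        "genome": genome,
        "design": design,
        "retained_lines": retained_ids,
        "contamination": contamination,
        "events": events,
        "summary": summary,
        "rates": rate_estimates,
        "spectrum": spectrum,
        "count_fits": {"poisson": pois_fit, "nb": nb_fit, "comparison": fit_cmp},
        "context": ctx_table,
        "context_significance": ctx_sig,
        "cpg": cpg_summary,
        "covariates": covariate_tables,
        "enrichment": enrichment_results,
        "chromosome_tests": chromosome_tests,
        "false_negative_rates": fn_rates,
        "popgen": popgen,
    }
    _write_outputs(results, config, outdir, seed)
    return results


def build_marker_matrix(ancestor_variants, raw_by_line, retained_ids):
    """Detection matrix of ancestor variants across retained lines.

    Built from pre-subtraction calls: a marker missing from a line's raw
    filtered calls is a false negative.
    """
    if not ancestor_variants:
        return None
    class_of = {}
    for v in ancestor_variants:
        if v.is_snm:
            cls = "SNM"
        elif v.length_change > 0:
            cls = "insertion"
        else:
            cls = "deletion"
        class_of[v.key] = cls
    marker_ids = [f"m{i + 1:04d}" for i in range(len(ancestor_variants))]
    keys = [v.key for v in ancestor_variants]
    det = pd.DataFrame(0, index=marker_ids, columns=retained_ids, dtype=int)
    for line_id in retained_ids:
        present = {v.key for v in raw_by_line[line_id]}
        det[line_id] = [1 if k in present else 0 for k in keys]
    return enr.MarkerMatrix(
        detected=det,
        marker_class=pd.Series([class_of[k] for k in keys], index=marker_ids),
    )


# ----------------------------------------------------------------------------
# serialization
# ----------------------------------------------------------------------------


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _write_outputs(results, config, outdir: Path, seed: int):
    cat.events_to_frame(results["events"]).to_csv(
        outdir / "catalog.tsv", sep="\t", index=False
    )
    results["summary"].to_csv(outdir / "class_counts.tsv", sep="\t")

    rates_json = {}
    for cls, est in results["rates"].items():
        rates_json[cls] = {"count": est.count, "rate": est.rate, "se": est.se,
                           "site_generations": est.site_generations}
    fits = results["count_fits"]
    fits_json = {"comparison": _jsonable(fits["comparison"])}
    for name in ("poisson", "nb"):
        f = fits[name]
        if f is not None:
            fits_json[name] = {"mean": f.mean, "k": f.k, "loglik": f.loglik,
                               "aic": f.aic, "gof_chi2": f.gof_chi2,
                               "gof_df": f.gof_df, "gof_p": f.gof_p}
    spectrum = results["spectrum"]
    spec_rows = [
        {"class": c, "count": spectrum.counts[c],
         "conditional_rate": spectrum.conditional_rates[c]}
        for c in rt.SNM_CLASSES
    ]
    pd.DataFrame(spec_rows).to_csv(outdir / "spectrum.tsv", sep="\t", index=False)

    with open(outdir / "rates.json", "w") as fh:
        json.dump(_jsonable({
            "rates": rates_json,
            "count_fits": fits_json,
            "spectrum_counts": spectrum.counts,
            "ts_tv": rt.ts_tv(spectrum) if spectrum.total_count else None,
            "equilibrium_gc": (
                rt.equilibrium_gc(spectrum) if spectrum.total_count else None
            ),
            "popgen": results["popgen"],
        }), fh, indent=2)

    results["context"].table.to_csv(outdir / "context.tsv", sep="\t")
    for base, table in results["context_significance"].items():
        table.to_csv(outdir / f"context_significance_{base}.tsv", sep="\t")
    for name, table in results["covariates"].items():
        table.bins.to_csv(outdir / f"covariate_{name}_bins.tsv", sep="\t",
                          index=False)
        table.groups.to_csv(outdir / f"covariate_{name}_groups.tsv", sep="\t",
                            index=False)

    qc = {
        "retained_lines": results["retained_lines"],
        "contamination": results["contamination"],
        "false_negative_rates": results["false_negative_rates"],
        "enrichment": {
            cls: [
                {"feature": r.feature, "observed": r.observed,
                 "expected": r.expected, "p": r.p}
                for r in res
            ]
            for cls, res in results["enrichment"].items()
        },
        "chromosome_tests": results["chromosome_tests"],
    }
    if results["cpg"] is not None:
        qc["cpg"] = {"counts": results["cpg"].counts,
                     "proportions": results["cpg"].proportions,
                     "chi2": results["cpg"].chi2, "p": results["cpg"].p,
                     "test": results["cpg"].test}
    with open(outdir / "qc.json", "w") as fh:
        json.dump(_jsonable(qc), fh, indent=2)

    manifest = {
        "seed": seed,
        "config_digest": hashlib.sha256(
            json.dumps(_jsonable(config), sort_keys=True).encode()
        ).hexdigest(),
        "input_digests": {
            k: _digest(Path(v)) for k, v in config["inputs"].items()
            if v and Path(v).is_file()
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    write_report(results, outdir / "report.txt")


def write_report(results, path):
    """Human-readable run summary: class counts, six-class spectrum,
    per-line histogram with fits, and context table highlights."""
    lines = ["MA pipeline report", "=" * 60, ""]
    summary = results["summary"]
    lines.append("Mutation class counts (retained lines):")
    totals = summary.loc["total"]
    for cls in cat.EVENT_CLASSES:
        lines.append(f"  {cls:16s} {int(totals[cls]):6d}")
    lines.append("")
    lines.append("Rates (per base per generation):")
    for cls, est in results["rates"].items():
        lines.append(f"  {cls:16s} {est.rate:.3g} +/- {est.se:.2g}"
                     f"  ({est.count} events)")
    spectrum = results["spectrum"]
    lines.append("")
    lines.append("Six-class SNM spectrum (count, conditional per-site rate):")
    for c in rt.SNM_CLASSES:
        lines.append(f"  {c:10s} {spectrum.counts[c]:5d}"
                     f"  {spectrum.conditional_rates[c]:.3g}")
    if spectrum.total_count:
        lines.append(f"  Ts/Tv = {rt.ts_tv(spectrum):.3f};"
                     f" equilibrium G/C = {100 * rt.equilibrium_gc(spectrum):.2f}%")
    fits = results["count_fits"]
    if fits["poisson"] is not None:
        counts = summary.drop(index="total")["SNM"]
        lines.append("")
        lines.append("Per-line SNM histogram:")
        hist = counts.value_counts().sort_index()
        for k, n in hist.items():
            lines.append(f"  {int(k):3d} SNMs: {'#' * int(n)} ({int(n)})")
        p = fits["poisson"]
        lines.append(f"  Poisson fit: mean {p.mean:.2f}, AIC {p.aic:.2f},"
                     f" GOF p {p.gof_p:.3g}")
        if fits["nb"] is not None:
            nb = fits["nb"]
            lines.append(f"  NB fit: mean {nb.mean:.2f}, k {nb.k:.2f},"
                         f" AIC {nb.aic:.2f}, GOF p {nb.gof_p:.3g}")
            lines.append(f"  best model: {fits['comparison']['best']}")
    ctx_t = results["context"].table
    lines.append("")
    lines.append("Trinucleotide context relative rates (top 5):")
    top = ctx_t.sort_values("relative_rate", ascending=False).head(5)
    for rep, row in top.iterrows():
        lines.append(f"  {row['label']}: {row['relative_rate']:.2f}"
                     f" ({int(row['count'])} SNMs / {int(row['sites'])} sites)")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return path
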