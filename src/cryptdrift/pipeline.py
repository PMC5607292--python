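"""End-to-end orchestration: simulate -> process -> analyze.

Each stage reads and writes plain TSV/FASTQ/YAML artifacts, so a run can be
restarted per stage from saved intermediates.  Every output directory gets
a ``run_config.yaml`` with the fully expanded parameters, the seed, package
version, and SHA-256 checksums of the inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .amplicon import build_amplicon_spec, convert_reference
from .readproc import AlignParams, process_reads, read_fastq
from . import tags, stats
from .simulate import (AssayParams, CohortDesign, NicheParams, simulate_cohort,
                       trial_polyp_table)

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_provenance(outdir: Path, stage: str, seed, params: dict,
                      inputs: dict[str, Path] | None = None) -> None:
    prov = {
        "stage": stage,
        "cryptdrift_version": __version__,
        "seed": seed,
        "params": json.loads(json.dumps(params, default=str)),
        "input_checksums": {k: _sha256(Path(v)) for k, v in (inputs or {}).items()
                            if Path(v).exists()},
    }
    with open(outdir / "run_config.yaml", "w") as fh:
        yaml.safe_dump(prov, fh, sort_keys=False)


def quick_design() -> CohortDesign:
    """Small smoke-test design: 2 patients per group, 2 crypts each,
    shallow sequencing."""
    return CohortDesign(
        n_patients_per_group=2, n_crypts_per_patient=2,
        assay=AssayParams(depth_meanlog=np.log(300.0), depth_sdlog=0.4,
                          depth_min=50, depth_max=2000),
    )


def design_from_config(config: str | Path | dict) -> CohortDesign:
    """Build a :class:`CohortDesign` from a YAML file or mapping; keys
    mirror the dataclass fields, with ``niche`` and ``assay`` sub-maps."""
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = dict(config or {})
    niche = NicheParams(**cfg.pop("niche", {}))
    assay = AssayParams(**cfg.pop("assay", {}))
    for key in ("timepoints_years", "timepoint_labels"):
        if key in cfg:
            cfg[key] = tuple(cfg[key])
    return CohortDesign(niche=niche, assay=assay, **cfg)


def run_simulate(outdir: str | Path, seed: int = 0,
                 design: CohortDesign | None = None,
                 quick: bool = False,
                 config: str | Path | dict | None = None) -> Path:
    """Write a full synthetic dataset (FASTQ + sample sheet + polyps +
    truth + assay definition) to ``outdir``."""
    outdir = Path(outdir)
    if design is None and config is not None:
        design = design_from_config(config)
    design = design or (quick_design() if quick else CohortDesign())
    data = simulate_cohort(design, seed=seed, outdir=outdir)
    _write_provenance(outdir, "simulate", seed, dataclasses.asdict(design))
    logger.info("simulated %d crypts, %d reads -> %s",
                len(data.truth_crypts), len(data.reads), outdir)
    return outdir


def run_process(
    fastq: str | Path,
    reference: str | Path,
    assay_config: str | Path | dict,
    sample_sheet: str | Path,
    outdir: str | Path,
    cutoff: float = 0.01,
    min_depth: float = 0,
    align_params: AlignParams | None = None,
) -> pd.DataFrame:
    """Demultiplex, align, filter and genotype a FASTQ; write the per-read
    call table, filter ledgers, and the crypt-level table.  Returns the
    crypt table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = build_amplicon_spec(reference, assay_config)
    sheet = pd.read_csv(sample_sheet, sep="\t", comment="#")

    orphans = sorted(set(spec.barcode_map.values()) - set(sheet["sample_id"]))
    if orphans:
        raise ValueError(
            f"samples in barcode map missing from sample sheet: {orphans}")

    ref = convert_reference(spec)
    params = align_params or AlignParams()
    calls, ledger, per_sample = process_reads(read_fastq(fastq), spec, ref, params)
    crypts = tags.crypt_table(calls, sheet, cutoff_fraction=cutoff,
                              min_depth=min_depth or 1000)

    calls.to_csv(outdir / "read_calls.tsv", sep="\t", index=False)
    pd.DataFrame([ledger.as_dict()]).to_csv(outdir / "filter_ledger.tsv",
                                            sep="\t", index=False)
    per_sample.to_csv(outdir / "filter_ledger_per_sample.tsv", sep="\t", index=False)
    crypts.to_csv(outdir / "crypt_table.tsv", sep="\t", index=False)
    _write_provenance(
        outdir, "process", None,
        {"cutoff": cutoff, "min_depth": min_depth,
         "align": dataclasses.asdict(params), "assay": spec.name},
        inputs={"fastq": Path(fastq), "reference": Path(reference),
                "sample_sheet": Path(sample_sheet)},
    )
    logger.info("processed %d reads: %s", ledger.total, ledger.as_dict())
    return crypts


def _percent_column(table: pd.DataFrame, weighting: str) -> str:
    col = {"reads": "percent_methylation_readweighted",
           "patterns": "percent_methylation_patternweighted"}.get(weighting)
    if col is None:
        raise ValueError(f"unknown percent weighting {weighting!r}")
    if col not in table.columns and "percent_methylation" in table.columns:
        col = "percent_methylation"
    return col


def _fit_block(table: pd.DataFrame, time_coding: str,
               percent_weighting: str = "reads") -> dict:
    out: dict = {}
    pct = _percent_column(table, percent_weighting)
    nb = stats.fit_nb_mixed(table, time_coding=time_coding)
    nb_nointer = stats.fit_nb_mixed(table, time_coding=time_coding,
                                    interaction=False)
    lm = stats.fit_linear_mixed(table, time_coding=time_coding, outcome=pct)
    lm_nointer = stats.fit_linear_mixed(table, time_coding=time_coding,
                                        outcome=pct, interaction=False)
    for label, full, red in (("patterns", nb, nb_nointer),
                             ("percent_methylation", lm, lm_nointer)):
        block = {
            "fixed_effects": full.fixed_effects.to_dict("records"),
            "interaction_wald_p": full.interaction_p,
            "interaction_lrt": stats.test_interaction(full, red),
            "random_intercept_variance": full.random_intercept_variance,
        }
        if full.group_means is not None:
            block["group_means"] = full.group_means.to_dict("records")
        if full.rates is not None:
            block["rates"] = full.rates.to_dict("records")
        if full.dispersion is not None:
            block["dispersion_theta"] = full.dispersion
        out[label] = block
    return out


def run_analyze(
    crypt_table: str | Path | pd.DataFrame,
    polyps: str | Path | pd.DataFrame | None = None,
    outdir: str | Path | None = None,
    min_depth_sensitivity: int = 1000,
    ages: pd.DataFrame | None = None,
    time_coding: str = "both",
    percent_weighting: str = "reads",
) -> dict:
    """Trend analysis report: both outcomes x both time codings, interaction
    tests, per-patient trends and correlations, and (when depths are
    available) a >=min_depth sensitivity re-analysis."""
    table = (crypt_table if isinstance(crypt_table, pd.DataFrame)
             else pd.read_csv(crypt_table, sep="\t", comment="#"))
    required = {"crypt_id", "patient_id", "group", "timepoint_label",
                "timepoint_years", "diversity"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"crypt table missing columns: {sorted(missing)}")
    if polyps is not None and not isinstance(polyps, pd.DataFrame):
        polyps = pd.read_csv(polyps, sep="\t", comment="#")

    report: dict = {"n_crypts": int(len(table))}
    enough = table.groupby("group")["patient_id"].nunique().min() >= 2
    codings = {"both": ("categorical", "continuous")}.get(time_coding,
                                                          (time_coding,))
    if enough:
        for coding in codings:
            report[coding] = _fit_block(table, coding, percent_weighting)
    else:
        logger.warning("fewer than 2 patients in a group: mixed fits "
                       "refused; reporting per-patient trends only")
        report["mixed_models"] = "refused: <2 patients per group"

    if polyps is not None:
        trends, corr = stats.per_patient_trends(table, polyps)
        report["patient_trends"] = trends.to_dict("records")
        report["correlations"] = corr

    if ages is not None and enough:
        adj = stats.adjust_for_age(table, ages, model="nb",
                                   time_coding="continuous")
        if adj["adjusted"] is not None:
            report["age_adjusted_rates"] = adj["adjusted"].rates.to_dict("records")

    if "depth" in table.columns and enough:
        deep = tags.depth_sensitivity_filter(table, min_depth_sensitivity)
        report["sensitivity"] = {
            "min_depth": min_depth_sensitivity,
            "retained": int(len(deep)), "total": int(len(table)),
        }
        if (len(deep) and deep.groupby("group")["patient_id"].nunique().min() >= 2
                and deep["timepoint_label"].nunique() == table["timepoint_label"].nunique()):
            report["sensitivity"]["continuous"] = _fit_block(
                deep, "continuous", percent_weighting)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
        if "patient_trends" in report:
            pd.DataFrame(report["patient_trends"]).to_csv(
                outdir / "patient_trends.tsv", sep="\t", index=False)
        _write_provenance(outdir, "analyze", None,
                          {"min_depth_sensitivity": min_depth_sensitivity})
    return report


def format_report(report: dict) -> str:
    """Compact human-readable trial-style summary of an analyze report."""
    lines = [f"crypts analyzed: {report.get('n_crypts')}"]
    cat = report.get("categorical", {})
    cont = report.get("continuous", {})
    for outcome, title in (("patterns", "methylation patterns (diversity)"),
                           ("percent_methylation", "percent methylation")):
        if outcome not in cat:
            continue
        lines.append(f"\n== {title} ==")
        for row in cat[outcome].get("group_means", []):
            lines.append(
                f"  {row['group']:<9s} {row['timepoint_label']:<4s} "
                f"mean {row['mean']:6.2f}  (95% CI {row['ci_low']:.2f}-{row['ci_high']:.2f})")
        for row in cont.get(outcome, {}).get("rates", []):
            key = "rate_per_year" if "rate_per_year" in row else "change_per_year"
            lines.append(
                f"  {row['group']:<9s} {key.replace('_', ' ')}: {row[key]:6.2f}  "
                f"(95% CI {row['ci_low']:.2f}-{row['ci_high']:.2f}; p={row['p']:.3f})")
        ip = cont.get(outcome, {}).get("interaction_wald_p")
        if ip is not None:
            lines.append(f"  treatment x time interaction p = {ip:.3f}")
    if "sensitivity" in report:
        s = report["sensitivity"]
        lines.append(f"\nsensitivity >= {s['min_depth']}x: retained "
                     f"{s['retained']} of {s['total']} crypts")
    if "correlations" in report:
        lines.append("\nper-patient correlations (Pearson):")
        for k, v in report["correlations"].items():
            a, b = k.split("__vs__")
            lines.append(f"  {a} vs {b}: r = {v['r']:.2f} (n={v['n']})")
    return "\n".join(lines)


def run_demo(outdir: str | Path, seed: int = 0) -> dict:
    """No-download end-to-end demonstration on the quick design; prints a
    trial-style report."""
    outdir = Path(outdir)
    sim_dir = outdir / "sim"
    run_simulate(sim_dir, seed=seed, quick=True)
    crypts = run_process(
        sim_dir / "reads.fastq.gz", sim_dir / "reference.fasta",
        sim_dir / "assay.yaml", sim_dir / "sample_sheet.tsv",
        outdir / "processed",
    )
    report = run_analyze(crypts, sim_dir / "polyps.tsv", outdir / "analysis")
    print(format_report(report))
    return report
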