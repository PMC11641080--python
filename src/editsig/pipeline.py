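"""End-to-end orchestration: simulate -> quantify -> select -> TEI ->
signatures -> random forest -> Monte-Carlo augmentation, plus cohort
summaries, all seeded and written as TSV stage outputs with a
machine-readable manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .augment import (
    estimate_prediction_error,
    fit_generator,
    sample_synthetic,
    validate_synthetic,
)
from .constants import DIAGNOSES, TREATMENT_CLASSES
from .panel import write_bed
from .quant import (
    QCConfig,
    build_biomarker_matrix,
    call_site_editing,
    isoforms_from_pattern_counts,
    normalize_by_global_editing,
    pattern_counts_table,
    _counts_from_readsets,
)
from .rf import (
    RFConfig,
    encode_covariates,
    evaluate_multiclass,
    feature_importance,
    predict_votes,
    predicted_classes,
    stratified_split,
    train_rf,
)
from .select import FeatureSelectionConfig, select_features
from .signature import run_all_comparisons, signature_coordinates
from .synthetic import SyntheticCohortSpec, generate_cohort, generate_reads, spec_from_table1
from .tei import compute_tei, tei_group_tests

logger = logging.getLogger(__name__)

_pkg_version = "0.1.0"

ALL_STAGES = ("simulate", "quantify", "select", "tei", "signature", "rf", "augment", "summary")


def _round1(x: float) -> float:
    """Round to one decimal, half away from zero."""
    return math.floor(abs(x) * 10 + 0.5) / 10 * (1 if x >= 0 else -1)


@dataclass
class Table1Report:
    """Cohort characteristics per group with an overall column.

    ``table`` rows: n, age_mean, age_sd, male_n, male_pct, female_n,
    female_pct and per-treatment counts/percentages; columns: one per
    group plus 'Total'.  Percentages are recomputed from counts to one
    decimal (half away from zero).
    """

    table: pd.DataFrame

    def cell(self, row: str, col: str) -> float:
        return self.table.loc[row, col]


def _summary_from_counts(per_group: dict[str, dict]) -> Table1Report:
    groups = list(per_group)
    total_n = sum(g["n"] for g in per_group.values())
    cols = {}
    for name, g in per_group.items():
        col = {"n": g["n"], "age_mean": _round1(g["age_mean"]), "age_sd": _round1(g["age_sd"])}
        col["male_n"] = g["male_n"]
        col["male_pct"] = _round1(100 * g["male_n"] / g["n"]) if g["n"] else np.nan
        col["female_n"] = g["n"] - g["male_n"]
        col["female_pct"] = _round1(100 * col["female_n"] / g["n"]) if g["n"] else np.nan
        for t in TREATMENT_CLASSES:
            col[f"{t}_n"] = g[t]
            col[f"{t}_pct"] = _round1(100 * g[t] / g["n"]) if g["n"] else np.nan
        cols[name] = col
    # overall column: counts are sums, mean age is size-weighted,
    # overall SD combines within- and between-group sums of squares
    overall = {"n": total_n}
    wmean = sum(g["n"] * g["age_mean"] for g in per_group.values()) / total_n
    ss_w = sum((g["n"] - 1) * g["age_sd"] ** 2 for g in per_group.values())
    ss_b = sum(g["n"] * (g["age_mean"] - wmean) ** 2 for g in per_group.values())
    overall["age_mean"] = _round1(wmean)
    overall["age_sd"] = _round1(math.sqrt((ss_w + ss_b) / (total_n - 1))) if total_n > 1 else np.nan
    male_total = sum(g["male_n"] for g in per_group.values())
    overall["male_n"] = male_total
    overall["male_pct"] = _round1(100 * male_total / total_n)
    overall["female_n"] = total_n - male_total
    overall["female_pct"] = _round1(100 * (total_n - male_total) / total_n)
    for t in TREATMENT_CLASSES:
        tn = sum(g[t] for g in per_group.values())
        overall[f"{t}_n"] = tn
        overall[f"{t}_pct"] = _round1(100 * tn / total_n)
    cols["Total"] = overall
    table = pd.DataFrame(cols)
    return Table1Report(table)


def cohort_summary(cohort) -> Table1Report:
    """Demographic/clinical summary table with an overall column.

    Accepts either a per-sample cohort table (columns diagnosis, sex,
    age, treatment flags) or a per-group summary DataFrame indexed by
    group with columns (n, age_mean, age_sd, male_n, <treatment>_n).
    With group summaries, the overall age mean is the size-weighted
    average of group means.
    """
    if isinstance(cohort, pd.DataFrame) and "diagnosis" in cohort.columns:
        if cohort.empty:
            raise ValueError("empty cohort")
        per_group = {}
        order = [d for d in DIAGNOSES if d in set(cohort["diagnosis"])] + [
            d for d in cohort["diagnosis"].unique() if d not in DIAGNOSES
        ]
        for diag in order:
            sub = cohort[cohort["diagnosis"] == diag]
            if sub.empty:
                logger.warning("group %s empty; omitted from summary", diag)
                continue
            per_group[diag] = {
                "n": len(sub),
                "age_mean": float(sub["age"].mean()),
                "age_sd": float(sub["age"].std(ddof=1)) if len(sub) > 1 else 0.0,
                "male_n": int((sub["sex"] == "M").sum()),
                **{t: int(sub[t].sum()) for t in TREATMENT_CLASSES},
            }
        return _summary_from_counts(per_group)
    if isinstance(cohort, pd.DataFrame):
        per_group = {}
        for name, row in cohort.iterrows():
            per_group[name] = {
                "n": int(row["n"]),
                "age_mean": float(row["age_mean"]),
                "age_sd": float(row.get("age_sd", 0.0)),
                "male_n": int(row["male_n"]),
                **{t: int(row.get(f"{t}_n", 0)) for t in TREATMENT_CLASSES},
            }
        return _summary_from_counts(per_group)
    raise TypeError("cohort must be a per-sample or per-group DataFrame")


@dataclass
class PipelineConfig:
    """Everything one run needs: spec, stage configs, outdir, seed.

    The global seed is propagated to every stochastic stage with fixed
    offsets, so identical config+seed reruns are byte-identical.
    """

    spec: SyntheticCohortSpec = None
    qc: QCConfig = field(default_factory=QCConfig)
    fs: FeatureSelectionConfig = field(default_factory=FeatureSelectionConfig)
    rf: RFConfig = field(default_factory=RFConfig)
    mc_points: int = 500
    tei_reference: str = "CTRL"
    stages: tuple = ALL_STAGES
    outdir: str | Path = "editsig_run"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spec is None:
            self.spec = spec_from_table1(seed=self.seed)
        else:
            self.spec = self.spec.with_seed(self.seed)
        self.fs = replace(self.fs, seed=self.seed + 1)
        self.rf = replace(self.rf, seed=self.seed + 2)

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "PipelineConfig":
        """Build a config from a nested key/value YAML file."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        spec_kw = raw.get("spec", {})
        spec = spec_from_table1(**spec_kw) if spec_kw or "spec" in raw else None
        return cls(
            spec=spec,
            qc=QCConfig(**raw.get("qc", {})),
            fs=FeatureSelectionConfig(**raw.get("select", {})),
            rf=RFConfig(**raw.get("rf", {})),
            mc_points=raw.get("mc_points", 500),
            tei_reference=raw.get("tei_reference", "CTRL"),
            stages=tuple(raw.get("stages", ALL_STAGES)),
            outdir=raw.get("outdir", "editsig_run"),
            seed=seed if seed is not None else raw.get("seed", 0),
        )


def _write(df: pd.DataFrame, path: Path, **kw) -> Path:
    df.to_csv(path, sep="\t", float_format="%.6g", **kw)
    return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and write per-stage TSV outputs.

    Returns a run report (also written as ``manifest.json``) with the
    chosen parameters, headline numbers and output file hashes.  A
    stage failure aborts with the stage name; outputs of completed
    stages remain on disk.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "log.txt"
    log_lines: list[str] = []

    def log(msg: str) -> None:
        line = f"{time.strftime('%Y-%m-%d %H:%M:%S')} {msg}"
        log_lines.append(line)
        logger.info(msg)

    report: dict = {
        "package_version": _pkg_version,
        "seed": config.seed,
        "stages": list(config.stages),
        "outputs": {},
        "numbers": {},
    }
    artifacts: dict[str, Path] = {}
    stage = "init"
    try:
        spec = config.spec
        panel = spec.site_panel

        stage = "simulate"
        if stage in config.stages:
            log("simulate: generating synthetic cohort and reads")
            matrix, cohort, latent = generate_cohort(spec, return_latent=True)
            counts_frames, pattern_frames = [], []
            for i, sample in enumerate(latent.index):
                rs = generate_reads(
                    spec, latent.loc[sample], sample_id=sample,
                    seed=spec.seed + 10_000 + i,
                )
                counts_frames.append(_counts_from_readsets([rs], panel))
                pattern_frames.append(pattern_counts_table([rs], panel))
            counts = pd.concat(counts_frames, ignore_index=True)
            patterns = pd.concat(pattern_frames, ignore_index=True)
            artifacts["cohort"] = _write(cohort, out / "cohort.tsv")
            write_bed(panel, out / "panel.bed")
            artifacts["panel"] = out / "panel.bed"
            artifacts["site_counts"] = _write(counts, out / "site_counts.tsv", index=False)
            artifacts["pattern_counts"] = _write(patterns, out / "pattern_counts.tsv", index=False)
        else:
            raise ValueError("pipeline currently requires the simulate stage")

        stage = "quantify"
        if stage in config.stages:
            log("quantify: computing editing values and biomarker matrix")
            sites = call_site_editing(counts, panel, config.qc)
            isoforms = {
                g: isoforms_from_pattern_counts(patterns, g, len(panel.gene_sites(g)))
                for g in panel.genes
            }
            motifs = {
                f"{g}_all": (g, list(panel.gene_sites(g)["site"])) for g in panel.genes
            }
            bmatrix = build_biomarker_matrix(sites, isoforms, config.qc, motifs)
            artifacts["site_editing"] = _write(sites.table, out / "site_editing.tsv", index=False)
            artifacts["biomarkers"] = _write(
                bmatrix.values, out / "biomarker_matrix.tsv", index_label="sample"
            )
            report["numbers"]["n_biomarkers"] = int(bmatrix.values.shape[1])
            report["numbers"]["n_background_dropped"] = len(bmatrix.dropped)

        labels = cohort["diagnosis"]

        stage = "select"
        if stage in config.stages:
            log("select: differential testing, correlation pruning, Boruta")
            sel = select_features(bmatrix, labels, config.fs)
            artifacts["selection"] = _write(
                sel.report.assign(gene=bmatrix.meta["gene"]), out / "selection_report.tsv"
            )
            report["numbers"]["n_selected"] = len(sel.selected)
            if sel.per_gene_counts is not None:
                report["numbers"]["selected_per_gene"] = sel.per_gene_counts.to_dict()
            selected = sel.selected

        stage = "tei"
        if stage in config.stages:
            log("tei: per-gene Target Editing Index and group tests")
            by_gene: dict[str, list] = {}
            for f in selected:
                by_gene.setdefault(bmatrix.meta.loc[f, "gene"], []).append(f)
            tei_res = compute_tei(bmatrix, labels, by_gene, config.tei_reference)
            tests = tei_group_tests(tei_res.tei, labels, config.fs.fdr_cutoff)
            artifacts["tei"] = _write(tei_res.tei, out / "tei.tsv", index_label="sample")
            artifacts["tei_tests"] = _write(tests, out / "tei_tests.tsv", index=False)
            report["numbers"]["tei_significant"] = int(tests["significant"].sum())

        stage = "signature"
        if stage in config.stages:
            log("signature: mROC virtual markers Z1..Z6")
            normalized = normalize_by_global_editing(bmatrix.subset(selected), sites)
            sigs, rocs, table = run_all_comparisons(normalized.values, labels)
            artifacts["signature_table"] = _write(table, out / "signature_table.tsv", index=False)
            zscores = pd.DataFrame({k: s.z for k, s in sigs.items()})
            artifacts["signature_scores"] = _write(
                zscores, out / "signature_scores.tsv", index_label="sample"
            )
            for trip, fname in ((("Z1", "Z2", "Z3"), "coords_z123.tsv"),
                                (("Z4", "Z5", "Z6"), "coords_z456.tsv")):
                if all(t in sigs for t in trip):
                    artifacts[fname] = _write(
                        signature_coordinates(sigs, trip), out / fname, index_label="sample"
                    )
            coefs = pd.DataFrame({k: s.coefficients for k, s in sigs.items()})
            artifacts["signature_coefficients"] = _write(
                coefs, out / "signature_coefficients.tsv", index_label="biomarker"
            )
            report["numbers"]["signature_auc"] = {
                k: round(r.auc, 4) for k, r in rocs.items()
            }

        stage = "rf"
        if stage in config.stages:
            log("rf: stratified split, OOB-tuned multiclass forest")
            covs = encode_covariates(cohort)
            rf_features = bmatrix.values[selected].join(covs)
            train_ids, test_ids = stratified_split(
                labels, config.rf.train_fraction, config.rf.seed
            )
            model = train_rf(rf_features.loc[train_ids], labels.loc[train_ids], config.rf)
            votes = predict_votes(model, rf_features.loc[test_ids])
            pred = predicted_classes(votes)
            conf, acc, sesp = evaluate_multiclass(pred, labels.loc[test_ids])
            imp = feature_importance(
                model, rf_features.loc[test_ids], labels.loc[test_ids], seed=config.rf.seed
            )
            artifacts["rf_votes"] = _write(votes, out / "rf_votes.tsv", index_label="sample")
            artifacts["rf_confusion"] = _write(conf, out / "rf_confusion.tsv")
            artifacts["rf_class_metrics"] = _write(sesp, out / "rf_class_metrics.tsv")
            artifacts["rf_importance"] = _write(imp, out / "rf_importance.tsv")
            report["numbers"]["rf_chosen_mtry"] = model.chosen_mtry
            report["numbers"]["rf_oob_accuracy"] = round(model.oob_accuracy[model.chosen_mtry], 4)
            report["numbers"]["rf_test_accuracy"] = round(acc, 4)
            report["numbers"]["rf_train_n"] = len(train_ids)
            report["numbers"]["rf_test_n"] = len(test_ids)

        stage = "augment"
        if stage in config.stages:
            log("augment: Monte-Carlo synthetic points and fidelity check")
            gen = fit_generator(bmatrix.values[selected], cohort, seed=config.seed + 3)
            syn_matrix, syn_cohort = sample_synthetic(gen, config.mc_points)
            fidelity = validate_synthetic(
                bmatrix.values[selected], labels, syn_matrix, syn_cohort["diagnosis"]
            )
            syn_out = syn_matrix.join(syn_cohort)
            header = f"# editsig MC synthetic data generator={gen.digest()} seed={config.seed + 3}\n"
            syn_path = out / "mc_synthetic.tsv"
            with open(syn_path, "w") as fh:
                fh.write(header)
                syn_out.to_csv(fh, sep="\t", float_format="%.6g", index_label="sample")
            artifacts["mc_synthetic"] = syn_path
            artifacts["mc_fidelity"] = _write(fidelity, out / "mc_fidelity.tsv", index=False)
            report["numbers"]["mc_fidelity_pass_rate"] = round(float(fidelity["pass"].mean()), 4)
            if "rf" in config.stages:
                err = estimate_prediction_error(model, syn_matrix, syn_cohort)
                artifacts["mc_prediction_error"] = _write(err, out / "mc_prediction_error.tsv")
                report["numbers"]["mc_error_overall"] = round(float(err.loc["overall", "error"]), 4)

        stage = "summary"
        if stage in config.stages:
            log("summary: cohort characteristics table")
            t1 = cohort_summary(cohort)
            artifacts["table1"] = _write(t1.table, out / "table1.tsv")

        report["outputs"] = {k: {"file": p.name, "sha256": _sha256(p)} for k, p in artifacts.items()}
        (out / "manifest.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        log("pipeline complete")
        log_path.write_text("\n".join(log_lines) + "\n")
        return report
    except Exception as exc:
        log_path.write_text("\n".join(log_lines) + f"\nFAILED at stage {stage}: {exc}\n")
        raise RuntimeError(
            f"pipeline failed at stage {stage!r}; completed artifacts: "
            f"{[str(p) for p in artifacts.values()]}"
        ) from exc
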