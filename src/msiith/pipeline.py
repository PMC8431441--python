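"""End-to-end orchestration: simulate/import -> preprocess -> components ->
segment -> heterogeneity -> stats -> annotate, with provenance-stamped
artifacts so any stage can be resumed from the previous stage's outputs."""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

from . import __version__
from .annotate import (
    decoy_match_rate,
    match_components,
    read_peptide_library,
    summarize_proteins,
    write_peptide_library,
)
from .components import (
    compute_feature_matrix,
    fit_gmm_components,
    read_components_csv,
    read_feature_matrix,
    write_components_csv,
    write_feature_matrix,
)
from .datatypes import CohortDataset, PipelineConfig
from .divik import divik
from .io import read_cohort, write_cohort
from .metrics import roi_profiles, roi_size_cluster_correlation
from .preprocess import mean_spectrum, preprocess_cohort
from .stats import (
    classify_effect_size,
    cluster_contribution,
    correlate_tils,
    screen_components,
    wilcoxon_rank_sum,
)
from .synth import CohortConfig, generate_cohort, generate_peptide_library

logger = logging.getLogger("msiith")

STAGES = [
    "input",
    "preprocess",
    "components",
    "segment",
    "heterogeneity",
    "stats",
    "annotate",
]


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str = __version__
    timings: Dict[str, float] = field(default_factory=dict)
    digests: Dict[str, str] = field(default_factory=dict)

    def record(self, path: Path) -> None:
        h = hashlib.sha256()
        with open(path, "rb") as fh:
            for chunk in iter(lambda: fh.read(1 << 20), b""):
                h.update(chunk)
        self.digests[path.name] = h.hexdigest()

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config": self.config,
                    "seed": self.seed,
                    "version": self.version,
                    "timings": self.timings,
                    "digests": self.digests,
                },
                fh,
                indent=2,
                sort_keys=True,
            )


def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, float):
        return f"{x:.10g}"
    return str(x)


def _write_csv(path: Path, header: List[str], rows: List[List]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for row in rows:
            w.writerow([_fmt(v) for v in row])


def run_pipeline(
    config: PipelineConfig,
    input: str = "simulate",
    out_dir: str = "msiith_run",
    cohort_config: Optional[CohortConfig] = None,
    input_format: str = "internal",
    resume: bool = False,
    stop_after: Optional[str] = None,
) -> RunManifest:
    """Execute the full analysis flow and write one artifact set per stage.

    ``input`` is either the literal ``"simulate"`` (the synthetic cohort
    generator provides the data, seeded from ``config.seed``) or a cohort
    path.  With ``resume=True``, stages whose artifacts already exist are
    loaded instead of recomputed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), seed=config.seed)
    t_all = time.time()

    def _finish() -> RunManifest:
        manifest.timings["total"] = time.time() - t_all
        for p in sorted(out.iterdir()):
            if p.is_file() and p.name != "manifest.json":
                manifest.record(p)
        manifest.save(out / "manifest.json")
        return manifest

    def timed(stage):
        def deco(fn):
            def wrapper():
                t0 = time.time()
                try:
                    result = fn()
                except Exception as exc:
                    raise RuntimeError(
                        f"pipeline stage {stage!r} failed: {exc}"
                    ) from exc
                manifest.timings[stage] = time.time() - t0
                return result

            return wrapper

        return deco

    # ---- stage: input -----------------------------------------------------
    cohort_path = out / "cohort.h5"
    library_path = out / "peptide_library.csv"
    truth = None

    @timed("input")
    def stage_input():
        nonlocal truth
        if resume and cohort_path.exists():
            return read_cohort(cohort_path)
        if input == "simulate":
            cfg = cohort_config or CohortConfig(seed=config.seed)
            cohort, truth_ = generate_cohort(cfg)
            truth = truth_
            write_cohort(cohort, cohort_path, overwrite=True)
            library = generate_peptide_library(truth_, decoy_fraction=0.2, seed=cfg.seed)
            write_peptide_library(library, library_path)
            _write_truth_tables(truth_, out)
            return cohort
        cohort = read_cohort(input, format=input_format)
        write_cohort(cohort, cohort_path, overwrite=True)
        return cohort

    cohort = stage_input()
    if stop_after == "input":
        return _finish()
    roi_patient = {r.roi_id: r.patient_id for r in cohort.rois}
    outcome_by_patient = {m.patient_id: m.outcome for m in cohort.metadata}
    roi_outcome = {rid: outcome_by_patient[pid] for rid, pid in roi_patient.items()}

    # ---- stage: preprocess ------------------------------------------------
    processed_path = out / "processed.h5"
    qc_path = out / "qc_report.csv"

    @timed("preprocess")
    def stage_preprocess():
        if resume and processed_path.exists():
            return read_cohort(processed_path)
        processed, qc = preprocess_cohort(cohort, config.preprocessing)
        write_cohort(processed, processed_path, overwrite=True)
        rows = qc.to_rows()
        _write_csv(
            qc_path,
            list(rows[0].keys()) if rows else ["roi_id"],
            [list(r.values()) for r in rows],
        )
        return processed

    processed = stage_preprocess()
    if stop_after == "preprocess":
        return _finish()

    # ---- stage: components ------------------------------------------------
    components_path = out / "components.csv"
    features_path = out / "features.h5"

    @timed("components")
    def stage_components():
        if resume and components_path.exists() and features_path.exists():
            return read_feature_matrix(features_path)
        mean = mean_spectrum(processed)
        comps = fit_gmm_components(mean, processed.axis, config.components, seed=config.seed)
        write_components_csv(comps, components_path)
        fm = compute_feature_matrix(processed, comps)
        write_feature_matrix(fm, features_path)
        return fm

    features = stage_components()
    if stop_after == "components":
        return _finish()

    # ---- stage: segment ---------------------------------------------------
    labels_path = out / "labels.csv"
    tree_path = out / "tree_summary.json"

    @timed("segment")
    def stage_segment():
        params = config.divik
        params.seed = config.seed
        tree = divik(features, params)
        tree.save_summary(tree_path)
        levels = {lv: tree.labels_at_level(lv) for lv in range(1, params.max_depth + 1)}
        header = ["roi_id", "x", "y"] + [f"level{lv}" for lv in levels]
        rows = []
        for i in range(features.n_pixels):
            rows.append(
                [features.roi_ids[i], features.coordinates[i, 0], features.coordinates[i, 1]]
                + [levels[lv].labels[i] for lv in levels]
            )
        _write_csv(labels_path, header, rows)
        return tree

    tree = stage_segment()
    if stop_after == "segment":
        return _finish()

    # ---- stage: heterogeneity --------------------------------------------
    profiles_path = out / "heterogeneity_profiles.csv"
    ecdf_path = out / "similarity_ecdf.csv"

    @timed("heterogeneity")
    def stage_heterogeneity():
        profs = roi_profiles(processed, tree, features, config.metrics)
        levels = sorted(profs[0].cluster_counts) if profs else []
        header = ["roi_id", "patient_id", "outcome", "n_pixels", "similarity_median"]
        header += [f"k_level{lv}" for lv in levels] + [f"simpson_level{lv}" for lv in levels]
        rows = []
        for p in profs:
            rows.append(
                [p.roi_id, roi_patient[p.roi_id], roi_outcome[p.roi_id], p.n_pixels,
                 p.similarity_median]
                + [p.cluster_counts[lv] for lv in levels]
                + [p.simpson[lv] for lv in levels]
            )
        _write_csv(profiles_path, header, rows)
        from .metrics import pairwise_similarity

        ecdf_rows = []
        for p in profs:
            rows_idx = features.rows_of(p.roi_id)
            if rows_idx.size < 2:
                continue
            sim = pairwise_similarity(
                features.values[rows_idx], roi_id=p.roi_id,
                max_pairs=min(config.metrics.max_pairs, 2000), seed=config.seed,
                measure=config.metrics.similarity,
            )
            step = max(1, sim.ecdf.shape[0] // 200)
            for s, q in sim.ecdf[::step]:
                ecdf_rows.append([p.roi_id, s, q])
        _write_csv(ecdf_path, ["roi_id", "similarity", "cum_prob"], ecdf_rows)
        return profs

    profiles = stage_heterogeneity()
    if stop_after == "heterogeneity":
        return _finish()

    # ---- stage: stats -----------------------------------------------------
    @timed("stats")
    def stage_stats():
        level1 = tree.labels_at_level(1)
        roi_labels = {
            rid: level1.labels[features.rows_of(rid)] for rid in roi_patient
            if features.rows_of(rid).size
        }
        # group tests on per-ROI heterogeneity metrics
        test_rows = []
        for lv in sorted(profiles[0].cluster_counts) if profiles else []:
            for metric, get in (
                (f"k_level{lv}", lambda p, lv=lv: p.cluster_counts[lv]),
                (f"simpson_level{lv}", lambda p, lv=lv: p.simpson[lv]),
            ):
                nd = [get(p) for p in profiles if roi_outcome[p.roi_id] == "ND"]
                pd_ = [get(p) for p in profiles if roi_outcome[p.roi_id] == "PD"]
                if not nd or not pd_:
                    continue
                t = wilcoxon_rank_sum(nd, pd_, mode=config.stats.wilcoxon_mode)
                test_rows.append(
                    [metric, "ND_vs_PD", t.test_name, t.statistic, t.p_value,
                     t.effect_size, t.effect_kind, t.group_sizes[0], t.group_sizes[1]]
                )
        _write_csv(
            out / "group_tests.csv",
            ["metric", "contrast", "test", "statistic", "p_value",
             "effect_size", "effect_kind", "n_nd", "n_pd"],
            test_rows,
        )

        # cluster contributions: every level-1 cluster, ND vs PD
        clusters = sorted(set(level1.labels))
        contrib_rows = []
        best_cluster, best_p = None, np.inf
        for cl in clusters:
            fracs, test = cluster_contribution(roi_labels, cl, roi_outcome)
            for rid in sorted(fracs):
                contrib_rows.append([cl, rid, roi_outcome[rid], fracs[rid], test.p_value])
            if test.p_value < best_p:
                best_p, best_cluster = test.p_value, cl
        _write_csv(
            out / "cluster_contributions.csv",
            ["cluster", "roi_id", "outcome", "fraction", "nd_vs_pd_p"],
            contrib_rows,
        )

        # component screening against the most outcome-associated cluster
        outcome_per_pixel = np.array(
            [roi_outcome[r] for r in features.roi_ids], dtype=object
        )
        screening = screen_components(
            features, level1, best_cluster, outcome_per_pixel,
            d_cluster_min=config.stats.d_cluster_min,
            d_outcome_min=config.stats.d_outcome_min,
        )
        d_rows = []
        for comp, dc, do in zip(features.components, screening.d_cluster, screening.d_outcome):
            d_rows.append(
                [comp.component_id, comp.center, dc, classify_effect_size(dc),
                 do, classify_effect_size(do),
                 int(comp.component_id in set(screening.selected))]
            )
        _write_csv(
            out / "effect_sizes.csv",
            ["component_id", "center_mz", "d_cluster_vs_rest", "class_cluster",
             "d_nd_vs_pd", "class_outcome", "selected"],
            d_rows,
        )
        _write_csv(
            out / "screening.csv",
            ["component_id", "target_cluster", "d_cluster_min", "d_outcome_min"],
            [[cid, screening.target_cluster, screening.d_cluster_min,
              screening.d_outcome_min] for cid in screening.selected],
        )

        # ROI size vs cluster count, and TILs correlation when available
        extra_rows = []
        if len(profiles) >= 3:
            rc = roi_size_cluster_correlation(profiles, level=1)
            extra_rows.append(["roi_size_vs_k1_spearman", rc.rho, rc.p_value, rc.n])
        try:
            tr = correlate_tils(profiles, cohort.metadata, level=1, roi_patient=roi_patient)
            extra_rows.append(["tils_vs_simpson1_pearson", tr.r, tr.p_value, tr.n])
            if tr.group_d is not None:
                extra_rows.append(["tils_nd_vs_pd_cohens_d", tr.group_d, "", tr.n])
        except ValueError as exc:
            logger.info("TILs correlation skipped: %s", exc)
        _write_csv(out / "correlations.csv", ["name", "value", "p_value", "n"], extra_rows)
        return screening

    screening = stage_stats()
    if stop_after == "stats":
        return _finish()

    # ---- stage: annotate --------------------------------------------------
    @timed("annotate")
    def stage_annotate():
        if not library_path.exists():
            logger.info("no peptide library; annotation skipped")
            return None
        library = read_peptide_library(library_path)
        comps = read_components_csv(components_path)
        matches = match_components(
            comps, library,
            tolerance=config.annotation.tolerance,
            charge_convention=config.annotation.charge_convention,
        )
        _write_csv(
            out / "component_matches.csv",
            ["component_id", "component_center", "peptide_id", "expected_mz",
             "relative_error", "protein_accession", "is_decoy"],
            [[m.component_id, m.component_center, m.peptide_id, m.expected_mz,
              m.relative_error, m.protein_accession, int(m.is_decoy)] for m in matches],
        )
        summary = summarize_proteins(matches, restrict_to=set(screening.selected))
        _write_csv(
            out / "protein_summary.csv",
            ["protein_accession", "n_components", "component_ids"],
            [[s.protein_accession, s.n_components,
              ";".join(map(str, s.component_ids))] for s in summary],
        )
        _write_csv(
            out / "annotation_qc.csv",
            ["decoy_match_rate"], [[decoy_match_rate(matches)]],
        )
        return summary

    stage_annotate()

    return _finish()


def _write_truth_tables(truth, out: Path) -> None:
    _write_csv(
        out / "truth_peaks.csv",
        ["peak_id", "center", "sigma", "base_amplitude", "region_modulated", "group_modulated"],
        [
            [i, truth.peak_centers[i], truth.peak_sigmas[i], truth.base_amplitudes[i],
             int(truth.modulated_mask[i]), int(truth.group_mask[i])]
            for i in range(truth.n_peaks)
        ],
    )
    rows = []
    for rid in sorted(truth.region_labels):
        labels = truth.region_labels[rid]
        for i, lab in enumerate(labels):
            rows.append([rid, i, lab, truth.pixel_gain[rid][i],
                         truth.pixel_shift[rid][i], int(truth.outlier_flags[rid][i])])
    _write_csv(
        out / "truth_pixels.csv",
        ["roi_id", "pixel_index", "region_label", "gain", "shift", "outlier"],
        rows,
    )
    _write_csv(
        out / "truth_rois.csv",
        ["roi_id", "outcome", "planted_simpson"],
        [[rid, truth.roi_outcome[rid], truth.planted_simpson[rid]]
         for rid in sorted(truth.roi_outcome)],
    )
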