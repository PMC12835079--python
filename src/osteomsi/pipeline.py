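"""End-to-end candidate-discovery / cohort-validation orchestration.

The workflow mirrors a two-stage marker study on osteochondral sections:

1. normalize every section to the spike-in reference peptide;
2. pick the top-N most abundant mean-spectrum features per tissue and
   build pixels x features tables on the union feature set;
3. screen for discriminating features by pixel-level AUROC between a
   diseased-bone region and a healthy-bone region of one representative
   sample pair (site-matched: control medial vs OA medial);
4. validate candidates across the cohort: per-sample guided-ROI mean
   intensities, one-sided paired t-tests (OA medial vs OA lateral) plus
   a descriptive PLS-DA;
5. annotate validated candidates against a peptide spectral library at
   a 2 mDa MS1 tolerance.

In simulate mode the cohort comes from :mod:`osteomsi.synthetic` and the
guided ROIs are the phantom's true region masks — the synthetic stand-in
for histology-guided manual segmentation. In load mode sections are read
from imzML/TSV files and ROIs from polygon TSVs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotation import SpectralLibrary, match_features, read_library_tsv
from .cohort_stats import plsda_scores, roi_mean_intensity, validate_candidates
from .config import PipelineConfig
from .core_data import drop_flagged, normalize_spectra, read_msi
from .discriminant import discriminating_features
from .features import (
    FeatureTable,
    extract_feature_table,
    mean_spectrum,
    merge_feature_sets,
    select_top_n,
    spectrum_peaks,
)
from .segmentation import RegionMask, bisect_segment, roi_from_polygon
from .synthetic import (
    GroundTruth,
    MarkerConfig,
    PhantomSpec,
    default_library,
    simulate_cohort,
)

logger = logging.getLogger("osteomsi")

__all__ = ["RunReport", "run_pipeline", "guided_roi", "load_run_config"]


@dataclass
class RunReport:
    """Summary of one pipeline run: counts, manifest, provenance."""

    config: dict
    seed: int
    version: str
    counts: dict = field(default_factory=dict)
    candidates: list = field(default_factory=list)
    validation: list = field(default_factory=list)
    annotations: list = field(default_factory=list)
    manifest: dict = field(default_factory=dict)   # filename -> sha256
    failure_stage: str | None = None

    def check_consistency(self) -> None:
        c = self.counts
        if c.get("candidates", 0) > c.get("features", 0):
            raise ValueError("more candidates than features")
        if c.get("validated", 0) > c.get("candidates", 0):
            raise ValueError("more validated hits than candidates")

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "seed": self.seed,
                "version": self.version,
                "counts": self.counts,
                "manifest": self.manifest,
                "failure_stage": self.failure_stage,
            },
            indent=2,
            sort_keys=True,
        )


def guided_roi(truth: GroundTruth, name: str = "") -> RegionMask:
    """Synthetic guided ROI: the diseased wedge, or its lateral equivalent.

    On a diseased (OA medial) section the ROI is the true diseased-bone
    mask. On a section without a wedge the ROI takes bone pixels from
    the same lateral edge of the bone area, matched in target area share
    — the synthetic analogue of drawing an equal-sized region at the
    mirrored position of the joint.
    """
    dis = truth.region_mask("diseased_bone")
    if dis.any():
        return RegionMask(mask=dis, name=name or "diseased wedge", origin="guided")
    bone = truth.region_mask("healthy_bone")
    width, _height = truth.cohort["grid"]
    kept = truth.cohort.get("kept_indices")
    x = (np.asarray(kept) if kept is not None else np.arange(len(bone))) % width
    target = max(1, int(round(bone.sum() * 0.25)))
    mask = np.zeros_like(bone)
    for cut in range(1, width + 1):
        mask = bone & (x < cut)
        if mask.sum() >= target:
            break
    return RegionMask(mask=mask, name=name or "lateral-equivalent ROI", origin="guided")


def _feature_tables(datasets, config: PipelineConfig):
    """Per-tissue top-N feature selection and union table extraction."""
    sets = []
    for ds in datasets:
        spec = mean_spectrum(ds)
        peaks = spectrum_peaks(spec, min_prominence=config.min_peak_prominence)
        sets.append(select_top_n(peaks, config.top_n_features))
    union = merge_feature_sets(sets, window_da=config.feature_window_da)
    tables = [
        extract_feature_table(ds, union, window_da=config.feature_window_da)
        for ds in datasets
    ]
    return union, tables


def load_run_config(path) -> dict:
    """Read a TOML run configuration."""
    import tomllib

    with open(path, "rb") as fh:
        return tomllib.load(fh)


def run_pipeline(
    config_path=None,
    *,
    raw: dict | None = None,
    out_dir=None,
) -> RunReport:
    """Execute the full discovery/validation workflow from a config.

    ``config_path`` names a TOML file (or pass its parsed content as
    ``raw``). Recognized tables: ``[pipeline]`` (PipelineConfig keys),
    ``[run]`` (``mode`` = "simulate" | "load", ``out_dir``, ``seed``),
    ``[simulate]`` (grid, cohort sizes, noise levels), ``[samples]`` /
    ``[rois]`` for load mode, ``[library]`` (``path`` to a TSV; simulate
    mode defaults to the built-in synthetic library).

    Deterministic per seed; every intermediate is written under
    ``out_dir`` and hashed into the report manifest.
    """
    if raw is None:
        if config_path is None:
            raise ValueError("provide config_path or raw")
        raw = load_run_config(config_path)
    run_cfg = raw.get("run", {})
    seed = int(run_cfg.get("seed", raw.get("pipeline", {}).get("seed", 0)))
    pipe_d = dict(raw.get("pipeline", {}))
    pipe_d["seed"] = seed
    config = PipelineConfig.from_dict(pipe_d)
    out = Path(out_dir or run_cfg.get("out_dir", "osteomsi_run"))
    out.mkdir(parents=True, exist_ok=True)
    mode = run_cfg.get("mode", "simulate")

    report = RunReport(config=raw, seed=seed, version=__version__)
    stage = "inputs"
    try:
        # ----- inputs ----------------------------------------------------
        if mode == "simulate":
            sim = raw.get("simulate", {})
            spec = PhantomSpec(
                grid=tuple(sim.get("grid", (120, 80))),
                pixel_pitch_um=float(sim.get("pixel_pitch_um", 40.0)),
            )
            markers = MarkerConfig(
                n_null_features=int(sim.get("n_null_features", 490)),
                noise_cv=float(sim.get("noise_cv", 0.2)),
                gain_cv=float(sim.get("gain_cv", 0.3)),
                ref_dropout=float(sim.get("ref_dropout", 0.0)),
            )
            sections = simulate_cohort(
                spec,
                markers,
                n_oa=int(sim.get("n_oa", 4)),
                n_control=int(sim.get("n_control", 4)),
                seed=seed,
            )
            datasets = [ds for ds, _t in sections]
            truths = [t for _ds, t in sections]
            library = default_library()
        elif mode == "load":
            samples = raw.get("samples", [])
            if not samples:
                raise ValueError("load mode requires a [[samples]] list")
            datasets, truths = [], []
            for s in samples:
                ds = read_msi(s["path"], format=s.get("format"))
                ds.metadata.update(
                    {k: s.get(k) for k in ("sample_id", "group", "side", "donor")}
                )
                datasets.append(ds)
                truths.append(None)
            lib_path = raw.get("library", {}).get("path")
            if not lib_path:
                raise ValueError("load mode requires [library].path")
            library = read_library_tsv(lib_path)
        else:
            raise ValueError(f"unknown run mode {mode!r}")

        meta = [ds.metadata for ds in datasets]
        rep_oa = _find(meta, group="OA", side="medial")
        rep_ctrl = _find(meta, group="control", side="medial")

        # ----- normalize --------------------------------------------------
        stage = "normalize"
        datasets = [
            normalize_spectra(ds, "reference_peak", config) for ds in datasets
        ]
        n_flagged = sum(ds.metadata["n_flagged"] for ds in datasets)
        keep_masks = [
            np.setdiff1d(np.arange(ds.n_pixels), ds.flagged_pixels())
            for ds in datasets
        ]
        datasets = [drop_flagged(ds) for ds in datasets]
        if mode == "simulate":
            truths = [
                _subset_truth(t, k) for t, k in zip(truths, keep_masks)
            ]

        # ----- features ---------------------------------------------------
        stage = "features"
        union, tables = _feature_tables(datasets, config)
        report.counts.update(
            pixels=int(sum(ds.n_pixels for ds in datasets)),
            flagged_pixels=int(n_flagged),
            features=len(union),
            samples=len(datasets),
        )

        # ----- segmentation (reported; ROIs below are guided) -------------
        stage = "segment"
        seg = bisect_segment(
            tables[rep_oa], config.n_leaves, seed=seed, zscore=config.zscore_features
        )
        report.counts["segments"] = seg.n_leaves
        _write_tsv(
            out / "segmentation_rep_oa.tsv",
            pd.DataFrame(
                {
                    "x": tables[rep_oa].pixels[:, 0],
                    "y": tables[rep_oa].pixels[:, 1],
                    "label": seg.labels,
                }
            ),
            report,
        )

        # ----- screening on the representative site-matched pair ----------
        stage = "discover"
        if mode == "simulate":
            mask_dis = RegionMask(
                truths[rep_oa].region_mask("diseased_bone"), "diseased bone", "guided"
            )
            mask_healthy = RegionMask(
                truths[rep_ctrl].region_mask("healthy_bone"), "healthy bone", "guided"
            )
        else:
            rois = raw.get("rois", {})
            mask_dis = _polygon_mask(rois["screen_diseased"], tables[rep_oa])
            mask_healthy = _polygon_mask(rois["screen_healthy"], tables[rep_ctrl])
        stacked = _stack_tables([tables[rep_oa], tables[rep_ctrl]], union)
        full_a = np.zeros(stacked.n_pixels, bool)
        full_a[: tables[rep_oa].n_pixels] = mask_dis.mask
        full_b = np.zeros(stacked.n_pixels, bool)
        full_b[tables[rep_oa].n_pixels :] = mask_healthy.mask
        candidates = discriminating_features(
            stacked,
            RegionMask(full_a, mask_dis.name, "guided"),
            RegionMask(full_b, mask_healthy.name, "guided"),
            threshold=config.auroc_threshold,
            comparison_id=f"{meta[rep_oa].get('sample_id')} vs {meta[rep_ctrl].get('sample_id')}",
        )
        report.candidates = candidates
        report.counts["candidates"] = len(candidates)
        _write_tsv(
            out / "candidates.tsv",
            pd.DataFrame(
                {
                    "mz": [c.mz for c in candidates],
                    "auroc": [c.auroc for c in candidates],
                    "direction": [c.direction for c in candidates],
                    "nA": [c.n_pixels_A for c in candidates],
                    "nB": [c.n_pixels_B for c in candidates],
                    "comparison_id": [c.comparison_id for c in candidates],
                }
            ),
            report,
        )

        # ----- cohort validation (paired OA medial vs lateral) -------------
        stage = "validate"
        oa_donors = sorted(
            {m["donor"] for m in meta if m.get("group") == "OA"}
        )
        per_sample = {}
        sample_rows, sample_labels, sample_ids = [], [], []
        for c in candidates:
            per_sample[c.mz] = {"medial": [], "lateral": []}
        for donor in oa_donors:
            for side in ("medial", "lateral"):
                i = _find(meta, donor=donor, side=side)
                roi = (
                    guided_roi(truths[i])
                    if mode == "simulate"
                    else _polygon_mask(raw["rois"][meta[i]["sample_id"]], tables[i])
                )
                row = []
                for c in candidates:
                    v = roi_mean_intensity(tables[i], roi, c.mz)
                    per_sample[c.mz][side].append(v)
                    row.append(v)
                sample_rows.append(row)
                sample_labels.append(side)
                sample_ids.append(meta[i]["sample_id"])
        validation = validate_candidates(
            per_sample, design="paired", group_a="medial", group_b="lateral",
            alpha=config.alpha,
        )
        report.validation = validation
        report.counts["validated"] = sum(v.significant for v in validation)
        report.counts["trend"] = sum(v.trend for v in validation)
        _write_tsv(
            out / "validation.tsv",
            pd.DataFrame(
                {
                    "mz": [v.mz for v in validation],
                    "t": [v.t_statistic for v in validation],
                    "df": [v.df for v in validation],
                    "p": [v.p_value for v in validation],
                    "significant": [v.significant for v in validation],
                    "trend": [v.trend for v in validation],
                    "p_BH": [v.p_bh for v in validation],
                }
            ),
            report,
        )
        if len(candidates) >= 2 and len(sample_rows) >= 4:
            scores = plsda_scores(
                np.array(sample_rows), np.array(sample_labels),
                n_components=min(3, len(sample_rows) - 1, len(candidates)),
            )
            _write_tsv(
                out / "plsda_scores.tsv",
                pd.DataFrame(
                    scores.scores,
                    columns=[f"comp{k + 1}" for k in range(scores.scores.shape[1])],
                ).assign(sample_id=sample_ids, side=sample_labels),
                report,
            )

        # ----- annotation ---------------------------------------------------
        stage = "annotate"
        annotated = match_features(candidates, library, tol_da=config.match_tol_da)
        report.annotations = annotated
        report.counts["annotated"] = sum(a.status != "unmatched" for a in annotated)
        _write_tsv(
            out / "annotated_candidates.tsv",
            pd.DataFrame(
                {
                    "mz": [a.candidate.mz for a in annotated],
                    "status": [a.status for a in annotated],
                    "matches": [
                        ";".join(f"{e.protein}:{e.label()}" for e, _d in a.matches)
                        for a in annotated
                    ],
                    "delta_mda": [
                        ";".join(f"{d * 1000:.3f}" for _e, d in a.matches)
                        for a in annotated
                    ],
                }
            ),
            report,
        )

        report.check_consistency()
        (out / "run_report.json").write_text(report.to_json())
        return report
    except Exception:
        report.failure_stage = stage
        logger.exception("pipeline failed at stage %s", stage)
        raise


def _find(meta: list[dict], **criteria) -> int:
    for i, m in enumerate(meta):
        if all(m.get(k) == v for k, v in criteria.items()):
            return i
    raise ValueError(f"no sample matching {criteria}")


def _subset_truth(truth: GroundTruth, keep: np.ndarray) -> GroundTruth:
    t = dataclasses.replace(truth)
    t.region_labels = truth.region_labels[keep]
    t.cohort = dict(truth.cohort)
    if len(keep) != len(truth.region_labels):
        t.cohort["kept_indices"] = keep.tolist()
    return t


def _stack_tables(tables: list[FeatureTable], union) -> FeatureTable:
    # pixel coordinates offset so stacked coordinates stay unique
    offset = 0
    pix, vals = [], []
    for t in tables:
        p = t.pixels.copy()
        p[:, 1] += offset
        offset = p[:, 1].max() + 1
        pix.append(p)
        vals.append(t.values)
    return FeatureTable(
        pixels=np.vstack(pix),
        features=union,
        values=np.vstack(vals),
        provenance={"stacked": [t.provenance.get("sample_id") for t in tables]},
    )


def _polygon_mask(roi_path, table: FeatureTable) -> RegionMask:
    verts = pd.read_csv(roi_path, sep="\t")
    return roi_from_polygon(
        list(zip(verts["x"], verts["y"])), table, name=str(roi_path)
    )


def _write_tsv(path: Path, df: pd.DataFrame, report: RunReport) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    report.manifest[path.name] = digest
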