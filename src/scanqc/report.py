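"""Stage IV: machine-readable tables, slice galleries, summary figures, and
the end-to-end pipeline orchestration.

Outputs per run: one feature CSV per sequence class, a ``voting.csv`` with
the five per-algorithm decisions and the 0-5 majority vote per scan, one
middle-slice PNG per scan (named ``<class>_<index>_<subject>.png``),
distribution figures with IQR outliers highlighted, a config snapshot, and
a timestamped run log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless rendering; no display required
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import motion as motion_mod
from . import outliers as outliers_mod
from . import snr as snr_mod
from .config import QcConfig
from .image import VoxelImage
from .ingest import Manifest, ReaderError, ScanRecord, read_image, scan_input_tree

log = logging.getLogger(__name__)


@dataclass
class QcReport:
    """Everything one pipeline run produced, ready for serialization."""

    manifest: Manifest
    feature_tables: dict[str, pd.DataFrame]
    voting_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    run_config: dict = field(default_factory=dict)
    log_events: list[str] = field(default_factory=list)

    def log(self, message: str) -> None:
        stamp = datetime.now(timezone.utc).isoformat(timespec="seconds")
        self.log_events.append(f"{stamp} {message}")
        log.info(message)


def slice_image_name(sequence_class: str, index: int, subject_id: str) -> str:
    """Naming scheme for exported middle slices: class, running per-class
    index (1-based, manifest order), subject."""
    return f"{sequence_class}_{index}_{subject_id}.png"


def compute_features(
    manifest: Manifest,
    config: QcConfig | None = None,
    reader=read_image,
    report: QcReport | None = None,
) -> dict[str, pd.DataFrame]:
    """Stage II: per-scan quality features, one table per sequence class.

    Rows keep failed features as missing values with an explanatory note —
    a scan is never silently dropped.  The exported slice-image name is
    included so reports and galleries can be joined.
    """
    cfg = config or QcConfig()
    rows: dict[str, list[dict]] = {}
    class_counter: dict[str, int] = {}
    for record in manifest.records:
        cls = record.sequence_class
        class_counter[cls] = class_counter.get(cls, 0) + 1
        row: dict[str, object] = {
            "path": str(record.path),
            "subject_id": record.subject_id,
            "sequence_name": record.sequence_name,
            "n_volumes": record.n_volumes,
            "voxel_size_x": record.voxel_size_mm[0],
            "voxel_size_y": record.voxel_size_mm[1],
            "voxel_size_z": record.voxel_size_mm[2],
            "image_file": slice_image_name(cls, class_counter[cls], record.subject_id),
        }
        notes: list[str] = []
        try:
            image = reader(record)
        except ReaderError as exc:
            notes.append(f"read failed: {exc}")
            image = None
        if image is not None:
            snr_result = snr_mod.compute_snr_features(
                image,
                cls,
                sphere_radius_frac=cfg.sphere_radius_frac,
                cuboid_edge_frac=cfg.cuboid_edge_frac,
                chang_window=cfg.chang_window,
                chang_smooth_bins=cfg.chang_smooth_bins,
                b0_threshold=cfg.b0_threshold,
            )
            notes.extend(snr_result.notes)
            for col in outliers_mod.CLASS_FEATURES.get(cls, ()):
                if col == "motion_severity":
                    continue
                row[col] = getattr(snr_result, col)
            if cls in ("diffusion", "functional") and image.is_4d:
                try:
                    trace = motion_mod.motion_trace(
                        image,
                        bins=cfg.mi_bins,
                        reference_threshold=cfg.reference_threshold,
                    )
                    row["motion_severity"] = motion_mod.motion_severity(trace)
                except ValueError as exc:
                    notes.append(f"motion trace failed: {exc}")
            try:
                ghost = motion_mod.ghost_curve(
                    image,
                    bins=cfg.mi_bins,
                    peak_prominence_frac=cfg.peak_prominence_frac,
                )
                row["ghost_detected"] = int(ghost.is_ghost)
            except ValueError as exc:
                notes.append(f"ghost analysis failed: {exc}")
        row["notes"] = "; ".join(notes)
        rows.setdefault(cls, []).append(row)
        if report is not None and notes:
            report.log(f"{record.path}: {row['notes']}")

    tables: dict[str, pd.DataFrame] = {}
    for cls, entries in rows.items():
        table = pd.DataFrame(entries)
        for col in outliers_mod.CLASS_FEATURES.get(cls, ()):
            if col not in table.columns:
                table[col] = np.nan
        tables[cls] = table
    return tables


def _detection_frame(table: pd.DataFrame, include_ghost: bool) -> pd.DataFrame:
    cols = [c for c in table.columns if c in outliers_mod.FEATURE_POLARITY]
    frame = table[cols].copy()
    if include_ghost and "ghost_detected" in table.columns:
        frame["ghost_detected"] = table["ghost_detected"]
    return frame


def compute_votes(
    feature_tables: dict[str, pd.DataFrame],
    config: QcConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Stage III bridge: run the outlier ensemble on computed features."""
    cfg = config or QcConfig()
    detection = {
        cls: _detection_frame(tab, cfg.include_ghost_in_features)
        for cls, tab in feature_tables.items()
    }
    votes = outliers_mod.run_outlier_stage(
        detection,
        mode=cfg.mode,
        threshold=cfg.review_threshold,
        seed=cfg.seed,
        ocsvm_nu=cfg.ocsvm_nu,
        iforest_contamination=cfg.iforest_contamination,
        iforest_n_estimators=cfg.iforest_n_estimators,
        lof_n_neighbors=cfg.lof_n_neighbors,
        lof_contamination=cfg.lof_contamination,
        ee_contamination=cfg.ee_contamination,
    )
    return votes


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def write_feature_tables(report: QcReport, outdir: str | Path) -> list[Path]:
    """One CSV per sequence class (UTF-8, comma-separated, header row)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for cls, table in sorted(report.feature_tables.items()):
        path = outdir / f"features_{cls}.csv"
        table.to_csv(path, index=False)
        written.append(path)
        report.log(f"wrote {path.name} ({len(table)} rows)")
    return written


def write_voting_table(report: QcReport, outdir: str | Path) -> Path:
    """voting.csv: per scan, the five algorithm columns, vote, review flag."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames = []
    for cls, votes in sorted(report.voting_tables.items()):
        features = report.feature_tables[cls]
        meta = features[["path", "subject_id", "sequence_name"]].reset_index(drop=True)
        meta.insert(2, "sequence_class", cls)
        frames.append(pd.concat([meta, votes.reset_index(drop=True)], axis=1))
    path = outdir / "voting.csv"
    if frames:
        pd.concat(frames, axis=0).to_csv(path, index=False)
    else:
        pd.DataFrame(
            columns=["path", "subject_id", "sequence_class", "sequence_name"]
        ).to_csv(path, index=False)
    report.log(f"wrote {path.name}")
    return path


def export_middle_slices(
    manifest: Manifest,
    outdir: str | Path,
    reader=read_image,
) -> list[Path]:
    """Save one grayscale middle-slice PNG per scan for visual inspection.

    4D scans are averaged over the 4th axis first.  A per-file failure is
    logged and skipped; the export continues.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    counter: dict[str, int] = {}
    for record in manifest.records:
        cls = record.sequence_class
        counter[cls] = counter.get(cls, 0) + 1
        name = slice_image_name(cls, counter[cls], record.subject_id)
        try:
            image = reader(record)
            vol = image.time_average()
            middle = vol[:, :, vol.shape[2] // 2]
            plt.imsave(outdir / name, middle.T, cmap="gray", origin="lower")
            written.append(outdir / name)
        except Exception as exc:
            log.warning("slice export failed for %s: %s", record.path, exc)
    return written


def render_summary_figures(report: QcReport, outdir: str | Path) -> list[Path]:
    """Voxel-size pie charts and per-feature distribution histograms.

    IQR-flagged scans are drawn in red on top of the cohort histogram, with
    the IQR fence marked, mirroring the at-a-glance report layout.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    # resolution pie charts, one per axis
    sizes = {
        axis: [round(r.voxel_size_mm[i], 4) for r in report.manifest.records]
        for i, axis in enumerate("xyz")
    }
    if report.manifest.records:
        fig, axes = plt.subplots(1, 3, figsize=(12, 4))
        for ax, (axis, values) in zip(axes, sizes.items()):
            labels, counts = np.unique(values, return_counts=True)
            ax.pie(counts, labels=[f"{v} mm" for v in labels], autopct="%d%%")
            ax.set_title(f"voxel size {axis}")
        path = outdir / "resolution_pie.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(path)

    for cls, table in sorted(report.feature_tables.items()):
        cols = [c for c in table.columns if c in outliers_mod.FEATURE_POLARITY]
        plotted = False
        flags = outliers_mod.iqr_flags(_detection_frame(table, False))
        for col in cols:
            values = pd.to_numeric(table[col], errors="coerce")
            finite = values[np.isfinite(values)]
            if finite.empty:
                continue
            fig, ax = plt.subplots(figsize=(6, 4))
            ax.hist(finite, bins=20, color="steelblue", label="cohort")
            outliers = values[flags & np.isfinite(values)]
            if not outliers.empty:
                ax.hist(outliers, bins=20, color="crimson", label="IQR outlier")
            q1, q3 = np.quantile(finite, [0.25, 0.75])
            iqr = q3 - q1
            fence = (
                q1 - 1.5 * iqr
                if outliers_mod.FEATURE_POLARITY[col] > 0
                else q3 + 1.5 * iqr
            )
            ax.axvline(fence, color="gray", linestyle="--", label="IQR fence")
            ax.set_xlabel(col)
            ax.set_ylabel("scans")
            ax.set_title(f"{cls}: {col}")
            ax.legend()
            path = outdir / f"distribution_{cls}_{col}.png"
            fig.savefig(path, dpi=100)
            plt.close(fig)
            written.append(path)
            plotted = True
        if not plotted:
            report.log(f"figures: class {cls} has no plottable features, skipped")
    return written


def write_log(report: QcReport, outdir: str | Path) -> Path:
    path = Path(outdir) / "run_log.txt"
    path.write_text("\n".join(report.log_events) + "\n")
    return path


def run_pipeline(
    root: str | Path,
    outdir: str | Path,
    config: QcConfig | None = None,
    format_hint: str | None = None,
) -> QcReport:
    """Execute parsing → features → outlier voting → reporting.

    Everything lands in ``outdir``: feature tables, voting.csv, the slice
    gallery, summary figures, the config snapshot, and the run log.
    """
    cfg = config or QcConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest = scan_input_tree(root, format_hint=format_hint)
    report = QcReport(
        manifest=manifest, feature_tables={}, run_config=cfg.to_dict()
    )
    report.log(
        f"stage I: {len(manifest.records)} scan(s), "
        f"{len(manifest.excluded)} excluded under {root}"
    )
    for path, reason in manifest.excluded:
        report.log(f"excluded {path}: {reason}")

    report.feature_tables = compute_features(manifest, cfg, report=report)
    report.log(
        "stage II: features for "
        + ", ".join(f"{len(t)} {c}" for c, t in sorted(report.feature_tables.items()))
    )

    report.voting_tables = compute_votes(report.feature_tables, cfg)
    report.log("stage III: outlier votes computed")

    write_feature_tables(report, outdir)
    write_voting_table(report, outdir)
    export_middle_slices(manifest, outdir / "manual_slice_inspection")
    render_summary_figures(report, outdir / "figures")
    cfg.dump(outdir / "config_snapshot.json")
    write_log(report, outdir)
    return report
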