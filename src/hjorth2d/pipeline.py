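"""Batch orchestration: extract descriptors, compare groups, classify.

This is the workflow layer: a directory (or manifest) of images becomes
a descriptor table; the table becomes a statistical report (normality,
variance homogeneity, Kruskal–Wallis, Dunn post hoc); optionally a
minimal leave-one-out nearest-centroid classifier gives a rough sense of
group separability. The classifier is exploratory plumbing only — the
scientific output of the method is the statistics.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import groupstats as gs
from .errors import DegenerateInputError, InputError
from .hjorth import PipelineConfig, descriptors
from .image_prep import GrayImage, load_gray

logger = logging.getLogger("hjorth2d")

DESCRIPTOR_COLUMNS = ("activity", "mobility", "complexity")
IMAGE_EXTENSIONS = (".png", ".tif", ".tiff", ".jpg", ".jpeg")


@dataclass
class BatchResult:
    """Descriptor table plus a record of any per-image failures."""

    table: pd.DataFrame
    failures: list[tuple[str, str]]  # (image_id/path, error message)
    config: dict


def _iter_inputs(source, manifest: pd.DataFrame | None):
    """Yield (image_id, group, path-or-GrayImage) from the accepted sources."""
    if isinstance(source, (str, Path)):
        root = Path(source)
        if manifest is not None:
            for row in manifest.itertuples(index=False):
                matches = sorted(root.glob(f"{row.image_id}.*"))
                path = matches[0] if matches else root / f"{row.image_id}.png"
                yield str(row.image_id), str(row.group), path
        else:
            paths = sorted(
                p for p in root.iterdir() if p.suffix.lower() in IMAGE_EXTENSIONS
            )
            if not paths:
                raise InputError(f"no readable images found in {root}")
            for p in paths:
                yield p.stem, None, p
    else:  # in-memory cohort: iterable of (image_id, group, GrayImage)
        yield from source


def batch_descriptors(
    source,
    config: PipelineConfig | None = None,
    manifest: pd.DataFrame | None = None,
) -> BatchResult:
    """One descriptor row per image, sorted by image_id.

    ``source`` is an image directory, or an in-memory iterable of
    (image_id, group, GrayImage). Per-image failures are logged and
    collected, never silently dropped.
    """
    cfg = config or PipelineConfig()
    rows, failures = [], []
    for image_id, group, item in _iter_inputs(source, manifest):
        t0 = time.perf_counter()
        try:
            img = item if isinstance(item, GrayImage) else load_gray(item)
            d = descriptors(img, cfg, image_id=image_id, group=group)
            rows.append(
                {
                    "image_id": image_id,
                    "group": group,
                    "activity": d.activity,
                    "mobility": d.mobility,
                    "complexity": d.complexity,
                }
            )
            logger.debug(
                "extract %s ok (%.1f ms)", image_id, 1e3 * (time.perf_counter() - t0)
            )
        except Exception as exc:  # noqa: BLE001 - batch robustness
            logger.warning("extract %s failed: %s", image_id, exc)
            failures.append((str(image_id), str(exc)))
    if not rows and failures:
        raise InputError(f"all {len(failures)} images failed descriptor extraction")
    table = pd.DataFrame(rows).sort_values("image_id").reset_index(drop=True)
    return BatchResult(table=table, failures=failures, config=cfg.to_dict())


def _grouped(table: pd.DataFrame, descriptor: str) -> gs.GroupedSample:
    groups = tuple(
        (str(label), tuple(sub[descriptor].to_numpy(float)))
        for label, sub in table.groupby("group", sort=False)
    )
    return gs.GroupedSample(descriptor, groups)


def compare_groups(table: pd.DataFrame, min_group_size: int = 3) -> dict:
    """Full rank-based group comparison for each descriptor.

    Per descriptor: Shapiro–Wilk per group, Levene, Kruskal–Wallis with
    rank sums/averages, and the Dunn–Bonferroni post hoc matrix.
    Returns a JSON-serializable dict; see :func:`report_markdown` for
    the human-readable rendering.
    """
    if "group" not in table.columns or table["group"].isna().any():
        raise InputError("descriptor table needs a complete 'group' column")
    missing = [c for c in DESCRIPTOR_COLUMNS if c not in table.columns]
    if missing:
        raise InputError(f"descriptor table lacks columns {missing}")
    counts = table.groupby("group").size()
    if len(counts) < 2:
        raise InputError("need at least 2 groups to compare")
    small = counts[counts < min_group_size]
    if not small.empty:
        raise InputError(
            f"groups below the minimum size {min_group_size}: {dict(small)}"
        )

    report: dict = {"n_images": int(len(table)), "group_sizes": {str(k): int(v) for k, v in counts.items()}, "descriptors": {}}
    for name in DESCRIPTOR_COLUMNS:
        sample = _grouped(table, name)
        summary = gs.rank_all(sample)
        kw = gs.kruskal_wallis(sample)
        lev = gs.levene(sample)
        dunn = gs.dunn_posthoc(summary)
        normality = {}
        for label, vals in sample.groups:
            try:
                sw = gs.shapiro_wilk(vals)
                normality[label] = {"W": sw.statistic, "p": sw.p_value}
            except DegenerateInputError as exc:
                normality[label] = {"error": str(exc)}
        report["descriptors"][name] = {
            "normality": normality,
            "levene": {
                "SS": lev.ss_between,
                "df": lev.df_between,
                "MS": lev.ms_between,
                "SS*": lev.ss_within,
                "df*": lev.df_within,
                "MS*": lev.ms_within,
                "F": lev.statistic,
                "p": lev.p_value,
            },
            "kruskal_wallis": {
                "H": kw.statistic,
                "p": kw.p_value,
                "df": len(sample.labels) - 1,
                "rank_sums": dict(zip(summary.labels, summary.rank_sums)),
                "rank_averages": dict(zip(summary.labels, summary.rank_averages)),
                "group_sizes": dict(zip(summary.labels, summary.sizes)),
            },
            "dunn_bonferroni": {
                "labels": list(dunn.labels),
                "p_adj": dunn.p_adj.tolist(),
                "z": dunn.z.tolist(),
            },
        }
    return report


def report_markdown(report: dict) -> str:
    """Render a compare_groups report as a Markdown document."""
    lines = ["# Hjorth descriptor group comparison", ""]
    lines.append(f"Images: {report['n_images']}; groups: " + ", ".join(
        f"{k} (n={v})" for k, v in report["group_sizes"].items()
    ))
    for name, r in report["descriptors"].items():
        lines += ["", f"## {name.capitalize()}", "", "### Normality (Shapiro–Wilk)", ""]
        lines.append("| group | W | p |")
        lines.append("|---|---|---|")
        for label, sw in r["normality"].items():
            if "error" in sw:
                lines.append(f"| {label} | – | {sw['error']} |")
            else:
                lines.append(f"| {label} | {sw['W']:.4f} | {sw['p']:.6f} |")
        lev = r["levene"]
        lines += ["", "### Variance homogeneity (Levene)", ""]
        lines.append("| SS | df | MS | SS* | df* | MS* | F | p |")
        lines.append("|---|---|---|---|---|---|---|---|")
        lines.append(
            f"| {lev['SS']:.6f} | {lev['df']} | {lev['MS']:.6f} | {lev['SS*']:.6f} "
            f"| {lev['df*']} | {lev['MS*']:.6f} | {lev['F']:.6f} | {lev['p']:.6f} |"
        )
        kw = r["kruskal_wallis"]
        lines += ["", "### Kruskal–Wallis rank ANOVA", ""]
        lines.append("| group | n | rank sum | rank average |")
        lines.append("|---|---|---|---|")
        for label in kw["rank_sums"]:
            lines.append(
                f"| {label} | {kw['group_sizes'][label]} | {kw['rank_sums'][label]:g} "
                f"| {kw['rank_averages'][label]:.3f} |"
            )
        lines.append("")
        lines.append(f"H = {kw['H']:.3f}, df = {kw['df']}, p = {kw['p']:.6g}")
        dunn = r["dunn_bonferroni"]
        lines += ["", "### Dunn post hoc (Bonferroni-adjusted p)", ""]
        labels = dunn["labels"]
        lines.append("| | " + " | ".join(labels) + " |")
        lines.append("|---|" + "---|" * len(labels))
        for i, la in enumerate(labels):
            cells = []
            for j in range(len(labels)):
                cells.append("" if i == j else f"{dunn['p_adj'][i][j]:.6f}")
            lines.append(f"| {la} | " + " | ".join(cells) + " |")
    lines.append("")
    return "\n".join(lines)


def classify_nearest_centroid(
    table: pd.DataFrame, standardize: bool = True
) -> dict:
    """Leave-one-out nearest-centroid classification in descriptor space.

    For each left-out image, descriptors are z-scored with the training
    fold's mean/std and the image is assigned to the closest group
    centroid. A training-fold descriptor with zero variance is dropped
    with a warning. Exploratory only.
    """
    if "group" not in table.columns or table["group"].isna().any():
        raise InputError("classification needs a complete 'group' column")
    counts = table.groupby("group").size()
    if len(counts) < 2 or (counts < 2).any():
        raise InputError("need >= 2 groups with >= 2 images each")

    x = table[list(DESCRIPTOR_COLUMNS)].to_numpy(float)
    y = table["group"].to_numpy(str)
    labels = sorted(set(y))
    n = len(table)
    confusion = {a: {b: 0 for b in labels} for a in labels}
    correct = 0
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        xtr, ytr = x[mask], y[mask]
        if standardize:
            mu, sd = xtr.mean(axis=0), xtr.std(axis=0)
            keep = sd > 0
            if not keep.all():
                logger.warning(
                    "dropping zero-variance descriptors %s in fold %d",
                    [DESCRIPTOR_COLUMNS[j] for j in np.where(~keep)[0]], i,
                )
            xtr_s = (xtr[:, keep] - mu[keep]) / sd[keep]
            xi = (x[i, keep] - mu[keep]) / sd[keep]
        else:
            xtr_s, xi = xtr, x[i]
        centroids = np.stack([xtr_s[ytr == lab].mean(axis=0) for lab in labels])
        dist = np.linalg.norm(centroids - xi, axis=1)
        pred = labels[int(np.argmin(dist))]  # argmin breaks ties by group order
        confusion[y[i]][pred] += 1
        correct += pred == y[i]
    return {
        "labels": labels,
        "confusion": confusion,
        "accuracy": correct / n,
        "n": n,
        "standardized": standardize,
    }


def write_report(report: dict, out_dir: str | Path, stem: str = "report") -> None:
    """Write compare_groups output as Markdown + JSON side by side."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / f"{stem}.json").write_text(json.dumps(report, indent=2))
    (out_dir / f"{stem}.md").write_text(report_markdown(report))


def export_scatter(table: pd.DataFrame, out_csv: str | Path, out_png: str | Path | None = None) -> None:
    """Export the 3D descriptor scatter as CSV, optionally a static PNG.

    Plotting is best-effort: a missing matplotlib never breaks the run.
    """
    table[["image_id", "group", *DESCRIPTOR_COLUMNS]].to_csv(out_csv, index=False)
    if out_png is None:
        return
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig = plt.figure(figsize=(6, 5))
        ax = fig.add_subplot(projection="3d")
        for label, sub in table.groupby("group"):
            ax.scatter(sub["activity"], sub["mobility"], sub["complexity"], label=str(label))
        ax.set_xlabel("Activity")
        ax.set_ylabel("Mobility")
        ax.set_zlabel("Complexity")
        ax.legend()
        fig.savefig(out_png, dpi=120)
        plt.close(fig)
    except Exception as exc:  # noqa: BLE001
        logger.warning("scatter plot skipped: %s", exc)
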