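"""Figure-style outputs: contrast heatmaps, FWHM field maps, NCC histograms.

All renderers accept explicit ``vmin``/``vmax`` so maps from different
objectives or channels can be put on identical color scales for
cross-comparison.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["render_heatmaps"]


def _save_map(arr, title, cbar_label, path, vmin=None, vmax=None, cmap="viridis"):
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(arr, origin="upper", cmap=cmap, vmin=vmin, vmax=vmax, aspect="auto")
    ax.set_title(title)
    ax.set_xlabel("subregion column")
    ax.set_ylabel("subregion row")
    fig.colorbar(im, ax=ax, label=cbar_label)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_heatmaps(results, out_dir, vmin=None, vmax=None) -> list[Path]:
    """Render a results object's 2D maps/histograms as PNG files.

    Dispatches on the maps the report exposes: flatness results produce
    ``cmax.png``, ``best_focus.png``, ``detrended.png`` and ``dof.png``;
    PSF results produce FWHM field maps and histograms; track results a
    pooled NCC null histogram. Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    report = getattr(results, "report", results)

    if hasattr(report, "cmax_map"):
        if np.asarray(report.cmax_map).size == 0:
            raise ValueError("empty contrast map")
        surface = getattr(results, "surface", None)
        items = [
            (report.cmax_map, "Maximum contrast C_max(x, y)", "contrast", "cmax.png", vmin, vmax),
            (report.detrended_z0_um, "Detrended best-focus surface", "z [um]",
             "detrended.png", None, None),
            (report.dof_map_um, "Depth of field", "DOF [um]", "dof.png", None, None),
        ]
        if surface is not None:
            items.insert(1, (surface.z0_um, "Best-focus surface z0(x, y)", "z [um]",
                             "best_focus.png", None, None))
        for arr, title, lab, name, lo, hi in items:
            p = out_dir / name
            _save_map(np.asarray(arr, float), title, lab, p, lo, hi)
            written.append(p)
        return written

    if hasattr(report, "lateral_values_um"):
        if report.positions_um.size == 0:
            raise ValueError("no bead positions to map")
        for vals, name, title in (
            (report.lateral_values_um, "lateral_fwhm.png", "Lateral FWHM across the field"),
            (report.axial_values_um, "axial_fwhm.png", "Axial FWHM across the field"),
        ):
            fig, ax = plt.subplots(figsize=(6, 4))
            sc = ax.scatter(report.positions_um[:, 2], report.positions_um[:, 1],
                            c=vals, cmap="viridis", vmin=vmin, vmax=vmax, s=30)
            ax.set_xlabel("x [um]")
            ax.set_ylabel("y [um]")
            ax.invert_yaxis()
            ax.set_title(title)
            fig.colorbar(sc, ax=ax, label="FWHM [um]")
            fig.tight_layout()
            p = out_dir / name
            fig.savefig(p, dpi=120)
            plt.close(fig)
            written.append(p)
        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        for axx, (counts, edges), title in (
            (axes[0], report.lateral_hist, "Lateral FWHM"),
            (axes[1], report.axial_hist, "Axial FWHM"),
        ):
            axx.bar(edges[:-1], counts, width=np.diff(edges), align="edge",
                    edgecolor="k", linewidth=0.3)
            axx.set_xlabel("FWHM [um]")
            axx.set_ylabel("beads")
            axx.set_title(title)
        fig.tight_layout()
        p = out_dir / "fwhm_histograms.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
        return written

    if hasattr(report, "scores_ab"):
        scores = list(report.scores_ab) + list(report.scores_ba)
        if not scores:
            raise ValueError("no candidate scores to plot")
        fig, ax = plt.subplots(figsize=(6, 4))
        pooled = np.concatenate([s.ncc_values for s in scores if s.ncc_values is not None])
        ax.hist(pooled, bins=60, range=(-1, 1), edgecolor="k", linewidth=0.3)
        for s in scores:
            ax.axvline(s.ncc_peak, color="crimson", linestyle="--", linewidth=0.8)
        ax.set_xlabel("NCC value")
        ax.set_ylabel("count")
        ax.set_title("NCC null distribution (peaks dashed)")
        fig.tight_layout()
        p = out_dir / "ncc_hist.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
        return written

    raise TypeError(f"no heatmap renderer for {type(results).__name__}")
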