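"""Spinal-cord lesion topography on the 44 hemi-vertebral levels.

Each patient contributes one column; each row is half a vertebral body,
from the superior half of C1 (level 1) to the inferior half of L3 (level
44).  A cell records the "worst" lesion category covering that level over
all of the patient's spine imaging — long (longitudinally extensive)
taking precedence over short — with Gd enhancement kept as an independent
overlay so enhancing levels can be marked without truncating the long/short
extent.  The per-group summary is the proportional frequency of lesion
occupancy at each level among patients with spine imaging.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import N_CORD_LEVELS, PatientRecord, cord_lesion_length_class

__all__ = ["CordHeatMap", "level_label", "build_heatmap", "render_heatmap"]

_VERTEBRAE = [f"C{i}" for i in range(1, 8)] + [f"T{i}" for i in range(1, 13)] + [
    f"L{i}" for i in range(1, 4)
]

CELL_NONE, CELL_SHORT, CELL_LONG = 0, 1, 2


def level_label(index: int) -> str:
    """Anatomical label of a hemi-vertebral level (1 -> C1-superior, 44 -> L3-inferior)."""
    if not 1 <= index <= N_CORD_LEVELS:
        raise ValueError(f"level index must be in 1..{N_CORD_LEVELS}, got {index}")
    vertebra = _VERTEBRAE[(index - 1) // 2]
    half = "superior" if index % 2 == 1 else "inferior"
    return f"{vertebra}-{half}"


@dataclass
class CordHeatMap:
    """Occupancy matrix (44 levels x patients) with per-level summary."""

    group: str
    cells: pd.DataFrame  # int codes 0=none, 1=short, 2=long
    gd: pd.DataFrame  # bool overlay, same shape
    summary: pd.Series  # per-level occupancy proportion within the group

    @property
    def levels(self) -> list[str]:
        return list(self.cells.index)


def build_heatmap(patients: Sequence[PatientRecord], group: str) -> CordHeatMap:
    """Union cord-lesion occupancy over every spine scan of each patient.

    Only patients of the requested diagnosis group with at least one spine
    scan contribute columns (and denominators).  Where long and short
    lesions overlap a level the cell is coded long; Gd enhancement is an
    independent overlay.
    """
    if group not in ("NMOSD", "MS"):
        raise ValueError("group must be NMOSD or MS")
    index = pd.Index([level_label(i) for i in range(1, N_CORD_LEVELS + 1)], name="level")
    columns = []
    cell_data = []
    gd_data = []
    for patient in patients:
        if patient.diagnosis != group:
            continue
        spine_scans = patient.scans_of("spine")
        if not spine_scans:
            continue
        cells = np.zeros(N_CORD_LEVELS, dtype=int)
        gd = np.zeros(N_CORD_LEVELS, dtype=bool)
        for scan in spine_scans:
            for les in scan.cord_lesions:
                code = CELL_LONG if cord_lesion_length_class(les) == "long" else CELL_SHORT
                sl = slice(les.start_level - 1, les.end_level)
                cells[sl] = np.maximum(cells[sl], code)
                if les.gd_enhancing:
                    gd[sl] = True
        columns.append(patient.patient_id)
        cell_data.append(cells)
        gd_data.append(gd)
    if columns:
        cells_df = pd.DataFrame(np.array(cell_data).T, index=index, columns=columns)
        gd_df = pd.DataFrame(np.array(gd_data).T, index=index, columns=columns)
        summary = (cells_df > 0).mean(axis=1)
    else:
        cells_df = pd.DataFrame(index=index)
        gd_df = pd.DataFrame(index=index)
        summary = pd.Series(0.0, index=index)
    summary.name = f"frequency_{group}"
    return CordHeatMap(group=group, cells=cells_df, gd=gd_df, summary=summary)


def render_heatmap(heatmap: CordHeatMap, path: str | Path) -> tuple[Path, Path]:
    """Write the occupancy plot and the raw matrices.

    ``path`` is a stem: ``<stem>.png`` gets the figure, ``<stem>_cells.csv``
    and ``<stem>_gd.csv`` the matrices and ``<stem>_summary.csv`` the
    per-level frequencies.  Output is deterministic for a fixed map.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cells_path = path.with_name(path.name + "_cells.csv")
    gd_path = path.with_name(path.name + "_gd.csv")
    summary_path = path.with_name(path.name + "_summary.csv")
    heatmap.cells.to_csv(cells_path)
    heatmap.gd.astype(int).to_csv(gd_path)
    heatmap.summary.to_csv(summary_path)

    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.12 * max(1, heatmap.cells.shape[1])), 7.0)
    )
    cmap = ListedColormap(["#f5f5f5", "#7fb8e6", "#1f4e9c"])  # none, short, long
    data = heatmap.cells.to_numpy() if heatmap.cells.shape[1] else np.zeros((N_CORD_LEVELS, 1))
    ax.imshow(data, aspect="auto", cmap=cmap, vmin=0, vmax=2, interpolation="nearest")
    if heatmap.gd.shape[1]:
        ys, xs = np.nonzero(heatmap.gd.to_numpy())
        ax.scatter(xs, ys, s=4, c="#d62728", marker="s", label="Gd-enhancing")
    ticks = range(0, N_CORD_LEVELS, 2)
    ax.set_yticks(list(ticks))
    ax.set_yticklabels([heatmap.levels[i] for i in ticks], fontsize=6)
    ax.set_xlabel("patients")
    ax.set_title(f"Spinal cord lesion occupancy — {heatmap.group}")
    fig.tight_layout()
    png_path = path.with_suffix(".png")
    fig.savefig(png_path, dpi=150)
    plt.close(fig)
    return png_path, cells_path
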