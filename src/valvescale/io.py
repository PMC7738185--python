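"""Readers and writers for the pipeline's on-disk formats.

Tabular time series and contours travel as CSV, intensity matrices as TSV,
images as 16-bit TIFF, and ground-truth / result sidecars as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from valvescale.assays import IntensityMatrix
from valvescale.biax import BiaxRecord
from valvescale.morphometry import SectionGeometry

BIAX_COLUMNS = [
    "t", "x1", "y1", "x2", "y2", "x3", "y3", "x4", "y4",
    "F_circ", "F_rad", "d_circ", "d_rad",
]


def write_biax_csv(record: BiaxRecord, path) -> None:
    """Write a biaxial record as CSV (marker coords mm, forces mN, rakes mm)."""
    cols = {"t": record.time_s}
    for m in range(4):
        cols[f"x{m + 1}"] = record.markers[:, m, 0]
        cols[f"y{m + 1}"] = record.markers[:, m, 1]
    cols["F_circ"] = record.force_circ_mN
    cols["F_rad"] = record.force_rad_mN
    cols["d_circ"] = record.rake_dist_circ_mm
    cols["d_rad"] = record.rake_dist_rad_mm
    df = pd.DataFrame(cols)
    df.to_csv(path, index=False)
    # stress-free reference marker positions travel in a JSON sidecar

    side = Path(str(path)).with_suffix(".ref.json")
    side.write_text(json.dumps({"reference_markers": record.reference_markers.tolist()}))


def read_biax_csv(path) -> BiaxRecord:
    df = pd.read_csv(path)
    side = Path(str(path)).with_suffix(".ref.json")
    ref = np.asarray(json.loads(side.read_text())["reference_markers"], float)
    markers = np.stack(
        [df[[f"x{m + 1}", f"y{m + 1}"]].to_numpy() for m in range(4)], axis=1
    )
    return BiaxRecord(
        reference_markers=ref,
        time_s=df["t"].to_numpy(),
        markers=markers,
        force_circ_mN=df["F_circ"].to_numpy(),
        force_rad_mN=df["F_rad"].to_numpy(),
        rake_dist_circ_mm=df["d_circ"].to_numpy(),
        rake_dist_rad_mm=df["d_rad"].to_numpy(),
    )


def write_contours_csv(section: SectionGeometry, path) -> None:
    a = pd.DataFrame(section.atrialis_mm, columns=["x_mm", "y_mm"])
    a["surface"] = "atrialis"
    v = pd.DataFrame(section.ventricularis_mm, columns=["x_mm", "y_mm"])
    v["surface"] = "ventricularis"
    pd.concat([a, v]).to_csv(path, index=False)


def read_contours_csv(path) -> SectionGeometry:
    df = pd.read_csv(path)
    return SectionGeometry(
        atrialis_mm=df[df.surface == "atrialis"][["x_mm", "y_mm"]].to_numpy(),
        ventricularis_mm=df[df.surface == "ventricularis"][["x_mm", "y_mm"]].to_numpy(),
    )


def write_intensity_tsv(matrix: IntensityMatrix, path, groups_path=None) -> None:
    matrix.intensities.to_csv(path, sep="\t")
    if groups_path is not None:
        matrix.groups.rename("group").to_csv(groups_path, sep="\t")


def read_intensity_tsv(path, groups_path) -> IntensityMatrix:
    X = pd.read_csv(path, sep="\t", index_col=0)
    g = pd.read_csv(groups_path, sep="\t", index_col=0)["group"]
    return IntensityMatrix(intensities=X, groups=g)


def write_image_tiff(image: np.ndarray, path) -> None:
    import tifffile

    arr = np.asarray(image)
    if arr.dtype == bool:
        arr = arr.astype(np.uint16) * 65535
    tifffile.imwrite(str(path), arr)


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(type(o))

    Path(str(path)).write_text(json.dumps(obj, indent=2, default=default))
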