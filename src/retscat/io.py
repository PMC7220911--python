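"""Disk formats: HDF5 dataset container, CSV boundary/metric tables.

Layout of the HDF5 container (one file per cohort):

    /eyes/<eye_id>                      attrs: group
    /eyes/<eye_id>/locations/<k>        attrs: quadrant, offset_x_um, offset_y_um
        bscan       (rows x cols)
        volume      (depth x theta_x x theta_y)   [volumes mode]
        planes/<layer>  (theta_x x theta_y)       [planes mode]
        raw         (n_k x theta_x x theta_y)     [raw spectra, optional]
        masks/<layer>   boolean exclusion masks   [optional]

Root attrs carry the master seed and the axial pixel sizes. Ground truth
travels separately as a flat CSV so it can be inspected without HDF5 tools.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import h5py
import numpy as np
import pandas as pd

from .config import OpticalConfig
from .layers import LayerBoundarySet
from .spectral import ScatteringVolume
from .synthetic import CohortDataset, CohortRecord, CohortSpec

__all__ = [
    "write_cohort_hdf5",
    "read_cohort_hdf5",
    "write_boundaries_csv",
    "read_boundaries_csv",
]


def write_cohort_hdf5(
    records: Iterable[CohortRecord],
    path: str | Path,
    cfg: OpticalConfig,
    seed: int | None = None,
) -> int:
    """Stream cohort records into the HDF5 container; returns record count."""
    n = 0
    with h5py.File(path, "w") as f:
        f.attrs["oct_axial_pixel"] = cfg.oct_axial_pixel
        f.attrs["alci_pixel_to_depth"] = cfg.alci_pixel_to_depth
        f.attrs["theta_span"] = cfg.theta_span
        f.attrs["center_wavelength"] = cfg.center_wavelength
        if seed is not None:
            f.attrs["seed"] = seed
        eyes = f.create_group("eyes")
        for rec in records:
            n += 1
            eye = eyes.require_group(rec.eye)
            eye.attrs["group"] = rec.group
            loc = eye.require_group(f"locations/{rec.location}")
            loc.attrs["quadrant"] = rec.quadrant
            loc.attrs["offset_x_um"] = rec.offset_um[0]
            loc.attrs["offset_y_um"] = rec.offset_um[1]
            if rec.bscan is not None:
                loc.create_dataset("bscan", data=rec.bscan)
            if rec.truth_bounds is not None:
                b = np.array([rec.truth_bounds.boundaries[l] for l in rec.truth_bounds.layers])
                d = loc.create_dataset("true_boundaries", data=b)
                d.attrs["layers"] = list(rec.truth_bounds.layers)
            if rec.volume is not None:
                loc.create_dataset("volume", data=rec.volume.intensity)
            if rec.planes is not None:
                pg = loc.create_group("planes")
                for layer, plane in rec.planes.items():
                    pg.create_dataset(layer, data=plane)
            if rec.artifacts:
                mg = loc.create_group("masks")
                for layer, fp in rec.artifacts.items():
                    mg.create_dataset(layer, data=fp.astype(bool))
    return n


def read_cohort_hdf5(path: str | Path, cfg: OpticalConfig | None = None,
                     spec: CohortSpec | None = None) -> CohortDataset:
    """Load a cohort container back into records (arrays in memory)."""
    records: list[CohortRecord] = []
    with h5py.File(path, "r") as f:
        if cfg is None:
            cfg = OpticalConfig(
                oct_axial_pixel=float(f.attrs["oct_axial_pixel"]),
                alci_pixel_to_depth=float(f.attrs["alci_pixel_to_depth"]),
                theta_span=float(f.attrs["theta_span"]),
                center_wavelength=float(f.attrs["center_wavelength"]),
            )
        for eye_id in sorted(f["eyes"]):
            eye = f["eyes"][eye_id]
            group = eye.attrs["group"]
            for k in sorted(eye["locations"], key=int):
                loc = eye["locations"][k]
                rec = CohortRecord(
                    eye=eye_id, group=str(group), location=int(k),
                    quadrant=str(loc.attrs["quadrant"]),
                    offset_um=(float(loc.attrs["offset_x_um"]),
                               float(loc.attrs["offset_y_um"])),
                    truth={},
                )
                if "bscan" in loc:
                    rec.bscan = loc["bscan"][()]
                if "true_boundaries" in loc:
                    d = loc["true_boundaries"]
                    layers = [str(x) for x in d.attrs["layers"]]
                    rec.truth_bounds = LayerBoundarySet(
                        boundaries={l: (int(t), int(b)) for l, (t, b) in zip(layers, d[()])},
                        oct_axial_pixel=cfg.oct_axial_pixel,
                    )
                if "volume" in loc:
                    n_t = loc["volume"].shape[1]
                    rec.volume = ScatteringVolume(
                        intensity=loc["volume"][()],
                        theta_x=(np.arange(n_t) - n_t / 2) * cfg.theta_span / n_t,
                        theta_y=(np.arange(loc["volume"].shape[2])
                                 - loc["volume"].shape[2] / 2)
                        * cfg.theta_span / loc["volume"].shape[2],
                        alci_pixel_to_depth=cfg.alci_pixel_to_depth,
                        provenance=(eye_id, k),
                    )
                if "planes" in loc:
                    rec.planes = {l: loc["planes"][l][()] for l in loc["planes"]}
                if "masks" in loc:
                    rec.artifacts = {l: loc["masks"][l][()].astype(bool)
                                     for l in loc["masks"]}
                records.append(rec)
    return CohortDataset(spec=spec, cfg=cfg, records=records, truth=pd.DataFrame())


def write_boundaries_csv(bounds_by_record: dict[tuple[str, int], LayerBoundarySet],
                         path: str | Path) -> None:
    """Export boundary sets as a flat CSV (eye, location, layer, top_px, bottom_px)."""
    rows = []
    for (eye, location), bounds in bounds_by_record.items():
        for layer, (top, bottom) in bounds.boundaries.items():
            rows.append(dict(eye=eye, location=location, layer=layer,
                             top_px=top, bottom_px=bottom))
    pd.DataFrame(rows).to_csv(path, index=False)


def read_boundaries_csv(path: str | Path, oct_axial_pixel: float
                        ) -> dict[tuple[str, int], LayerBoundarySet]:
    """Import externally supplied boundary tables (the manual-segmentation path)."""
    df = pd.read_csv(path)
    required = {"eye", "location", "layer", "top_px", "bottom_px"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"boundary CSV missing columns: {sorted(missing)}")
    out: dict[tuple[str, int], LayerBoundarySet] = {}
    for (eye, location), g in df.groupby(["eye", "location"]):
        boundaries = {row["layer"]: (int(row["top_px"]), int(row["bottom_px"]))
                      for _, row in g.iterrows()}
        out[(str(eye), int(location))] = LayerBoundarySet(
            boundaries=boundaries, oct_axial_pixel=oct_axial_pixel)
    return out
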