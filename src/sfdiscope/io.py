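"""Serialization: multi-page TIFF stacks with JSON sidecars, CSV tables.

Frames and maps travel as float32 TIFF; structured metadata (frame
indices, optical properties, calibration coefficients) travels in a JSON
sidecar next to the TIFF so a calibration is a reusable artifact across
runs.
"""

from __future__ import annotations

import json
import pathlib

import numpy as np
import tifffile

from .calibration import HeightCalibration, ReferenceCalibration
from .demod import ModulationMaps
from .optics import OpticalProperties
from .scene import FrameSet

__all__ = [
    "save_frameset",
    "load_frameset",
    "save_map",
    "load_map",
    "save_roi_mask",
    "save_reference_calibration",
    "load_reference_calibration",
    "save_height_calibration",
    "load_height_calibration",
    "write_spectrum_csv",
    "read_spectrum_csv",
]


def _tif_and_json(prefix) -> tuple[pathlib.Path, pathlib.Path]:
    prefix = pathlib.Path(prefix)
    return prefix.with_suffix(".tif"), prefix.with_suffix(".json")


def save_frameset(fs: FrameSet, prefix) -> pathlib.Path:
    """Write a FrameSet as multi-page TIFF + JSON page index."""
    tif, js = _tif_and_json(prefix)
    keys = sorted(fs.frames)
    pages = [fs.frames[k].astype(np.float32) for k in keys] + [
        fs.dark.astype(np.float32)
    ]
    tifffile.imwrite(tif, np.stack(pages), photometric="minisblack")
    js.write_text(
        json.dumps(
            {
                "pages": [
                    {"wavelength_nm": k[0], "frequency_cm": k[1], "phase_index": k[2]}
                    for k in keys
                ],
                "dark_page": len(keys),
                "exposure_s": fs.exposure_s,
            },
            indent=1,
        )
    )
    return tif


def load_frameset(prefix) -> FrameSet:
    tif, js = _tif_and_json(prefix)
    meta = json.loads(js.read_text())
    stack = tifffile.imread(tif).astype(float)
    frames = {}
    for page, entry in enumerate(meta["pages"]):
        key = (entry["wavelength_nm"], entry["frequency_cm"], entry["phase_index"])
        frames[key] = stack[page]
    return FrameSet(
        frames=frames, exposure_s=meta["exposure_s"], dark=stack[meta["dark_page"]]
    )


def save_map(img: np.ndarray, path) -> pathlib.Path:
    path = pathlib.Path(path)
    tifffile.imwrite(path, np.asarray(img, dtype=np.float32))
    return path


def load_map(path) -> np.ndarray:
    return tifffile.imread(path).astype(float)


def save_roi_mask(mask: np.ndarray, path) -> pathlib.Path:
    path = pathlib.Path(path)
    tifffile.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)))
    return path


def _op_to_json(op: OpticalProperties) -> dict:
    return {"mu_a": op.mu_a, "mu_s_prime": op.mu_s_prime, "wavelength": op.wavelength}


def _op_from_json(d: dict) -> OpticalProperties:
    return OpticalProperties(d["mu_a"], d["mu_s_prime"], d["wavelength"])


def save_reference_calibration(cal: ReferenceCalibration, prefix) -> pathlib.Path:
    tif, js = _tif_and_json(prefix)
    pages, index = [], []
    for wl, maps in sorted(cal.measured.items()):
        index.append({"wavelength_nm": wl, "kind": "m_dc", "page": len(pages)})
        pages.append(maps.m_dc.astype(np.float32))
        for f in maps.frequencies():
            index.append(
                {"wavelength_nm": wl, "kind": "m_ac", "frequency_cm": f, "page": len(pages)}
            )
            pages.append(maps.m_ac[f].astype(np.float32))
    tifffile.imwrite(tif, np.stack(pages), photometric="minisblack")
    js.write_text(
        json.dumps(
            {
                "kind": "reference_calibration",
                "reference_ops": {str(wl): _op_to_json(op) for wl, op in cal.reference_ops.items()},
                "index": index,
            },
            indent=1,
        )
    )
    return tif


def load_reference_calibration(prefix) -> ReferenceCalibration:
    tif, js = _tif_and_json(prefix)
    meta = json.loads(js.read_text())
    stack = tifffile.imread(tif).astype(float)
    measured: dict[float, ModulationMaps] = {}
    for entry in meta["index"]:
        wl = float(entry["wavelength_nm"])
        if wl not in measured:
            measured[wl] = ModulationMaps(m_ac={}, m_dc=None, wavelength=wl)
        if entry["kind"] == "m_dc":
            measured[wl].m_dc = stack[entry["page"]]
        else:
            measured[wl].m_ac[float(entry["frequency_cm"])] = stack[entry["page"]]
    ops = {float(wl): _op_from_json(d) for wl, d in meta["reference_ops"].items()}
    return ReferenceCalibration(reference_ops=ops, measured=measured)


def save_height_calibration(cal: HeightCalibration, prefix) -> pathlib.Path:
    tif, js = _tif_and_json(prefix)
    pages, index = [], []

    def add(kind: str, arr: np.ndarray, **extra):
        index.append({"kind": kind, "page": len(pages), **extra})
        pages.append(np.asarray(arr, dtype=np.float32))

    for wl, (slope, intercept) in sorted(cal.phase_fit.items()):
        add("phase_slope", slope, wavelength_nm=wl)
        add("phase_intercept", intercept, wavelength_nm=wl)
    for (wl, f), stack in sorted(cal.ref_amp.items()):
        for i, h in enumerate(cal.heights_mm):
            add("ref_amp", stack[i], wavelength_nm=wl, frequency_cm=f, height_mm=float(h))
    tifffile.imwrite(tif, np.stack(pages), photometric="minisblack")
    js.write_text(
        json.dumps(
            {
                "kind": "height_calibration",
                "heights_mm": list(map(float, cal.heights_mm)),
                "reference_ops": {str(wl): _op_to_json(op) for wl, op in cal.reference_ops.items()},
                "index": index,
            },
            indent=1,
        )
    )
    return tif


def load_height_calibration(prefix) -> HeightCalibration:
    tif, js = _tif_and_json(prefix)
    meta = json.loads(js.read_text())
    stack = tifffile.imread(tif).astype(float)
    heights = np.array(meta["heights_mm"])
    phase_fit: dict[float, list] = {}
    ref_amp_pages: dict[tuple[float, float], dict[float, np.ndarray]] = {}
    for entry in meta["index"]:
        wl = float(entry["wavelength_nm"])
        img = stack[entry["page"]]
        if entry["kind"] == "phase_slope":
            phase_fit.setdefault(wl, [None, None])[0] = img
        elif entry["kind"] == "phase_intercept":
            phase_fit.setdefault(wl, [None, None])[1] = img
        else:
            key = (wl, float(entry["frequency_cm"]))
            ref_amp_pages.setdefault(key, {})[float(entry["height_mm"])] = img
    ref_amp = {
        key: np.stack([by_h[h] for h in heights]) for key, by_h in ref_amp_pages.items()
    }
    ops = {float(wl): _op_from_json(d) for wl, d in meta["reference_ops"].items()}
    return HeightCalibration(
        heights_mm=heights,
        reference_ops=ops,
        phase_fit={wl: tuple(v) for wl, v in phase_fit.items()},
        ref_amp=ref_amp,
    )


def write_spectrum_csv(wavelengths_nm, counts, path) -> pathlib.Path:
    path = pathlib.Path(path)
    lines = ["wavelength_nm,counts"]
    for wl, c in zip(wavelengths_nm, counts):
        lines.append(f"{wl:g},{c:.6g}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_spectrum_csv(path):
    import pandas as pd

    df = pd.read_csv(path)
    return df["wavelength_nm"].to_numpy(float), df["counts"].to_numpy(float)
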