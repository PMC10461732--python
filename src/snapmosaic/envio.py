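"""File formats and configuration: ENVI cubes, TIFF snapshots, sensor YAML.

Hypercubes interchange as ENVI (ASCII ``.hdr`` header next to a raw binary
file): float32 BSQ is written; BSQ, BIL and BIP with common data types are
read.  Snapshots are 16-bit single-page TIFFs with a JSON sidecar recording
the value scale and the mosaic pattern.  Sensor descriptions are versioned
YAML holding the wavelength grid, ideal band specs, parasitic parameters
(or explicit measured curves), the mosaic assignment, and optionally an
explicit calibration matrix.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .mosaic import Hypercube, SnapshotMosaic
from .sensor import (
    CalibrationMatrix,
    IdealBandSpec,
    MosaicPattern,
    SensorModel,
    SpectralResponseMatrix,
    WavelengthGrid,
    build_response_matrix,
    compute_calibration_matrix,
    synthesize_measured_responses,
)

__all__ = [
    "read_envi",
    "write_envi",
    "read_snapshot",
    "write_snapshot",
    "load_sensor",
    "save_sensor",
    "default_sensor",
    "write_provenance",
]

_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32,
                5: np.float64, 12: np.uint16, 13: np.uint32}
_DTYPE_CODES = {np.dtype(np.float32): 4}


def _parse_envi_header(path: Path) -> dict:
    text = path.read_text()
    if not text.lstrip().upper().startswith("ENVI"):
        raise ValueError(f"{path} is not an ENVI header")
    fields: dict = {}
    key, buf, in_braces = None, "", False
    for line in text.splitlines()[1:]:
        if in_braces:
            buf += " " + line.strip()
            if "}" in line:
                fields[key] = buf.split("{", 1)[1].rsplit("}", 1)[0].strip()
                in_braces = False
            continue
        if "=" not in line:
            continue
        key, val = (p.strip() for p in line.split("=", 1))
        key = key.lower()
        if val.startswith("{") and "}" not in val:
            buf, in_braces = val, True
        elif val.startswith("{"):
            fields[key] = val.split("{", 1)[1].rsplit("}", 1)[0].strip()
        else:
            fields[key] = val
    return fields


def read_envi(header_path) -> Hypercube:
    """Read an ENVI cube (BSQ, BIL or BIP interleave) with its wavelengths."""
    header_path = Path(header_path)
    fields = _parse_envi_header(header_path)
    lines = int(fields["lines"])
    samples = int(fields["samples"])
    bands = int(fields["bands"])
    dtype = np.dtype(_ENVI_DTYPES[int(fields["data type"])])
    if int(fields.get("byte order", 0)) == 1:
        dtype = dtype.newbyteorder(">")
    interleave = fields.get("interleave", "bsq").lower()
    data_path = header_path.with_suffix(".raw")
    if not data_path.exists():
        for ext in (".img", ".dat", ""):
            cand = header_path.with_suffix(ext)
            if cand.exists() and cand != header_path:
                data_path = cand
                break
    raw = np.fromfile(data_path, dtype=dtype)
    if raw.size != lines * samples * bands:
        raise ValueError("ENVI data size does not match header dimensions")
    if interleave == "bsq":
        cube = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        cube = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        cube = raw.reshape(lines, samples, bands)
    else:
        raise ValueError(f"unsupported interleave {interleave!r}")
    if "wavelength" in fields:
        wl = np.array([float(v) for v in fields["wavelength"].split(",")])
    else:
        wl = np.arange(bands, dtype=np.float64)
    role = fields.get("snapmosaic role", "hr")
    return Hypercube(np.ascontiguousarray(cube, dtype=np.float32), wl, role)


def write_envi(cube: Hypercube, header_path) -> Path:
    """Write a cube as float32 BSQ ENVI; returns the header path."""
    header_path = Path(header_path)
    data_path = header_path.with_suffix(".raw")
    x, y, b = cube.shape
    data = np.ascontiguousarray(
        np.asarray(cube.data, dtype=np.float32).transpose(2, 0, 1)
    )
    data.tofile(data_path)
    wl = ", ".join(f"{v:.6f}" for v in cube.band_centers)
    header_path.write_text(
        "ENVI\n"
        f"samples = {y}\n"
        f"lines = {x}\n"
        f"bands = {b}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 4\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        f"snapmosaic role = {cube.role}\n"
        f"wavelength = {{ {wl} }}\n"
    )
    return header_path


def write_snapshot(snapshot: SnapshotMosaic, path, sensor_name: str = "sensor") -> Path:
    """Write a snapshot as 16-bit TIFF plus a JSON sidecar.

    Values are scaled to the uint16 range; the scale factor and the mosaic
    pattern are recorded in the sidecar so the round trip is lossless up to
    the 16-bit quantisation (exactly lossless for images already quantised).
    """
    path = Path(path)
    img = np.asarray(snapshot.image, dtype=np.float64)
    peak = img.max()
    scale = 65535.0 / peak if peak > 0 else 1.0
    quant = np.round(img * scale).astype(np.uint16)
    tifffile.imwrite(path, quant)
    sidecar = {
        "format_version": 1,
        "sensor": sensor_name,
        "scale": scale,
        "pattern_n": snapshot.pattern.n,
        "pattern_assignment": snapshot.pattern.assignment.tolist(),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_snapshot(path) -> SnapshotMosaic:
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"snapshot sidecar {sidecar_path} is missing; cannot recover the "
            "mosaic pattern or value scale"
        )
    sidecar = json.loads(sidecar_path.read_text())
    quant = tifffile.imread(path).astype(np.float64)
    image = quant / sidecar["scale"]
    pattern = MosaicPattern(
        sidecar["pattern_n"], np.array(sidecar["pattern_assignment"])
    )
    return SnapshotMosaic(image, pattern)


# ---------------------------------------------------------------------------
# Sensor description files
# ---------------------------------------------------------------------------

SENSOR_SCHEMA_VERSION = 1


def default_sensor(seed: int = 0) -> SensorModel:
    """Visible-range 4x4 snapshot sensor (16 measured bands, 470-620 nm,
    13 ideal bands), in the mould of a Ximea/imec 4x4 visible mosaic camera.

    Measured responses are synthesised from the ideal Lorentzians with mild
    cross-talk, one harmonic and a leakage floor; C is fitted by ridge
    least squares.
    """
    grid = WavelengthGrid.regular(440.0, 650.0, 1.0)
    ns_centers = np.linspace(470.0, 620.0, 16)
    ideal_centers = np.linspace(475.0, 615.0, 13)
    measured_specs = [
        IdealBandSpec(c, 0.55 + 0.3 * np.exp(-(((c - 545.0) / 80.0) ** 2)), 12.0)
        for c in ns_centers
    ]
    ideal_specs = [IdealBandSpec(c, 0.8, 15.0) for c in ideal_centers]
    nominal = build_response_matrix(grid, measured_specs)
    measured = synthesize_measured_responses(
        nominal, cross_talk=0.08, harmonic=0.05, leakage=0.01, seed=seed
    )
    ideal = build_response_matrix(grid, ideal_specs)
    calibration = compute_calibration_matrix(measured, ideal)
    return SensorModel(
        grid, measured, ideal, calibration, MosaicPattern.row_major(4),
        name="vis-4x4-default",
    )


def save_sensor(sensor: SensorModel, path) -> Path:
    path = Path(path)
    doc = {
        "schema_version": SENSOR_SCHEMA_VERSION,
        "name": sensor.name,
        "grid": {
            "start": float(sensor.grid.values[0]),
            "stop": float(sensor.grid.values[-1]),
            "step": float(sensor.grid.values[1] - sensor.grid.values[0]),
        },
        "measured_responses": sensor.measured.responses.tolist(),
        "ideal_responses": sensor.ideal.responses.tolist(),
        "mosaic": {
            "n": sensor.pattern.n,
            "assignment": sensor.pattern.assignment.tolist(),
        },
        "calibration": sensor.calibration.c.tolist(),
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def load_sensor(path) -> SensorModel:
    """Load a sensor description (YAML or JSON).

    Measured responses may be explicit curves or parasitic parameters to be
    synthesised; the calibration matrix is loaded when present, otherwise
    fitted by ridge least squares (recorded in the sensor name).
    """
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ValueError(f"malformed sensor file {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ValueError(f"sensor file {path} does not contain a mapping")
    for key in ("schema_version", "grid", "mosaic"):
        if key not in doc:
            raise ValueError(f"sensor file {path} is missing the {key!r} field")
    if int(doc["schema_version"]) != SENSOR_SCHEMA_VERSION:
        raise ValueError(
            f"unsupported sensor schema version {doc['schema_version']}"
        )
    g = doc["grid"]
    grid = WavelengthGrid.regular(float(g["start"]), float(g["stop"]), float(g["step"]))
    if "ideal_responses" in doc:
        ideal = SpectralResponseMatrix(np.array(doc["ideal_responses"]), grid)
    elif "ideal_bands" in doc:
        ideal_specs = [
            IdealBandSpec(float(b["lambda0"]), float(b["qe"]), float(b["fwhm"]))
            for b in doc["ideal_bands"]
        ]
        ideal = build_response_matrix(grid, ideal_specs)
    else:
        raise ValueError(f"sensor file {path} needs ideal_responses or ideal_bands")
    if "measured_responses" in doc:
        measured = SpectralResponseMatrix(np.array(doc["measured_responses"]), grid)
    elif "measured_bands" in doc:
        specs = [
            IdealBandSpec(float(b["lambda0"]), float(b["qe"]), float(b["fwhm"]))
            for b in doc["measured_bands"]
        ]
        nominal = build_response_matrix(grid, specs)
        par = doc.get("parasitics", {})
        measured = synthesize_measured_responses(
            nominal,
            cross_talk=float(par.get("cross_talk", 0.0)),
            harmonic=float(par.get("harmonic", 0.0)),
            leakage=float(par.get("leakage", 0.0)),
            seed=int(par.get("seed", 0)),
        )
    else:
        raise ValueError(
            f"sensor file {path} needs measured_responses or measured_bands"
        )
    mosaic = doc["mosaic"]
    pattern = MosaicPattern(int(mosaic["n"]), np.array(mosaic["assignment"]))
    name = str(doc.get("name", path.stem))
    if "calibration" in doc:
        calibration = CalibrationMatrix(np.array(doc["calibration"]))
    else:
        calibration = compute_calibration_matrix(measured, ideal)
        name += "+fitted-C"
    return SensorModel(grid, measured, ideal, calibration, pattern, name=name)


def write_provenance(path, config: dict, seeds: dict) -> Path:
    """Sidecar recording what produced an artifact: config hash, seeds,
    package version."""
    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str)
    doc = {
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "config": config,
        "seeds": seeds,
        "snapmosaic_version": __version__,
        "numpy_version": np.__version__,
    }
    path = Path(path)
    path.write_text(json.dumps(doc, indent=2, default=str))
    return path
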