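"""File formats: CSV chromatograms, mzML scan series, YAML configuration.

Chromatograms round-trip through plain CSV (``time_s`` plus one column
per species). Scan series are written as minimal profile-mode mzML
(64-bit little-endian arrays, no compression) readable by any mzML
consumer; the bundled reader handles that profile (plus zlib-compressed
and 32-bit variants) with the standard library only. Configuration is a
single YAML document whose sections mirror the parameter dataclasses;
unknown keys produce a warning rather than being dropped silently.
"""

from __future__ import annotations

import base64
import hashlib
import json
import struct
import warnings
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from .column import Chromatogram
from .ms import ScanSeries
from .smb import PAPER_RUN, SMBConfig
from .transport import ColumnParams, FluidProps, SpeciesParams

__all__ = [
    "write_chromatogram",
    "read_chromatogram",
    "write_mzml",
    "read_mzml",
    "load_config",
    "build_column",
    "build_fluid",
    "build_species",
    "build_smb_config",
    "write_manifest",
]


# ---------------------------------------------------------------------------
# CSV chromatograms


def write_chromatogram(chrom: Chromatogram, path: str | Path) -> Path:
    path = Path(path)
    chrom.to_frame().to_csv(path, index=False)
    return path


def read_chromatogram(path: str | Path) -> Chromatogram:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: missing required 'time_s' column")
    return Chromatogram.from_frame(df)


# ---------------------------------------------------------------------------
# mzML

_CV = {
    "ms_level": ("MS:1000511", "ms level"),
    "profile": ("MS:1000128", "profile spectrum"),
    "mz_array": ("MS:1000514", "m/z array"),
    "intensity_array": ("MS:1000515", "intensity array"),
    "f64": ("MS:1000523", "64-bit float"),
    "no_compression": ("MS:1000576", "no compression"),
    "scan_start": ("MS:1000016", "scan start time"),
}


def _cv(parent: ET.Element, key: str, value: str = "", unit: Optional[tuple[str, str]] = None):
    acc, name = _CV[key]
    attrs = {"cvRef": "MS", "accession": acc, "name": name, "value": value}
    if unit:
        attrs.update({"unitCvRef": "UO", "unitAccession": unit[0], "unitName": unit[1]})
    ET.SubElement(parent, "cvParam", attrs)


def _binary_array(parent: ET.Element, data: np.ndarray, kind: str) -> None:
    raw = np.asarray(data, dtype="<f8").tobytes()
    b64 = base64.b64encode(raw).decode("ascii")
    bda = ET.SubElement(parent, "binaryDataArray", {"encodedLength": str(len(b64))})
    _cv(bda, "f64")
    _cv(bda, "no_compression")
    _cv(bda, kind)
    ET.SubElement(bda, "binary").text = b64


def write_mzml(series: ScanSeries, path: str | Path) -> Path:
    """Write a scan series as minimal profile-mode mzML."""
    path = Path(path)
    root = ET.Element(
        "mzML",
        {
            "xmlns": "http://psi.hupo.org/ms/mzml",
            "version": "1.1.0",
        },
    )
    cvlist = ET.SubElement(root, "cvList", {"count": "2"})
    ET.SubElement(
        cvlist,
        "cv",
        {"id": "MS", "fullName": "Proteomics Standards Initiative Mass Spectrometry Ontology",
         "URI": "https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"},
    )
    ET.SubElement(
        cvlist, "cv", {"id": "UO", "fullName": "Unit Ontology",
                       "URI": "http://obo.cvs.sourceforge.net/obo/obo/ontology/phenotype/unit.obo"},
    )
    run = ET.SubElement(root, "run", {"id": "synthetic_run"})
    slist = ET.SubElement(run, "spectrumList", {"count": str(series.n_scans)})
    for i in range(series.n_scans):
        spec = ET.SubElement(
            slist,
            "spectrum",
            {
                "index": str(i),
                "id": f"scan={i + 1}",
                "defaultArrayLength": str(series.mz.size),
            },
        )
        _cv(spec, "ms_level", "1")
        _cv(spec, "profile")
        scan_list = ET.SubElement(spec, "scanList", {"count": "1"})
        scan = ET.SubElement(scan_list, "scan")
        _cv(
            scan,
            "scan_start",
            f"{series.scan_times[i] / 60.0:.9f}",
            unit=("UO:0000031", "minute"),
        )
        bdal = ET.SubElement(spec, "binaryDataArrayList", {"count": "2"})
        _binary_array(bdal, series.mz, "mz_array")
        _binary_array(bdal, series.intensities[i], "intensity_array")
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="utf-8")
    return path


def _decode_binary(bda: ET.Element, ns: str) -> np.ndarray:
    accs = {cv.get("accession") for cv in bda.findall(f"{ns}cvParam")}
    node = bda.find(f"{ns}binary")
    raw = base64.b64decode(node.text or "")
    if "MS:1000574" in accs:  # zlib compression
        import zlib

        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in accs else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path: str | Path) -> ScanSeries:
    """Read an mzML file (ours or any profile-mode file on a shared m/z grid)."""
    tree = ET.parse(path)
    root = tree.getroot()
    ns = root.tag[: root.tag.index("}") + 1] if root.tag.startswith("{") else ""
    times, mzs, intens = [], None, []
    for spec in root.iter(f"{ns}spectrum"):
        t = 0.0
        for cv in spec.iter(f"{ns}cvParam"):
            if cv.get("accession") == _CV["scan_start"][0]:
                t = float(cv.get("value", "0"))
                if cv.get("unitName", "minute") == "minute":
                    t *= 60.0
        times.append(t)
        arrays: dict[str, np.ndarray] = {}
        for bda in spec.iter(f"{ns}binaryDataArray"):
            accs = {cv.get("accession") for cv in bda.findall(f"{ns}cvParam")}
            data = _decode_binary(bda, ns)
            if _CV["mz_array"][0] in accs:
                arrays["mz"] = data
            elif _CV["intensity_array"][0] in accs:
                arrays["intensity"] = data
        if "mz" not in arrays or "intensity" not in arrays:
            raise ValueError(f"{path}: spectrum {spec.get('id')} lacks m/z or intensity array")
        if mzs is None:
            mzs = arrays["mz"]
        intens.append(arrays["intensity"])
    if mzs is None:
        raise ValueError(f"{path}: no spectra found")
    return ScanSeries(np.asarray(times), mzs, np.vstack(intens))


# ---------------------------------------------------------------------------
# YAML configuration

_KNOWN_SECTIONS = {"fluid", "column", "species", "smb", "plan", "ms"}
_KNOWN_KEYS = {
    "fluid": {"density", "viscosity"},
    "column": {
        "length_mm",
        "inner_diameter_mm",
        "particle_diameter_um",
        "interstitial_porosity",
        "particle_porosity",
        "n_cells",
        "dead_time_s",
    },
    "smb": {
        "diluent_flow",
        "extract_flow",
        "feed_flow",
        "raffinate_flow",
        "waste_flow",
        "switching_time",
    },
    "species": {"name", "molar_mass", "pore_access", "feed_conc", "diffusivity"},
}


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML config; warn about keys the schema does not know."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    for key in cfg:
        if key not in _KNOWN_SECTIONS:
            warnings.warn(f"config section {key!r} is not recognised and will be ignored")
    for section, known in _KNOWN_KEYS.items():
        entries = cfg.get(section)
        if entries is None:
            continue
        items = entries if isinstance(entries, list) else [entries]
        for item in items:
            for k in item:
                if k not in known:
                    warnings.warn(f"config key {section}.{k!r} is not recognised")
    return cfg


def build_fluid(cfg: dict[str, Any]) -> FluidProps:
    return FluidProps(**{k: v for k, v in cfg.get("fluid", {}).items() if k in _KNOWN_KEYS["fluid"]})


def build_column(cfg: dict[str, Any]) -> ColumnParams:
    return ColumnParams(
        **{k: v for k, v in cfg.get("column", {}).items() if k in _KNOWN_KEYS["column"]}
    )


def build_species(cfg: dict[str, Any]) -> list[SpeciesParams]:
    out = []
    for item in cfg.get("species", []):
        out.append(
            SpeciesParams(**{k: v for k, v in item.items() if k in _KNOWN_KEYS["species"]})
        )
    return out


def build_smb_config(cfg: dict[str, Any]) -> SMBConfig:
    section = cfg.get("smb")
    if not section:
        return PAPER_RUN
    return SMBConfig(**{k: v for k, v in section.items() if k in _KNOWN_KEYS["smb"]})


# ---------------------------------------------------------------------------
# run manifest


def write_manifest(
    out_dir: str | Path,
    config: dict[str, Any],
    seed: int,
    files: list[Path],
    timings: Optional[dict[str, float]] = None,
) -> Path:
    """JSON manifest: config snapshot, seed, versions, output checksums."""
    import musmb

    out_dir = Path(out_dir)
    entries = []
    for f in files:
        digest = hashlib.sha256(Path(f).read_bytes()).hexdigest()
        entries.append({"file": str(Path(f).name), "sha256": digest})
    manifest = {
        "package": "musmb",
        "version": getattr(musmb, "__version__", "unknown"),
        "numpy": np.__version__,
        "seed": seed,
        "config": config,
        "timings_s": timings or {},
        "outputs": entries,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
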