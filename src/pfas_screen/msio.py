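"""Reading and writing centroided LC-MS/MS runs, and ion-chromatogram extraction.

Runs are mzML 1.1.0 files.  Both directions are implemented here on top of
lxml: the writer emits a minimal but valid mzML document with uncompressed
64-bit little-endian binary arrays and standard controlled-vocabulary
accessions, and the reader parses compliant centroided mzML (64/32-bit float
arrays, plain or zlib-compressed) by CV accession, streaming spectrum by
spectrum.

Sample role (sample / blank / standard) and replicate index are not part of
mzML; they travel in a run-manifest CSV with columns
``sample_id,role,replicate,path``.
"""

from __future__ import annotations

import base64
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple
from xml.sax.saxutils import escape

import numpy as np
import pandas as pd
from lxml import etree

__all__ = [
    "CentroidSpectrum",
    "Run",
    "EIC",
    "RunSpec",
    "read_mzml",
    "write_mzml",
    "extract_eic",
    "ms2_for_precursor",
    "read_manifest",
    "write_manifest",
    "load_runs",
]

MS1_MZ_RANGE = (70.0, 1040.0)


@dataclass
class CentroidSpectrum:
    """A single centroided scan (MS1 full scan or MS2 product-ion spectrum)."""

    ms_level: int
    rt: float  # minutes
    mz: np.ndarray  # strictly increasing, Th
    intensity: np.ndarray
    precursor_mz: Optional[float] = None  # MS2 only
    isolation_halfwidth: Optional[float] = None  # Th, MS2 only
    collision_energies: Tuple[float, ...] = ()

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays differ in length")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("centroid m/z values must be strictly increasing")
        if self.ms_level == 2 and self.precursor_mz is None:
            raise ValueError("MS2 spectrum requires a precursor m/z")


@dataclass
class Run:
    """An RT-ordered list of spectra plus its sample identity."""

    spectra: List[CentroidSpectrum]
    sample_id: str
    role: str = "sample"  # sample | blank | standard
    replicate: int = 1

    def __post_init__(self) -> None:
        rts = [s.rt for s in self.spectra]
        if any(b < a for a, b in zip(rts, rts[1:])):
            raise ValueError("spectra must be in non-decreasing RT order")
        if not any(s.ms_level == 1 for s in self.spectra):
            raise ValueError("run contains no MS1 spectra")

    def ms1(self) -> List[CentroidSpectrum]:
        return [s for s in self.spectra if s.ms_level == 1]

    def ms2(self) -> List[CentroidSpectrum]:
        return [s for s in self.spectra if s.ms_level == 2]


@dataclass
class EIC:
    """Extracted ion chromatogram over a run's MS1 scans.

    ``mz_weight`` carries per-scan sum(m/z x intensity) inside the window so
    downstream peak integration can report an intensity-weighted mean m/z.
    """

    target_mz: float
    tol_ppm: float
    rt: np.ndarray  # minutes, one per MS1 scan
    intensity: np.ndarray
    mz_weight: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz_weight is None:
            self.mz_weight = self.target_mz * self.intensity
        self.mz_weight = np.asarray(self.mz_weight, dtype=float)
        if not (len(self.rt) == len(self.intensity) == len(self.mz_weight)):
            raise ValueError("EIC arrays must have equal lengths")


# ---------------------------------------------------------------------------
# mzML writing
# ---------------------------------------------------------------------------

def _b64(values: np.ndarray) -> str:
    return base64.b64encode(
        np.asarray(values, dtype="<f8").tobytes()
    ).decode("ascii")


def _binary_array(values: np.ndarray, kind: str) -> str:
    acc, name = (
        ("MS:1000514", "m/z array")
        if kind == "mz"
        else ("MS:1000515", "intensity array")
    )
    payload = _b64(values)
    unit = (
        ' unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"'
        if kind == "mz"
        else ""
    )
    return (
        f'<binaryDataArray encodedLength="{len(payload)}">'
        '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>'
        '<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>'
        f'<cvParam cvRef="MS" accession="{acc}" name="{name}" value=""{unit}/>'
        f"<binary>{payload}</binary></binaryDataArray>"
    )


def _spectrum_xml(index: int, s: CentroidSpectrum) -> str:
    parts = [
        f'<spectrum index="{index}" id="scan={index + 1}" '
        f'defaultArrayLength="{s.mz.size}">',
        f'<cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{s.ms_level}"/>',
        '<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>',
        '<cvParam cvRef="MS" accession="MS:1000129" name="negative scan" value=""/>',
        '<scanList count="1">'
        '<cvParam cvRef="MS" accession="MS:1000795" name="no combination" value=""/>'
        "<scan>"
        f'<cvParam cvRef="MS" accession="MS:1000016" name="scan start time" '
        f'value="{s.rt!r}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>'
        "</scan></scanList>",
    ]
    if s.ms_level == 2:
        half = s.isolation_halfwidth if s.isolation_halfwidth is not None else 0.5
        activation = "".join(
            f'<cvParam cvRef="MS" accession="MS:1000045" name="collision energy" '
            f'value="{ce!r}" unitCvRef="UO" unitAccession="UO:0000266" unitName="electronvolt"/>'
            for ce in (s.collision_energies or ())
        ) or '<cvParam cvRef="MS" accession="MS:1000133" name="collision-induced dissociation" value=""/>'
        parts.append(
            '<precursorList count="1"><precursor>'
            "<isolationWindow>"
            f'<cvParam cvRef="MS" accession="MS:1000827" name="isolation window target m/z" value="{s.precursor_mz!r}"/>'
            f'<cvParam cvRef="MS" accession="MS:1000828" name="isolation window lower offset" value="{half!r}"/>'
            f'<cvParam cvRef="MS" accession="MS:1000829" name="isolation window upper offset" value="{half!r}"/>'
            "</isolationWindow>"
            '<selectedIonList count="1"><selectedIon>'
            f'<cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{s.precursor_mz!r}"/>'
            "</selectedIon></selectedIonList>"
            f"<activation>{activation}</activation>"
            "</precursor></precursorList>"
        )
    parts.append(
        '<binaryDataArrayList count="2">'
        + _binary_array(s.mz, "mz")
        + _binary_array(s.intensity, "intensity")
        + "</binaryDataArrayList></spectrum>"
    )
    return "".join(parts)


_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
<cvList count="2">
<cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
<cv id="UO" fullName="Unit Ontology" URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>
</cvList>
<fileDescription><fileContent>
<cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
<cvParam cvRef="MS" accession="MS:1000580" name="MSn spectrum" value=""/>
</fileContent></fileDescription>
<softwareList count="1"><software id="pfas_screen" version="0"/></softwareList>
<instrumentConfigurationList count="1"><instrumentConfiguration id="IC1">
<cvParam cvRef="MS" accession="MS:1000031" name="instrument model" value=""/>
</instrumentConfigurationList_placeholder></instrumentConfigurationList>
<dataProcessingList count="1"><dataProcessing id="dp1"><processingMethod order="1" softwareRef="pfas_screen">
<cvParam cvRef="MS" accession="MS:1000544" name="Conversion to mzML" value=""/>
</processingMethod></dataProcessing></dataProcessingList>
"""


def write_mzml(path, spectra: Sequence[CentroidSpectrum], run_id: str = "run") -> None:
    """Write centroided spectra to a minimal mzML 1.1.0 document."""
    header = _MZML_HEADER.replace(
        "</instrumentConfigurationList_placeholder>", "</instrumentConfiguration>"
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        fh.write(
            f'<run id="{escape(run_id)}" defaultInstrumentConfigurationRef="IC1">\n'
            f'<spectrumList count="{len(spectra)}" defaultDataProcessingRef="dp1">\n'
        )
        for i, s in enumerate(spectra):
            fh.write(_spectrum_xml(i, s))
            fh.write("\n")
        fh.write("</spectrumList>\n</run>\n</mzML>\n")


# ---------------------------------------------------------------------------
# mzML reading
# ---------------------------------------------------------------------------

_NS = "{http://psi.hupo.org/ms/mzml}"

# CV accessions this reader acts on
_ACC_PROFILE = "MS:1000128"
_ACC_MS_LEVEL = "MS:1000511"
_ACC_SCAN_START = "MS:1000016"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"
_ACC_ISO_TARGET = "MS:1000827"
_ACC_ISO_LOWER = "MS:1000828"
_ACC_SELECTED_MZ = "MS:1000744"
_ACC_COLLISION_E = "MS:1000045"


def _cv_params(element) -> List[dict]:
    return [dict(cv.attrib) for cv in element.iter(_NS + "cvParam")]


def _decode_binary_array(bda) -> np.ndarray:
    dtype = "<f8"
    compressed = False
    for cv in _cv_params(bda):
        acc = cv.get("accession")
        if acc == _ACC_F32:
            dtype = "<f4"
        elif acc == _ACC_ZLIB:
            compressed = True
    node = bda.find(_NS + "binary")
    raw = base64.b64decode(node.text or "")
    if compressed:
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _parse_spectrum(path, idx: int, elem) -> CentroidSpectrum:
    rt = None
    level = 1
    for cv in _cv_params(elem):
        acc = cv.get("accession")
        if acc == _ACC_PROFILE:
            raise ValueError(
                f"{path}: spectrum index {idx} is profile mode; "
                "centroided data required"
            )
        elif acc == _ACC_MS_LEVEL:
            level = int(cv["value"])
        elif acc == _ACC_SCAN_START:
            rt = float(cv["value"])
            if "second" in (cv.get("unitName") or "").lower():
                rt /= 60.0
    if rt is None:
        raise ValueError(f"{path}: spectrum index {idx} lacks a scan start time")

    mz = inten = None
    for bda in elem.iter(_NS + "binaryDataArray"):
        accs = {cv.get("accession") for cv in _cv_params(bda)}
        if _ACC_MZ_ARRAY in accs:
            mz = _decode_binary_array(bda)
        elif _ACC_INT_ARRAY in accs:
            inten = _decode_binary_array(bda)
    if mz is None or inten is None:
        raise ValueError(f"{path}: spectrum index {idx} lacks m/z or intensity array")

    precursor_mz = None
    halfwidth = None
    energies: Tuple[float, ...] = ()
    if level >= 2:
        prec = elem.find(f"{_NS}precursorList/{_NS}precursor")
        if prec is not None:
            selected = None
            target = None
            ce: List[float] = []
            for cv in _cv_params(prec):
                acc = cv.get("accession")
                if acc == _ACC_ISO_TARGET:
                    target = float(cv["value"])
                elif acc == _ACC_ISO_LOWER:
                    halfwidth = float(cv["value"])
                elif acc == _ACC_SELECTED_MZ:
                    selected = float(cv["value"])
                elif acc == _ACC_COLLISION_E:
                    ce.append(float(cv["value"]))
            precursor_mz = target if target is not None else selected
            energies = tuple(ce)
    return CentroidSpectrum(
        ms_level=level,
        rt=rt,
        mz=mz,
        intensity=inten,
        precursor_mz=precursor_mz,
        isolation_halfwidth=halfwidth,
        collision_energies=energies,
    )


def read_mzml(
    path, sample_id: Optional[str] = None, role: str = "sample", replicate: int = 1
) -> Run:
    """Read a centroided mzML file into a :class:`Run`.

    Profile-mode spectra are rejected with the offending spectrum index, and a
    spectrum without a scan start time is an error: downstream peak picking
    needs a complete RT axis.
    """
    spectra: List[CentroidSpectrum] = []
    idx = 0
    for _, elem in etree.iterparse(str(path), tag=_NS + "spectrum"):
        spectra.append(_parse_spectrum(path, idx, elem))
        idx += 1
        elem.clear()
        while elem.getprevious() is not None:
            del elem.getparent()[0]
    return Run(
        spectra=spectra,
        sample_id=sample_id or Path(path).stem,
        role=role,
        replicate=replicate,
    )


# ---------------------------------------------------------------------------
# chromatogram extraction
# ---------------------------------------------------------------------------

def extract_eic(run: Run, target_mz: float, tol_ppm: float = 5.0) -> EIC:
    """Per-MS1-scan summed intensity within ``target_mz`` +/- tol_ppm.

    Scans with no centroid inside the window contribute zero.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    half = target_mz * tol_ppm * 1e-6
    lo, hi = target_mz - half, target_mz + half
    ms1 = run.ms1()
    rt = np.empty(len(ms1))
    inten = np.zeros(len(ms1))
    mzw = np.zeros(len(ms1))
    for i, s in enumerate(ms1):
        rt[i] = s.rt
        a = np.searchsorted(s.mz, lo, side="left")
        b = np.searchsorted(s.mz, hi, side="right")
        if b > a:
            inten[i] = s.intensity[a:b].sum()
            mzw[i] = (s.mz[a:b] * s.intensity[a:b]).sum()
    return EIC(target_mz=target_mz, tol_ppm=tol_ppm, rt=rt, intensity=inten, mz_weight=mzw)


def ms2_for_precursor(
    run: Run, mz: float, rt_window: Tuple[float, float]
) -> List[CentroidSpectrum]:
    """MS2 spectra whose isolation window covers ``mz`` within the RT window."""
    lo, hi = rt_window
    out = []
    for s in run.ms2():
        if not (lo <= s.rt <= hi):
            continue
        half = s.isolation_halfwidth if s.isolation_halfwidth is not None else 0.5
        if abs(s.precursor_mz - mz) <= half:
            out.append(s)
    return out


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunSpec:
    sample_id: str
    role: str
    replicate: int
    path: str


def read_manifest(path) -> List[RunSpec]:
    df = pd.read_csv(path)
    required = {"sample_id", "role", "replicate", "path"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest {path} must have columns {sorted(required)}")
    return [
        RunSpec(
            sample_id=str(r.sample_id),
            role=str(r.role),
            replicate=int(r.replicate),
            path=str(r.path),
        )
        for r in df.itertuples()
    ]


def write_manifest(path, specs: Sequence[RunSpec]) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "role": s.role,
                "replicate": s.replicate,
                "path": s.path,
            }
            for s in specs
        ]
    ).to_csv(path, index=False)


def load_runs(manifest_path) -> List[Run]:
    """Read every run named in a manifest; relative paths resolve against it."""
    base = Path(manifest_path).parent
    runs = []
    for spec in read_manifest(manifest_path):
        p = Path(spec.path)
        if not p.is_absolute():
            p = base / p
        runs.append(
            read_mzml(p, sample_id=spec.sample_id, role=spec.role, replicate=spec.replicate)
        )
    return runs
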