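"""Reading identification tables and mzML runs; writing the ``.list`` tables.

Identification tables come in several tab-separated dialects (pGlyco3,
Byonic, MSFragger-Glyco). Each dialect is a documented column map onto the
package's normalized *native* dialect, which is the single internal currency:

====================  =============================================
native column         content
====================  =============================================
run_id                run identifier
spectrum_ref          spectrum title / scan reference
peptide               amino-acid sequence (J = glycosylated Asn)
modifications         ``pos,Name,mass`` triples joined by ``;`` (may be empty)
glycan                composition string, e.g. ``H(5)N(4)A(2)``
glycan_structure      optional canonical structure string
glycosite             1-based residue index
charge                precursor charge
precursor_mz          precursor m/z
precursor_mass        neutral monoisotopic mass (Da)
rt                    retention time (minutes)
protein               protein accession(s)
====================  =============================================
"""

from __future__ import annotations

import base64
import os
import re
import struct
import xml.etree.ElementTree as ET
import zlib
from collections import defaultdict

import numpy as np
import pandas as pd

from .constants import GLYCAN_LETTER_CODES, PROTON_MASS
from .model import GPSM, QuantMatrix, Run, Scan

NATIVE_COLUMNS = [
    "run_id",
    "spectrum_ref",
    "peptide",
    "modifications",
    "glycan",
    "glycan_structure",
    "glycosite",
    "charge",
    "precursor_mz",
    "precursor_mass",
    "rt",
    "protein",
]

_WORD_TOKEN = re.compile(r"(Hex(?:NAc)?|Neu[AG]c|Fuc|dHex)\[(\d+)\]")
_LETTER_TOKEN = re.compile(r"([HNAGF])\((\d+)\)")


def parse_glycan_composition(text: str) -> dict[str, int]:
    """Parse ``H(5)N(4)A(2)`` or ``Hex[5]HexNAc[4]NeuAc[2]`` into counts.

    Returns canonical keys {Hex, HexNAc, NeuAc, NeuGc, Fuc}; keys with zero
    count are omitted.
    """
    text = (text or "").strip()
    if not text:
        raise ValueError("empty glycan composition string")
    counts: dict[str, int] = {}
    if "[" in text:
        matches = list(_WORD_TOKEN.finditer(text))
        consumed = "".join(m.group(0) for m in matches)
        if consumed.replace(" ", "") != text.replace(" ", ""):
            raise ValueError(f"unparseable glycan composition {text!r}")
        for m in matches:
            name = {"dHex": "Fuc"}.get(m.group(1), m.group(1))
            counts[name] = counts.get(name, 0) + int(m.group(2))
    else:
        matches = list(_LETTER_TOKEN.finditer(text))
        consumed = "".join(m.group(0) for m in matches)
        if consumed.replace(" ", "") != text.replace(" ", ""):
            raise ValueError(f"unparseable glycan composition {text!r}")
        for m in matches:
            name = GLYCAN_LETTER_CODES[m.group(1)]
            counts[name] = counts.get(name, 0) + int(m.group(2))
    if not counts or not any(counts.values()):
        raise ValueError(f"glycan composition {text!r} has no residues")
    return {k: v for k, v in counts.items() if v}


def format_glycan_composition(counts: dict[str, int]) -> str:
    """Write composition counts in the letter notation, canonical key order."""
    inverse = {v: k for k, v in GLYCAN_LETTER_CODES.items()}
    order = ["Hex", "HexNAc", "NeuAc", "NeuGc", "Fuc"]
    return "".join(f"{inverse[k]}({counts[k]})" for k in order if counts.get(k))


def _parse_modifications(text: str) -> list[tuple[int, str, float]]:
    mods = []
    for token in filter(None, (text or "").split(";")):
        pos, name, mass = token.split(",")
        mods.append((int(pos), name, float(mass)))
    return mods


def _format_modifications(mods: list[tuple[int, str, float]]) -> str:
    return ";".join(f"{p},{n},{m:.6f}" for p, n, m in mods)


# dialect -> native-column -> source column; callables post-process the frame
_DIALECT_MAPS: dict[str, dict[str, str]] = {
    "pglyco3": {
        "spectrum_ref": "GlySpec",
        "peptide": "Peptide",
        "modifications": "Mod",
        "glycan": "Glycan(H,N,A,G,F)",
        "glycan_structure": "PlausibleStruct",
        "glycosite": "GlySite",
        "charge": "Charge",
        "precursor_mz": "PrecursorMZ",
        "precursor_mass": "PrecursorMH",
        "rt": "RT",
        "protein": "Proteins",
        "run_id": "RawName",
    },
    "byonic": {
        "spectrum_ref": "Scan #",
        "peptide": "Peptide",
        "modifications": "Modification Type(s)",
        "glycan": "Glycans",
        "glycosite": "Glycan Position",
        "charge": "z",
        "precursor_mz": "m/z",
        "rt": "Scan Time",
        "protein": "Protein Name",
        "run_id": "Raw File",
    },
    "msfragger": {
        "spectrum_ref": "Spectrum",
        "peptide": "Peptide",
        "modifications": "Assigned Modifications",
        "glycan": "Total Glycan Composition",
        "glycosite": "Glycan Site",
        "charge": "Charge",
        "precursor_mz": "Precursor m/z",
        "rt": "Retention",
        "protein": "Protein",
        "run_id": "Spectrum File",
    },
}

# pGlyco3 RT is in seconds; MSFragger Retention likewise
_RT_IN_SECONDS = {"pglyco3", "msfragger"}


def parse_identifications(path: str, dialect: str = "native") -> list[GPSM]:
    """Read a tab-separated identification table into GPSM records.

    Rows are taken as given: no FDR re-filtering is applied. Unknown dialects
    raise a configuration error; a missing mandatory column raises a parse
    error naming the column.
    """
    if dialect not in {"native", *_DIALECT_MAPS}:
        raise ValueError(f"unknown identification dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if dialect == "native":
        colmap = {c: c for c in NATIVE_COLUMNS}
    else:
        colmap = _DIALECT_MAPS[dialect]
    mandatory = ["peptide", "glycan", "glycosite", "charge", "rt"]
    for native_col in mandatory:
        src = colmap.get(native_col)
        if src is None or src not in df.columns:
            raise ValueError(
                f"dialect {dialect!r}: missing mandatory column "
                f"{src or native_col!r}"
            )
    gpsms: list[GPSM] = []
    for _, row in df.iterrows():

        def get(native_col: str, default: str = "") -> str:
            src = colmap.get(native_col)
            return row[src] if src in row.index else default

        composition = parse_glycan_composition(get("glycan"))
        charge = int(float(get("charge")))
        rt = float(get("rt"))
        if dialect in _RT_IN_SECONDS:
            rt /= 60.0
        mz_text = get("precursor_mz")
        mass_text = get("precursor_mass")
        precursor_mz = float(mz_text) if mz_text else 0.0
        if mass_text:
            mass = float(mass_text)
            if dialect == "pglyco3":  # PrecursorMH is the MH+ mass
                mass -= PROTON_MASS
        elif precursor_mz:
            mass = (precursor_mz - PROTON_MASS) * charge
        else:
            raise ValueError("row lacks both precursor m/z and mass")
        if not precursor_mz:
            precursor_mz = mass / charge + PROTON_MASS
        structure = get("glycan_structure") or None
        gpsms.append(
            GPSM(
                run_id=get("run_id") or os.path.splitext(os.path.basename(path))[0],
                spectrum_ref=get("spectrum_ref"),
                peptide=get("peptide"),
                modifications=_parse_modifications(get("modifications")),
                glycan_composition=composition,
                glycan_structure=structure,
                glycosite=int(float(get("glycosite"))),
                charge=charge,
                precursor_mz=precursor_mz,
                precursor_mass=mass,
                rt=rt,
                protein=get("protein"),
            )
        )
    return gpsms


def write_identifications(gpsms: list[GPSM], path: str) -> None:
    """Write GPSMs as a native-dialect table (inverse of the native reader)."""
    rows = []
    for g in gpsms:
        rows.append(
            {
                "run_id": g.run_id,
                "spectrum_ref": g.spectrum_ref,
                "peptide": g.peptide,
                "modifications": _format_modifications(g.modifications),
                "glycan": format_glycan_composition(g.glycan_composition),
                "glycan_structure": g.glycan_structure or "",
                "glycosite": g.glycosite,
                "charge": g.charge,
                "precursor_mz": repr(g.precursor_mz),
                "precursor_mass": repr(g.precursor_mass),
                "rt": repr(g.rt),
                "protein": g.protein,
            }
        )
    pd.DataFrame(rows, columns=NATIVE_COLUMNS).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


# ---------------------------------------------------------------------------
# mzML
# ---------------------------------------------------------------------------


def _strip_ns(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _cv_params(element: ET.Element) -> dict[str, dict]:
    out = {}
    for child in element:
        if _strip_ns(child.tag) == "cvParam":
            out[child.get("name")] = dict(child.attrib)
    return out


def _decode_array(array_el: ET.Element) -> np.ndarray:
    params = _cv_params(array_el)
    binary = None
    for child in array_el:
        if _strip_ns(child.tag) == "binary":
            binary = child.text or ""
    raw = base64.b64decode(binary)
    if "zlib compression" in params:
        raw = zlib.decompress(raw)
    dtype = "<f4" if "32-bit float" in params else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _parse_spectrum(spec_el: ET.Element) -> Scan:
    scan_id = spec_el.get("id", "")
    params = _cv_params(spec_el)
    if "ms level" not in params:
        raise ValueError(f"scan {scan_id!r} lacks an ms level")
    ms_level = int(params["ms level"]["value"])
    rt = None
    precursor = None
    mz = intensity = None
    for child in spec_el.iter():
        tag = _strip_ns(child.tag)
        if tag == "scan":
            scan_params = _cv_params(child)
            if "scan start time" in scan_params:
                attrs = scan_params["scan start time"]
                rt = float(attrs["value"])
                if attrs.get("unitName") == "second":
                    rt /= 60.0
        elif tag == "precursor":
            parent = child.get("spectrumRef", "")
            pmz, pcharge = 0.0, 0
            for ion in child.iter():
                if _strip_ns(ion.tag) == "selectedIon":
                    ion_params = _cv_params(ion)
                    if "selected ion m/z" in ion_params:
                        pmz = float(ion_params["selected ion m/z"]["value"])
                    if "charge state" in ion_params:
                        pcharge = int(ion_params["charge state"]["value"])
            precursor = (pmz, pcharge, parent)
        elif tag == "binaryDataArray":
            arr_params = _cv_params(child)
            if "m/z array" in arr_params:
                mz = _decode_array(child)
            elif "intensity array" in arr_params:
                intensity = _decode_array(child)
    if rt is None:
        raise ValueError(f"scan {scan_id!r} lacks a retention time")
    if mz is None or intensity is None:
        raise ValueError(f"scan {scan_id!r} lacks peak arrays")
    return Scan(
        scan_id=scan_id,
        ms_level=ms_level,
        rt=rt,
        mz=mz,
        intensity=intensity,
        precursor=precursor,
    )


def read_mzml(path: str) -> Run:
    """Read a centroided mzML file into a Run.

    Understands the standard vocabulary subset: ms level, scan start time
    (minute or second units), precursor selected ions, and 32/64-bit binary
    peak arrays with or without zlib compression.
    """
    run_id = os.path.splitext(os.path.basename(path))[0]
    scans: list[Scan] = []
    try:
        for event, element in ET.iterparse(path, events=("end",)):
            if _strip_ns(element.tag) == "spectrum":
                scans.append(_parse_spectrum(element))
                element.clear()
    except ET.ParseError as exc:
        raise ValueError(f"malformed mzML {path!r}: {exc}") from exc
    return Run(run_id=run_id, scans=scans)


def _encode_array(values: np.ndarray) -> str:
    raw = struct.pack(f"<{len(values)}d", *map(float, values))
    return base64.b64encode(zlib.compress(raw)).decode("ascii")


def _cv(parent: ET.Element, accession: str, name: str, value: str = "", **extra):
    attrs = {"cvRef": "MS", "accession": accession, "name": name, "value": value}
    attrs.update(extra)
    ET.SubElement(parent, "cvParam", attrs)


def write_mzml(run: Run, path: str) -> None:
    """Write a Run as a minimal centroided mzML document.

    Emits the subset of the PSI mzML vocabulary needed for round-tripping
    through standard readers: ms level, scan start time (minutes), precursor
    selected-ion metadata, and zlib-compressed 64-bit m/z / intensity arrays.
    """
    root = ET.Element(
        "mzML",
        {
            "xmlns": "http://psi.hupo.org/ms/mzml",
            "version": "1.1.0",
            "id": run.run_id,
        },
    )
    cvlist = ET.SubElement(root, "cvList", {"count": "1"})
    ET.SubElement(
        cvlist,
        "cv",
        {
            "id": "MS",
            "fullName": "Proteomics Standards Initiative Mass Spectrometry Ontology",
            "URI": "https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
        },
    )
    run_el = ET.SubElement(root, "run", {"id": run.run_id})
    spectrum_list = ET.SubElement(
        run_el, "spectrumList", {"count": str(len(run.scans))}
    )
    for index, scan in enumerate(run.scans):
        spec = ET.SubElement(
            spectrum_list,
            "spectrum",
            {
                "index": str(index),
                "id": scan.scan_id,
                "defaultArrayLength": str(len(scan.mz)),
            },
        )
        _cv(spec, "MS:1000511", "ms level", str(scan.ms_level))
        _cv(spec, "MS:1000127", "centroid spectrum")
        scan_list = ET.SubElement(spec, "scanList", {"count": "1"})
        _cv(scan_list, "MS:1000795", "no combination")
        scan_el = ET.SubElement(scan_list, "scan")
        _cv(
            scan_el,
            "MS:1000016",
            "scan start time",
            repr(scan.rt),
            unitCvRef="UO",
            unitAccession="UO:0000031",
            unitName="minute",
        )
        if scan.precursor is not None:
            pmz, pcharge, parent = scan.precursor
            plist = ET.SubElement(spec, "precursorList", {"count": "1"})
            prec_attrs = {"spectrumRef": parent} if parent else {}
            prec = ET.SubElement(plist, "precursor", prec_attrs)
            silist = ET.SubElement(prec, "selectedIonList", {"count": "1"})
            ion = ET.SubElement(silist, "selectedIon")
            _cv(ion, "MS:1000744", "selected ion m/z", repr(pmz))
            if pcharge:
                _cv(ion, "MS:1000041", "charge state", str(pcharge))
        arrays = ET.SubElement(spec, "binaryDataArrayList", {"count": "2"})
        for accession, name, values in (
            ("MS:1000514", "m/z array", scan.mz),
            ("MS:1000515", "intensity array", scan.intensity),
        ):
            encoded = _encode_array(values)
            arr = ET.SubElement(
                arrays, "binaryDataArray", {"encodedLength": str(len(encoded))}
            )
            _cv(arr, "MS:1000523", "64-bit float")
            _cv(arr, "MS:1000574", "zlib compression")
            _cv(arr, accession, name)
            ET.SubElement(arr, "binary").text = encoded
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, xml_declaration=True, encoding="utf-8")


# ---------------------------------------------------------------------------
# .list outputs
# ---------------------------------------------------------------------------

LIST_FILES = [
    "spectra.list",
    "modification.list",
    "site.list",
    "protein.list",
    "glycan_occupancy.list",
    "site_occupancy.list",
]


def _matrix_frame(matrix: QuantMatrix, key_fn, key_cols: list[str]) -> pd.DataFrame:
    """Aggregate record intensities by key and pivot run/channel columns."""
    cells: dict[tuple, dict[str, float]] = defaultdict(dict)
    meta: dict[tuple, dict[str, str]] = {}
    for rec in matrix.records:
        if not rec.accepted:
            continue
        key = key_fn(rec)
        cells[key][rec.channel] = cells[key].get(rec.channel, 0.0) + rec.intensity
        meta.setdefault(key, dict(zip(key_cols, map(str, key))))
    rows = []
    for key in sorted(cells, key=lambda k: tuple(map(str, k))):
        row = dict(meta[key])
        for col in matrix.columns:
            value = cells[key].get(col)
            row[col] = repr(value) if value is not None else ""
        rows.append(row)
    return pd.DataFrame(rows, columns=key_cols + matrix.columns)


def _mods_str(rec) -> str:
    return _format_modifications(rec.gpsm.modifications)


def _glycan_str(rec) -> str:
    return format_glycan_composition(rec.gpsm.glycan_composition)


def write_list_tables(matrix: QuantMatrix, out_dir: str) -> list[str]:
    """Write the six tab-separated ``.list`` result tables.

    All aggregations are sums of spectrum intensities; ``spectra.list`` is the
    per-GPSM base table, the rest are pure roll-ups, so per-protein totals are
    identical across levels.
    """
    os.makedirs(out_dir, exist_ok=True)
    levels = {
        "spectra.list": (
            lambda r: (r.gpsm.run_id, r.gpsm.spectrum_ref, r.gpsm.peptide,
                       _glycan_str(r), r.gpsm.charge, r.origin),
            ["source_run", "spectrum_ref", "peptide", "glycan", "charge", "origin"],
        ),
        "modification.list": (
            lambda r: (r.gpsm.peptide, _mods_str(r), _glycan_str(r)),
            ["peptide", "modifications", "glycan"],
        ),
        "site.list": (
            lambda r: (r.gpsm.protein, r.gpsm.glycosite, _glycan_str(r)),
            ["protein", "glycosite", "glycan"],
        ),
        "protein.list": (
            lambda r: (r.gpsm.protein,),
            ["protein"],
        ),
        "glycan_occupancy.list": (
            lambda r: (r.gpsm.protein, r.gpsm.glycosite, _glycan_str(r)),
            ["protein", "glycosite", "glycan"],
        ),
        "site_occupancy.list": (
            lambda r: (r.gpsm.protein, _glycan_str(r), r.gpsm.glycosite),
            ["protein", "glycan", "glycosite"],
        ),
    }
    written = []
    for filename, (key_fn, key_cols) in levels.items():
        frame = _matrix_frame(matrix, key_fn, key_cols)
        path = os.path.join(out_dir, filename)
        frame.to_csv(path, sep="\t", index=False, lineterminator="\n")
        written.append(path)
    return written
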