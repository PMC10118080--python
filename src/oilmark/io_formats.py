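"""Readers and writers for the formats the pipeline touches.

Three formats are supported: per-sample feature tables as CSV, a minimal
XML dialect of the Compound Exchange Format (CEF) carrying one ``<Compound>``
element per molecular feature, and the tab-separated marker-library table
(one row per library marker, five MS/MS fragments each).

The CEF dialect is deliberately small: only the attributes needed to carry
(m/z, RT, height, quality, abundance) are read or written; unknown elements
are ignored with a logged warning.  m/z values are written with 4 decimal
places, matching the precision of the marker library.
"""

from __future__ import annotations

import json
import logging
import xml.etree.ElementTree as ET
from importlib import resources
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .types import FEATURE_COLUMNS, MarkerRecord, MixtureSpec, Sample, as_feature_table

log = logging.getLogger(__name__)

PathLike = Union[str, Path]

_CSV_REQUIRED = ["mz", "rt_min", "height"]


# ---------------------------------------------------------------- feature CSV

def read_feature_csv(path: PathLike, **sample_meta) -> Sample:
    """Read a per-sample feature table (columns mz, rt_min, height[, quality,
    abundance]) into a :class:`Sample`.

    Raises ``ValueError`` naming the offending column/row on missing columns
    or non-numeric cells.
    """
    df = pd.read_csv(path)
    missing = [c for c in _CSV_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    present = [c for c in FEATURE_COLUMNS if c in df.columns]
    for col in present:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in column "
                f"{col!r} at data row {row}"
            )
        df[col] = coerced
    meta = {"id": Path(path).stem, **sample_meta}
    return Sample(features=as_feature_table(df), **meta)


def write_feature_csv(sample: Sample, path: PathLike) -> None:
    df = sample.features.copy()
    df["mz"] = df["mz"].round(4)
    df.to_csv(path, index=False, lineterminator="\n", float_format="%.6g")


# ------------------------------------------------------------------ CEF XML

def read_cef(path: PathLike, **sample_meta) -> Sample:
    """Read a minimal CEF-dialect XML file: one Feature per <Compound>.

    Each compound must carry a <Location> element with m/z and RT attributes
    (``m``/``mz`` and ``rt``); height is ``y``/``height``, abundance
    ``v``/``abundance``, quality ``q``/``quality``.  Compounds without a
    height are skipped with a warning; malformed XML raises with the parser's
    line/column position.
    """
    try:
        tree = ET.parse(str(path))
    except ET.ParseError as e:
        raise ET.ParseError(f"{path}: malformed XML at line:column {e.position}") from e
    root = tree.getroot()
    rows = []
    for comp in root.iter("Compound"):
        loc = comp.find("Location")
        if loc is None:
            log.warning("%s: <Compound> without <Location> skipped", path)
            continue
        a = loc.attrib

        def get(*names):
            for n in names:
                if n in a:
                    return float(a[n])
            return None

        mz, rt, height = get("m", "mz"), get("rt",), get("y", "height")
        if mz is None or rt is None or height is None:
            log.warning("%s: compound missing m/z, rt or height skipped", path)
            continue
        rows.append(
            {
                "mz": mz,
                "rt_min": rt,
                "height": height,
                "quality": get("q", "quality") if get("q", "quality") is not None else 100.0,
                "abundance": get("v", "abundance") if get("v", "abundance") is not None else 100.0 * height,
            }
        )
    for child in root:
        if child.tag != "CompoundList":
            log.warning("%s: unknown element <%s> ignored", path, child.tag)
    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS) if rows else None
    meta = {"id": Path(path).stem, **sample_meta}
    if df is None:
        return Sample(**meta)
    return Sample(features=as_feature_table(df), **meta)


def write_cef(sample: Sample, path: PathLike) -> None:
    root = ET.Element("CEF", version="1.0.0")
    clist = ET.SubElement(root, "CompoundList")
    for _, r in sample.features.iterrows():
        comp = ET.SubElement(clist, "Compound")
        ET.SubElement(
            comp,
            "Location",
            m=f"{r.mz:.4f}",
            rt=f"{r.rt_min:.4f}",
            y=f"{r.height:.6g}",
            v=f"{r.abundance:.6g}",
            q=f"{r.quality:.6g}",
        )
    ET.ElementTree(root).write(str(path), xml_declaration=True, encoding="unicode")


# ------------------------------------------------------------- marker library

def _parse_flag(v) -> bool:
    s = str(v).strip()
    if s in {"+", "1", "True", "true"}:
        return True
    if s in {"-", "0", "False", "false"}:
        return False
    raise ValueError(f"unrecognised detectability flag {v!r}")


def read_marker_library(path: PathLike | None = None) -> list[MarkerRecord]:
    """Read a marker-library TSV; with no path, the packaged library of the
    29 seed-oil markers (sunflower/rapeseed/sesame/flax) is loaded.

    Rejects duplicate marker numbers and fragments at or above the precursor.
    """
    if path is None:
        with resources.as_file(
            resources.files("oilmark").joinpath("data/table1_markers.tsv")
        ) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    if df["no"].duplicated().any():
        dupes = sorted(df.loc[df["no"].duplicated(), "no"])
        raise ValueError(f"duplicate marker number(s) {dupes}")
    records = []
    for _, r in df.iterrows():
        frags = tuple(
            float(r[f"ms2_{i}"]) for i in range(1, 6) if pd.notna(r.get(f"ms2_{i}"))
        )
        records.append(
            MarkerRecord(
                oil=str(r["oil"]),
                number=int(r["no"]),
                precursor_mz=float(r["mz"]),
                rt_mean=float(r["rt"]),
                rt_tol=float(r["rt_tol"]),
                fragments=frags,
                collision_energy=float(r["ce"]),
                detect_1pct=_parse_flag(r["det1"]),
                detect_5pct=_parse_flag(r["det5"]),
            )
        )
    return records


def write_marker_library(markers: list[MarkerRecord], path: PathLike) -> None:
    rows = []
    for m in markers:
        row = {
            "oil": m.oil,
            "no": m.number,
            "mz": f"{m.precursor_mz:.4f}",
            "rt": m.rt_mean,
            "rt_tol": m.rt_tol,
        }
        for i in range(5):
            row[f"ms2_{i + 1}"] = f"{m.fragments[i]:.4f}" if i < len(m.fragments) else ""
        row["ce"] = m.collision_energy
        row["det1"] = "+" if m.detect_1pct else "-"
        row["det5"] = "+" if m.detect_5pct else "-"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


# ----------------------------------------------------------- bioassay fixture

def read_bioactivity_table(path: PathLike | None = None) -> pd.DataFrame:
    """Load the packaged per-producer bioactivity summary table.

    One row per oil sample (4 species x 4 producers) with TEAC, TPC and TCC
    replicate means and SDs (n = 3) plus the published homogeneous-group
    letters.  TPC "nd" (phenolics not detected) is parsed as mean 0, sd 0
    with ``tpc_nd = True``.
    """
    if path is None:
        with resources.as_file(
            resources.files("oilmark").joinpath("data/table2_bioactivity.tsv")
        ) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    df["tpc_nd"] = df["tpc_mean"].astype(str).str.strip() == "nd"
    for col in ["tpc_mean", "tpc_sd"]:
        df[col] = pd.to_numeric(df[col], errors="coerce").fillna(0.0)
    return df


# -------------------------------------------------------------- JSON manifest

def _sample_record(s: Sample, features_path: str) -> dict:
    rec = {
        "id": s.id,
        "species": s.species,
        "producer": s.producer,
        "batch": s.batch,
        "role": s.role,
        "features": features_path,
    }
    if s.mixture is not None:
        rec["mixture"] = {
            "minor_species": s.mixture.minor_species,
            "major_species": s.mixture.major_species,
            "fraction": s.mixture.fraction,
        }
    return rec


def write_dataset(samples: list[Sample], out_dir: PathLike, truth: dict | None = None) -> Path:
    """Write per-sample feature CSVs plus a JSON manifest (and, separately,
    the ground-truth table when simulating — the pipeline never reads it)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for s in samples:
        fname = f"{s.id}.csv"
        write_feature_csv(s, out / fname)
        manifest.append(_sample_record(s, fname))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    if truth is not None:
        (out / "ground_truth.json").write_text(json.dumps(truth, indent=1) + "\n")
    return out / "manifest.json"


def read_dataset(manifest_path: PathLike) -> list[Sample]:
    manifest_path = Path(manifest_path)
    records = json.loads(manifest_path.read_text())
    samples = []
    for rec in records:
        mix = rec.get("mixture")
        samples.append(
            read_feature_csv(
                manifest_path.parent / rec["features"],
                id=rec["id"],
                species=rec["species"],
                producer=rec["producer"],
                batch=rec["batch"],
                role=rec["role"],
                mixture=MixtureSpec(**mix) if mix else None,
            )
        )
    return samples
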