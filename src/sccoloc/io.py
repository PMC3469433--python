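"""Reading and writing the package's on-disk formats.

SCTSV ("SC tab-separated values") is a small BED-like dialect for linear
SC stretches and the foci on them: one row per element, tab-separated,
with a required header ``stretch_id  element  start_um  end_um``.
``element`` is one of STRETCH, ZIP3, GFP, CEN. A STRETCH row encodes the
stretch length in ``end_um`` (with ``start_um = 0``); positions are
0-based continuous micrometres and intervals are closed.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .geometry import FocusInterval, Label, Stretch, StretchSet

SCTSV_COLUMNS = ["stretch_id", "element", "start_um", "end_um"]


def write_sctsv(data: StretchSet, path: str | Path) -> None:
    rows = []
    for s in data:
        rows.append((s.id, "STRETCH", 0.0, s.length))
        for z in s.zip3:
            rows.append((s.id, "ZIP3", z.start, z.end))
        for f in s.gfp:
            rows.append((s.id, "GFP", f.start, f.end))
        if s.cen is not None:
            rows.append((s.id, "CEN", s.cen.start, s.cen.end))
    df = pd.DataFrame(rows, columns=SCTSV_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_sctsv(path: str | Path, name: str | None = None) -> StretchSet:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SCTSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"SCTSV file {path} missing columns: {missing}")
    lengths: dict[str, float] = {}
    elements: dict[str, dict[str, list]] = {}
    for row in df.itertuples(index=False):
        sid = str(row.stretch_id)
        kind = str(row.element).upper()
        if kind == "STRETCH":
            lengths[sid] = float(row.end_um)
            elements.setdefault(sid, {"ZIP3": [], "GFP": [], "CEN": []})
        elif kind in ("ZIP3", "GFP", "CEN"):
            iv = FocusInterval(float(row.start_um), float(row.end_um), Label(kind))
            elements.setdefault(sid, {"ZIP3": [], "GFP": [], "CEN": []})[kind].append(iv)
        else:
            raise ValueError(f"SCTSV file {path}: unknown element {row.element!r}")
    stretches = []
    for sid, length in lengths.items():
        el = elements[sid]
        if len(el["CEN"]) > 1:
            raise ValueError(f"stretch {sid!r}: at most one CEN marker supported")
        stretches.append(
            Stretch(
                id=sid,
                length=length,
                zip3=el["ZIP3"],
                gfp=el["GFP"],
                cen=el["CEN"][0] if el["CEN"] else None,
            )
        )
    orphans = set(elements) - set(lengths)
    if orphans:
        raise ValueError(f"foci reference undeclared stretches: {sorted(orphans)}")
    return StretchSet(stretches, name=name or Path(path).stem)


def write_json_report(report: dict, path: str | Path) -> None:
    """Serialize a report deterministically (sorted keys, fixed float repr)."""
    Path(path).write_text(json.dumps(report, sort_keys=True, indent=2) + "\n")


def write_provenance(config: dict, seed: int, path: str | Path) -> None:
    """YAML sidecar recording how a generated dataset was produced."""
    from . import __version__

    doc = {"tool": "sccoloc", "version": __version__, "seed": int(seed),
           "config": config}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))
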