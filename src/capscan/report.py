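"""Report serialization: one TSV row per folding event plus a JSON document."""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .errors import DataError
from .geometry import SiteGeometry
from .screen import FoldingEvent, StateAssignment

SCHEMA_VERSION = 1

EVENT_COLUMNS = [
    "segment_start",
    "segment_end",
    "length",
    "helical_members",
    "disordered_members",
    "mean_dip",
    "p_value",
    "near_active_site",
    "active_site_distance",
]


def events_frame(events: Sequence[FoldingEvent]) -> pd.DataFrame:
    rows = [
        {
            "segment_start": ev.segment[0],
            "segment_end": ev.segment[1],
            "length": ev.length,
            "helical_members": ev.helical_members,
            "disordered_members": ev.disordered_members,
            "mean_dip": ev.mean_dip,
            "p_value": ev.p_value,
            "near_active_site": ev.near_active_site,
            "active_site_distance": ev.active_site_distance,
        }
        for ev in events
    ]
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def write_report(
    events: Sequence[FoldingEvent],
    states: Optional[StateAssignment],
    geometry: Optional[SiteGeometry],
    path: Union[str, os.PathLike],
    ss_tracks: Optional[dict[str, str]] = None,
    extras: Optional[dict] = None,
) -> dict[str, Path]:
    """Write ``events.tsv`` and ``report.json`` under ``path`` (a directory).

    The JSON document is self-describing and byte-deterministic for identical
    inputs (sorted keys, no timestamps).
    """
    out = Path(path)
    try:
        out.mkdir(parents=True, exist_ok=True)
        tsv_path = out / "events.tsv"
        events_frame(events).to_csv(tsv_path, sep="\t", index=False)

        doc: dict = {
            "schema_version": SCHEMA_VERSION,
            "events": json.loads(events_frame(events).to_json(orient="records")),
        }
        if states is not None:
            doc["states"] = {
                "labels": states.labels,
                "fractions": {
                    "folded": states.fractions[0],
                    "unfolded": states.fractions[1],
                    "alternative": states.fractions[2],
                },
                "displacement_threshold": states.displacement_threshold,
                "reference_member": states.reference_member,
            }
        if geometry is not None:
            doc["geometry"] = geometry.to_dict()
        if ss_tracks:
            doc["ss_tracks"] = ss_tracks
        if extras:
            doc.update(extras)
        json_path = out / "report.json"
        with open(json_path, "w") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except OSError as exc:
        raise DataError(f"cannot write report under {out}: {exc}") from exc
    return {"events_tsv": tsv_path, "report_json": json_path}


def read_report(path: Union[str, os.PathLike]) -> dict:
    """Load a previously written ``report.json``."""
    p = Path(path)
    if p.is_dir():
        p = p / "report.json"
    with open(p) as fh:
        return json.load(fh)
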