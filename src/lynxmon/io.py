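"""CSV readers and writers for the monitoring data families.

All formats are plain CSV with ISO-8601 dates and projected coordinates in
meters (the CRS is free-text metadata, never interpreted).  Each writer's
output round-trips losslessly through its reader.

Formats
-------
genotypes   ``individual_id,sample_date,group,destination,<locus>_a1,<locus>_a2,...``
            missing allele written as 0 (empty on read also accepted)
traps       ``session,trap_id,x,y,location_type,n_occasions_active``
detections  ``session,individual_id,sex,trap_id,occasion`` (long format)
tracks      ``animal_id,timestamp,x,y`` (Movebank-like)
periods     ``animal_id,group,start,end,end_status``
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .popgen import MISSING, GenotypeTable
from .predation import GpsTrack
from .scr import CaptureDataset, SessionData

__all__ = [
    "write_genotypes",
    "read_genotypes",
    "write_traps",
    "write_detections",
    "read_capture_data",
    "capture_dataset_from_frames",
    "write_tracks",
    "read_tracks",
    "write_periods",
    "read_periods",
]


# ---------------------------------------------------------------------------
# Genotypes


def write_genotypes(table: GenotypeTable, path: str | Path) -> None:
    out = table.meta.copy()
    out["sample_date"] = pd.to_datetime(out["sample_date"]).dt.strftime("%Y-%m-%d")
    for j, locus in enumerate(table.locus_names):
        out[f"{locus}_a1"] = table.genotypes[:, j, 0]
        out[f"{locus}_a2"] = table.genotypes[:, j, 1]
    out.to_csv(path, index=False)


def read_genotypes(path: str | Path) -> GenotypeTable:
    df = pd.read_csv(path)
    allele_cols = [c for c in df.columns if c.endswith("_a1")]
    loci = [c[:-3] for c in allele_cols]
    geno = np.zeros((len(df), len(loci), 2), dtype=np.int64)
    for j, locus in enumerate(loci):
        for k, suffix in enumerate(("_a1", "_a2")):
            col = pd.to_numeric(df[f"{locus}{suffix}"], errors="coerce")
            geno[:, j, k] = col.fillna(MISSING).astype(np.int64)
    meta = df[["individual_id", "sample_date", "group", "destination"]].copy()
    return GenotypeTable(meta, geno, loci)


# ---------------------------------------------------------------------------
# Capture-recapture


def write_traps(data: CaptureDataset, path: str | Path) -> None:
    rows = []
    for s in data.sessions:
        t = s.traps.copy()
        t.insert(0, "session", s.session)
        if "n_occasions_active" not in t.columns:
            t["n_occasions_active"] = s.n_occasions
        rows.append(t)
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def write_detections(data: CaptureDataset, path: str | Path) -> None:
    rows = []
    for s in data.sessions:
        trap_ids = s.traps["trap_id"].to_numpy()
        for i, (_, ind) in enumerate(s.individuals.iterrows()):
            jj, kk = np.nonzero(s.detections[i])
            for j, k in zip(jj, kk):
                rows.append(
                    {
                        "session": s.session,
                        "individual_id": ind["individual_id"],
                        "sex": ind["sex"],
                        "trap_id": trap_ids[j],
                        "occasion": int(k),
                    }
                )
    pd.DataFrame(
        rows, columns=["session", "individual_id", "sex", "trap_id", "occasion"]
    ).to_csv(path, index=False)


def capture_dataset_from_frames(
    traps: pd.DataFrame, detections: pd.DataFrame
) -> CaptureDataset:
    """Assemble a multi-session dataset from long-format frames."""
    sessions = []
    for sess in sorted(traps["session"].astype(str).unique()):
        t = traps[traps["session"].astype(str) == sess].reset_index(drop=True)
        det = detections[detections["session"].astype(str) == sess]
        inds = (
            det[["individual_id", "sex"]]
            .drop_duplicates("individual_id")
            .sort_values("individual_id", kind="mergesort")
            .reset_index(drop=True)
        )
        n_occ = int(t.get("n_occasions_active", pd.Series([1])).max())
        if len(det):
            n_occ = max(n_occ, int(det["occasion"].max()) + 1)
        arr = np.zeros((len(inds), len(t), n_occ), dtype=np.int8)
        trap_pos = {tid: j for j, tid in enumerate(t["trap_id"])}
        ind_pos = {iid: i for i, iid in enumerate(inds["individual_id"])}
        for _, row in det.iterrows():
            arr[ind_pos[row["individual_id"]], trap_pos[row["trap_id"]], int(row["occasion"])] = 1
        cols = ["trap_id", "x", "y"]
        for extra in ("location_type", "n_occasions_active"):
            if extra in t.columns:
                cols.append(extra)
        sessions.append(
            SessionData(
                session=sess,
                traps=t[cols],
                individuals=inds,
                n_occasions=n_occ,
                detections=arr,
            )
        )
    return CaptureDataset(sessions)


def read_capture_data(traps_path: str | Path, detections_path: str | Path) -> CaptureDataset:
    return capture_dataset_from_frames(
        pd.read_csv(traps_path), pd.read_csv(detections_path)
    )


# ---------------------------------------------------------------------------
# GPS tracks


def write_tracks(tracks: list[GpsTrack], path: str | Path) -> None:
    rows = []
    for tr in tracks:
        rows.append(
            pd.DataFrame(
                {
                    "animal_id": tr.animal_id,
                    "timestamp": tr.timestamps.strftime("%Y-%m-%dT%H:%M:%S"),
                    "x": tr.xy[:, 0],
                    "y": tr.xy[:, 1],
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_tracks(path: str | Path) -> list[GpsTrack]:
    df = pd.read_csv(path)
    return [
        GpsTrack.from_frame(df, animal_id=aid)
        for aid in df["animal_id"].astype(str).unique()
    ]


# ---------------------------------------------------------------------------
# Tracking periods


def write_periods(periods: pd.DataFrame, path: str | Path) -> None:
    out = periods.copy()
    for col in ("start", "end"):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_periods(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = ["animal_id", "group", "start", "end", "end_status"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"periods: missing required columns {missing}")
    for col in ("start", "end"):
        df[col] = pd.to_datetime(df[col])
    return df
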