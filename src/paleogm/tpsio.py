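"""Readers and writers for landmark data, manifests and score tables.

Two landmark interchange formats are supported:

* the TPS dialect: records of ``LM=k`` (2D) or ``LM3=k`` (3D) followed by
  k whitespace-separated coordinate rows, then ``ID=<specimen>`` and an
  optional ``SCALE=<factor>``; a missing landmark is coded by the sentinel
  row ``9999 9999`` (``9999 9999 9999`` in 3D);
* a long CSV format with columns ``specimen_id, landmark_index, x, y[, z],
  present``.

A specimen manifest CSV (columns ``specimen_id, group, side, latitude,
longitude, mis_group``) attaches metadata to configurations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .template import Configuration

MISSING_SENTINEL = 9999.0


class LandmarkFormatError(ValueError):
    pass


def _finish_record(records, coords, spec_id, scale, k, dim, line_no):
    if k is None:
        return
    if len(coords) != k:
        raise LandmarkFormatError(
            f"record {spec_id or '<unnamed>'!r}: expected {k} rows, got "
            f"{len(coords)} (near line {line_no})"
        )
    arr = np.asarray(coords, dtype=float) * scale
    present = ~np.all(np.isclose(np.asarray(coords), MISSING_SENTINEL), axis=1)
    arr[~present] = np.nan
    records.append(Configuration(
        specimen_id=spec_id or f"specimen_{len(records)}",
        coords=np.where(present[:, None], arr, 0.0),
        present=present,
    ))


def read_tps(path):
    """Read a TPS landmark file into a list of configurations."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    records, coords = [], []
    spec_id, scale, k, dim = None, 1.0, None, None
    first_dim = None
    for ln, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        upper = line.upper()
        if upper.startswith("LM3=") or upper.startswith("LM="):
            _finish_record(records, coords, spec_id, scale, k, dim, ln)
            dim = 3 if upper.startswith("LM3=") else 2
            try:
                k = int(line.split("=", 1)[1])
            except ValueError as exc:
                raise LandmarkFormatError(f"line {ln}: bad landmark count") from exc
            if first_dim is None:
                first_dim = dim
            elif dim != first_dim:
                raise LandmarkFormatError(
                    f"line {ln}: mixed 2D/3D records in one file"
                )
            coords, spec_id, scale = [], None, 1.0
        elif upper.startswith("ID="):
            spec_id = line.split("=", 1)[1].strip()
        elif upper.startswith("SCALE="):
            scale = float(line.split("=", 1)[1])
        elif upper.startswith("IMAGE=") or upper.startswith("CURVES=") \
                or upper.startswith("POINTS="):
            continue
        else:
            parts = line.split()
            if dim is None:
                raise LandmarkFormatError(f"line {ln}: coordinates before LM=")
            if len(parts) != dim:
                raise LandmarkFormatError(
                    f"line {ln}: expected {dim} coordinates, got {len(parts)}"
                )
            try:
                coords.append([float(p) for p in parts])
            except ValueError as exc:
                raise LandmarkFormatError(f"line {ln}: non-numeric row") from exc
    _finish_record(records, coords, spec_id, scale, k, dim, len(lines))
    _check_consistent(records)
    return records


def write_tps(configs, path, decimals=6):
    """Write configurations to the TPS dialect (missing landmarks as the
    9999 sentinel)."""
    with open(path, "w") as fh:
        for c in configs:
            tag = "LM3" if c.dim == 3 else "LM"
            fh.write(f"{tag}={c.k}\n")
            for i in range(c.k):
                if c.present[i]:
                    row = " ".join(f"{v:.{decimals}f}" for v in c.coords[i])
                else:
                    row = " ".join(f"{MISSING_SENTINEL:.{decimals}f}"
                                   for _ in range(c.dim))
                fh.write(row + "\n")
            fh.write(f"ID={c.specimen_id}\n")


def read_landmark_csv(path):
    """Read the long CSV landmark format into configurations."""
    df = pd.read_csv(path)
    needed = {"specimen_id", "landmark_index", "x", "y"}
    if not needed.issubset(df.columns):
        raise LandmarkFormatError(
            f"missing columns {sorted(needed - set(df.columns))}"
        )
    dim = 3 if "z" in df.columns else 2
    cols = ["x", "y", "z"][:dim]
    configs = []
    for spec_id, sub in df.groupby("specimen_id", sort=False):
        sub = sub.sort_values("landmark_index")
        if not np.array_equal(sub["landmark_index"].to_numpy(),
                              np.arange(len(sub))):
            raise LandmarkFormatError(
                f"specimen {spec_id!r}: landmark_index must be 0..k-1"
            )
        coords = sub[cols].to_numpy(dtype=float)
        present = (sub["present"].to_numpy(dtype=bool)
                   if "present" in sub.columns
                   else np.ones(len(sub), dtype=bool))
        coords = np.where(present[:, None], coords, 0.0)
        configs.append(Configuration(specimen_id=str(spec_id), coords=coords,
                                     present=present))
    _check_consistent(configs)
    return configs


def write_landmark_csv(configs, path, decimals=6):
    rows = []
    for c in configs:
        for i in range(c.k):
            row = {"specimen_id": c.specimen_id, "landmark_index": i}
            vals = c.coords[i] if c.present[i] else np.zeros(c.dim)
            for name, v in zip("xyz", vals):
                row[name] = round(float(v), decimals)
            row["present"] = int(c.present[i])
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_landmarks(path, format="tps"):
    """Dispatch on format: ``tps`` or ``csv``."""
    if format == "tps":
        return read_tps(path)
    if format == "csv":
        return read_landmark_csv(path)
    raise ValueError(f"unknown landmark format {format!r}")


def write_landmarks(configs, path, format="tps"):
    if format == "tps":
        return write_tps(configs, path)
    if format == "csv":
        return write_landmark_csv(configs, path)
    raise ValueError(f"unknown landmark format {format!r}")


def _check_consistent(configs):
    if not configs:
        raise LandmarkFormatError("no specimens in file")
    k, dim = configs[0].k, configs[0].dim
    for c in configs:
        if (c.k, c.dim) != (k, dim):
            raise LandmarkFormatError(
                f"specimen {c.specimen_id!r} has k={c.k}, dim={c.dim}; "
                f"expected k={k}, dim={dim}"
            )


def apply_manifest(configs, manifest_path):
    """Attach group/side/geography/chronology metadata from a manifest CSV."""
    df = pd.read_csv(manifest_path).set_index("specimen_id")
    for c in configs:
        if c.specimen_id not in df.index:
            continue
        row = df.loc[c.specimen_id]
        if "group" in row and not pd.isna(row["group"]):
            c.group = str(row["group"])
        if "side" in row and not pd.isna(row["side"]):
            c.side = str(row["side"])
        for key in ("latitude", "longitude", "mis_group"):
            if key in row and not pd.isna(row[key]):
                c.meta[key] = row[key]
    return configs


def write_manifest(configs, path):
    rows = []
    for c in configs:
        rows.append({
            "specimen_id": c.specimen_id,
            "group": c.group,
            "side": c.side,
            "latitude": c.meta.get("latitude", np.nan),
            "longitude": c.meta.get("longitude", np.nan),
            "mis_group": c.meta.get("mis_group", ""),
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_scores_csv(scores, path, labels=None, specimen_ids=None,
                     prefix="PC"):
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    df = pd.DataFrame(scores, columns=[f"{prefix}{j + 1}"
                                       for j in range(scores.shape[1])])
    if specimen_ids is not None:
        df.insert(0, "specimen_id", specimen_ids)
    if labels is not None:
        df.insert(1 if specimen_ids is not None else 0, "group", labels)
    df.to_csv(path, index=False)
    return df
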