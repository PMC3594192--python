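"""Plain-text I/O: the force-curve TSV dialect, event tables, ground-truth
sidecars and topograph grids.

Force-curve dialect: header lines starting ``#`` carrying ``key=value`` pairs
(curve_id, velocity_nm_s, dwell_s, spring_constant_pN_nm, sensitivity_nm_V),
then three tab-separated columns ``z_nm  f_approach_pN  f_retract_pN``.

Topograph grid: one header line ``rows cols pixel_size_nm`` followed by the
height matrix in nm, one image row per line.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .afm import Topograph
from .curves import ForceCurve, RuptureEvent
from .synthetic import GroundTruth

__all__ = [
    "write_force_curve",
    "read_force_curve",
    "write_curve_dir",
    "read_curve_dir",
    "write_events",
    "read_events",
    "write_ground_truth",
    "write_topograph",
    "read_topograph",
]

_HEADER_KEYS = ("curve_id", "velocity_nm_s", "dwell_s",
                "spring_constant_pN_nm", "sensitivity_nm_V")


def write_force_curve(curve: ForceCurve, path) -> None:
    meta = {
        "curve_id": curve.curve_id,
        "velocity_nm_s": curve.retract_velocity,
        "dwell_s": curve.dwell_time,
        "spring_constant_pN_nm": curve.metadata.get("spring_constant_pN_nm", ""),
        "sensitivity_nm_V": curve.metadata.get("sensitivity_nm_V", ""),
    }
    with open(path, "w") as fh:
        for key in _HEADER_KEYS:
            fh.write(f"# {key}={meta[key]}\n")
        fh.write("# z_nm\tf_approach_pN\tf_retract_pN\n")
        for z, fa, fr in zip(curve.z, curve.force_approach, curve.force_retract):
            fh.write(f"{z:.6g}\t{fa:.6g}\t{fr:.6g}\n")


def read_force_curve(path) -> ForceCurve:
    meta: dict = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
                continue
            rows.append([float(v) for v in line.split("\t")])
    arr = np.asarray(rows)
    md = {}
    if meta.get("spring_constant_pN_nm"):
        md["spring_constant_pN_nm"] = float(meta["spring_constant_pN_nm"])
    if meta.get("sensitivity_nm_V"):
        md["sensitivity_nm_V"] = float(meta["sensitivity_nm_V"])
    return ForceCurve(
        curve_id=meta.get("curve_id", Path(path).stem),
        z=arr[:, 0],
        force_approach=arr[:, 1],
        force_retract=arr[:, 2],
        retract_velocity=float(meta.get("velocity_nm_s", 400.0)),
        dwell_time=float(meta.get("dwell_s", 0.5)),
        metadata=md,
    )


def write_curve_dir(curves, directory) -> None:
    os.makedirs(directory, exist_ok=True)
    for c in curves:
        write_force_curve(c, Path(directory) / f"{c.curve_id}.tsv")


def read_curve_dir(directory) -> list[ForceCurve]:
    """Read every force-curve TSV in a directory (files opening with the
    ``# curve_id=`` header; sidecars such as ground-truth tables are skipped)."""
    curves = []
    for p in sorted(Path(directory).glob("*.tsv")):
        with open(p) as fh:
            if not fh.readline().startswith("# curve_id="):
                continue
        curves.append(read_force_curve(p))
    return curves


def write_events(events: list[RuptureEvent], path) -> None:
    df = pd.DataFrame([{
        "curve_id": e.curve_id,
        "rupture_force_pN": e.rupture_force,
        "rupture_distance_nm": e.rupture_distance,
        "Lc_nm": e.contour_length,
        "Lp_nm": e.persistence_length,
        "residual_pN": e.fit_residual,
        "specific": e.specific,
        "multiplicity": e.multiplicity,
    } for e in events])
    df.to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_ground_truth(truth: GroundTruth, path) -> None:
    df = pd.DataFrame([{
        "curve_id": c.curve_id,
        "n_events": c.n_events,
        "true_forces_pN": ";".join(f"{f:.4f}" for f in c.forces),
        "true_Lc_nm": ";".join(f"{l:.4f}" for l in c.contour_lengths),
    } for c in truth.curves])
    df.to_csv(path, sep="\t", index=False)


def write_topograph(topo: Topograph, path) -> None:
    ny, nx = topo.heights.shape
    with open(path, "w") as fh:
        fh.write(f"{ny} {nx} {topo.pixel_size:.6g}\n")
        np.savetxt(fh, topo.heights, fmt="%.5g")


def read_topograph(path) -> Topograph:
    with open(path) as fh:
        ny, nx, px = fh.readline().split()
        heights = np.loadtxt(fh)
    heights = heights.reshape(int(ny), int(nx))
    return Topograph(heights=heights, pixel_size=float(px))
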